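#!/usr/bin/env python
"""Site-arrangement statistics over planted and reconstructed regulons.

Measures the simulator's site-position distribution (fraction of centers
140-30 bp upstream of the start codon over ~10,000 sites), the pooled
intersite-distance histogram under 22-bp tandem spacing, the
autoregulation rate, and the palindrome census of the reconstructed motif
from 02_reconstruct_regulons.py.  Writes tables under results/.
"""

import argparse
import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from regulonkit.experiments import (
    simulator_contract_experiment,
    tandem_spacing_experiment,
)
from regulonkit.motif import read_meme
from regulonkit.stats import palindrome_census


def main() -> None:
    root = Path(__file__).resolve().parents[1]
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--run", type=Path, default=root / "results" / "reconstruction")
    parser.add_argument("--out", type=Path, default=root / "results")
    args = parser.parse_args()

    contract = simulator_contract_experiment(base_seed=args.seed)
    tandem22 = tandem_spacing_experiment(seed=args.seed + 1, spacing=22)
    tandem32 = tandem_spacing_experiment(seed=args.seed + 2, spacing=32)

    summary = {
        "n_sites": contract.n_sites,
        "fraction_core_minus140_minus30": round(contract.fraction_core, 4),
        "autoregulated_fraction": round(contract.autoregulated_fraction, 4),
        "autoregulation_target": contract.autoreg_target,
        "tandem22_pooled_mode_bp": tandem22,
        "tandem32_pooled_mode_bp": tandem32,
    }
    args.out.mkdir(parents=True, exist_ok=True)
    (args.out / "site_statistics.json").write_text(json.dumps(summary, indent=2) + "\n")
    print(json.dumps(summary, indent=2))

    meme = args.run / "motifs.meme"
    if meme.exists():
        census = palindrome_census(read_meme(meme))
        census.to_csv(args.out / "palindrome_census.tsv", sep="\t", index=False)
        print(census.to_string(index=False))
    else:
        print(f"(no reconstructed motif at {meme}; run 02_reconstruct_regulons.py first)")


if __name__ == "__main__":
    main()
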