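#!/usr/bin/env python
"""Reconstruct the regulog on the reference clade and score it against truth.

Loads the genomes written by 01_simulate_clade.py, runs the full pipeline
(orthology, operons, palindromic motif discovery on the TF's orthologous
promoters, thresholded scanning, consistency filtering, regulog assembly),
writes the run artifacts under results/reconstruction/, and prints recovery
metrics against the planted truth.
"""

import argparse
import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from regulonkit.cli import _load_genomes, _load_truth
from regulonkit.pipeline import PipelineParams, run_reconstruction, write_result
from regulonkit.synthetic_data import evaluate_recovery


def main() -> None:
    root = Path(__file__).resolve().parents[1]
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--sim", type=Path, default=root / "scratch" / "simulation")
    parser.add_argument("--out", type=Path, default=root / "results" / "reconstruction")
    args = parser.parse_args()

    genomes = _load_genomes(args.sim)
    truth = _load_truth(args.sim)
    params = PipelineParams(seed=args.seed)
    result = run_reconstruction(genomes, params)
    write_result(result, args.out, params)

    metrics = evaluate_recovery(truth, result.regulons, consensus=result.pwm.consensus)
    payload = {
        "consensus_recovered": result.pwm.consensus,
        "consensus_planted": truth.planted_consensus,
        "threshold_bits": round(float(result.pwm.threshold), 3),
        "n_regulons": result.regulog.n_regulons,
        "n_member_operons": result.regulog.n_operons,
        "n_sites": result.regulog.n_sites,
        "operon_precision": metrics.operon_precision,
        "operon_recall": metrics.operon_recall,
        "site_precision": metrics.site_precision,
        "site_recall": metrics.site_recall,
        "consensus_distance": metrics.consensus_distance,
    }
    (args.out / "evaluation.json").write_text(json.dumps(payload, indent=2) + "\n")
    print(json.dumps(payload, indent=2))


if __name__ == "__main__":
    main()
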