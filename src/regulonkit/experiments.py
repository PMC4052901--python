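"""Reproducible benchmark experiments over the simulator and pipeline.

These are the package's own validation studies: motif parameter recovery,
end-to-end regulon recovery with and without the cross-genome consistency
filter, and the simulator's statistical contracts (site-position fractions,
tandem spacing, autoregulation rate).  The analysis scripts, the test suite
and the reproduction script all call these functions, so the numbers they
report are always recomputed from scratch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_model import extract_promoter
from .motif import consensus_distance, discover_palindromic_motif
from .operons import operon_of_gene, predict_operons
from .pipeline import PipelineParams, run_reconstruction
from .stats import intersite_distances
from .synthetic_data import (
    GroundTruth,
    SimulationConfig,
    evaluate_recovery,
    simulate_pangenome,
)


def regulated_promoters(genomes, truth: GroundTruth):
    """Promoter windows of the planted regulated operons (TF's own excluded)."""
    promoters = []
    for genome in genomes:
        ops = predict_operons(genome)
        for first in sorted(truth.true_regulons[genome.genome_id]):
            if genome.gene(first).is_tf:
                continue
            op = operon_of_gene(ops, first)
            if op is None:
                continue
            anchor = genome.gene(op.first_gene_id)
            promoters.append(
                extract_promoter(genome, anchor, anchor_operon_id=op.operon_id)
            )
    return promoters


@dataclass
class MotifRecoveryResult:
    distances: list[int]
    widths: list[int]
    recovery_rate: float  # fraction of seeds with consensus distance <= 2


def motif_recovery_experiment(
    n_seeds: int = 50,
    base_seed: int = 0,
    n_regulated_operons: int = 8,
    motif_width: int = 18,
    conserved_fraction: float = 0.9,
) -> MotifRecoveryResult:
    """Parameter recovery: can discovery find a planted width-18 palindrome?

    Each replicate simulates 10 genomes with ``n_regulated_operons`` planted
    operons (per-position corruption 1 - ``conserved_fraction``), runs
    discovery on the regulated operons' promoter windows, and measures the
    best-alignment distance between the recovered and planted consensus
    (width differences count as mismatches).
    """
    distances, widths = [], []
    for k in range(n_seeds):
        seed = base_seed + k + 1
        genomes, truth = simulate_pangenome(
            SimulationConfig(
                seed=seed,
                n_regulated_operons=n_regulated_operons,
                motif_width=motif_width,
                motif_conserved_fraction=conserved_fraction,
            )
        )
        promoters = regulated_promoters(genomes, truth)
        result = discover_palindromic_motif(promoters, seed=seed)
        distances.append(consensus_distance(result.pwm.consensus, truth.planted_consensus))
        widths.append(result.pwm.width)
    rate = float(np.mean([d <= 2 for d in distances]))
    return MotifRecoveryResult(distances=distances, widths=widths, recovery_rate=rate)


@dataclass
class RegulonRecoveryResult:
    precisions: list[float]
    recalls: list[float]
    consensus_distances: list[int]
    pass_rate: float  # fraction of seeds with precision >= 0.9 and recall >= 0.9

    @property
    def mean_precision(self) -> float:
        return float(np.mean(self.precisions))

    @property
    def mean_recall(self) -> float:
        return float(np.mean(self.recalls))


def regulon_recovery_experiment(
    n_seeds: int = 25,
    base_seed: int = 0,
    min_genomes: int = 2,
) -> RegulonRecoveryResult:
    """End-to-end recovery on the default clade (decoys on, gene loss on).

    Runs the full pipeline per replicate and scores operon-membership
    precision/recall against the planted truth.  ``min_genomes=1`` disables
    the cross-genome consistency filter's effect, which is the control arm
    for measuring filter efficacy.
    """
    precisions, recalls, cds = [], [], []
    for k in range(n_seeds):
        seed = base_seed + k + 1
        genomes, truth = simulate_pangenome(SimulationConfig(seed=seed))
        result = run_reconstruction(
            genomes, PipelineParams(seed=seed, min_genomes=min_genomes)
        )
        metrics = evaluate_recovery(
            truth, result.regulons, consensus=result.pwm.consensus
        )
        precisions.append(metrics.operon_precision if metrics.operon_precision is not None else 0.0)
        recalls.append(metrics.operon_recall if metrics.operon_recall is not None else 0.0)
        cds.append(metrics.consensus_distance)
    pass_rate = float(
        np.mean([(p >= 0.9 and r >= 0.9) for p, r in zip(precisions, recalls)])
    )
    return RegulonRecoveryResult(
        precisions=precisions, recalls=recalls, consensus_distances=cds,
        pass_rate=pass_rate,
    )


@dataclass
class SimulatorContractResult:
    n_sites: int
    fraction_core: float  # site centers in [-140, -30]
    n_genomes: int
    autoregulated_fraction: float
    autoreg_target: float
    binomial_halfwidth: float  # 95% CI half-width at the configured rate


def simulator_contract_experiment(
    base_seed: int = 0,
    n_sims: int = 10,
    n_genomes: int = 25,
    n_regulated_operons: int = 40,
) -> SimulatorContractResult:
    """Measure the simulator's statistical contracts over ~10,000 sites.

    Checks that planted site centers fall in the core window [-140, -30] at
    the configured 75% rate and that the autoregulation frequency matches
    the configured 72% within binomial error.
    """
    offsets = []
    auto_n = 0
    total_genomes = 0
    cfg0 = SimulationConfig()
    for k in range(n_sims):
        cfg = SimulationConfig(
            seed=base_seed + k + 1,
            n_genomes=n_genomes,
            n_genes=3 * n_regulated_operons + 20,
            n_regulated_operons=n_regulated_operons,
        )
        genomes, truth = simulate_pangenome(cfg)
        offsets.extend(s.offset_center for s in truth.planted_sites)
        auto = {
            s.genome_id for s in truth.planted_sites if s.kind == "autoregulation"
        }
        with_tf = set(truth.tf_genes)
        auto_n += len(auto & with_tf)
        total_genomes += len(with_tf)
    arr = np.asarray(offsets)
    lo, hi = cfg0.site_core_window
    frac_core = float(((arr >= lo) & (arr <= hi)).mean())
    p = cfg0.autoregulation_prob
    halfwidth = 1.96 * float(np.sqrt(p * (1 - p) / total_genomes))
    return SimulatorContractResult(
        n_sites=len(arr),
        fraction_core=frac_core,
        n_genomes=total_genomes,
        autoregulated_fraction=auto_n / total_genomes,
        autoreg_target=p,
        binomial_halfwidth=halfwidth,
    )


def tandem_spacing_experiment(seed: int = 1, spacing: int = 22) -> float | None:
    """Pooled intersite-distance mode for a tandem-site simulation."""
    cfg = SimulationConfig(seed=seed, sites_per_operon=2, tandem_spacing=spacing)
    _, truth = simulate_pangenome(cfg)
    from .motif import SiteInstance

    sites = [
        SiteInstance(
            contig_id=s.contig_id,
            interval=s.interval,
            strand=s.strand,
            sequence=s.sequence,
            score=0.0,
            offset_center=s.offset_center,
            offset_end=0,
            anchor_operon_id=s.anchor_operon_id,
            genome_id=s.genome_id,
        )
        for s in truth.planted_sites
    ]
    return intersite_distances(sites).mode()
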