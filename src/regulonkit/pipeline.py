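"""End-to-end regulon reconstruction over a clade of annotated genomes.

Stage order: orthology -> layout operons -> motif discovery on the TF's own
orthologous promoters (phylogenetic footprinting: autoregulatory sites seed
the training set) -> threshold -> genome-wide scan -> operon re-split on
internal sites -> cross-genome consistency filter -> optional refinement
round (PWM rebuilt from the retained sites, rescanned) -> regulog assembly.

All randomness flows from a single root seed; a fixed config yields
byte-identical tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .core_model import Genome, extract_promoter, write_bed6, DEFAULT_PROMOTER_WINDOW
from .motif import (
    DiscoveryResult,
    PWM,
    build_pwm,
    discover_palindromic_motif,
    training_threshold,
    write_meme,
)
from .operons import Operon, operon_of_gene, predict_operons
from .orthology import (
    OrthologGroup,
    bidirectional_best_hits,
    build_ortholog_groups,
    pairwise_similarity,
)
from .reconstruction import (
    Regulog,
    Regulon,
    assemble_regulog,
    classify_regulon,
    consistency_filter,
    detect_autoregulation,
    reconstruct_regulon,
)

logger = logging.getLogger("regulonkit")


@dataclass
class PipelineParams:
    """Stage parameters of the reconstruction pipeline."""

    window: tuple[int, int] = DEFAULT_PROMOTER_WINDOW
    width_range: tuple[int, int] = (14, 24)
    restarts: int = 2
    pseudocount: float = 0.5
    max_gap: int = 100
    min_genomes: int = 2
    tau: float = 0.8
    similarity_method: str = "kmer"
    kmer_size: int = 4
    refine_rounds: int = 2
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.width_range
        if not (2 <= lo <= hi):
            raise ValueError(f"invalid width_range {self.width_range}")
        if self.window[0] >= self.window[1]:
            raise ValueError(f"invalid promoter window {self.window}")
        if self.max_gap < 0 or self.min_genomes < 1 or self.restarts < 1:
            raise ValueError("max_gap >= 0, min_genomes >= 1, restarts >= 1 required")
        if not 0.0 <= self.tau <= 1.0:
            raise ValueError(f"tau must be in [0, 1], got {self.tau}")


@dataclass
class PipelineResult:
    pwm: PWM
    discovery: DiscoveryResult
    regulons: list[Regulon]  # after consistency filtering
    candidate_regulons: list[Regulon]  # before filtering (last round)
    regulog: Regulog
    ortholog_groups: list[OrthologGroup]
    gene_to_group: dict[str, str]
    operons_by_genome: dict[str, list[Operon]]
    tf_group_id: str


def compute_orthology(
    genomes: Sequence[Genome], params: PipelineParams
) -> tuple[list[OrthologGroup], dict[str, str]]:
    """BBH over all genome pairs, then connected components."""
    pairs: set[tuple[str, str]] = set()
    for i, ga in enumerate(genomes):
        for gb in genomes[i + 1 :]:
            ab = pairwise_similarity(
                ga.proteins, gb.proteins, method=params.similarity_method,
                k=params.kmer_size, genome_a=ga.genome_id, genome_b=gb.genome_id,
            )
            ba = pairwise_similarity(
                gb.proteins, ga.proteins, method=params.similarity_method,
                k=params.kmer_size, genome_a=gb.genome_id, genome_b=ga.genome_id,
            )
            pairs |= bidirectional_best_hits(ab, ba)
    all_genes = [g.gene_id for genome in genomes for g in genome.genes]
    tf_genes = [g.gene_id for genome in genomes for g in genome.tf_genes]
    groups = build_ortholog_groups(pairs, all_genes, tf_genes)
    gene_to_group = {m: grp.group_id for grp in groups for m in grp.members}
    return groups, gene_to_group


def tf_promoters(
    genomes: Sequence[Genome],
    operons_by_genome: Mapping[str, Sequence[Operon]],
    window: tuple[int, int] = DEFAULT_PROMOTER_WINDOW,
):
    """Promoter windows of the operons containing each genome's TF gene."""
    promoters = []
    for genome in genomes:
        for tf in genome.tf_genes:
            op = operon_of_gene(operons_by_genome[genome.genome_id], tf.gene_id)
            if op is None:
                continue
            anchor = genome.gene(op.first_gene_id)
            promoters.append(
                extract_promoter(genome, anchor, window, anchor_operon_id=op.operon_id)
            )
    return promoters


def _scan_round(
    genomes: Sequence[Genome],
    pwm: PWM,
    params: PipelineParams,
) -> tuple[list[Regulon], dict[str, list[Operon]]]:
    """Scan all genomes with a two-pass operon prediction.

    Pass 1 predicts operons from layout alone; after scanning, operons are
    re-split at internal intergenic gaps that contain predicted sites, and
    the scan is repeated on the final operon set.
    """
    regulons = []
    operons_final: dict[str, list[Operon]] = {}
    for genome in genomes:
        tf = genome.tf_genes[0] if genome.tf_genes else None
        ops = predict_operons(genome, max_gap=params.max_gap)
        candidate = reconstruct_regulon(tf, pwm, genome, ops, params.window)
        sites = candidate.all_sites
        ops2 = predict_operons(genome, internal_sites=sites, max_gap=params.max_gap)
        candidate = reconstruct_regulon(tf, pwm, genome, ops2, params.window)
        regulons.append(candidate)
        operons_final[genome.genome_id] = ops2
    return regulons, operons_final


def _footprint_training(
    genomes: Sequence[Genome],
    pwm: PWM,
    signatures: set[str],
    operons_by_genome: Mapping[str, Sequence[Operon]],
    gene_to_group: Mapping[str, str],
    params: PipelineParams,
) -> list[str]:
    """Best promoter window per genome for each retained ortholog-operon,
    accepted above the PWM's background detection floor."""
    from .motif import _window_scores, detection_floor, encode

    # total windows scanned across all operon promoters in the clade
    window_len = params.window[1] - params.window[0]
    n_windows = sum(
        len(ops) * max(window_len - pwm.width + 1, 1)
        for ops in operons_by_genome.values()
    )
    floor = detection_floor(pwm, n_windows, expected_false=1.0)
    training: list[str] = []
    for genome in genomes:
        for op in operons_by_genome[genome.genome_id]:
            sig = gene_to_group.get(op.first_gene_id, f"singleton:{op.first_gene_id}")
            if sig not in signatures:
                continue
            anchor = genome.gene(op.first_gene_id)
            region = extract_promoter(
                genome, anchor, params.window, anchor_operon_id=op.operon_id
            )
            scores = _window_scores(pwm.log_odds, encode(region.sequence))
            if len(scores) == 0 or np.all(np.isnan(scores)):
                continue
            best = np.nanmax(scores)
            if best >= floor:
                j = int(np.nanargmax(scores))
                training.append(region.sequence[j : j + pwm.width])
    return sorted(set(training))


def run_reconstruction(
    genomes: Sequence[Genome], params: PipelineParams | None = None
) -> PipelineResult:
    """Full pipeline from annotated genomes to an assembled regulog."""
    params = params or PipelineParams()
    params.validate()
    t0 = time.perf_counter()
    groups, gene_to_group = compute_orthology(genomes, params)
    logger.info("orthology: %d groups (%.1fs)", len(groups), time.perf_counter() - t0)

    layout_ops = {
        g.genome_id: predict_operons(g, max_gap=params.max_gap) for g in genomes
    }
    promoters = tf_promoters(genomes, layout_ops, params.window)
    if len(promoters) < 2:
        raise ValueError(
            "need TF annotations in at least 2 genomes to seed motif discovery"
        )
    discovery = discover_palindromic_motif(
        promoters,
        width_range=params.width_range,
        restarts=params.restarts,
        seed=params.seed,
        pseudocount=params.pseudocount,
    )
    pwm = discovery.pwm
    logger.info(
        "discovery: width=%d consensus=%s IC/col=%.2f threshold=%.2f%s",
        pwm.width, pwm.consensus, discovery.mean_ic_per_column,
        pwm.threshold, " (low confidence)" if discovery.low_confidence else "",
    )

    candidates, operons_by_genome = _scan_round(genomes, pwm, params)
    filtered = consistency_filter(candidates, gene_to_group, params.min_genomes)

    # Refinement by phylogenetic footprint completion: every ortholog-operon
    # retained by the consistency check contributes its best-scoring promoter
    # window in EVERY genome where the operon exists, accepted when the score
    # clears a background floor (expected <= 1 false window per clade scan,
    # from the PWM's exact null distribution).  This grows the training set
    # with the weaker orthologous sites the initial threshold missed; the
    # detection threshold stays the minimum over the training set.
    for _ in range(params.refine_rounds):
        signatures = {
            gene_to_group.get(m.operon.first_gene_id, f"singleton:{m.operon.first_gene_id}")
            for r in filtered
            for m in r.members
        }
        if not signatures:
            break
        training = _footprint_training(
            genomes, pwm, signatures, operons_by_genome, gene_to_group, params
        )
        if len(training) < 2:
            break
        new_pwm = build_pwm(training, pseudocount=params.pseudocount, symmetrize=True)
        training_threshold(new_pwm, training)
        pwm = new_pwm
        candidates, operons_by_genome = _scan_round(genomes, pwm, params)
        filtered = consistency_filter(candidates, gene_to_group, params.min_genomes)

    for reg in filtered:
        ops = operons_by_genome[reg.genome_id]
        reg.autoregulated = (
            detect_autoregulation(reg, ops) if reg.tf_gene_id else False
        )
        reg.classification = classify_regulon(reg)

    tf_groups = [g for g in groups if g.is_tf_group]
    tf_group_id = tf_groups[0].group_id if tf_groups else "TF"
    regulog = assemble_regulog(tf_group_id, filtered)
    if regulog.merged_motif is not None:
        regulog.merged_motif.name = tf_group_id
    logger.info(
        "reconstruction: %d regulons, %d operons, %d sites (%.1fs)",
        regulog.n_regulons, regulog.n_operons, regulog.n_sites,
        time.perf_counter() - t0,
    )
    return PipelineResult(
        pwm=pwm,
        discovery=discovery,
        regulons=filtered,
        candidate_regulons=candidates,
        regulog=regulog,
        ortholog_groups=groups,
        gene_to_group=gene_to_group,
        operons_by_genome=operons_by_genome,
        tf_group_id=tf_group_id,
    )


# ---------------------------------------------------------------------------
# Tabular serialization of results
# ---------------------------------------------------------------------------


def sites_table(regulons: Sequence[Regulon]) -> pd.DataFrame:
    rows = []
    for reg in regulons:
        for m in reg.members:
            for s in m.sites:
                rows.append(
                    {
                        "genome_id": reg.genome_id,
                        "contig_id": s.contig_id,
                        "start": s.interval[0],
                        "end": s.interval[1],
                        "strand": s.strand,
                        "score": round(s.score, 4),
                        "sequence": s.sequence,
                        "offset_center": s.offset_center,
                        "offset_end": s.offset_end,
                        "operon_id": m.operon.operon_id,
                        "first_gene_id": m.operon.first_gene_id,
                    }
                )
    df = pd.DataFrame(
        rows,
        columns=[
            "genome_id", "contig_id", "start", "end", "strand", "score",
            "sequence", "offset_center", "offset_end", "operon_id", "first_gene_id",
        ],
    )
    return df.sort_values(
        ["genome_id", "contig_id", "start", "operon_id"]
    ).reset_index(drop=True)


def regulons_table(regulons: Sequence[Regulon]) -> pd.DataFrame:
    rows = []
    for reg in regulons:
        for m in reg.members:
            rows.append(
                {
                    "genome_id": reg.genome_id,
                    "tf_gene_id": reg.tf_gene_id,
                    "operon_id": m.operon.operon_id,
                    "first_gene_id": m.operon.first_gene_id,
                    "strand": m.operon.strand,
                    "n_genes": m.operon.n_genes,
                    "gene_ids": ",".join(m.operon.gene_ids),
                    "n_sites": len(m.sites),
                    "autoregulated": reg.autoregulated,
                    "classification": reg.classification,
                }
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "genome_id", "tf_gene_id", "operon_id", "first_gene_id", "strand",
            "n_genes", "gene_ids", "n_sites", "autoregulated", "classification",
        ],
    )
    return df.sort_values(["genome_id", "operon_id"]).reset_index(drop=True)


def operons_table(operons_by_genome: Mapping[str, Sequence[Operon]]) -> pd.DataFrame:
    rows = [
        {
            "genome_id": gid,
            "operon_id": op.operon_id,
            "contig_id": op.contig_id,
            "strand": op.strand,
            "n_genes": op.n_genes,
            "gene_ids": ",".join(op.gene_ids),
            "cross_genome_support": op.cross_genome_support,
        }
        for gid in sorted(operons_by_genome)
        for op in operons_by_genome[gid]
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "genome_id", "operon_id", "contig_id", "strand", "n_genes",
            "gene_ids", "cross_genome_support",
        ],
    )


def write_result(result: PipelineResult, outdir: str | Path, params: PipelineParams) -> None:
    """Write all stage outputs plus a content-hashed manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sites = sites_table(result.regulons)
    sites.to_csv(outdir / "sites.tsv", sep="\t", index=False)
    write_bed6(
        (
            (r.contig_id, int(r.start), int(r.end), r.operon_id, float(r.score), r.strand)
            for r in sites.itertuples()
        ),
        outdir / "sites.bed",
    )
    regulons_table(result.regulons).to_csv(outdir / "regulons.tsv", sep="\t", index=False)
    operons_table(result.operons_by_genome).to_csv(
        outdir / "operons.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        [
            {"gene_id": m, "group_id": g.group_id, "is_tf_group": g.is_tf_group}
            for g in result.ortholog_groups
            for m in sorted(g.members)
        ]
    ).to_csv(outdir / "ortholog_groups.tsv", sep="\t", index=False)
    motifs = [result.pwm]
    if result.regulog.merged_motif is not None:
        motifs.append(result.regulog.merged_motif)
    write_meme(motifs, outdir / "motifs.meme")
    from .motif import pwm_to_table

    pwm_to_table(result.pwm).round(6).to_csv(outdir / "motif_frequencies.tsv", sep="\t")
    from . import __version__

    config_dict = asdict(params)
    manifest = {
        "regulonkit_version": __version__,
        "config": config_dict,
        "config_sha256": hashlib.sha256(
            yaml.safe_dump(config_dict, sort_keys=True).encode()
        ).hexdigest(),
        "seed": params.seed,
        "tf_group": result.tf_group_id,
        "consensus": result.pwm.consensus,
        "threshold_bits": round(float(result.pwm.threshold), 6),
        "n_regulons": result.regulog.n_regulons,
        "n_operons": result.regulog.n_operons,
        "n_genes": result.regulog.n_genes,
        "n_sites": result.regulog.n_sites,
        "autoregulated": sum(r.autoregulated for r in result.regulons),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
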