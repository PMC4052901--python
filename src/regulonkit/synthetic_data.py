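"""Seeded simulator for clades of related genomes with planted regulons.

The generator emulates the situation the reconstruction pipeline is built
for: a set of N related bacterial genomes sharing orthologous gene
complements (with gene-loss noise), one transcription factor (TF) per
genome, and a palindromic binding motif (even width, central CG consensus)
planted upstream of a fixed set of regulated operons.  Site centers
concentrate 140-30 bp upstream of the start codon (75% by default), the TF
autoregulates its own operon with probability 0.72, and optional tandem
sites sit at a fixed center-to-center spacing (22 or 32 bp are the
biologically observed helical-period values).  Near-threshold palindromic
decoys planted independently per genome exercise the cross-genome
consistency filter.

Background sequence is i.i.d. at the configured GC content; orthologous
proteins differ only by substitutions from a common ancestor (no indels).
Everything is driven by one integer-seeded generator, so a fixed seed gives
byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core_model import Gene, Genome, reverse_complement, write_genome
from .motif import PWM, build_pwm, score_site, training_threshold

_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class SimulationConfig:
    """Knobs of the pangenome simulator; defaults are the study conditions."""

    n_genomes: int = 10
    n_genes: int = 60
    gene_length_mean: int = 750
    gene_length_jitter: int = 400  # group lengths ~ U(mean - j/2, mean + j/2)
    operon_size_range: tuple[int, int] = (1, 4)
    intra_operon_gap: tuple[int, int] = (20, 80)  # <= 100 so layout merges
    inter_operon_gap: tuple[int, int] = (260, 450)  # > 100 and room for sites
    # Upstream gap of operons that receive sites.  Promoter windows reach
    # 400 bp past a divergent neighbor's start codon, so gaps of at least
    # ~650 bp keep each planted site inside exactly one promoter window
    # (shared divergon sites are exercised by dedicated fixtures instead).
    regulated_upstream_gap: tuple[int, int] = (660, 900)
    contig_length: int | None = None  # None: sized to fit the layout
    motif_width: int = 18
    central_pair: str = "CG"
    motif_conserved_fraction: float = 0.9
    n_regulated_operons: int = 6
    sites_per_operon: int = 1
    site_core_fraction: float = 0.75  # site centers in the core window
    site_core_window: tuple[int, int] = (-140, -30)
    site_offcore_windows: tuple[tuple[int, int], ...] = ((-220, -141), (-29, -15))
    tandem_spacing: int | None = None  # center-to-center bp for extra sites
    autoregulation_prob: float = 0.72
    gene_loss_rate: float = 0.05
    decoy_rate: float = 2.0
    protein_mutation_rate: float = 0.10
    gc_content: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "motif_conserved_fraction",
            "site_core_fraction",
            "autoregulation_prob",
            "gene_loss_rate",
            "protein_mutation_rate",
            "gc_content",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 14 <= self.motif_width <= 24:
            raise ValueError(f"motif_width must be in [14, 24], got {self.motif_width}")
        if self.n_genomes < 1 or self.n_genes < 2:
            raise ValueError("need at least 1 genome and 2 genes")
        if self.sites_per_operon < 1:
            raise ValueError("sites_per_operon must be >= 1")


@dataclass
class PlantedSite:
    genome_id: str
    contig_id: str
    interval: tuple[int, int]
    strand: str
    anchor_operon_id: str
    anchor_first_gene: str
    offset_center: float  # oriented center offset from the start codon
    sequence: str  # oriented 5'->3' with respect to the anchor
    kind: str  # regulated | autoregulation | tandem | decoy


@dataclass
class GroundTruth:
    """Machine-readable record of everything the simulator planted."""

    planted_consensus: str
    planted_sites: list[PlantedSite]
    decoy_sites: list[PlantedSite]
    true_regulons: dict[str, set[str]]  # genome -> first-gene ids of regulated operons
    orthology_map: dict[str, str]  # gene_id -> ortholog group label
    tf_genes: dict[str, str]  # genome -> TF gene id
    pwm: PWM | None = None  # PWM over the planted (corrupted) sites
    config: SimulationConfig | None = None

    def sites_frame(self) -> pd.DataFrame:
        rows = [
            {
                "genome_id": s.genome_id,
                "contig_id": s.contig_id,
                "start": s.interval[0],
                "end": s.interval[1],
                "strand": s.strand,
                "anchor_operon_id": s.anchor_operon_id,
                "anchor_first_gene": s.anchor_first_gene,
                "offset_center": s.offset_center,
                "sequence": s.sequence,
                "kind": s.kind,
            }
            for s in self.planted_sites + self.decoy_sites
        ]
        return pd.DataFrame(rows)


def generate_palindromic_consensus(
    width: int, central_pair: str = "CG", seed: int | np.random.Generator = 0
) -> str:
    """Random even-width palindromic consensus with a fixed central pair.

    The string equals its own reverse complement; for the default central
    pair the two middle bases are C and G.  Odd widths are rejected: a DNA
    base cannot be its own complement, so an exact odd palindrome with a
    defined unpaired center does not exist.
    """
    if width % 2 != 0:
        raise ValueError(
            f"width {width} is odd: an exact palindrome needs paired centers"
        )
    if len(central_pair) != 2 or reverse_complement(central_pair) != central_pair:
        raise ValueError(
            f"central pair {central_pair!r} must be a self-complementary dinucleotide"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    half = width // 2
    left = list(rng.choice(list("ACGT"), size=half))
    left[-1] = central_pair[0]
    left_str = "".join(left)
    return left_str + reverse_complement(left_str)


def _corrupt(consensus: str, keep_prob: float, rng: np.random.Generator) -> str:
    out = []
    for base in consensus:
        if rng.random() < keep_prob:
            out.append(base)
        else:
            out.append(rng.choice([b for b in "ACGT" if b != base]))
    return "".join(out)


def _random_background(n: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=n, p=p)


def _mutate_protein(seq: str, rate: float, rng: np.random.Generator) -> str:
    out = []
    for aa in seq:
        if rng.random() < rate:
            out.append(_AA[rng.integers(len(_AA))])
        else:
            out.append(aa)
    return "".join(out)


def _near_threshold_decoy(
    consensus: str, pwm: PWM, threshold: float, rng: np.random.Generator
) -> str:
    """Palindromic string scoring within about 1 bit of the threshold.

    Starts from the consensus and walks down by mutating complementary base
    pairs, rejecting moves that would drop more than 1 bit below threshold.
    """
    w = len(consensus)
    current = list(consensus)
    score = score_site(pwm, "".join(current))
    for _ in range(300):
        if score <= threshold + 1.0:
            break
        i = int(rng.integers(w // 2))
        j = w - 1 - i
        old_i, old_j = current[i], current[j]
        new_i = rng.choice([b for b in "ACGT" if b != old_i])
        current[i] = new_i
        current[j] = reverse_complement(new_i)
        new_score = score_site(pwm, "".join(current))
        if new_score < threshold - 1.0:
            current[i], current[j] = old_i, old_j
        else:
            score = new_score
    return "".join(current)


def _draw_offset(cfg: SimulationConfig, rng: np.random.Generator) -> int:
    """Site-center offset from the start codon (negative = upstream)."""
    if rng.random() < cfg.site_core_fraction:
        lo, hi = cfg.site_core_window
        return int(rng.integers(lo, hi + 1))
    spans = cfg.site_offcore_windows
    widths = np.array([hi - lo + 1 for lo, hi in spans], dtype=float)
    k = int(rng.choice(len(spans), p=widths / widths.sum()))
    lo, hi = spans[k]
    return int(rng.integers(lo, hi + 1))


@dataclass
class _PanOperon:
    index: int
    groups: list[str]  # ortholog group labels, 5'->3'
    strand: str
    regulated: bool
    is_tf_operon: bool
    pathway: str


def _plan_pangenome(cfg: SimulationConfig, rng: np.random.Generator):
    """Shared clade-level layout: operon structure, strands, gene lengths."""
    sizes: list[int] = []
    remaining = cfg.n_genes - 1  # one gene reserved for the TF operon
    lo, hi = cfg.operon_size_range
    while remaining > 0:
        s = int(rng.integers(lo, hi + 1))
        sizes.append(min(s, remaining))
        remaining -= sizes[-1]
    n_ops = len(sizes)
    if cfg.n_regulated_operons > n_ops:
        raise ValueError(
            f"n_regulated_operons={cfg.n_regulated_operons} exceeds the "
            f"{n_ops} operons implied by the gene layout"
        )
    regulated = set(rng.choice(n_ops, size=cfg.n_regulated_operons, replace=False).tolist())
    tf_position = int(rng.integers(n_ops + 1))
    pathways = ["fructose_utilization", "ribose_utilization", "maltose_utilization"]
    operons: list[_PanOperon] = []
    gi = 0
    reg_seen = 0
    for k, size in enumerate(sizes):
        if k == tf_position:
            operons.append(
                _PanOperon(
                    index=len(operons),
                    groups=["og_tf"],
                    strand="+" if rng.random() < 0.5 else "-",
                    regulated=False,
                    is_tf_operon=True,
                    pathway="regulation",
                )
            )
        is_reg = k in regulated
        pw = pathways[reg_seen % len(pathways)] if is_reg else "housekeeping"
        if is_reg:
            reg_seen += 1
        operons.append(
            _PanOperon(
                index=len(operons),
                groups=[f"og_{gi + j:03d}" for j in range(size)],
                strand="+" if rng.random() < 0.5 else "-",
                regulated=is_reg,
                is_tf_operon=False,
                pathway=pw,
            )
        )
        gi += size
    if tf_position == n_ops:
        operons.append(
            _PanOperon(
                index=len(operons),
                groups=["og_tf"],
                strand="+" if rng.random() < 0.5 else "-",
                regulated=False,
                is_tf_operon=True,
                pathway="regulation",
            )
        )
    # re-number indices after insertion
    for i, op in enumerate(operons):
        op.index = i
    all_groups = [g for op in operons for g in op.groups]
    jit = cfg.gene_length_jitter
    lengths = {
        g: 3 * int(rng.integers((cfg.gene_length_mean - jit // 2) // 3,
                                (cfg.gene_length_mean + jit // 2) // 3 + 1))
        for g in all_groups
    }
    ancestors = {
        g: "".join(rng.choice(list(_AA), size=max(lengths[g] // 3 - 1, 30)))
        for g in all_groups
    }
    return operons, lengths, ancestors


def simulate_pangenome(config: SimulationConfig) -> tuple[list[Genome], GroundTruth]:
    """Generate the clade and its ground truth.  Deterministic per seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    operons, lengths, ancestors = _plan_pangenome(config, rng)
    consensus = generate_palindromic_consensus(
        config.motif_width, config.central_pair, rng
    )
    w = config.motif_width

    genome_parts: list[tuple[str, list[Gene], dict[str, str]]] = []
    planted: list[PlantedSite] = []
    truth_regulons: dict[str, set[str]] = {}
    orthology: dict[str, str] = {}
    tf_genes: dict[str, str] = {}
    # Deferred decoy placements: (genome index, contig array, anchor info)
    pending_decoys: list[tuple[int, dict]] = []
    arrays: list[np.ndarray] = []

    for gidx in range(config.n_genomes):
        genome_id = f"g{gidx:02d}"
        present = {
            g: (rng.random() >= config.gene_loss_rate)
            for op in operons
            for g in op.groups
        }
        # ----- layout -----
        pos = 0
        genes: list[Gene] = []
        placements: list[tuple[_PanOperon, list[Gene]]] = []
        prev_op: _PanOperon | None = None

        def _upstream_gap(current: _PanOperon | None, previous: _PanOperon | None) -> int:
            wide = False
            if current is not None and (current.regulated or current.is_tf_operon) \
                    and current.strand == "+":
                wide = True
            if previous is not None and (previous.regulated or previous.is_tf_operon) \
                    and previous.strand == "-":
                wide = True
            rng_range = config.regulated_upstream_gap if wide else config.inter_operon_gap
            return int(rng.integers(*rng_range))

        for op in operons:
            groups_here = [g for g in op.groups if present[g]]
            if not groups_here:
                continue
            pos += _upstream_gap(op, prev_op)
            prev_op = op
            ordered = groups_here if op.strand == "+" else list(reversed(groups_here))
            placed: list[Gene] = []
            for k, grp in enumerate(ordered):
                if k > 0:
                    pos += int(rng.integers(*config.intra_operon_gap))
                gene = Gene(
                    gene_id=f"{genome_id}_{grp}",
                    contig_id="chr",
                    start=pos,
                    end=pos + lengths[grp],
                    strand=op.strand,
                    locus_tag=f"{genome_id}_{grp}",
                    function_label=op.pathway,
                    is_tf=(grp == "og_tf"),
                )
                placed.append(gene)
                genes.append(gene)
                orthology[gene.gene_id] = grp
                pos = gene.end
            # 5'-most first
            placed_coding = placed if op.strand == "+" else list(reversed(placed))
            placements.append((op, placed_coding))
        pos += _upstream_gap(None, prev_op)
        required = pos
        if config.contig_length is not None and required > config.contig_length:
            raise ValueError(
                f"infeasible layout: genome {genome_id} needs {required} bp "
                f"but contig_length={config.contig_length}"
            )
        total = config.contig_length or required
        arr = _random_background(total, config.gc_content, rng)

        # ----- plant sites -----
        regulated_first: set[str] = set()

        def plant(anchor: Gene, op: _PanOperon, offset: int, kind: str, seq: str):
            t = anchor.translation_start
            if anchor.strand == "+":
                start = t + offset - w // 2
                written = seq
            else:
                start = t - offset - w // 2
                written = reverse_complement(seq)
            arr[start : start + w] = np.frombuffer(written.encode(), dtype="S1")
            planted.append(
                PlantedSite(
                    genome_id=genome_id,
                    contig_id="chr",
                    interval=(start, start + w),
                    strand=anchor.strand,
                    anchor_operon_id=f"{genome_id}:op{op.index:03d}",
                    anchor_first_gene=anchor.gene_id,
                    offset_center=float(offset),
                    sequence=seq,
                    kind=kind,
                )
            )

        for op, placed in placements:
            anchor = placed[0]
            if op.is_tf_operon:
                tf_genes[genome_id] = next(
                    g.gene_id for g in placed if g.is_tf
                )
                if rng.random() < config.autoregulation_prob:
                    off = _draw_offset(config, rng)
                    plant(anchor, op, off, "autoregulation",
                          _corrupt(consensus, config.motif_conserved_fraction, rng))
                    regulated_first.add(anchor.gene_id)
                continue
            if not op.regulated:
                continue
            first_offset = _draw_offset(config, rng)
            spacing = config.tandem_spacing or (w + 6)
            for s in range(config.sites_per_operon):
                off = first_offset - s * spacing
                kind = "regulated" if s == 0 else "tandem"
                plant(anchor, op, off, kind,
                      _corrupt(consensus, config.motif_conserved_fraction, rng))
            regulated_first.add(anchor.gene_id)

        truth_regulons[genome_id] = regulated_first
        arrays.append(arr)
        # remember decoy anchors (non-regulated, non-TF operons)
        anchors = [
            (op, placed[0])
            for op, placed in placements
            if not op.regulated and not op.is_tf_operon
        ]
        pending_decoys.append((gidx, {"genome_id": genome_id, "anchors": anchors}))

        # ----- proteins -----
        proteins = {
            g.gene_id: _mutate_protein(
                ancestors[orthology[g.gene_id]], config.protein_mutation_rate, rng
            )
            for g in genes
        }
        genome_parts.append((genome_id, genes, proteins))

    # ----- ground-truth PWM and threshold over the planted sites -----
    site_seqs = [s.sequence for s in planted]
    truth_pwm = None
    decoys: list[PlantedSite] = []
    if site_seqs:
        truth_pwm = build_pwm(site_seqs, symmetrize=True)
        threshold = training_threshold(truth_pwm, site_seqs)
        # Decoy anchors are never reused across genomes: decoys model
        # genome-private false motif look-alikes, and at genome scale the
        # chance of two genomes sprouting one upstream of the same ortholog
        # operon is negligible — the desk-scale operon count would otherwise
        # make such coincidences common by the birthday effect.
        used_anchor_ops: set[int] = set()
        for gidx, info in pending_decoys:
            arr = arrays[gidx]
            anchors = [
                (op, anchor)
                for op, anchor in info["anchors"]
                if op.index not in used_anchor_ops
            ]
            n_decoys = int(rng.poisson(config.decoy_rate))
            for _ in range(n_decoys):
                if not anchors:
                    break
                k = int(rng.integers(len(anchors)))
                op, anchor = anchors.pop(k)
                # also retire layout neighbors: a decoy in a shared
                # (divergon) gap is attributable to either flanking operon
                used_anchor_ops.update({op.index - 1, op.index, op.index + 1})
                anchors = [
                    (o, a) for o, a in anchors if o.index not in used_anchor_ops
                ]
                offset = int(rng.integers(-200, -29))
                seq = _near_threshold_decoy(consensus, truth_pwm, threshold, rng)
                t = anchor.translation_start
                if anchor.strand == "+":
                    start = t + offset - w // 2
                    written = seq
                else:
                    start = t - offset - w // 2
                    written = reverse_complement(seq)
                arr[start : start + w] = np.frombuffer(written.encode(), dtype="S1")
                decoys.append(
                    PlantedSite(
                        genome_id=info["genome_id"],
                        contig_id="chr",
                        interval=(start, start + w),
                        strand=anchor.strand,
                        anchor_operon_id=f"{info['genome_id']}:op{op.index:03d}",
                        anchor_first_gene=anchor.gene_id,
                        offset_center=float(offset),
                        sequence=seq,
                        kind="decoy",
                    )
                )

    genomes = [
        Genome(
            genome_id=gid,
            contigs={"chr": arr.tobytes().decode()},
            genes=genes,
            proteins=proteins,
        )
        for (gid, genes, proteins), arr in zip(genome_parts, arrays)
    ]

    truth = GroundTruth(
        planted_consensus=consensus,
        planted_sites=planted,
        decoy_sites=decoys,
        true_regulons=truth_regulons,
        orthology_map=orthology,
        tf_genes=tf_genes,
        pwm=truth_pwm,
        config=config,
    )
    return genomes, truth


# ---------------------------------------------------------------------------
# Recovery metrics
# ---------------------------------------------------------------------------


@dataclass
class RecoveryMetrics:
    site_precision: float | None
    site_recall: float | None
    operon_precision: float | None
    operon_recall: float | None
    consensus_distance: int | None


def evaluate_recovery(
    truth: GroundTruth,
    regulons: Sequence,
    site_tolerance: int = 3,
    consensus: str | None = None,
) -> RecoveryMetrics:
    """Score a reconstruction against the planted ground truth.

    A planted site counts as recovered when a predicted site center in the
    same genome lies within ``site_tolerance`` bp of its center.  Operon
    membership is matched by the anchoring first gene.  Precision is null
    (None) when nothing was predicted; recall is null when nothing was
    planted.
    """
    from .motif import consensus_distance as cdist

    pred_centers: dict[str, list[float]] = {}
    pred_members: set[tuple[str, str]] = set()
    for reg in regulons:
        for member in reg.members:
            operon, sites = member.operon, member.sites
            pred_members.add((reg.genome_id, operon.first_gene_id))
            for s in sites:
                pred_centers.setdefault(reg.genome_id, []).append(s.center)

    true_centers = [
        (s.genome_id, (s.interval[0] + s.interval[1]) / 2.0)
        for s in truth.planted_sites
    ]
    true_members = {
        (gid, first) for gid, firsts in truth.true_regulons.items() for first in firsts
    }

    n_pred_sites = sum(len(v) for v in pred_centers.values())
    matched_true = 0
    for gid, center in true_centers:
        if any(abs(c - center) <= site_tolerance for c in pred_centers.get(gid, [])):
            matched_true += 1
    matched_pred = 0
    truth_by_genome: dict[str, list[float]] = {}
    for gid, c in true_centers:
        truth_by_genome.setdefault(gid, []).append(c)
    for gid, centers in pred_centers.items():
        for c in centers:
            if any(abs(c - tc) <= site_tolerance for tc in truth_by_genome.get(gid, [])):
                matched_pred += 1

    site_precision = matched_pred / n_pred_sites if n_pred_sites else None
    site_recall = matched_true / len(true_centers) if true_centers else None

    tp = len(pred_members & true_members)
    operon_precision = tp / len(pred_members) if pred_members else None
    operon_recall = tp / len(true_members) if true_members else None

    cd = None
    if consensus is not None:
        cd = cdist(consensus, truth.planted_consensus)
    return RecoveryMetrics(
        site_precision=site_precision,
        site_recall=site_recall,
        operon_precision=operon_precision,
        operon_recall=operon_recall,
        consensus_distance=cd,
    )


# ---------------------------------------------------------------------------
# On-disk representation of a simulated run
# ---------------------------------------------------------------------------


def write_simulation(
    genomes: Sequence[Genome],
    truth: GroundTruth,
    outdir: str | Path,
) -> None:
    """Write per-genome FASTA/GFF3/proteins, truth tables, and a manifest."""
    import yaml

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for genome in genomes:
        base = outdir / genome.genome_id
        write_genome(
            genome,
            base.with_suffix(".fna"),
            base.with_suffix(".gff3"),
            base.with_suffix(".faa"),
        )
    df = truth.sites_frame()
    # BED6 + anchor column
    if not df.empty:
        bed = df[["contig_id", "start", "end", "kind", "offset_center", "strand",
                  "genome_id", "anchor_first_gene"]]
        bed.to_csv(outdir / "truth_sites.bed", sep="\t", index=False, header=False)
    df.to_csv(outdir / "truth_sites.tsv", sep="\t", index=False)
    reg_rows = [
        {"genome_id": gid, "anchor_first_gene": first}
        for gid, firsts in truth.true_regulons.items()
        for first in sorted(firsts)
    ]
    pd.DataFrame(reg_rows).to_csv(outdir / "truth_regulons.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"gene_id": k, "ortholog_group": v} for k, v in sorted(truth.orthology_map.items())]
    ).to_csv(outdir / "truth_orthology.tsv", sep="\t", index=False)
    manifest = {
        "consensus": truth.planted_consensus,
        "tf_genes": dict(sorted(truth.tf_genes.items())),
        "config": asdict(truth.config) if truth.config else None,
    }
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
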