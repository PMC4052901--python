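"""Regulon assembly: scanning, cross-genome consistency, regulog aggregation.

A per-genome candidate regulon is the set of operons whose promoter window
contains at least one PWM hit at or above the training-derived threshold.
The cross-genome consistency check then keeps a candidate operon only when
operons sharing its first gene's ortholog group carry above-threshold sites
in at least ``min_genomes`` related genomes (counting itself) — planted-in
one-genome decoys fail this test, orthologous regulation passes it.

A site falling inside two overlapping promoter windows (divergently
transcribed operons, "divergons") is attributed to both operons; scanning
each window independently yields exactly that behavior.

Regulons are classified global when they control more than 15 genes in at
least 7 operons spanning at least two annotated pathways; otherwise local.
A regulog is the set of genome-specific regulons of one orthologous TF
group, with a merged motif rebuilt from the union of member sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .core_model import Gene, Genome, extract_promoter, DEFAULT_PROMOTER_WINDOW
from .motif import PWM, SiteInstance, build_pwm, scan_region, training_threshold
from .operons import Operon, operon_of_gene


@dataclass
class RegulonMember:
    operon: Operon
    sites: list[SiteInstance]


@dataclass
class Regulon:
    tf_gene_id: str
    genome_id: str
    members: list[RegulonMember] = field(default_factory=list)
    autoregulated: bool = False
    classification: str = "local"
    gene_functions: dict[str, str] = field(default_factory=dict)

    @property
    def n_operons(self) -> int:
        return len(self.members)

    @property
    def n_genes(self) -> int:
        return sum(m.operon.n_genes for m in self.members)

    @property
    def n_sites(self) -> int:
        return sum(len(m.sites) for m in self.members)

    @property
    def pathways(self) -> set[str]:
        labels = {
            self.gene_functions.get(g, "")
            for m in self.members
            for g in m.operon.gene_ids
        }
        return {l for l in labels if l}

    @property
    def all_sites(self) -> list[SiteInstance]:
        return [s for m in self.members for s in m.sites]


@dataclass
class Regulog:
    tf_group_id: str
    regulons: list[Regulon]
    merged_motif: PWM | None = None

    @property
    def nonempty_regulons(self) -> list[Regulon]:
        return [r for r in self.regulons if r.members]

    @property
    def n_regulons(self) -> int:
        return len(self.nonempty_regulons)

    @property
    def n_operons(self) -> int:
        return sum(r.n_operons for r in self.regulons)

    @property
    def n_genes(self) -> int:
        return sum(r.n_genes for r in self.regulons)

    @property
    def n_sites(self) -> int:
        return sum(r.n_sites for r in self.regulons)


def reconstruct_regulon(
    tf: Gene | None,
    pwm: PWM,
    genome: Genome,
    operons: Sequence[Operon],
    window: tuple[int, int] = DEFAULT_PROMOTER_WINDOW,
) -> Regulon:
    """Scan every operon's promoter window; operons with hits become members."""
    if pwm.threshold is None:
        raise ValueError("PWM threshold is unset")
    members = []
    for op in operons:
        anchor = genome.gene(op.first_gene_id)
        region = extract_promoter(genome, anchor, window, anchor_operon_id=op.operon_id)
        hits = scan_region(pwm, region)
        if hits:
            members.append(RegulonMember(operon=op, sites=hits))
    return Regulon(
        tf_gene_id=tf.gene_id if tf else "",
        genome_id=genome.genome_id,
        members=members,
        gene_functions={g.gene_id: g.function_label for g in genome.genes},
    )


def consistency_filter(
    candidates: Sequence[Regulon],
    gene_to_group: Mapping[str, str],
    min_genomes: int = 2,
) -> list[Regulon]:
    """Keep member operons whose ortholog-operon is hit in >= min_genomes genomes.

    The operon's signature is its first gene's ortholog group (promoter
    identity follows the first gene); genes without a group count as
    genome-private singletons.  Output is a subset of the input, and raising
    ``min_genomes`` never adds members.
    """

    def signature(op: Operon) -> str:
        return gene_to_group.get(op.first_gene_id, f"singleton:{op.first_gene_id}")

    genomes_with_hit: dict[str, set[str]] = {}
    for reg in candidates:
        for m in reg.members:
            genomes_with_hit.setdefault(signature(m.operon), set()).add(reg.genome_id)

    filtered = []
    for reg in candidates:
        kept = [
            m
            for m in reg.members
            if len(genomes_with_hit[signature(m.operon)]) >= min_genomes
        ]
        filtered.append(
            Regulon(
                tf_gene_id=reg.tf_gene_id,
                genome_id=reg.genome_id,
                members=kept,
                autoregulated=reg.autoregulated,
                classification=reg.classification,
                gene_functions=reg.gene_functions,
            )
        )
    return filtered


def detect_autoregulation(regulon: Regulon, operons: Sequence[Operon]) -> bool:
    """True iff the operon containing the TF gene is a regulon member.

    Membership is operon-level: a TF sitting as an internal gene of a
    regulated operon still counts.
    """
    if not regulon.tf_gene_id:
        return False
    own = operon_of_gene(operons, regulon.tf_gene_id)
    if own is None:
        raise ValueError(
            f"TF gene {regulon.tf_gene_id!r} is not assigned to any operon"
        )
    member_ids = {m.operon.operon_id for m in regulon.members}
    return own.operon_id in member_ids


def classify_regulon(regulon: Regulon) -> str:
    """Global: >15 target genes in >=7 operons over >=2 distinct pathways."""
    if (
        regulon.n_genes > 15
        and regulon.n_operons >= 7
        and len(regulon.pathways) >= 2
    ):
        return "global"
    return "local"


def assemble_regulog(tf_group_id: str, regulons: Sequence[Regulon]) -> Regulog:
    """Aggregate genome-specific regulons of one orthologous TF group.

    The merged motif is rebuilt (symmetrized) from the union of member site
    sequences; its threshold is the lowest score among them.  Genomes whose
    regulon retained no members are reported but excluded from the regulon
    count.
    """
    if not regulons:
        raise ValueError("cannot assemble a regulog from zero regulons")
    site_seqs = [s.sequence for r in regulons for s in r.all_sites]
    merged = None
    if site_seqs:
        merged = build_pwm(site_seqs, symmetrize=True)
        training_threshold(merged, site_seqs)
        merged.name = tf_group_id
    return Regulog(
        tf_group_id=tf_group_id, regulons=list(regulons), merged_motif=merged
    )


@dataclass
class TFAttribution:
    assigned_group: str | None
    support: int
    tally: dict[str, int]
    tie: bool
    autoregulatory_boost: bool


def attribute_tf_to_motif(
    tf_candidates: Mapping[str, Sequence[Gene]],
    regulated_operons: Mapping[str, Sequence[Operon]],
    genomes: Mapping[str, Genome],
    gene_to_group: Mapping[str, str],
    max_distance: int = 10_000,
    min_genomes: int = 1,
) -> TFAttribution:
    """Assign a candidate TF (ortholog group) to an orphan motif/regulon.

    A TF supports the assignment in a genome when its gene lies within
    ``max_distance`` bp of (or inside) a regulated operon on the same
    contig.  The TF group with support in the largest number of genomes
    wins; ties leave the motif unassigned with both candidates reported.  A
    TF inside a regulated operon (autoregulation) marks the assignment as
    higher confidence.
    """
    tally: dict[str, set[str]] = {}
    autoreg: set[str] = set()
    for genome_id, tfs in tf_candidates.items():
        genome = genomes[genome_id]
        for tf in tfs:
            group = gene_to_group.get(tf.gene_id, f"singleton:{tf.gene_id}")
            for op in regulated_operons.get(genome_id, []):
                if op.contig_id != tf.contig_id:
                    continue
                span = [genome.gene(g) for g in op.gene_ids]
                lo = min(g.start for g in span)
                hi = max(g.end for g in span)
                dist = max(lo - tf.end, tf.start - hi, 0)
                if dist <= max_distance:
                    tally.setdefault(group, set()).add(genome_id)
                    if tf.gene_id in op.gene_ids:
                        autoreg.add(group)
                    break
    counts = {g: len(v) for g, v in tally.items()}
    if not counts:
        return TFAttribution(None, 0, {}, False, False)
    best = max(counts.values())
    winners = sorted(g for g, c in counts.items() if c == best)
    if len(winners) > 1 or best < min_genomes:
        return TFAttribution(None, best, counts, len(winners) > 1, False)
    return TFAttribution(winners[0], best, counts, False, winners[0] in autoreg)
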