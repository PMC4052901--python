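"""Operon prediction from gene layout and predicted internal binding sites.

An operon is a maximal run of adjacent co-directional genes whose
intergenic distances do not exceed ``max_gap`` (100 bp by default,
inclusive) and whose internal intergenic gaps contain no binding site of
the transcription factor under study.  Overlapping same-strand genes
(negative gap) always merge.  The output partitions the gene set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .core_model import Gene, Genome
from .motif import SiteInstance

DEFAULT_MAX_GAP = 100


@dataclass
class Operon:
    operon_id: str
    genome_id: str
    contig_id: str
    strand: str
    gene_ids: list[str]  # 5'-most (promoter-proximal) gene first
    first_gene_id: str
    cross_genome_support: int = 0

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


def _site_in_gap(
    sites: Sequence[SiteInstance], contig_id: str, gap: tuple[int, int]
) -> bool:
    lo, hi = gap
    for s in sites:
        if s.contig_id != contig_id:
            continue
        if lo <= s.center < hi:
            return True
    return False


def predict_operons(
    genome: Genome,
    internal_sites: Sequence[SiteInstance] | None = None,
    max_gap: int = DEFAULT_MAX_GAP,
) -> list[Operon]:
    """Partition the genes of each contig into predicted operons.

    Adjacent genes join the same operon iff they share a strand, their
    intergenic distance (end of upstream gene to start of downstream gene on
    genomic coordinates) is <= ``max_gap``, and no supplied binding site has
    its center inside the intergenic gap.  Deterministic and idempotent.
    """
    sites = list(internal_sites or [])
    operons: list[Operon] = []
    counter = 0
    for contig_id in sorted(genome.contigs):
        run: list[Gene] = []
        for gene in genome.genes_on(contig_id):
            if run:
                prev = run[-1]
                gap = (prev.end, gene.start)
                same = gene.strand == prev.strand
                close = gene.start - prev.end <= max_gap
                clean = gene.start <= prev.end or not _site_in_gap(sites, contig_id, gap)
                if same and close and clean:
                    run.append(gene)
                    continue
                operons.append(_finalize(run, genome.genome_id, counter))
                counter += 1
                run = [gene]
            else:
                run = [gene]
        if run:
            operons.append(_finalize(run, genome.genome_id, counter))
            counter += 1
    return operons


def _finalize(run: list[Gene], genome_id: str, counter: int) -> Operon:
    strand = run[0].strand
    ordered = [g.gene_id for g in run] if strand == "+" else [g.gene_id for g in reversed(run)]
    return Operon(
        operon_id=f"{genome_id}:pred{counter:04d}",
        genome_id=genome_id,
        contig_id=run[0].contig_id,
        strand=strand,
        gene_ids=ordered,
        first_gene_id=ordered[0],
    )


def operon_conservation(
    operons_by_genome: Mapping[str, Sequence[Operon]],
    gene_to_group: Mapping[str, str],
    min_genomes: int = 2,
    split: bool = False,
) -> dict[str, list[Operon]]:
    """Score each internal gene adjacency by its cross-genome support.

    Support of an ordered ortholog-group pair (a, b) is the number of genomes
    where a and b are co-operonic in that order.  Each operon's
    ``cross_genome_support`` is the minimum support over its internal
    adjacencies (number of genomes for single-gene operons).  With ``split``,
    adjacencies supported in fewer than ``min_genomes`` genomes are cut;
    otherwise operons pass through unchanged.  Genes without an ortholog
    group count as their own singleton group.
    """
    def group_of(gene_id: str) -> str:
        return gene_to_group.get(gene_id, f"singleton:{gene_id}")

    support: dict[tuple[str, str], set[str]] = {}
    for gid, operons in operons_by_genome.items():
        for op in operons:
            for a, b in zip(op.gene_ids, op.gene_ids[1:]):
                support.setdefault((group_of(a), group_of(b)), set()).add(gid)

    n_genomes = len(operons_by_genome)
    out: dict[str, list[Operon]] = {}
    for gid, operons in operons_by_genome.items():
        new_ops: list[Operon] = []
        for op in operons:
            adj_support = [
                len(support[(group_of(a), group_of(b))])
                for a, b in zip(op.gene_ids, op.gene_ids[1:])
            ]
            if not split or not adj_support or min(adj_support) >= min_genomes:
                op.cross_genome_support = (
                    min(adj_support) if adj_support else n_genomes
                )
                new_ops.append(op)
                continue
            # cut unsupported adjacencies
            segment: list[str] = [op.gene_ids[0]]
            segments: list[list[str]] = []
            for (a, b), sup in zip(zip(op.gene_ids, op.gene_ids[1:]), adj_support):
                if sup >= min_genomes:
                    segment.append(b)
                else:
                    segments.append(segment)
                    segment = [b]
            segments.append(segment)
            for k, seg in enumerate(segments):
                seg_support = [
                    len(support[(group_of(a), group_of(b))])
                    for a, b in zip(seg, seg[1:])
                ]
                new_ops.append(
                    Operon(
                        operon_id=f"{op.operon_id}.{k}",
                        genome_id=op.genome_id,
                        contig_id=op.contig_id,
                        strand=op.strand,
                        gene_ids=seg,
                        first_gene_id=seg[0],
                        cross_genome_support=(
                            min(seg_support) if seg_support else n_genomes
                        ),
                    )
                )
        out[gid] = new_ops
    return out


def operon_of_gene(operons: Iterable[Operon], gene_id: str) -> Operon | None:
    for op in operons:
        if gene_id in op.gene_ids:
            return op
    return None
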