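"""Protein similarity, bidirectional best hits, and ortholog groups.

Orthology across the clade is operationalized as connected components of the
bidirectional-best-hit (BBH) graph over all genome pairs.  TF groups are
additionally split by binding-motif similarity (single linkage at a
threshold tau), which approximates the field's practice of requiring
orthologous regulators to recognize highly similar motifs.

Two similarity backends are provided: a fast normalized shared k-mer count
(default, k=4) and Smith-Waterman local alignment with BLOSUM62 and affine
gaps via Biopython's PairwiseAligner.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
from Bio import Align
from Bio.Align import substitution_matrices

from .motif import PWM, motif_similarity


@dataclass
class Hit:
    query: str
    subject: str
    score: float


@dataclass
class HitTable:
    """Directional similarity scores between two proteomes."""

    query_genome: str
    subject_genome: str
    hits: list[Hit] = field(default_factory=list)

    def best_subject(self, query: str) -> tuple[str | None, bool]:
        """Best subject for a query; ties broken lexicographically and flagged."""
        best_score = None
        candidates: list[str] = []
        for h in self.hits:
            if h.query != query:
                continue
            if best_score is None or h.score > best_score:
                best_score = h.score
                candidates = [h.subject]
            elif h.score == best_score:
                candidates.append(h.subject)
        if not candidates:
            return None, False
        return min(candidates), len(candidates) > 1


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def pairwise_similarity(
    proteins_a: Mapping[str, str],
    proteins_b: Mapping[str, str],
    method: str = "kmer",
    k: int = 4,
    genome_a: str = "A",
    genome_b: str = "B",
) -> HitTable:
    """All-vs-all similarity of two proteomes.

    ``kmer``: shared k-mer count normalized by the smaller k-mer set (in
    [0, 1]).  ``alignment``: Smith-Waterman local alignment score (BLOSUM62,
    gap open -11 / extend -1).  Self-comparisons are excluded when the two
    proteomes are the same mapping.
    """
    if not proteins_a or not proteins_b:
        raise ValueError("empty proteome")
    for gid, seq in list(proteins_a.items()) + list(proteins_b.items()):
        if not seq:
            raise ValueError(f"empty protein sequence for gene {gid!r}")
    same = proteins_a is proteins_b or (
        genome_a == genome_b and set(proteins_a) == set(proteins_b)
    )
    table = HitTable(query_genome=genome_a, subject_genome=genome_b)
    if method == "kmer":
        sets_a = {g: _kmer_set(s, k) for g, s in proteins_a.items()}
        sets_b = {g: _kmer_set(s, k) for g, s in proteins_b.items()}
        for qa, ka in sets_a.items():
            for qb, kb in sets_b.items():
                if same and qa == qb:
                    continue
                denom = min(len(ka), len(kb))
                score = len(ka & kb) / denom if denom else 0.0
                table.hits.append(Hit(qa, qb, score))
    elif method == "alignment":
        aligner = _make_aligner()
        for qa, sa in proteins_a.items():
            for qb, sb in proteins_b.items():
                if same and qa == qb:
                    continue
                table.hits.append(Hit(qa, qb, float(aligner.score(sa, sb))))
    else:
        raise ValueError(f"unknown similarity method {method!r}")
    return table


def smith_waterman_score(a: str, b: str) -> float:
    """Local alignment score of two protein strings (BLOSUM62, affine gaps)."""
    return float(_make_aligner().score(a, b))


def bidirectional_best_hits(
    a_vs_b: HitTable, b_vs_a: HitTable
) -> set[tuple[str, str]]:
    """Pairs (x, y) where y is x's unique best subject and vice versa.

    Score ties are broken lexicographically by subject id; tie-broken pairs
    are still eligible (and discoverable via ``best_subject``'s flag).
    """
    def best_map(table: HitTable) -> dict[str, str]:
        acc: dict[str, tuple[float, str]] = {}
        for h in table.hits:
            cur = acc.get(h.query)
            if cur is None or h.score > cur[0] or (h.score == cur[0] and h.subject < cur[1]):
                acc[h.query] = (h.score, h.subject)
        return {q: s for q, (_, s) in acc.items()}

    fwd = best_map(a_vs_b)
    rev = best_map(b_vs_a)
    return {(x, y) for x, y in fwd.items() if rev.get(y) == x}


@dataclass
class OrthologGroup:
    group_id: str
    members: frozenset[str]
    is_tf_group: bool = False
    effector_annotation: str = ""  # free text; effector specificity is not computed
    motif_split: bool = False  # True when carved out of a BBH component by motif similarity


def build_ortholog_groups(
    pairs: Iterable[tuple[str, str]],
    all_genes: Iterable[str],
    tf_genes: Iterable[str] = (),
) -> list[OrthologGroup]:
    """Connected components of the BBH graph; unpaired genes are singletons.

    Groups partition the gene set and get deterministic labels ordered by
    their lexicographically smallest member.
    """
    graph = nx.Graph()
    graph.add_nodes_from(all_genes)
    graph.add_edges_from(pairs)
    tf_set = set(tf_genes)
    components = sorted(
        (sorted(c) for c in nx.connected_components(graph)), key=lambda c: c[0]
    )
    return [
        OrthologGroup(
            group_id=f"OG{idx:04d}",
            members=frozenset(comp),
            is_tf_group=any(g in tf_set for g in comp),
        )
        for idx, comp in enumerate(components)
    ]


def form_tf_groups(
    candidate_groups: Sequence[OrthologGroup],
    motifs: Mapping[str, PWM],
    tau: float = 0.8,
) -> list[OrthologGroup]:
    """Split BBH-derived TF groups by motif similarity (single linkage >= tau).

    Regulators without a motif model stay with their BBH group, flagged by an
    empty ``effector_annotation`` and ``motif_split=False``.  Genes from
    different BBH components are never merged.
    """
    out: list[OrthologGroup] = []
    for group in candidate_groups:
        if not group.is_tf_group:
            out.append(group)
            continue
        with_motif = sorted(g for g in group.members if g in motifs)
        without = sorted(g for g in group.members if g not in motifs)
        if len(with_motif) <= 1:
            out.append(group)
            continue
        sub = nx.Graph()
        sub.add_nodes_from(with_motif)
        for i, a in enumerate(with_motif):
            for b in with_motif[i + 1 :]:
                if motif_similarity(motifs[a], motifs[b]) >= tau:
                    sub.add_edge(a, b)
        comps = sorted(
            (sorted(c) for c in nx.connected_components(sub)), key=lambda c: c[0]
        )
        if len(comps) == 1:
            out.append(group)
            continue
        # motif-less TFs stay with their BBH kin: attach to the first subgroup
        comps[0] = sorted(comps[0] + without) if without else comps[0]
        for j, comp in enumerate(comps):
            out.append(
                OrthologGroup(
                    group_id=f"{group.group_id}.{j}",
                    members=frozenset(comp),
                    is_tf_group=True,
                    motif_split=True,
                )
            )
    return out
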