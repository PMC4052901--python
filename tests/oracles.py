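"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (double loops, explicit dynamic
programming, full enumeration) and shares no code with the library paths it
checks.
"""

from __future__ import annotations

from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def sw_score_oracle(a: str, b: str, gap_open: float = -11, gap_extend: float = -1) -> float:
    """Smith-Waterman local alignment score, Gotoh affine-gap recursion.

    Gap of length k costs gap_open + (k-1) * gap_extend, matching the
    open/extend convention of Biopython's PairwiseAligner.
    """
    n, m = len(a), len(b)
    NEG = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (vertical)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (horizontal)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i - 1][j] + gap_open, E[i - 1][j] + gap_extend)
            F[i][j] = max(H[i][j - 1] + gap_open, F[i][j - 1] + gap_extend)
            sub = H[i - 1][j - 1] + float(_BLOSUM62[a[i - 1], b[j - 1]])
            H[i][j] = max(0.0, sub, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def bbh_oracle(scores_ab: dict, scores_ba: dict) -> set:
    """Bidirectional best hits by exhaustive double loop.

    ``scores_ab``: {(x, y): score} for queries x against subjects y; ties
    broken by lexicographically smallest subject.
    """
    def best(scores, query):
        rows = [(s, subj) for (q, subj), s in scores.items() if q == query]
        if not rows:
            return None
        top = max(s for s, _ in rows)
        return min(subj for s, subj in rows if s == top)

    xs = {q for q, _ in scores_ab}
    pairs = set()
    for x in xs:
        y = best(scores_ab, x)
        if y is not None and best(scores_ba, y) == x:
            pairs.add((x, y))
    return pairs


def components_oracle(nodes, edges) -> list[frozenset]:
    """Connected components by repeated flood fill."""
    nodes = set(nodes)
    adj: dict = {n: set() for n in nodes}
    for u, v in edges:
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
        nodes.update((u, v))
    seen: set = set()
    comps = []
    for start in sorted(nodes):
        if start in seen:
            continue
        stack, comp = [start], set()
        while stack:
            u = stack.pop()
            if u in comp:
                continue
            comp.add(u)
            stack.extend(adj.get(u, ()) - comp)
        seen |= comp
        comps.append(frozenset(comp))
    return comps
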