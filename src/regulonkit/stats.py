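"""Descriptive statistics over reconstructed regulons and their sites.

Covers the analyses a regulog survey reports: where sites sit relative to
start codons, how adjacent sites in one regulatory region are spaced
(tandem sites at helical-period spacings indicate cooperative dimer pairs),
how palindromic motif widths and central base pairs distribute, and regulon
size / autoregulation summaries.

Conventions: distances to the start codon are measured from the site center
(negative = upstream); 3'-end measurement is available as an option.
Intersite distances are center-to-center of adjacent sites, which makes
helical-period spacings (22, 32 bp) literal.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .motif import PWM, SiteInstance
from .reconstruction import Regulog, Regulon


# ---------------------------------------------------------------------------
# Site position relative to the start codon
# ---------------------------------------------------------------------------


@dataclass
class PositionSummary:
    histogram: pd.DataFrame  # columns: bin_left, bin_right, count
    fraction_core: float | None  # centers within [-140, -30]
    fraction_coding: float | None  # centers downstream of the start (> 0)
    fraction_far_upstream: float | None  # centers < -200
    n_sites: int


def site_position_histogram(
    regulons: Sequence[Regulon],
    bin_width: int = 10,
    core_window: tuple[int, int] = (-140, -30),
    measure: str = "center",
) -> PositionSummary:
    """Histogram of site offsets from the translation start.

    ``measure`` selects the center (default) or the 3' end of each site.
    Also reports the fractions of sites in the core window, inside coding
    sequence, and far upstream (< -200 bp); all fractions are None for an
    empty input.
    """
    offsets = []
    for reg in regulons:
        for s in reg.all_sites:
            offsets.append(s.offset_center if measure == "center" else s.offset_end)
    n = len(offsets)
    if n == 0:
        empty = pd.DataFrame(columns=["bin_left", "bin_right", "count"])
        return PositionSummary(empty, None, None, None, 0)
    arr = np.asarray(offsets, float)
    lo = np.floor(arr.min() / bin_width) * bin_width
    hi = np.ceil((arr.max() + 1) / bin_width) * bin_width
    edges = np.arange(lo, hi + bin_width, bin_width)
    counts, _ = np.histogram(arr, bins=edges)
    hist = pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )
    core_lo, core_hi = core_window
    return PositionSummary(
        histogram=hist,
        fraction_core=float(((arr >= core_lo) & (arr <= core_hi)).mean()),
        fraction_coding=float((arr > 0).mean()),
        fraction_far_upstream=float((arr < -200).mean()),
        n_sites=n,
    )


# ---------------------------------------------------------------------------
# Intersite spacing within regulatory regions
# ---------------------------------------------------------------------------


@dataclass
class SpacingRecord:
    region_id: str
    centers: list[float]  # sorted
    distances: list[float]  # adjacent center-to-center


@dataclass
class SpacingSummary:
    records: list[SpacingRecord]
    pooled: pd.DataFrame  # columns: distance, count
    multiplicity: dict[int, int]  # sites-per-region -> number of regions

    def mode(self) -> float | None:
        if self.pooled.empty:
            return None
        best = self.pooled.sort_values(["count", "distance"], ascending=[False, True])
        return float(best.iloc[0]["distance"])


def intersite_distances(
    sites: Iterable[SiteInstance],
    region_key: str = "anchor",
) -> SpacingSummary:
    """Adjacent center-to-center distances for regions holding >= 2 sites.

    Sites are grouped into regulatory regions by (genome, contig, anchor
    operon) by default, or by (genome, contig) with ``region_key='contig'``.
    Duplicate attributions of one genomic site to the same region (e.g. via
    a re-scan) are collapsed by center coordinate.
    """
    regions: dict[str, set[float]] = {}
    for s in sites:
        if region_key == "anchor":
            key = f"{s.genome_id}:{s.contig_id}:{s.anchor_operon_id}"
        else:
            key = f"{s.genome_id}:{s.contig_id}"
        regions.setdefault(key, set()).add(s.center)
    records = []
    pooled: Counter = Counter()
    multiplicity: Counter = Counter()
    for key in sorted(regions):
        centers = sorted(regions[key])
        multiplicity[len(centers)] += 1
        if len(centers) < 2:
            continue
        dists = [b - a for a, b in zip(centers, centers[1:])]
        records.append(SpacingRecord(region_id=key, centers=centers, distances=dists))
        pooled.update(dists)
    pooled_df = pd.DataFrame(
        sorted(pooled.items()), columns=["distance", "count"]
    )
    return SpacingSummary(records=records, pooled=pooled_df, multiplicity=dict(multiplicity))


# ---------------------------------------------------------------------------
# Palindrome census over motifs
# ---------------------------------------------------------------------------


def palindrome_census(
    motifs: Sequence[PWM], degeneracy_cutoff: float = 0.5
) -> pd.DataFrame:
    """Classify motifs by width parity and central-pair identity.

    Even-width motifs are called ``CG`` when the two central consensus bases
    are C then G and each reaches the consensus-frequency cutoff;
    ``degenerate`` when either central column is below the cutoff; ``other``
    otherwise.  Odd-width motifs get parity ``odd`` and no central-pair call.
    """
    rows = []
    for pwm in motifs:
        w = pwm.width
        parity = "even" if w % 2 == 0 else "odd"
        central_class = ""
        if parity == "even":
            left, right = pwm.freqs[w // 2 - 1], pwm.freqs[w // 2]
            if left.max() < degeneracy_cutoff or right.max() < degeneracy_cutoff:
                central_class = "degenerate"
            else:
                pair = pwm.consensus[w // 2 - 1 : w // 2 + 1]
                central_class = "CG" if pair == "CG" else "other"
        rows.append(
            {
                "motif": pwm.name,
                "width": w,
                "parity": parity,
                "central_class": central_class,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Regulon / regulog census
# ---------------------------------------------------------------------------


@dataclass
class RegulonCensus:
    regulons_per_group: pd.Series
    genes_per_regulon: pd.Series
    operons_per_regulon: pd.Series
    autoregulated_fraction: float | None
    global_count: int
    local_count: int
    total_regulons: int

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "quantity": [
                    "total_regulons",
                    "mean_regulons_per_group",
                    "mean_genes_per_regulon",
                    "mean_operons_per_regulon",
                    "autoregulated_fraction",
                    "global_regulons",
                    "local_regulons",
                ],
                "value": [
                    self.total_regulons,
                    self.regulons_per_group.mean() if len(self.regulons_per_group) else np.nan,
                    self.genes_per_regulon.mean() if len(self.genes_per_regulon) else np.nan,
                    self.operons_per_regulon.mean() if len(self.operons_per_regulon) else np.nan,
                    self.autoregulated_fraction if self.autoregulated_fraction is not None else np.nan,
                    self.global_count,
                    self.local_count,
                ],
            }
        )


def regulon_census(regulogs: Sequence[Regulog]) -> RegulonCensus:
    """Distributions of regulog/regulon sizes and the autoregulation rate.

    Counts only non-empty regulons; totals are conserved (the per-group
    regulon counts sum to the total number of regulons) and invariant to
    genome processing order.
    """
    per_group = pd.Series(
        {rg.tf_group_id: rg.n_regulons for rg in regulogs}, dtype=float
    )
    regs = [r for rg in regulogs for r in rg.nonempty_regulons]
    genes = pd.Series([r.n_genes for r in regs], dtype=float)
    operons = pd.Series([r.n_operons for r in regs], dtype=float)
    auto = (
        float(np.mean([r.autoregulated for r in regs])) if regs else None
    )
    global_count = sum(1 for r in regs if r.classification == "global")
    return RegulonCensus(
        regulons_per_group=per_group,
        genes_per_regulon=genes,
        operons_per_regulon=operons,
        autoregulated_fraction=auto,
        global_count=global_count,
        local_count=len(regs) - global_count,
        total_regulons=len(regs),
    )
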