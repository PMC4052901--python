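"""Palindromic motif discovery, PWM construction, scoring and scanning.

The binding model is a position weight matrix over A/C/G/T with log-odds in
bits against an explicit background.  Homodimeric regulators bind palindromic
sites, so count matrices can be symmetrized, ``C <- (C + revcomp(C)) / 2``,
which makes every score strand-flip invariant: scanning one strand with a
symmetric matrix is equivalent to scanning both.

Discovery runs a zero-or-one-occurrence-per-sequence (ZOOPS)
expectation-maximization over each candidate width, re-symmetrizing the
expected counts every iteration, and selects the width maximizing total
information content after subtracting the small-sample bias expected under
background.  The detection threshold is always the minimum score over the
training sites, which makes the bit scale self-calibrating.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .core_model import PromoterRegion, reverse_complement

BASES = "ACGT"
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
# complement permutation of base indices: A<->T, C<->G
_COMP_PERM = np.array([3, 2, 1, 0])

UNIFORM_BACKGROUND = np.full(4, 0.25)


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as int8; non-ACGT becomes -1."""
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        out[arr == ord(base)] = idx
    return out


def _revcomp_matrix(m: np.ndarray) -> np.ndarray:
    """Reverse complement of a (width x 4) count/frequency matrix."""
    return m[::-1][:, _COMP_PERM]


@dataclass
class PWM:
    """Position weight matrix with log-odds in bits and an optional threshold."""

    freqs: np.ndarray  # (width, 4) probabilities per column
    background: np.ndarray = field(default_factory=lambda: UNIFORM_BACKGROUND.copy())
    pseudocount: float = 0.5
    palindromic: bool = False
    threshold: float | None = None
    n_sites: int = 0
    name: str = "motif"

    @property
    def width(self) -> int:
        return self.freqs.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        return np.log2(self.freqs / self.background[None, :])

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in np.argmax(self.freqs, axis=1))

    def information_content(self) -> float:
        """Total relative-entropy information content in bits."""
        return float(np.sum(self.freqs * self.log_odds))

    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    def is_palindromic(self, tol: float = 1e-9) -> bool:
        lo = self.log_odds
        return bool(np.allclose(lo, _revcomp_matrix(lo), atol=tol))


@dataclass
class SiteInstance:
    """A scored PWM match placed on a genome, tied to its anchor operon."""

    contig_id: str
    interval: tuple[int, int]
    strand: str
    sequence: str
    score: float
    offset_center: float  # site center minus translation start; negative = upstream
    offset_end: int  # 3' end of the site minus translation start
    anchor_operon_id: str
    genome_id: str = ""

    @property
    def center(self) -> float:
        return (self.interval[0] + self.interval[1]) / 2.0


def build_pwm(
    sites: Sequence[str],
    pseudocount: float = 0.5,
    background: np.ndarray | None = None,
    symmetrize: bool = True,
) -> PWM:
    """Build a PWM from equal-length ACGT site sequences.

    Frequencies are ``(count + pseudocount) / (n + 4 * pseudocount)``; with
    ``symmetrize`` the count matrix is first averaged with its reverse
    complement, which enforces the palindromic invariant exactly.
    """
    if not sites:
        raise ValueError("cannot build a PWM from an empty site list")
    width = len(sites[0])
    bg = UNIFORM_BACKGROUND.copy() if background is None else np.asarray(background, float)
    counts = np.zeros((width, 4))
    for s in sites:
        if len(s) != width:
            raise ValueError(
                f"site {s!r} has length {len(s)}, expected {width}"
            )
        enc = encode(s)
        if (enc < 0).any():
            raise ValueError(f"site {s!r} contains non-ACGT characters")
        counts[np.arange(width), enc] += 1.0
    if symmetrize:
        counts = (counts + _revcomp_matrix(counts)) / 2.0
    n = len(sites)
    freqs = (counts + pseudocount) / (n + 4.0 * pseudocount)
    return PWM(
        freqs=freqs,
        background=bg,
        pseudocount=pseudocount,
        palindromic=symmetrize,
        n_sites=n,
    )


def score_site(pwm: PWM, seq: str) -> float:
    """Sum of per-position log-odds (bits) for a window of exactly PWM width."""
    if len(seq) != pwm.width:
        raise ValueError(
            f"sequence length {len(seq)} does not match PWM width {pwm.width}"
        )
    enc = encode(seq)
    if (enc < 0).any():
        raise ValueError(f"window {seq!r} contains non-ACGT characters")
    return float(pwm.log_odds[np.arange(pwm.width), enc].sum())


def training_threshold(pwm: PWM, training_sites: Sequence[str]) -> float:
    """Minimum score over the training sites; stored on the PWM."""
    if not training_sites:
        raise ValueError("training set is empty")
    threshold = min(score_site(pwm, s) for s in training_sites)
    pwm.threshold = threshold
    return threshold


def _window_scores(log_odds: np.ndarray, enc: np.ndarray) -> np.ndarray:
    """Scores of all width-w windows of an encoded sequence; NaN where N occurs."""
    w = log_odds.shape[0]
    m = len(enc) - w + 1
    if m <= 0:
        return np.empty(0)
    windows = np.lib.stride_tricks.sliding_window_view(enc, w)
    valid = (windows >= 0).all(axis=1)
    scores = np.full(m, np.nan)
    if valid.any():
        vw = windows[valid]
        scores[valid] = log_odds[np.arange(w)[None, :], vw].sum(axis=1)
    return scores


def scan_region(pwm: PWM, region: PromoterRegion) -> list[SiteInstance]:
    """All windows scoring >= the PWM threshold, one hit per position.

    The matrix is palindrome-symmetric so strands are equivalent; hits are
    reported on the anchor's coding strand.  Overlapping hits are retained
    (tandem and overlapping sites are biologically meaningful).  Windows
    containing N are skipped.
    """
    if pwm.threshold is None:
        raise ValueError("PWM threshold is unset; derive it from training sites")
    enc = encode(region.sequence)
    scores = _window_scores(pwm.log_odds, enc)
    hits = []
    w = pwm.width
    for pos in np.flatnonzero(~np.isnan(scores) & (scores >= pwm.threshold)):
        pos = int(pos)
        gstart, gend = region.to_genomic(pos, w)
        hits.append(
            SiteInstance(
                contig_id=region.contig_id,
                interval=(gstart, gend),
                strand=region.strand,
                sequence=region.sequence[pos : pos + w],
                score=float(scores[pos]),
                offset_center=region.center_offset(pos, w),
                offset_end=region.end_offset(pos, w),
                anchor_operon_id=region.anchor_operon_id,
                genome_id=region.genome_id,
            )
        )
    return hits


# ---------------------------------------------------------------------------
# Discovery: ZOOPS EM with palindromic symmetrization
# ---------------------------------------------------------------------------


@dataclass
class DiscoveryResult:
    pwm: PWM
    training_sites: list[SiteInstance]
    mean_ic_per_column: float
    adjusted_ic: float
    low_confidence: bool


class _WindowSet:
    """All width-w windows of a promoter set, flattened for vectorized EM."""

    def __init__(self, encs: list[np.ndarray], width: int):
        mats = [np.lib.stride_tricks.sliding_window_view(e, width) for e in encs]
        offsets = np.cumsum([0] + [len(m) for m in mats])
        self.width = width
        self.n_seqs = len(encs)
        self.W = np.vstack(mats).astype(np.int64)
        self.valid = (self.W >= 0).all(axis=1)
        self.Wc = np.where(self.W < 0, 0, self.W)
        self.starts = offsets[:-1]
        self.per_seq = np.diff(offsets)
        self.seq_idx = np.repeat(np.arange(self.n_seqs), self.per_seq)
        self.m_of_window = self.per_seq[self.seq_idx].astype(float)
        self._cols = np.arange(width)[None, :]
        # Self-complementarity of each window: number of base pairs (i,
        # w-1-i) that are complementary (complement of code b is 3 - b).
        # Near-palindromic real sites rank far above background windows,
        # which makes these the natural EM seeds.
        half = width // 2
        pal = (self.Wc[:, :half] == 3 - self.Wc[:, ::-1][:, :half]).sum(axis=1)
        self.pal_score = np.where(self.valid, pal, -1)

    def scores(self, log_odds: np.ndarray) -> np.ndarray:
        s = log_odds[self._cols, self.Wc].sum(axis=1)
        s[~self.valid] = -np.inf
        return s

    def seed_windows(self, n: int, rng: np.random.Generator) -> list[int]:
        """Indices of the ``n`` most palindromic windows with distinct
        sequences (random tie-break among equals)."""
        noise = rng.random(len(self.pal_score))
        order = np.lexsort((noise, -self.pal_score))
        picked: list[int] = []
        seen: set[bytes] = set()
        for j in order:
            if self.pal_score[j] < 0:
                break
            key = self.Wc[j].tobytes()
            if key in seen:
                continue
            seen.add(key)
            picked.append(int(j))
            if len(picked) >= n:
                break
        return picked


def _em_run(
    ws: _WindowSet,
    rng: np.random.Generator,
    background: np.ndarray,
    pseudocount: float,
    max_iter: int,
    tol: float,
    seed_window: int | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """One seeded ZOOPS EM run; returns (freqs, responsibilities, n_eff)."""
    width = ws.width
    # Initialize from a real window (the caller picks palindromic seeds),
    # softened toward background.
    j0 = seed_window if seed_window is not None else rng.choice(np.flatnonzero(ws.valid))
    counts = np.full((width, 4), 1.0)
    counts[np.arange(width), ws.Wc[j0]] += 4.0
    counts = (counts + _revcomp_matrix(counts)) / 2.0
    freqs = counts / counts.sum(axis=1, keepdims=True)
    gamma = 0.75
    log_bg = np.log2(background)
    prev_ll = -np.inf
    r = np.zeros(len(ws.Wc))
    n_eff = 0.0
    for _ in range(max_iter):
        log_odds = np.log2(freqs) - log_bg[None, :]
        scores = ws.scores(log_odds)
        # ZOOPS posterior: a site at window j has prior gamma/m, no site 1-gamma.
        lik = np.where(np.isfinite(scores), np.exp2(scores), 0.0) * (gamma / ws.m_of_window)
        denom = (1.0 - gamma) + np.add.reduceat(lik, ws.starts)
        r = lik / denom[ws.seq_idx]
        ll = float(np.log(np.maximum(denom, 1e-300)).sum())
        n_eff = float(r.sum())
        rv = np.where(ws.valid, r, 0.0)
        counts = np.stack(
            [np.bincount(ws.Wc[:, i], weights=rv, minlength=4) for i in range(width)]
        )
        counts = (counts + _revcomp_matrix(counts)) / 2.0
        freqs = (counts + pseudocount) / (
            counts.sum(axis=1, keepdims=True) + 4.0 * pseudocount
        )
        gamma = float(np.clip(n_eff / ws.n_seqs, 0.05, 0.99))
        if abs(ll - prev_ll) < tol:
            break
        prev_ll = ll
    return freqs, r, n_eff


def discover_palindromic_motif(
    promoters: Sequence[PromoterRegion],
    width_range: tuple[int, int] = (14, 24),
    restarts: int = 3,
    seed: int = 0,
    pseudocount: float = 0.5,
    background: np.ndarray | None = None,
    max_iter: int = 60,
    tol: float = 1e-2,
    ic_floor: float = 0.5,
    coherence_fraction: float = 0.5,
    trim_ic: float = 0.3,
) -> DiscoveryResult:
    """Discover the best palindromic motif of width 14-24 in promoter windows.

    Each candidate width gets ``restarts`` seeded EM runs; the winner is the
    run maximizing total information content minus the per-column
    finite-sample expectation under background (``3 / (2 ln2 n)`` bits per
    column for n effective sites), which prevents trivially preferring the
    widest matrix.  A mean per-column information content below ``ic_floor``
    flags the result as low confidence (background-like).
    """
    if len(promoters) < 2:
        raise ValueError("motif discovery needs at least 2 promoter regions")
    wlo, whi = width_range
    if not (2 <= wlo <= whi):
        raise ValueError(f"invalid width range {width_range}")
    for p in promoters:
        if len(p.sequence) < whi:
            raise ValueError(
                f"promoter {p.anchor_operon_id!r} shorter than maximum "
                f"motif width {whi}"
            )
    bg = UNIFORM_BACKGROUND.copy() if background is None else np.asarray(background, float)
    encs = [encode(p.sequence) for p in promoters]
    rng = np.random.default_rng(seed)
    best = None  # (adjusted_ic, windows, freqs, resp, n_eff)
    for width in range(wlo, whi + 1):
        ws = _WindowSet(encs, width)
        if not ws.valid.any():
            continue
        seeds = ws.seed_windows(restarts, rng)
        for j0 in seeds:
            freqs, resp, n_eff = _em_run(
                ws, rng, bg, pseudocount, max_iter, tol, seed_window=j0
            )
            with np.errstate(divide="ignore", invalid="ignore"):
                ic = float(np.sum(freqs * (np.log2(freqs) - np.log2(bg)[None, :])))
            bias = 3.0 / (2.0 * math.log(2) * max(n_eff, 1.0))
            adjusted = ic - width * bias
            if best is None or adjusted > best[0]:
                best = (adjusted, ws, freqs, resp, n_eff)
    if best is None:
        raise ValueError("no scannable (ACGT) windows in the promoter set")
    adjusted, ws, freqs, resp, n_eff = best
    width = ws.width
    # Trim uninformative flanking columns (symmetric, so both ends match):
    # EM at an overwide window recovers the motif plus background flanks,
    # which would otherwise win the width comparison on accumulated noise.
    with np.errstate(divide="ignore", invalid="ignore"):
        col_ic = np.nansum(
            freqs * (np.log2(freqs) - np.log2(bg)[None, :]), axis=1
        )
    trim = 0
    while (
        width - 2 * (trim + 1) >= wlo
        and col_ic[trim] < trim_ic
        and col_ic[width - 1 - trim] < trim_ic
    ):
        trim += 1
    # Harvest training sites: the top-posterior window of each promoter.
    picks: list[tuple[float, int, int]] = []  # (posterior, promoter idx, pos)
    for i in range(ws.n_seqs):
        seg = resp[ws.starts[i] : ws.starts[i] + ws.per_seq[i]]
        if len(seg) == 0:
            continue
        j = int(np.argmax(seg))
        picks.append((float(seg[j]), i, j + trim))
    width = width - 2 * trim
    chosen = [(i, j) for post, i, j in picks if post > 0.5]
    if not chosen:
        picks.sort(reverse=True)
        chosen = [(i, j) for _, i, j in picks[:1]]
    site_seqs = [promoters[i].sequence[j : j + width] for i, j in chosen]
    pwm = build_pwm(site_seqs, pseudocount=pseudocount, background=bg, symmetrize=True)
    # Coherence cut: in the ZOOPS model every promoter competes for a site,
    # so promoters that actually lack one can contribute background windows.
    # Real site sets are score-coherent; windows scoring far below the median
    # of the harvested set are curation rejects, not training sites.
    if len(chosen) > 2 and coherence_fraction > 0:
        scores = np.array([score_site(pwm, s) for s in site_seqs])
        cut = coherence_fraction * float(np.median(scores))
        kept = [c for c, s in zip(chosen, scores) if s >= cut]
        if len(kept) >= 2 and len(kept) < len(chosen):
            chosen = kept
            site_seqs = [promoters[i].sequence[j : j + width] for i, j in chosen]
            pwm = build_pwm(
                site_seqs, pseudocount=pseudocount, background=bg, symmetrize=True
            )
    training_threshold(pwm, site_seqs)
    sites = []
    for i, j in chosen:
        region = promoters[i]
        gstart, gend = region.to_genomic(j, width)
        sites.append(
            SiteInstance(
                contig_id=region.contig_id,
                interval=(gstart, gend),
                strand=region.strand,
                sequence=region.sequence[j : j + width],
                score=score_site(pwm, region.sequence[j : j + width]),
                offset_center=region.center_offset(j, width),
                offset_end=region.end_offset(j, width),
                anchor_operon_id=region.anchor_operon_id,
                genome_id=region.genome_id,
            )
        )
    mean_ic = pwm.information_content() / width
    return DiscoveryResult(
        pwm=pwm,
        training_sites=sites,
        mean_ic_per_column=mean_ic,
        adjusted_ic=adjusted,
        low_confidence=mean_ic < ic_floor,
    )


# ---------------------------------------------------------------------------
# Null score distribution and detection floor
# ---------------------------------------------------------------------------


def score_pvalue_table(pwm: PWM, bin_width: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Exact null distribution of window scores under the background model.

    Returns (score grid, P(score >= grid value)) computed by per-column
    convolution over discretized log-odds (the standard dynamic-programming
    p-value for PWM matches).
    """
    offsets = np.round(pwm.log_odds / bin_width).astype(int)
    dist = np.array([1.0])  # point mass at score 0
    base = 0
    for i in range(pwm.width):
        col_off = offsets[i]
        new_base = base + col_off.min()
        new_len = len(dist) + col_off.max() - col_off.min()
        new = np.zeros(new_len)
        for b in range(4):
            shift = col_off[b] - col_off.min()
            new[shift : shift + len(dist)] += dist * pwm.background[b]
        dist = new
        base = new_base
    grid = (base + np.arange(len(dist))) * bin_width
    survival = dist[::-1].cumsum()[::-1]
    return grid, survival


def detection_floor(
    pwm: PWM, n_windows: int, expected_false: float = 1.0
) -> float:
    """Smallest score whose expected background hit count over ``n_windows``
    scanned windows stays at or below ``expected_false``."""
    grid, survival = score_pvalue_table(pwm)
    target = expected_false / max(n_windows, 1)
    idx = np.searchsorted(-survival, -target)
    if idx >= len(grid):
        return float(grid[-1])
    return float(grid[idx])


# ---------------------------------------------------------------------------
# Motif comparison
# ---------------------------------------------------------------------------


def _column_correlation(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa < 1e-12 or sb < 1e-12:
        return 1.0 if np.allclose(a, b) else 0.0
    return float(np.corrcoef(a, b)[0, 1])


def motif_similarity(pwm_a: PWM, pwm_b: PWM, min_overlap: int | None = None) -> float:
    """Best mean per-column Pearson correlation over orientations and offsets.

    Returns a value in [-1, 1]; widths differing by more than 4 yield 0.0
    (incomparable).  Symmetric by construction.
    """
    wa, wb = pwm_a.width, pwm_b.width
    if abs(wa - wb) > 4:
        return 0.0
    if min_overlap is None:
        min_overlap = max(4, min(wa, wb) - 4)
    fa = pwm_a.freqs
    best = -1.0
    for fb in (pwm_b.freqs, _revcomp_matrix(pwm_b.freqs)):
        for shift in range(-(wb - min_overlap), wa - min_overlap + 1):
            lo_a, hi_a = max(0, shift), min(wa, shift + wb)
            if hi_a - lo_a < min_overlap:
                continue
            cols_a = fa[lo_a:hi_a]
            cols_b = fb[lo_a - shift : hi_a - shift]
            corr = np.mean(
                [_column_correlation(ca, cb) for ca, cb in zip(cols_a, cols_b)]
            )
            best = max(best, float(corr))
    return best


def consensus_distance(a: str, b: str) -> int:
    """Distance between two consensus strings: best-aligned mismatches plus
    the width difference, minimized over orientation and shift."""
    best = None
    for bb in (b, reverse_complement(b)):
        for shift in range(-len(bb) + 1, len(a)):
            lo_a, hi_a = max(0, shift), min(len(a), shift + len(bb))
            if hi_a <= lo_a:
                continue
            mism = sum(
                1
                for i in range(lo_a, hi_a)
                if a[i] != bb[i - shift]
            )
            d = mism + (len(a) - (hi_a - lo_a)) + (len(bb) - (hi_a - lo_a))
            if best is None or d < best:
                best = d
    return best if best is not None else max(len(a), len(b))


# ---------------------------------------------------------------------------
# MEME minimal motif format and TSV export
# ---------------------------------------------------------------------------


def write_meme(pwms: Iterable[PWM], path: str | Path) -> None:
    """Write motifs in MEME minimal format (threshold kept in a comment)."""
    pwms = list(pwms)
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        bg = pwms[0].background if pwms else UNIFORM_BACKGROUND
        fh.write("Background letter frequencies\n")
        fh.write(
            " ".join(f"{b} {f:.5f}" for b, f in zip(BASES, bg)) + "\n\n"
        )
        for pwm in pwms:
            fh.write(f"MOTIF {pwm.name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {pwm.width} "
                f"nsites= {max(pwm.n_sites, 1)} E= 0\n"
            )
            for row in pwm.freqs:
                fh.write(" " + " ".join(f"{x:.6f}" for x in row) + "\n")
            if pwm.threshold is not None:
                fh.write(f"# regulonkit threshold_bits= {pwm.threshold:.6f}\n")
            fh.write("\n")


def read_meme(path: str | Path) -> list[PWM]:
    pwms: list[PWM] = []
    background = UNIFORM_BACKGROUND.copy()
    lines = Path(path).read_text().splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            parts = lines[i + 1].split()
            background = np.array([float(parts[k]) for k in (1, 3, 5, 7)])
            i += 2
            continue
        if line.startswith("MOTIF"):
            name = line.split(None, 1)[1].strip()
            i += 1
            header = lines[i].strip()
            assert header.startswith("letter-probability matrix")
            tokens = header.replace("=", " = ").split()
            width = int(tokens[tokens.index("w") + 2])
            nsites = int(tokens[tokens.index("nsites") + 2])
            rows = []
            for k in range(width):
                rows.append([float(x) for x in lines[i + 1 + k].split()])
            i += 1 + width
            threshold = None
            if i < len(lines) and "threshold_bits=" in lines[i]:
                threshold = float(lines[i].split("threshold_bits=")[1])
                i += 1
            freqs = np.array(rows)
            pwms.append(
                PWM(
                    freqs=freqs,
                    background=background.copy(),
                    palindromic=bool(
                        np.allclose(freqs, _revcomp_matrix(freqs), atol=1e-4)
                    ),
                    threshold=threshold,
                    n_sites=nsites,
                    name=name,
                )
            )
            continue
        i += 1
    return pwms


def pwm_to_table(pwm: PWM) -> "pd.DataFrame":
    import pandas as pd

    return pd.DataFrame(pwm.freqs, columns=list(BASES)).rename_axis("position")
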