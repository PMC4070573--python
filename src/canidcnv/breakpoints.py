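"""Breakpoint architecture: GC peaks, homology and repeat enrichment.

CNV breakpoints are represented as fixed-width windows (400 bp by default,
the size of the smallest detectable CNV) centred on the inferred start and
end coordinates, absorbing the positional uncertainty of array calls.
Three NAHR-motivated analyses run on these windows:

* GC peaks — >=500 bp spans whose GC fraction exceeds 1.5x that of a
  centred 10 kb background window — and their enrichment near breakpoints;
* the longest stretch of perfect homology between the two windows of a
  pair, against a null where pairs are re-placed uniformly on their own
  chromosome with the intra-pair distance preserved (Wilcoxon rank-sum);
* repeat-family overlap enrichment (with L1 elements stratified by age
  class), by the same chromosome-wise redistribution, across a range of
  window sizes.

All randomizations are deterministic given their seed. N bases never count
toward GC denominators and never match in homology; windows that are more
than half N are dropped from GC profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._stats import empirical_p
from .io_formats import GenomeSequence, IntervalSet


@dataclass
class BreakpointPair:
    cnv_id: str
    chrom: str
    left_start: int
    left_end: int
    right_start: int
    right_end: int
    left_seq: str = ""
    right_seq: str = ""

    @property
    def left_center(self) -> int:
        return (self.left_start + self.left_end) // 2

    @property
    def right_center(self) -> int:
        return (self.right_start + self.right_end) // 2

    @property
    def distance(self) -> int:
        """Distance between the two breakpoint centres (the CNV length)."""
        return self.right_center - self.left_center


@dataclass
class GCPeak:
    chrom: str
    start: int
    end: int
    peak_gc: float
    background_gc: float


@dataclass
class EnrichmentResult:
    label: str
    observed: float
    null_mean: float
    null_sd: float
    n_resamples: int
    p_value: float

    @property
    def ratio(self) -> float:
        return self.observed / self.null_mean if self.null_mean > 0 else float("inf")


def gc_fraction(seq: str) -> float:
    """GC fraction with N excluded from the denominator; NaN if all N."""
    n_acgt = len(seq) - seq.count("N")
    if n_acgt == 0:
        return float("nan")
    return (seq.count("G") + seq.count("C")) / n_acgt


# ---------------------------------------------------------------------------
# Breakpoint windows
# ---------------------------------------------------------------------------


def make_breakpoint_pairs(
    cnvs: IntervalSet, genome: GenomeSequence, window: int = 400
) -> list[BreakpointPair]:
    """Windows of ``window`` bp centred on each CNV's start and end.

    CNVs shorter than the window are skipped; windows running off a
    chromosome edge are clipped (both with a warning).
    """
    lengths = genome.lengths
    pairs: list[BreakpointPair] = []
    half = window // 2
    for rec in cnvs:
        if rec.end - rec.start < window:
            warnings.warn(
                f"CNV {rec.label} ({rec.end - rec.start} bp) shorter than the "
                f"{window} bp breakpoint window; skipped"
            )
            continue
        chrom_len = lengths[rec.chrom]
        ls, le = rec.start - half, rec.start + half
        rs, re_ = rec.end - half, rec.end + half
        if ls < 0 or re_ > chrom_len:
            warnings.warn(f"breakpoint window of {rec.label} clipped at chromosome edge")
        ls, le = max(0, ls), min(chrom_len, le)
        rs, re_ = max(0, rs), min(chrom_len, re_)
        pairs.append(
            BreakpointPair(
                cnv_id=rec.label, chrom=rec.chrom,
                left_start=ls, left_end=le, right_start=rs, right_end=re_,
                left_seq=genome.fetch(rec.chrom, ls, le),
                right_seq=genome.fetch(rec.chrom, rs, re_),
            )
        )
    return pairs


def _redistribute(
    pairs: list[BreakpointPair],
    genome: GenomeSequence,
    rng: np.random.Generator,
    window: int,
) -> list[BreakpointPair]:
    """Re-place each pair uniformly on its own chromosome, keeping the two
    breakpoints at the same distance from each other; windows must fit."""
    lengths = genome.lengths
    half = window // 2
    out = []
    for pair in pairs:
        chrom_len = lengths[pair.chrom]
        d = pair.distance
        lo, hi = half, chrom_len - d - half
        if hi <= lo:
            raise ValueError(
                f"chromosome {pair.chrom} too short to re-place pair {pair.cnv_id}"
            )
        lc = int(rng.integers(lo, hi))
        rc = lc + d
        out.append(
            BreakpointPair(
                cnv_id=pair.cnv_id, chrom=pair.chrom,
                left_start=lc - half, left_end=lc + half,
                right_start=rc - half, right_end=rc + half,
                left_seq=genome.fetch(pair.chrom, lc - half, lc + half),
                right_seq=genome.fetch(pair.chrom, rc - half, rc + half),
            )
        )
    return out


# ---------------------------------------------------------------------------
# GC peaks
# ---------------------------------------------------------------------------


def _window_gc_passes(
    seq: str, start: int, end: int, background: int, factor: float
) -> bool:
    c = (start + end) // 2
    bs = max(0, c - background // 2)
    be = min(len(seq), c + background // 2)
    peak_gc = gc_fraction(seq[start:end])
    bg_gc = gc_fraction(seq[bs:be])
    if np.isnan(peak_gc) or np.isnan(bg_gc) or bg_gc == 0:
        return False
    return peak_gc > factor * bg_gc


def detect_gc_peaks(
    genome: GenomeSequence,
    peak_window: int = 500,
    background_window: int = 10_000,
    step: int = 100,
    rel_increase: float = 0.5,
) -> list[GCPeak]:
    """Slide a peak window and a centred background window together and
    report maximal spans whose GC exceeds (1 + rel_increase) x background.

    Qualifying overlapping/adjacent peak windows are merged; a merged span
    is re-checked against its own background and shrunk back to its best
    qualifying window if the merged span no longer qualifies, so every
    reported peak satisfies the criterion directly against the sequence.
    The background window always includes the peak span.
    """
    factor = 1.0 + rel_increase
    peaks: list[GCPeak] = []
    for chrom, seq in genome.chroms.items():
        n = len(seq)
        if n < background_window:
            continue
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        is_gc = ((arr == ord("G")) | (arr == ord("C"))).astype(np.int64)
        is_n = (arr == ord("N")).astype(np.int64)
        cum_gc = np.concatenate(([0], np.cumsum(is_gc)))
        cum_n = np.concatenate(([0], np.cumsum(is_n)))

        def frac(a: int, b: int) -> float:
            denom = (b - a) - (cum_n[b] - cum_n[a])
            if denom <= 0:
                return float("nan")
            return (cum_gc[b] - cum_gc[a]) / denom

        starts = np.arange(0, n - peak_window + 1, step)
        qualifying: list[tuple[int, int, float]] = []
        for s in starts:
            e = s + peak_window
            if (cum_n[e] - cum_n[s]) * 2 > peak_window:
                continue
            c = (s + e) // 2
            bs, be = max(0, c - background_window // 2), min(n, c + background_window // 2)
            pg, bg = frac(s, e), frac(bs, be)
            if not (np.isnan(pg) or np.isnan(bg)) and bg > 0 and pg > factor * bg:
                qualifying.append((int(s), int(e), pg))
        # merge overlapping/adjacent qualifying windows into maximal spans
        i = 0
        while i < len(qualifying):
            s, e, best_gc = qualifying[i]
            best = (s, e)
            j = i + 1
            while j < len(qualifying) and qualifying[j][0] <= e:
                if qualifying[j][2] > best_gc:
                    best_gc = qualifying[j][2]
                    best = (qualifying[j][0], qualifying[j][1])
                e = max(e, qualifying[j][1])
                j += 1
            span = (s, e)
            if not _window_gc_passes(seq, s, e, background_window, factor):
                span = best  # fall back to the strongest constituent window
            c = (span[0] + span[1]) // 2
            bs, be = max(0, c - background_window // 2), min(n, c + background_window // 2)
            peaks.append(
                GCPeak(chrom, span[0], span[1], frac(span[0], span[1]), frac(bs, be))
            )
            i = j
    return peaks


def _overlap_counts(
    starts: np.ndarray, ends: np.ndarray, win_starts: np.ndarray, win_ends: np.ndarray
) -> np.ndarray:
    """For each query window, the number of intervals overlapping it by >=1 bp.

    ``starts``/``ends`` must be the interval starts sorted ascending and the
    interval ends sorted ascending (independently).
    """
    return np.searchsorted(starts, win_ends, side="left") - np.searchsorted(
        ends, win_starts, side="right"
    )


def _pairs_overlapping_peaks(
    pairs: list[BreakpointPair],
    peaks_by_chrom: dict[str, tuple[np.ndarray, np.ndarray]],
    offset: int,
    lengths: dict[str, int],
) -> int:
    """Number of breakpoint windows that, shifted ``offset`` bp outward
    (left window left, right window right), overlap >= 1 GC peak."""
    count = 0
    for pair in pairs:
        if pair.chrom not in peaks_by_chrom:
            continue
        starts, ends = peaks_by_chrom[pair.chrom]
        for ws, we, sign in (
            (pair.left_start, pair.left_end, -1),
            (pair.right_start, pair.right_end, +1),
        ):
            s, e = ws + sign * offset, we + sign * offset
            s, e = max(0, s), min(lengths[pair.chrom], e)
            if e <= s:
                continue
            n = np.searchsorted(starts, e, side="left") - np.searchsorted(
                ends, s, side="right"
            )
            if n > 0:
                count += 1
    return count


def gc_peak_breakpoint_profile(
    peaks: list[GCPeak],
    pairs: list[BreakpointPair],
    genome: GenomeSequence,
    step: int = 400,
    max_distance: int = 4_000,
    n_resamples: int = 1000,
    seed: int = 0,
    window: int = 400,
) -> list[EnrichmentResult]:
    """Enrichment of GC peaks at increasing outward distance from breakpoints.

    For each distance bin (0, step, 2*step, ... up to max_distance) the
    observed count of peak-overlapping breakpoint windows is compared with
    a null built by chromosome-wise random redistribution of the pairs.
    """
    rng = np.random.default_rng(seed)
    lengths = genome.lengths
    peaks_by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {p.chrom for p in peaks}:
        ch = [p for p in peaks if p.chrom == chrom]
        peaks_by_chrom[chrom] = (
            np.sort(np.array([p.start for p in ch])),
            np.sort(np.array([p.end for p in ch])),
        )
    offsets = list(range(0, max_distance + 1, step))
    observed = [
        _pairs_overlapping_peaks(pairs, peaks_by_chrom, off, lengths)
        for off in offsets
    ]
    null = np.zeros((n_resamples, len(offsets)))
    for i in range(n_resamples):
        rand_pairs = _redistribute(pairs, genome, rng, window)
        for j, off in enumerate(offsets):
            null[i, j] = _pairs_overlapping_peaks(
                rand_pairs, peaks_by_chrom, off, lengths
            )
    results = []
    for j, off in enumerate(offsets):
        results.append(
            EnrichmentResult(
                label=f"distance_{off}",
                observed=float(observed[j]),
                null_mean=float(null[:, j].mean()),
                null_sd=float(null[:, j].std(ddof=1)) if n_resamples > 1 else 0.0,
                n_resamples=n_resamples,
                p_value=empirical_p(null[:, j], observed[j], "greater"),
            )
        )
    return results


def gc_profile_around_breakpoints(
    pairs: list[BreakpointPair],
    genome: GenomeSequence,
    window: int = 400,
    flank: int = 4_000,
) -> "np.recarray":
    """Mean GC in sliding windows at signed distances around breakpoints.

    Negative positions lie inside the CNV, positive outside; windows step
    by one window width and are recorded at their centre. At each inside
    position only CNVs long enough to contain the window contribute, and
    the contributing proportion is reported alongside the mean. Windows
    with more than 50% N are dropped.
    """
    if flank % window != 0:
        raise ValueError("flank must be a multiple of the window size")
    lengths = genome.lengths
    positions = np.arange(-flank, flank + 1, window)
    means = np.full(len(positions), np.nan)
    coverage = np.zeros(len(positions))
    half = window // 2
    n_pairs = len(pairs)
    for k, x in enumerate(positions):
        vals = []
        contributing = 0
        for pair in pairs:
            cnv_len = pair.distance
            if x < 0 and (-x) + half > cnv_len:
                continue
            contributing += 1
            for center in (pair.left_center - x, pair.right_center + x):
                s, e = center - half, center + half
                if s < 0 or e > lengths[pair.chrom]:
                    continue
                seq = genome.fetch(pair.chrom, s, e)
                if seq.count("N") * 2 > len(seq):
                    continue
                vals.append(gc_fraction(seq))
        means[k] = float(np.mean(vals)) if vals else np.nan
        coverage[k] = contributing / n_pairs if n_pairs else 0.0
    out = np.recarray(len(positions), dtype=[("position", int), ("gc", float),
                                             ("coverage", float)])
    out.position, out.gc, out.coverage = positions, means, coverage
    return out


# ---------------------------------------------------------------------------
# Perfect homology
# ---------------------------------------------------------------------------


def _has_common_substring(a: str, b: str, length: int) -> bool:
    if length == 0:
        return True
    subs = {
        a[i : i + length]
        for i in range(len(a) - length + 1)
        if "N" not in a[i : i + length]
    }
    if not subs:
        return False
    return any(
        b[i : i + length] in subs
        for i in range(len(b) - length + 1)
        if "N" not in b[i : i + length]
    )


def longest_perfect_homology(a: str, b: str) -> int:
    """Length of the longest common substring of two sequences; N never
    matches. Binary search over the answer with exact substring sets."""
    if not a or not b:
        return 0
    lo, hi = 0, min(len(a), len(b))
    while lo < hi:
        mid = (lo + hi + 1) // 2
        if _has_common_substring(a, b, mid):
            lo = mid
        else:
            hi = mid - 1
    return lo


def homology_permutation_test(
    pairs: list[BreakpointPair],
    genome: GenomeSequence,
    n_permutations: int = 100,
    seed: int = 0,
    window: int = 400,
) -> tuple[float, float, float]:
    """(observed mean, null mean, Wilcoxon rank-sum p).

    Observed: per-pair longest perfect homology between the two breakpoint
    windows. Null: the same statistic for the pairs re-placed uniformly on
    their own chromosome (intra-pair distance preserved), pooled over
    permutations. The p-value is a two-sample Wilcoxon rank-sum between the
    observed and the pooled null per-pair values (exact for small samples,
    normal approximation with tie correction otherwise).
    """
    if len(pairs) < 2:
        raise ValueError("need >= 2 breakpoint pairs")
    rng = np.random.default_rng(seed)
    obs = np.array(
        [longest_perfect_homology(p.left_seq, p.right_seq) for p in pairs], float
    )
    null_vals = []
    for _ in range(n_permutations):
        for rp in _redistribute(pairs, genome, rng, window):
            null_vals.append(longest_perfect_homology(rp.left_seq, rp.right_seq))
    null = np.array(null_vals, float)
    method = "exact" if len(obs) + len(null) < 30 else "asymptotic"
    res = stats.mannwhitneyu(obs, null, alternative="two-sided", method=method)
    return float(obs.mean()), float(null.mean()), float(res.pvalue)


# ---------------------------------------------------------------------------
# Repeat enrichment
# ---------------------------------------------------------------------------


def _windows_overlapping(
    pairs: list[BreakpointPair],
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]],
    size: int,
    lengths: dict[str, int],
) -> int:
    count = 0
    half = size // 2
    for pair in pairs:
        if pair.chrom not in by_chrom:
            continue
        starts, ends = by_chrom[pair.chrom]
        for center in (pair.left_center, pair.right_center):
            s, e = max(0, center - half), min(lengths[pair.chrom], center + half)
            n = np.searchsorted(starts, e, side="left") - np.searchsorted(
                ends, s, side="right"
            )
            if n > 0:
                count += 1
    return count


def repeat_enrichment(
    pairs: list[BreakpointPair],
    repeats: IntervalSet,
    genome: GenomeSequence,
    families: list[str] | None = None,
    n_resamples: int = 1000,
    seed: int = 0,
    window_sizes: list[int] | None = None,
) -> dict[tuple[str, int], EnrichmentResult]:
    """Observed/expected breakpoint-window overlap per repeat family and
    window size, null by chromosome-wise pair redistribution.

    Returns {(family, window_size): EnrichmentResult}; the expected count
    is the null mean and the p-value is the upper-tail add-one fraction.
    """
    known = set(repeats.labels())
    families = families if families is not None else sorted(known)
    unknown = set(families) - known
    if unknown:
        raise ValueError(f"unknown repeat family labels: {sorted(unknown)}")
    window_sizes = window_sizes or [400]
    lengths = genome.lengths
    fam_index: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = {}
    for fam in families:
        sub = repeats.with_label(fam)
        fam_index[fam] = {
            chrom: (
                np.sort(sub.df.loc[sub.df["chrom"] == chrom, "start"].to_numpy()),
                np.sort(sub.df.loc[sub.df["chrom"] == chrom, "end"].to_numpy()),
            )
            for chrom in sub.df["chrom"].unique()
        }
    results: dict[tuple[str, int], EnrichmentResult] = {}
    for size in window_sizes:
        rng = np.random.default_rng((seed, size))
        observed = {
            fam: _windows_overlapping(pairs, fam_index[fam], size, lengths)
            for fam in families
        }
        null = {fam: np.zeros(n_resamples) for fam in families}
        for i in range(n_resamples):
            rand_pairs = _redistribute(pairs, genome, rng, size)
            for fam in families:
                null[fam][i] = _windows_overlapping(
                    rand_pairs, fam_index[fam], size, lengths
                )
        for fam in families:
            results[(fam, size)] = EnrichmentResult(
                label=f"{fam}@{size}",
                observed=float(observed[fam]),
                null_mean=float(null[fam].mean()),
                null_sd=float(null[fam].std(ddof=1)) if n_resamples > 1 else 0.0,
                n_resamples=n_resamples,
                p_value=empirical_p(null[fam], observed[fam], "greater"),
            )
    return results
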