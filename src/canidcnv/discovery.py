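"""Stage 1: per-sample CNV discovery and cross-sample region definition.

Two independent callers run on every sample track and are combined
conservatively:

* a fixed-architecture 3-state (loss / normal / gain) Gaussian hidden
  Markov model decoded per chromosome, with forward-backward posterior
  probabilities backing the confidence filters, and
* a robust run-length caller flagging maximal runs of probes beyond
  +-k robust SDs of the chromosome median.

An HMM segment survives only if at least half of its length is covered by
a same-state segment from the run-length caller. Surviving segments are
filtered on their average posterior (>0.60 at >=50 probes, >0.75 at 30-49,
discarded below 30 probes), joined within a sample when less than 3 kb
apart or when the intervening bases are more than 80% repeats or gaps, and
finally unioned across samples into CNV regions for genotyping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .io_formats import IntervalSet, ProbeTrack

STATES = ("loss", "normal", "gain")


@dataclass
class HMMParams:
    """Emission means for loss/normal/gain, shared SD and self-transition.

    ``sd=None`` estimates the emission SD from the track's median absolute
    deviation (scaled to Gaussian SD), which is robust to the CNV probes.
    """

    means: tuple[float, float, float] = (-0.6, 0.0, 0.45)
    sd: float | None = None
    self_transition: float = 0.999

    def __post_init__(self) -> None:
        if not self.means[0] < 0.0 < self.means[2]:
            raise ValueError("need loss mean < 0 < gain mean")
        if not 0.0 < self.self_transition < 1.0:
            raise ValueError("self-transition must be in (0,1)")


@dataclass
class SecondCallerParams:
    k_sd: float = 2.0
    min_probes: int = 30


@dataclass
class FilterParams:
    """Average-posterior confidence filter thresholds."""

    min_probes: int = 30
    mid_probes: int = 50  # boundary between the two posterior rules
    posterior_small: float = 0.75  # segments with min_probes..mid_probes-1 probes
    posterior_large: float = 0.60  # segments with >= mid_probes probes


@dataclass
class MergeParams:
    max_gap: int = 3_000
    repeat_gap_fraction: float = 0.80


@dataclass
class CNVSegment:
    sample: str
    chrom: str
    start: int
    end: int
    state: str  # 'loss' | 'gain'
    n_probes: int
    mean_log2: float
    posterior: float = float("nan")

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("segment start >= end")
        if self.n_probes < 1:
            raise ValueError("segment needs >= 1 probe")
        if self.state not in ("loss", "gain"):
            raise ValueError(f"bad segment state {self.state!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class CNVRegion:
    region_id: str
    chrom: str
    start: int
    end: int
    segments: list[CNVSegment] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start


def robust_sd(values: np.ndarray) -> float:
    """Gaussian-consistent SD from the median absolute deviation."""
    med = np.median(values)
    mad = np.median(np.abs(values - med))
    return float(1.4826 * mad)


# ---------------------------------------------------------------------------
# HMM caller
# ---------------------------------------------------------------------------


def _log_gauss(x: np.ndarray, mean: float, sd: float) -> np.ndarray:
    return -0.5 * ((x - mean) / sd) ** 2 - np.log(sd * np.sqrt(2 * np.pi))


def forward_backward(
    values: np.ndarray, params: HMMParams, sd: float
) -> np.ndarray:
    """Posterior state probabilities, shape (n, 3), rows summing to 1."""
    n = len(values)
    k = 3
    log_b = np.stack([_log_gauss(values, m, sd) for m in params.means], axis=1)
    p_stay = params.self_transition
    trans = np.full((k, k), (1.0 - p_stay) / (k - 1))
    np.fill_diagonal(trans, p_stay)
    log_trans = np.log(trans)
    log_pi = np.log(np.full(k, 1.0 / k))

    log_alpha = np.empty((n, k))
    log_alpha[0] = log_pi + log_b[0]
    for t in range(1, n):
        log_alpha[t] = log_b[t] + _logsumexp_rows(log_alpha[t - 1][:, None] + log_trans)
    log_beta = np.zeros((n, k))
    for t in range(n - 2, -1, -1):
        v = log_b[t + 1] + log_beta[t + 1]
        log_beta[t] = _logsumexp_rows((log_trans + v[None, :]).T)
    log_gamma = log_alpha + log_beta
    log_gamma -= log_gamma.max(axis=1, keepdims=True)
    gamma = np.exp(log_gamma)
    gamma /= gamma.sum(axis=1, keepdims=True)
    return gamma


def _logsumexp_rows(m: np.ndarray) -> np.ndarray:
    mx = m.max(axis=0)
    return mx + np.log(np.exp(m - mx[None, :]).sum(axis=0))


def viterbi(values: np.ndarray, params: HMMParams, sd: float) -> np.ndarray:
    """Most probable state path; 0=loss, 1=normal, 2=gain."""
    n = len(values)
    k = 3
    log_b = np.stack([_log_gauss(values, m, sd) for m in params.means], axis=1)
    p_stay = params.self_transition
    trans = np.full((k, k), (1.0 - p_stay) / (k - 1))
    np.fill_diagonal(trans, p_stay)
    log_trans = np.log(trans)
    delta = np.log(np.full(k, 1.0 / k)) + log_b[0]
    psi = np.zeros((n, k), dtype=np.int8)
    for t in range(1, n):
        scores = delta[:, None] + log_trans
        psi[t] = scores.argmax(axis=0)
        delta = scores.max(axis=0) + log_b[t]
    path = np.empty(n, dtype=np.int8)
    path[-1] = int(delta.argmax())
    for t in range(n - 2, -1, -1):
        path[t] = psi[t + 1][path[t + 1]]
    return path


def segment_hmm(track: ProbeTrack, params: HMMParams | None = None) -> list[CNVSegment]:
    """Decode each chromosome with the 3-state Gaussian HMM and return the
    maximal non-normal Viterbi runs, each annotated with the mean posterior
    of its called state over its probes."""
    params = params or HMMParams()
    segments: list[CNVSegment] = []
    for chrom in track.chroms:
        pos, val = track.chrom_arrays(chrom)
        if len(val) < 2:
            warnings.warn(f"chromosome {chrom}: fewer than 2 probes, skipped")
            continue
        sd = params.sd if params.sd is not None else max(robust_sd(val), 1e-6)
        path = viterbi(val, params, sd)
        gamma = forward_backward(val, params, sd)
        for s, e in _runs(path != 1):
            # a non-normal run may switch loss<->gain; split by state
            for ss, ee in _runs_by_value(path, s, e):
                st = int(path[ss])
                seg = CNVSegment(
                    sample=track.sample,
                    chrom=chrom,
                    start=int(pos[ss]),
                    end=int(pos[ee - 1]) + 1,
                    state="loss" if st == 0 else "gain",
                    n_probes=ee - ss,
                    mean_log2=float(val[ss:ee].mean()),
                    posterior=float(gamma[ss:ee, st].mean()),
                )
                segments.append(seg)
    return segments


def _runs(mask: np.ndarray):
    """Maximal runs of True; yields (start, end) index pairs."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    for s, e in zip(idx[0::2], idx[1::2]):
        yield int(s), int(e)


def _runs_by_value(path: np.ndarray, start: int, end: int):
    """Split [start, end) into maximal constant-value runs."""
    s = start
    for i in range(start + 1, end + 1):
        if i == end or path[i] != path[s]:
            yield s, i
            s = i


# ---------------------------------------------------------------------------
# Run-length threshold caller
# ---------------------------------------------------------------------------


def second_caller(
    track: ProbeTrack, params: SecondCallerParams | None = None
) -> list[CNVSegment]:
    """Flag maximal runs of >= min_probes consecutive probes all beyond
    +-k robust SDs of the chromosome median."""
    params = params or SecondCallerParams()
    segments: list[CNVSegment] = []
    for chrom in track.chroms:
        pos, val = track.chrom_arrays(chrom)
        if len(val) == 0:
            continue
        med = float(np.median(val))
        sd = max(robust_sd(val), 1e-6)
        hi = val > med + params.k_sd * sd
        lo = val < med - params.k_sd * sd
        for mask, state in ((lo, "loss"), (hi, "gain")):
            for s, e in _runs(mask):
                if e - s < params.min_probes:
                    continue
                segments.append(
                    CNVSegment(
                        sample=track.sample,
                        chrom=chrom,
                        start=int(pos[s]),
                        end=int(pos[e - 1]) + 1,
                        state=state,
                        n_probes=e - s,
                        mean_log2=float(val[s:e].mean()),
                    )
                )
    segments.sort(key=lambda g: (g.chrom, g.start))
    return segments


# ---------------------------------------------------------------------------
# Combination, filtering, merging
# ---------------------------------------------------------------------------


def combine_callers(
    hmm_segments: list[CNVSegment], other_segments: list[CNVSegment],
    min_coverage: float = 0.5,
) -> list[CNVSegment]:
    """Conservative intersection: keep an HMM segment iff same-state
    segments from the other caller cover >= ``min_coverage`` of its length;
    surviving coordinates are the HMM segment's."""
    kept = []
    for seg in hmm_segments:
        cover = 0
        pieces = sorted(
            (max(seg.start, o.start), min(seg.end, o.end))
            for o in other_segments
            if o.chrom == seg.chrom and o.state == seg.state
            and o.start < seg.end and seg.start < o.end
        )
        # union of intersection pieces
        cur_s = cur_e = None
        for a, b in pieces:
            if cur_e is None or a > cur_e:
                if cur_e is not None:
                    cover += cur_e - cur_s
                cur_s, cur_e = a, b
            else:
                cur_e = max(cur_e, b)
        if cur_e is not None:
            cover += cur_e - cur_s
        if cover >= min_coverage * seg.length:
            kept.append(seg)
    return kept


def filter_segments(
    segments: list[CNVSegment], params: FilterParams | None = None
) -> list[CNVSegment]:
    """Confidence filter on probe count and average posterior probability."""
    p = params or FilterParams()
    out = []
    for seg in segments:
        if seg.n_probes < p.min_probes:
            continue
        threshold = (
            p.posterior_large if seg.n_probes >= p.mid_probes else p.posterior_small
        )
        if seg.posterior > threshold:
            out.append(seg)
    return out


def merge_within_sample(
    segments: list[CNVSegment],
    repeats: IntervalSet,
    gaps: IntervalSet,
    track: ProbeTrack | None = None,
    params: MergeParams | None = None,
) -> list[CNVSegment]:
    """Join same-state segments of one sample when they are < 3 kb apart or
    the open interval between them is > 80% repeats or gaps; transitive.

    Probe count and mean log2 of a merged segment are recomputed from the
    track when one is supplied, else summed / length-weighted.
    """
    p = params or MergeParams()
    out: list[CNVSegment] = []
    by_key: dict[tuple[str, str], list[CNVSegment]] = {}
    for seg in segments:
        by_key.setdefault((seg.chrom, seg.state), []).append(seg)
    for (chrom, state), segs in by_key.items():
        segs = sorted(segs, key=lambda s: s.start)
        cluster = [segs[0]]
        for seg in segs[1:]:
            prev = cluster[-1]
            gap_len = seg.start - prev.end
            join = gap_len < p.max_gap
            if not join and gap_len > 0:
                covered = repeats.covered_bases(chrom, prev.end, seg.start)
                covered = max(covered, 0) + gaps.covered_bases(chrom, prev.end, seg.start)
                covered = min(covered, gap_len)
                join = covered / gap_len > p.repeat_gap_fraction
            if join:
                cluster.append(seg)
            else:
                out.append(_fuse(cluster, track))
                cluster = [seg]
        out.append(_fuse(cluster, track))
    out.sort(key=lambda s: (s.chrom, s.start))
    return out


def _fuse(cluster: list[CNVSegment], track: ProbeTrack | None) -> CNVSegment:
    if len(cluster) == 1:
        return cluster[0]
    first, last = cluster[0], cluster[-1]
    start, end = first.start, last.end
    if track is not None:
        mean, n = track.region_mean(first.chrom, start, end)
    else:
        n = sum(s.n_probes for s in cluster)
        mean = sum(s.mean_log2 * s.n_probes for s in cluster) / n
    post = float(np.mean([s.posterior for s in cluster]))
    return CNVSegment(
        sample=first.sample, chrom=first.chrom, start=start, end=end,
        state=first.state, n_probes=n, mean_log2=mean, posterior=post,
    )


def define_regions(all_segments: list[CNVSegment]) -> list[CNVRegion]:
    """Single-linkage union of overlapping (>= 1 bp) segments across all
    samples, ignoring state; regions sorted by coordinate and id'd."""
    regions: list[CNVRegion] = []
    by_chrom: dict[str, list[CNVSegment]] = {}
    for seg in all_segments:
        by_chrom.setdefault(seg.chrom, []).append(seg)
    raw: list[tuple[str, int, int, list[CNVSegment]]] = []
    for chrom in sorted(by_chrom):
        segs = sorted(by_chrom[chrom], key=lambda s: s.start)
        cur = [segs[0]]
        cur_end = segs[0].end
        for seg in segs[1:]:
            if seg.start < cur_end:  # >=1 bp overlap
                cur.append(seg)
                cur_end = max(cur_end, seg.end)
            else:
                raw.append((chrom, cur[0].start, cur_end, cur))
                cur = [seg]
                cur_end = seg.end
        raw.append((chrom, cur[0].start, cur_end, cur))
    for i, (chrom, start, end, segs) in enumerate(raw):
        regions.append(CNVRegion(f"region_{i:04d}", chrom, start, end, segs))
    return regions


def discover_sample(
    track: ProbeTrack,
    repeats: IntervalSet,
    gaps: IntervalSet,
    hmm_params: HMMParams | None = None,
    caller2_params: SecondCallerParams | None = None,
    filter_params: FilterParams | None = None,
    merge_params: MergeParams | None = None,
) -> list[CNVSegment]:
    """The full per-sample discovery stack: HMM + run-length caller,
    conservative combination, confidence filter, within-sample merging."""
    hmm_segs = segment_hmm(track, hmm_params)
    rl_segs = second_caller(track, caller2_params)
    combined = combine_callers(hmm_segs, rl_segs)
    filtered = filter_segments(combined, filter_params)
    if not filtered:
        return []
    return merge_within_sample(filtered, repeats, gaps, track, merge_params)
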