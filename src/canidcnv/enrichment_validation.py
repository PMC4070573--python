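"""Gene-overlap randomization tests and quality-control computations.

The gene-enrichment test asks whether a target set of CNV regions holds
more (or fewer) genes than expected for region sets of the same number and
lengths drawn from a universe — here the array footprint, i.e. the full
set of assayed regions. The QC side reproduces the study's false-discovery
accounting: calls on single-copy control regions, calls on self-self
hybridizations, and concordance of array calls with qPCR copy numbers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import empirical_p
from .discovery import discover_sample
from .io_formats import IntervalSet, ProbeTrack, floor_truncate_percent


@dataclass
class GeneOverlapTest:
    observed: int
    null_counts: np.ndarray
    p_value: float

    @property
    def null_mean(self) -> float:
        return float(self.null_counts.mean())


@dataclass
class ConcordanceReport:
    comparisons: int
    false_positive_rate: float
    false_negative_rate: float

    def __post_init__(self) -> None:
        for rate in (self.false_positive_rate, self.false_negative_rate):
            if not (0.0 <= rate <= 1.0 or np.isnan(rate)):
                raise ValueError("rates must lie in [0,1]")


def count_gene_overlaps(regions: IntervalSet, genes: IntervalSet) -> int:
    """Number of distinct genes overlapping (>= 1 bp) any region."""
    hit: set[int] = set()
    for chrom in genes.df["chrom"].unique():
        gsub = genes.df[genes.df["chrom"] == chrom]
        rstarts, rends = regions.by_chrom(chrom)
        if len(rstarts) == 0:
            continue
        order = np.argsort(rstarts)
        rs, re_ = rstarts[order], rends[order]
        re_sorted = np.sort(re_)
        n = np.searchsorted(rs, gsub["end"].to_numpy(), side="left") - np.searchsorted(
            re_sorted, gsub["start"].to_numpy(), side="right"
        )
        hit.update(gsub.index[n > 0])
    return len(hit)


def gene_enrichment_test(
    target: IntervalSet,
    universe: IntervalSet,
    genes: IntervalSet,
    n_resamples: int = 1000,
    seed: int = 0,
) -> GeneOverlapTest:
    """Two-sided randomization test of gene content in the target regions.

    Each null set re-draws every target region as a same-length window
    placed uniformly inside a universe region chosen uniformly among those
    large enough to contain it. The two-sided mid-p empirical p-value
    doubles the smaller tail of the null gene-count distribution.
    """
    if n_resamples < 1:
        raise ValueError("need n_resamples >= 1")
    rng = np.random.default_rng(seed)
    observed = count_gene_overlaps(target, genes)
    uni = universe.df
    uni_lengths = (uni["end"] - uni["start"]).to_numpy()
    target_lengths = (target.df["end"] - target.df["start"]).to_numpy()
    too_long = target_lengths > uni_lengths.max()
    if too_long.any():
        rec = target.df[too_long].iloc[0]
        raise ValueError(
            f"target region {rec.chrom}:{rec.start}-{rec.end} longer than any "
            "universe region"
        )
    # candidate universe rows per target, by length
    order = np.argsort(uni_lengths)
    sorted_lengths = uni_lengths[order]
    null_counts = np.empty(n_resamples, dtype=int)
    for i in range(n_resamples):
        records = []
        for length in target_lengths:
            first = int(np.searchsorted(sorted_lengths, length, side="left"))
            pick = order[int(rng.integers(first, len(order)))]
            row = uni.iloc[pick]
            start = int(rng.integers(row.start, row.end - length + 1))
            records.append((row.chrom, start, start + int(length)))
        null_counts[i] = count_gene_overlaps(IntervalSet.from_records(records), genes)
    return GeneOverlapTest(
        observed=observed,
        null_counts=null_counts,
        p_value=empirical_p(null_counts, observed, "two-sided"),
    )


# ---------------------------------------------------------------------------
# QC: control regions, self-self chips, qPCR concordance
# ---------------------------------------------------------------------------


def control_region_fdr(calls: int, tests: int) -> tuple[int, int, float]:
    """(calls, tests, FDR%) with the percentage floor-truncated to two
    decimals (17 calls / 966 tests -> 1.75)."""
    if tests < 1:
        raise ValueError("need >= 1 control test")
    return calls, tests, floor_truncate_percent(100.0 * calls / tests)


def control_calls_from_matrix(calls_df: pd.DataFrame) -> tuple[int, int, float]:
    """Control-region FDR from a region x sample call matrix restricted to
    control regions: every non-equal cell is a false call."""
    tests = int(calls_df.size)
    n_calls = int((calls_df.values != "equal").sum())
    return control_region_fdr(n_calls, tests)


def self_self_calls(track: ProbeTrack, repeats: IntervalSet, gaps: IntervalSet,
                    **discover_kwargs) -> int:
    """Number of post-filter CNV calls on a self-self chip (every call is a
    false positive); runs the full discovery stack."""
    return len(discover_sample(track, repeats, gaps, **discover_kwargs))


def qpcr_concordance(
    acgh_calls: dict[tuple[str, str], str],
    qpcr_copies: dict[tuple[str, str], int],
    reference_copy: int = 2,
) -> ConcordanceReport:
    """Concordance of 3-state array calls with integer qPCR copy numbers.

    qPCR state: gain above the reference copy number, loss below, equal at
    it. Rates are fractions of all paired comparisons: FP = array non-equal
    where qPCR says equal; FN = array equal where qPCR says non-equal.
    """
    if set(acgh_calls) != set(qpcr_copies):
        raise ValueError("aCGH and qPCR observations must be paired")
    if not acgh_calls:
        raise ValueError("no paired observations")
    fp = fn = 0
    for key, call in acgh_calls.items():
        copies = qpcr_copies[key]
        qstate = (
            "gain" if copies > reference_copy
            else "loss" if copies < reference_copy
            else "equal"
        )
        if call != "equal" and qstate == "equal":
            fp += 1
        if call == "equal" and qstate != "equal":
            fn += 1
    n = len(acgh_calls)
    return ConcordanceReport(
        comparisons=n, false_positive_rate=fp / n, false_negative_rate=fn / n
    )
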