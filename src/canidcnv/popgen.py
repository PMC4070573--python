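"""Population genetics of CNV genotypes: EM allele frequencies, expected
heterozygosity and the VST differentiation statistic.

The three observable genotype categories (loss / equal / gain) are mapped
onto a diploid copy-arithmetic model with haplotype alleles L (0 copies),
N (1) and G (2): a diploid sum of 2 reads as "equal" (NN or GL), below 2
as "loss" (LL, NL), above as "gain" (NG, GG). Under Hardy-Weinberg
equilibrium with allele frequencies p (N), q (G), r (L):

    P(loss)  = r^2 + 2pr
    P(equal) = p^2 + 2qr
    P(gain)  = q^2 + 2pq

and the EM algorithm maximizes the multinomial likelihood of the observed
category counts over (p, q, r). Expected heterozygosity is
He = 1 - (p^2 + q^2 + r^2).

VST = (VT - VS) / VT compares per-sample mean log2 ratios between dogs
(including the dingo) and gray wolves: VT is the variance over all
included samples and VS the population-size-weighted mean of the
within-group variances (unbiased n-1 variances throughout).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotyping import GenotypeMatrix


@dataclass
class AlleleFrequencies:
    p: float  # normal allele
    q: float  # gain allele
    r: float  # loss allele
    log_likelihood: float
    iterations: int

    def __post_init__(self) -> None:
        if abs(self.p + self.q + self.r - 1.0) > 1e-9:
            raise ValueError("allele frequencies must sum to 1")
        if min(self.p, self.q, self.r) < -1e-12:
            raise ValueError("negative allele frequency")


@dataclass
class VstResult:
    region_id: str
    chrom: str
    start: int
    end: int
    vt: float
    vs: float
    vst: float


def category_probs(p: float, q: float, r: float) -> tuple[float, float, float]:
    """(P(loss), P(equal), P(gain)) under HWE and the copy-arithmetic map."""
    return (r * r + 2 * p * r, p * p + 2 * q * r, q * q + 2 * p * q)


def _loglik(n_loss: int, n_equal: int, n_gain: int, p: float, q: float, r: float) -> float:
    probs = category_probs(p, q, r)
    counts = (n_loss, n_equal, n_gain)
    ll = 0.0
    for n, pr in zip(counts, probs):
        if n > 0:
            if pr <= 0:
                return -np.inf
            ll += n * np.log(pr)
    return ll


def em_allele_freqs(
    n_loss: int,
    n_equal: int,
    n_gain: int,
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> AlleleFrequencies:
    """EM estimate of (p, q, r) from category counts.

    The likelihood surface of this map can carry several local maxima
    (including boundary ones), so EM is run from a small fixed set of
    starts — the add-one-smoothed category proportions plus one start
    dominant in each allele — and the highest-likelihood solution is
    returned. The exact uniform point is avoided as a start: it is a fixed
    point of the EM map for symmetric data.
    """
    n = n_loss + n_equal + n_gain
    if n < 1:
        raise ValueError("need at least one observation")
    starts = [
        ((n_equal + 1.0) / (n + 3.0), (n_gain + 1.0) / (n + 3.0),
         (n_loss + 1.0) / (n + 3.0)),
        (0.8, 0.1, 0.1),
        (0.1, 0.8, 0.1),
        (0.1, 0.1, 0.8),
    ]
    best: AlleleFrequencies | None = None
    for start in starts:
        cand = _em_single(n_loss, n_equal, n_gain, start, tol, max_iter)
        if best is None or cand.log_likelihood > best.log_likelihood:
            best = cand
    return best


def _em_single(
    n_loss: int,
    n_equal: int,
    n_gain: int,
    start: tuple[float, float, float],
    tol: float,
    max_iter: int,
) -> AlleleFrequencies:
    p, q, r = start
    ll_old = -np.inf
    iters = 0
    for iters in range(1, max_iter + 1):
        # E-step: expected allele counts
        cl, cn, cg = 0.0, 0.0, 0.0  # L, N, G allele counts
        if n_loss:
            denom = r * r + 2 * p * r
            w_ll = (r * r) / denom if denom > 0 else 1.0
            cl += n_loss * (2 * w_ll + (1 - w_ll))
            cn += n_loss * (1 - w_ll)
        if n_equal:
            denom = p * p + 2 * q * r
            w_nn = (p * p) / denom if denom > 0 else 1.0
            cn += n_equal * 2 * w_nn
            cg += n_equal * (1 - w_nn)
            cl += n_equal * (1 - w_nn)
        if n_gain:
            denom = q * q + 2 * p * q
            w_gg = (q * q) / denom if denom > 0 else 1.0
            cg += n_gain * (2 * w_gg + (1 - w_gg))
            cn += n_gain * (1 - w_gg)
        total = cl + cn + cg  # = 2n
        p, q, r = cn / total, cg / total, cl / total
        ll = _loglik(n_loss, n_equal, n_gain, p, q, r)
        if ll - ll_old < tol:
            break
        ll_old = ll
    return AlleleFrequencies(p=p, q=q, r=r, log_likelihood=ll, iterations=iters)


def expected_het(freqs: AlleleFrequencies | tuple[float, float, float]) -> float:
    """He = 1 - (p^2 + q^2 + r^2); ranges over [0, 2/3]."""
    if isinstance(freqs, AlleleFrequencies):
        p, q, r = freqs.p, freqs.q, freqs.r
    else:
        p, q, r = freqs
    return 1.0 - (p * p + q * q + r * r)


def direct_het(n_loss: int, n_equal: int, n_gain: int) -> float:
    """He from the observed category proportions (no EM, no HWE)."""
    n = n_loss + n_equal + n_gain
    if n < 1:
        raise ValueError("need at least one observation")
    fr, fp, fq = n_loss / n, n_equal / n, n_gain / n
    return 1.0 - (fp * fp + fq * fq + fr * fr)


# ---------------------------------------------------------------------------
# VST
# ---------------------------------------------------------------------------


def vst(values_a: np.ndarray, values_b: np.ndarray) -> tuple[float, float, float]:
    """(VT, VS, VST) between two groups of per-sample region log2 means.

    Unbiased (n-1) variances; VT = 0 yields VST = 0 by convention.
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 samples")
    allv = np.concatenate([a, b])
    vt = float(allv.var(ddof=1))
    vs = float((len(a) * a.var(ddof=1) + len(b) * b.var(ddof=1)) / (len(a) + len(b)))
    v = 0.0 if vt == 0.0 else (vt - vs) / vt
    return vt, vs, v


def vst_by_region(
    gm: GenotypeMatrix,
    tracks: dict,
) -> list[VstResult]:
    """VST per region between dogs (incl. dingo) and gray wolves, using each
    sample's mean log2 ratio over the region's probes."""
    if gm.regions is None:
        raise ValueError("genotype matrix lacks region coordinates")
    dogs, wolves = gm.samples.dogs, gm.samples.wolves
    out = []
    for rid in gm.region_ids:
        region = gm.regions[rid]
        a = np.array(
            [tracks[s].region_mean(region.chrom, region.start, region.end)[0]
             for s in dogs]
        )
        b = np.array(
            [tracks[s].region_mean(region.chrom, region.start, region.end)[0]
             for s in wolves]
        )
        vt, vs, v = vst(a, b)
        out.append(VstResult(rid, region.chrom, region.start, region.end, vt, vs, v))
    return out


def rank_vst(results: list[VstResult], k: int) -> pd.DataFrame:
    """Top-k regions by VST, descending; ties broken by (chrom, start)."""
    ordered = sorted(results, key=lambda x: (-x.vst, x.chrom, x.start))
    rows = [
        (x.vst, x.chrom, x.start, x.end, x.region_id, x.vt, x.vs)
        for x in ordered[:k]
    ]
    return pd.DataFrame(
        rows, columns=["vst", "chrom", "start", "end", "region_id", "vt", "vs"]
    )


# ---------------------------------------------------------------------------
# Heterozygosity comparison with wolf subsampling
# ---------------------------------------------------------------------------


@dataclass
class HeComparison:
    dog_he: float
    null_mean: float
    null_sd: float
    n_draws: int
    p_value: float
    null_means: np.ndarray


def _group_mean_he(gm: GenotypeMatrix, members: list[str]) -> float:
    """Mean direct-frequency He over regions polymorphic within ``members``."""
    vals = []
    for rid in gm.region_ids:
        nl, ne, ng = gm.counts(rid, members)
        he = direct_het(nl, ne, ng)
        if he > 0:
            vals.append(he)
    return float(np.mean(vals)) if vals else 0.0


def wolf_subsample_he_test(
    gm: GenotypeMatrix,
    group_size: int = 5,
    n_draws: int = 1000,
    seed: int = 0,
) -> HeComparison:
    """Compare dog He with the distribution over random wolf subsamples.

    Dogs (incl. dingo) are few, so He in the larger wolf panel is put on an
    equal footing by averaging He over ``n_draws`` random groups of
    ``group_size`` gray wolves. The empirical p-value is the add-one
    fraction of draws whose mean He is at or below the dog value.
    """
    wolves = gm.samples.wolves
    if len(wolves) < group_size:
        raise ValueError(
            f"need >= {group_size} gray wolves, have {len(wolves)}"
        )
    rng = np.random.default_rng(seed)
    dog_he = _group_mean_he(gm, gm.samples.dogs)
    null = np.empty(n_draws)
    for i in range(n_draws):
        draw = list(rng.choice(wolves, size=group_size, replace=False))
        null[i] = _group_mean_he(gm, draw)
    b = int((null <= dog_he).sum())
    return HeComparison(
        dog_he=dog_he,
        null_mean=float(null.mean()),
        null_sd=float(null.std(ddof=1)),
        n_draws=n_draws,
        p_value=(b + 1) / (n_draws + 1),
        null_means=null,
    )


def he_table(gm: GenotypeMatrix) -> pd.DataFrame:
    """Per-region EM-based He for the dog and gray-wolf groups."""
    rows = []
    for rid in gm.region_ids:
        rec = {"region_id": rid}
        for group, members in (("dog", gm.samples.dogs), ("wolf", gm.samples.wolves)):
            nl, ne, ng = gm.counts(rid, members)
            freqs = em_allele_freqs(nl, ne, ng)
            rec[f"he_{group}"] = expected_het(freqs)
            rec[f"p_{group}"] = freqs.p
            rec[f"q_{group}"] = freqs.q
            rec[f"r_{group}"] = freqs.r
        rows.append(rec)
    return pd.DataFrame(rows).set_index("region_id")
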