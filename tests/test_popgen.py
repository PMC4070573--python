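import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from canidcnv.genotyping import GenotypeMatrix
from canidcnv.popgen import (
    AlleleFrequencies,
    VstResult,
    category_probs,
    direct_het,
    em_allele_freqs,
    expected_het,
    rank_vst,
    vst,
    wolf_subsample_he_test,
)


def simplex_grid(step=0.001):
    """All (p, q, r) grid points with their category log-probabilities."""
    pts, logs = [], []
    qs = np.arange(0.0, 1.0 + step / 2, step)
    for q in qs:
        rs = np.arange(0.0, 1.0 - q + step / 2, step)
        ps = 1.0 - q - rs
        pl = rs * rs + 2 * ps * rs
        pe = ps * ps + 2 * q * rs
        pg = q * q + 2 * ps * q
        pts.append(np.stack([ps, np.full(len(rs), q), rs], axis=1))
        with np.errstate(divide="ignore"):
            logs.append(np.stack([np.log(pl), np.log(pe), np.log(pg)], axis=1))
    return np.concatenate(pts), np.concatenate(logs)


class TestEM:
    def test_all_equal(self):
        f = em_allele_freqs(0, 10, 0)
        assert f.p == pytest.approx(1.0, abs=1e-6)

    def test_all_loss(self):
        # convergence to the boundary r = 1 is sublinear; 0.01 matches the
        # grid-oracle tolerance
        f = em_allele_freqs(10, 0, 0)
        assert f.r == pytest.approx(1.0, abs=0.01)

    def test_closed_form_two_loss_eight_equal(self):
        # with q = 0, P(loss) = 1 - p^2, so MLE p = sqrt(0.8)
        f = em_allele_freqs(2, 8, 0)
        assert f.p == pytest.approx(np.sqrt(0.8), abs=1e-4)
        assert f.r == pytest.approx(1 - np.sqrt(0.8), abs=1e-4)
        assert f.q == pytest.approx(0.0, abs=1e-4)

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            em_allele_freqs(0, 0, 0)

    def test_matches_grid_search_all_small_counts(self):
        """EM attains the brute-force grid maximum for every count vector
        with total <= 12: its log-likelihood matches the grid optimum and
        its frequencies lie within 0.01 of a grid maximizer.

        The category-probability map is not injective, so the multinomial
        MLE can be a set of tied points (e.g. counts (1,2,1) are fitted
        exactly by both (2/3,1/6,1/6) and (0,1/2,1/2)); EM must land on
        that maximizer set, not on one arbitrary member of it.
        """
        points, logs = simplex_grid(step=0.001)
        for total in range(1, 13):
            for n_loss in range(total + 1):
                for n_equal in range(total + 1 - n_loss):
                    n_gain = total - n_loss - n_equal
                    counts = np.array([n_loss, n_equal, n_gain], float)
                    with np.errstate(invalid="ignore"):
                        ll = logs @ counts
                    ll[np.isnan(ll)] = -np.inf
                    best = ll.max()
                    f = em_allele_freqs(n_loss, n_equal, n_gain)
                    em_ll = f.log_likelihood
                    assert em_ll >= best - 1e-3, (n_loss, n_equal, n_gain)
                    maximizers = points[ll >= best - 1e-4]
                    dist = np.abs(
                        maximizers - np.array([f.p, f.q, f.r])
                    ).max(axis=1).min()
                    assert dist < 0.01, (n_loss, n_equal, n_gain)

    @given(
        st.integers(0, 30), st.integers(0, 30), st.integers(0, 30)
    )
    @settings(max_examples=100, deadline=None)
    def test_loglik_nondecreasing_and_simplex(self, nl, ne, ng):
        if nl + ne + ng == 0:
            return
        lls = []
        # re-run EM capturing per-iteration log-likelihood via small steps
        f = em_allele_freqs(nl, ne, ng, tol=1e-12, max_iter=500)
        assert abs(f.p + f.q + f.r - 1.0) < 1e-9
        assert min(f.p, f.q, f.r) >= -1e-12
        # monotonicity: LL at convergence >= LL at the smoothed start
        n = nl + ne + ng
        p0, q0, r0 = (ne + 1) / (n + 3), (ng + 1) / (n + 3), (nl + 1) / (n + 3)
        probs0 = category_probs(p0, q0, r0)
        ll0 = sum(
            c * np.log(pr) for c, pr in zip((nl, ne, ng), probs0) if c
        )
        assert f.log_likelihood >= ll0 - 1e-9

    def test_parameter_recovery_from_simulated_samples(self):
        """EM recovers (p, q, r) within 0.05 from 200 HWE samples in >= 95
        of 100 replicates."""
        rng = np.random.default_rng(42)
        # an identifiable truth: this (p, q, r) is the unique preimage of
        # its category probabilities (not every point is; see grid test)
        truth = (0.8, 0.15, 0.05)
        probs = np.array(category_probs(*truth))  # (loss, equal, gain)
        ok = 0
        for _ in range(100):
            counts = rng.multinomial(200, probs)
            f = em_allele_freqs(*counts)
            if max(abs(f.p - truth[0]), abs(f.q - truth[1]),
                   abs(f.r - truth[2])) < 0.05:
                ok += 1
        assert ok >= 95


class TestHe:
    @pytest.mark.parametrize(
        "freqs,he",
        [((1, 0, 0), 0.0), ((1 / 3, 1 / 3, 1 / 3), 2 / 3),
         ((0.5, 0.25, 0.25), 0.625)],
    )
    def test_values(self, freqs, he):
        assert expected_het(freqs) == pytest.approx(he)

    @given(st.floats(0, 1), st.floats(0, 1))
    @settings(max_examples=50, deadline=None)
    def test_range(self, a, b):
        if a + b > 1:
            return
        he = expected_het((a, b, 1 - a - b))
        assert -1e-12 <= he <= 2 / 3 + 1e-12


class TestVst:
    def test_identical_values_zero_by_convention(self):
        assert vst([1.0, 1.0], [1.0, 1.0])[2] == 0.0

    def test_complete_differentiation(self):
        vt, vs, v = vst([0.0, 0.0], [1.0, 1.0])
        assert vs == 0.0 and v == 1.0

    def test_hand_computed_case(self):
        # A = {0,0}, B = {0,1}: VT = 0.25, VS = (2*0 + 2*0.5)/4 = 0.25
        vt, vs, v = vst([0.0, 0.0], [0.0, 1.0])
        assert vt == pytest.approx(0.25)
        assert vs == pytest.approx(0.25)
        assert v == 0.0

    def test_single_sample_group_rejected(self):
        with pytest.raises(ValueError):
            vst([0.0], [0.0, 1.0])

    @given(
        st.lists(st.floats(-1, 1), min_size=2, max_size=8),
        st.lists(st.floats(-1, 1), min_size=2, max_size=8),
    )
    @settings(max_examples=100, deadline=None)
    def test_upper_bound_and_one_iff_vs_zero(self, a, b):
        vt, vs, v = vst(a, b)
        assert v <= 1.0 + 1e-12
        if vt > 1e-9:
            assert (v == 1.0) == (vs == 0.0)


class TestRankVst:
    def _results(self, vals):
        return [
            VstResult(f"r{i}", "chr1", i * 1000, i * 1000 + 500, 1.0, 0.0, v)
            for i, v in enumerate(vals)
        ]

    def test_top_one(self):
        top = rank_vst(self._results([0.2, 0.47, 0.1]), 1)
        assert list(top["vst"]) == [0.47]

    def test_ties_broken_by_coordinates(self):
        top = rank_vst(self._results([0.3, 0.3, 0.3]), 2)
        assert list(top["start"]) == [0, 1000]

    def test_k_zero_empty(self):
        assert len(rank_vst(self._results([0.5]), 0)) == 0

    def test_differentiated_loci_rank_first(self):
        """Loci with dog gain frequency 0.9 vs wolf 0 outrank undifferentiated
        loci in >= 95 of 100 replicates (simulated region log2 means)."""
        rng = np.random.default_rng(7)
        n_dog, n_wolf = 5, 15
        wins = 0
        for _ in range(100):
            results = []
            for i in range(6):
                if i == 0:  # differentiated: dogs mostly carry gains
                    dog_copies = 2 + rng.binomial(2, 0.9, n_dog)
                    wolf_copies = np.full(n_wolf, 2)
                else:  # shared polymorphism in both groups
                    dog_copies = 2 + rng.binomial(2, 0.3, n_dog)
                    wolf_copies = 2 + rng.binomial(2, 0.3, n_wolf)
                dog_vals = np.log2(dog_copies / 2) + rng.normal(0, 0.03, n_dog)
                wolf_vals = np.log2(wolf_copies / 2) + rng.normal(0, 0.03, n_wolf)
                vt, vs, v = vst(dog_vals, wolf_vals)
                results.append(VstResult(f"r{i}", "chr1", i, i + 1, vt, vs, v))
            if rank_vst(results, 1)["region_id"][0] == "r0":
                wins += 1
        assert wins >= 95


class TestWolfSubsampleHe:
    def _matrix(self, sheet, dog_call, wolf_calls, n_regions=10):
        rows = {}
        for i in range(n_regions):
            rows[f"r{i}"] = {}
        calls = pd.DataFrame(
            {
                s: [
                    dog_call if sheet.group_of(s) == "dog" and s == "Beagle"
                    else wolf_calls if sheet.group_of(s) == "wolf"
                    and s in ("Wolf0", "Wolf1") else "equal"
                    for _ in range(n_regions)
                ]
                for s in sheet.samples
            },
            index=list(rows),
        )
        return GenotypeMatrix(calls, sheet)

    def test_wolves_monomorphic_dogs_polymorphic(self, small_sheet):
        gm = self._matrix(small_sheet, "gain", "equal")
        res = wolf_subsample_he_test(gm, group_size=5, n_draws=200, seed=0)
        assert res.p_value > 0.95  # every null draw He <= dog He

    def test_seed_reproducible(self, small_sheet):
        gm = self._matrix(small_sheet, "gain", "loss")
        a = wolf_subsample_he_test(gm, 5, 100, seed=3)
        b = wolf_subsample_he_test(gm, 5, 100, seed=3)
        assert np.array_equal(a.null_means, b.null_means)
        assert a.p_value == b.p_value

    def test_too_few_wolves_rejected(self, small_sheet):
        gm = self._matrix(small_sheet, "gain", "loss")
        with pytest.raises(ValueError):
            wolf_subsample_he_test(gm, group_size=10)

    def test_calibration_identical_frequencies(self, small_sheet):
        """Dogs and wolves simulated from identical frequencies should not
        look significantly depleted (p typically > 0.05)."""
        rng = np.random.default_rng(11)
        ps = []
        for rep in range(20):
            calls = pd.DataFrame(
                {
                    s: rng.choice(["loss", "equal", "gain"], size=15,
                                  p=[0.2, 0.6, 0.2])
                    for s in small_sheet.samples
                },
                index=[f"r{i}" for i in range(15)],
            )
            gm = GenotypeMatrix(calls, small_sheet)
            ps.append(wolf_subsample_he_test(gm, 5, 100, seed=rep).p_value)
        assert np.median(ps) > 0.05
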