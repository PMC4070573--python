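import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from canidcnv.breakpoints import (
    BreakpointPair,
    _redistribute,
    detect_gc_peaks,
    gc_fraction,
    gc_peak_breakpoint_profile,
    gc_profile_around_breakpoints,
    homology_permutation_test,
    longest_perfect_homology,
    make_breakpoint_pairs,
    repeat_enrichment,
)
from canidcnv.io_formats import GenomeSequence, IntervalSet


def lcs_dp(a, b):
    """O(nm) dynamic-programming oracle for the longest common substring;
    N never matches."""
    best = 0
    prev = [0] * (len(b) + 1)
    for i, ca in enumerate(a, 1):
        cur = [0] * (len(b) + 1)
        for j, cb in enumerate(b, 1):
            if ca == cb and ca != "N":
                cur[j] = prev[j - 1] + 1
                best = max(best, cur[j])
        prev = cur
    return best


def random_genome(length=50_000, gc=0.4, seed=0, chrom="chr1"):
    rng = np.random.default_rng(seed)
    bases = rng.choice(
        list("GCAT"), size=length, p=[gc / 2, gc / 2, (1 - gc) / 2, (1 - gc) / 2]
    )
    return GenomeSequence({chrom: "".join(bases)})


class TestMakePairs:
    def test_centering(self):
        genome = random_genome(30_000)
        cnvs = IntervalSet.from_records([("chr1", 10_000, 20_000, "c")])
        (pair,) = make_breakpoint_pairs(cnvs, genome, window=400)
        assert (pair.left_start, pair.left_end) == (9_800, 10_200)
        assert (pair.right_start, pair.right_end) == (19_800, 20_200)
        assert pair.distance == 10_000

    def test_clipped_at_chromosome_start(self):
        genome = random_genome(10_000)
        cnvs = IntervalSet.from_records([("chr1", 100, 5_000, "c")])
        with pytest.warns(UserWarning, match="clipped"):
            (pair,) = make_breakpoint_pairs(cnvs, genome)
        assert pair.left_start == 0

    def test_short_cnv_skipped(self):
        genome = random_genome(10_000)
        cnvs = IntervalSet.from_records([("chr1", 1_000, 1_300, "c")])
        with pytest.warns(UserWarning, match="skipped"):
            assert make_breakpoint_pairs(cnvs, genome, window=400) == []


class TestGCPeaks:
    def test_uniform_sequence_no_peaks(self):
        genome = random_genome(40_000, gc=0.4, seed=1)
        assert detect_gc_peaks(genome) == []

    def test_implanted_strong_peak_detected(self):
        # 500 bp at 90% GC in 40% background: background incl. peak ~= 0.425,
        # 0.90 > 1.5 * 0.425
        genome = random_genome(40_000, gc=0.4, seed=2)
        seq = genome.chroms["chr1"]
        rng = np.random.default_rng(3)
        peak = "".join(
            rng.choice(list("GCAT"), size=500, p=[0.45, 0.45, 0.05, 0.05])
        )
        genome = GenomeSequence({"chr1": seq[:20_000] + peak + seq[20_500:]})
        peaks = detect_gc_peaks(genome)
        assert any(p.start < 20_500 and 20_000 < p.end for p in peaks)

    def test_weak_elevation_not_a_peak(self):
        # 55% GC < 1.5 x ~0.41 background: no peak
        genome = random_genome(40_000, gc=0.4, seed=4)
        seq = genome.chroms["chr1"]
        rng = np.random.default_rng(5)
        bump = "".join(
            rng.choice(list("GCAT"), size=500, p=[0.275, 0.275, 0.225, 0.225])
        )
        genome = GenomeSequence({"chr1": seq[:20_000] + bump + seq[20_500:]})
        assert detect_gc_peaks(genome) == []

    def test_reported_peaks_satisfy_criterion_on_recount(self):
        """Every reported peak re-verifies the 1.5x criterion directly
        against the sequence."""
        rng = np.random.default_rng(6)
        seq = list(random_genome(60_000, gc=0.38, seed=6).chroms["chr1"])
        for pos in (15_000, 30_000, 30_700, 45_000):
            seq[pos : pos + 600] = rng.choice(
                list("GC"), size=600, p=[0.5, 0.5]
            )
        genome = GenomeSequence({"chr1": "".join(seq)})
        peaks = detect_gc_peaks(genome)
        assert peaks
        for p in peaks:
            peak_gc = gc_fraction(genome.fetch(p.chrom, p.start, p.end))
            c = (p.start + p.end) // 2
            bg = gc_fraction(
                genome.fetch(p.chrom, max(0, c - 5_000), c + 5_000)
            )
            assert p.end - p.start >= 500
            assert peak_gc > 1.5 * bg


class TestHomology:
    @pytest.mark.parametrize(
        "a,b,expected",
        [("ACGT", "ACGT", 4), ("AAAA", "CCCC", 0), ("GATTACA", "TTAC", 4),
         ("", "ACGT", 0), ("ANNA", "NN", 0)],
    )
    def test_known_values(self, a, b, expected):
        assert longest_perfect_homology(a, b) == expected

    def test_equals_dp_oracle_on_500_random_pairs(self):
        rng = np.random.default_rng(7)
        for _ in range(500):
            a = "".join(rng.choice(list("ACGTN"), size=rng.integers(0, 61)))
            b = "".join(rng.choice(list("ACGTN"), size=rng.integers(0, 61)))
            assert longest_perfect_homology(a, b) == lcs_dp(a, b)

    @given(st.text(alphabet="ACGTN", max_size=40), st.text(alphabet="ACGTN", max_size=40))
    @settings(max_examples=200, deadline=None)
    def test_symmetric_and_bounded(self, a, b):
        h = longest_perfect_homology(a, b)
        assert h == longest_perfect_homology(b, a)
        assert h <= min(len(a), len(b))

    @given(st.text(alphabet="ACGT", min_size=1, max_size=30),
           st.text(alphabet="ACGT", max_size=20))
    @settings(max_examples=100, deadline=None)
    def test_substring_gives_full_length(self, a, pad):
        assert longest_perfect_homology(a, pad + a) == len(a)


def _pairs_at(genome, positions, distance=2_000, window=400):
    cnvs = IntervalSet.from_records(
        [("chr1", p, p + distance, f"c{i}") for i, p in enumerate(positions)]
    )
    return make_breakpoint_pairs(cnvs, genome, window)


class TestHomologyPermutation:
    def test_implanted_motifs_significant(self):
        rng = np.random.default_rng(8)
        genome = random_genome(200_000, seed=8)
        seq = list(genome.chroms["chr1"])
        positions = list(range(10_000, 190_000, 12_000))
        motif_pool = rng.choice(list("ACGT"), size=(len(positions), 25))
        for i, p in enumerate(positions):
            motif = list(motif_pool[i])
            seq[p - 12 : p + 13] = motif
            seq[p + 2_000 - 12 : p + 2_000 + 13] = motif
        genome = GenomeSequence({"chr1": "".join(seq)})
        pairs = _pairs_at(genome, positions)
        obs, null, p = homology_permutation_test(pairs, genome, 20, seed=0)
        assert obs >= 25
        assert obs > null
        assert p < 0.01

    def test_seed_reproducible(self):
        genome = random_genome(100_000, seed=9)
        pairs = _pairs_at(genome, [20_000, 50_000, 80_000])
        r1 = homology_permutation_test(pairs, genome, 10, seed=4)
        r2 = homology_permutation_test(pairs, genome, 10, seed=4)
        assert r1 == r2

    def test_too_few_pairs_rejected(self):
        genome = random_genome(100_000, seed=10)
        with pytest.raises(ValueError):
            homology_permutation_test(_pairs_at(genome, [20_000]), genome, 5)


class TestRedistribution:
    def test_preserves_distance_exactly(self):
        genome = random_genome(100_000, seed=11)
        pairs = _pairs_at(genome, [10_000, 40_000, 70_000], distance=3_333)
        rng = np.random.default_rng(0)
        for _ in range(20):
            for rp, orig in zip(_redistribute(pairs, genome, rng, 400), pairs):
                assert rp.distance == orig.distance
                assert rp.chrom == orig.chrom

    def test_chromosome_too_short_raises(self):
        genome = random_genome(10_000, seed=12)
        pair = BreakpointPair("c0", "chr1", 0, 400, 9_700, 10_100)
        with pytest.raises(ValueError, match="c0"):
            _redistribute([pair], genome, np.random.default_rng(0), 400)


class TestGCProfile:
    def test_flat_on_uniform_genome(self):
        genome = random_genome(200_000, gc=0.4, seed=13)
        pairs = _pairs_at(genome, list(range(20_000, 180_000, 20_000)),
                          distance=5_000)
        prof = gc_profile_around_breakpoints(pairs, genome, flank=2_000)
        assert np.nanmax(np.abs(prof.gc - 0.4)) < 0.05

    def test_coverage_drops_inside_short_cnvs(self):
        genome = random_genome(100_000, seed=14)
        pairs = _pairs_at(genome, [20_000, 50_000], distance=1_000)
        prof = gc_profile_around_breakpoints(pairs, genome, window=400,
                                             flank=2_000)
        deep_inside = prof.coverage[prof.position == -2_000]
        assert deep_inside[0] < 1.0
        outside = prof.coverage[prof.position == 2_000]
        assert outside[0] == 1.0

    def test_elevated_gc_outside_breakpoint_localized(self):
        rng = np.random.default_rng(15)
        seq = list(random_genome(150_000, gc=0.35, seed=15).chroms["chr1"])
        positions = list(range(10_000, 140_000, 10_000))
        for p in positions:  # high-GC block ~1.2 kb outside each left breakpoint
            block = rng.choice(list("GC"), size=400)
            start = p - 1_200 - 200
            seq[start : start + 400] = block
        genome = GenomeSequence({"chr1": "".join(seq)})
        pairs = _pairs_at(genome, positions, distance=4_000)
        prof = gc_profile_around_breakpoints(pairs, genome, flank=2_000)
        k = int(np.flatnonzero(prof.position == 1_200)[0])
        assert prof.gc[k] == np.nanmax(prof.gc)


class TestGCPeakProfile:
    def test_peaks_at_breakpoints_enriched_in_bin_zero(self):
        genome = random_genome(300_000, gc=0.35, seed=16)
        positions = list(range(20_000, 280_000, 20_000))
        seq = list(genome.chroms["chr1"])
        rng = np.random.default_rng(17)
        for p in positions:
            seq[p - 300 : p + 300] = rng.choice(list("GC"), size=600)
        genome = GenomeSequence({"chr1": "".join(seq)})
        pairs = _pairs_at(genome, positions, distance=5_000)
        peaks = detect_gc_peaks(genome)
        assert peaks
        results = gc_peak_breakpoint_profile(
            peaks, pairs, genome, n_resamples=100, seed=0, max_distance=1_600
        )
        bin0 = results[0]
        assert bin0.observed > bin0.null_mean
        assert bin0.p_value < 0.05

    def test_no_peaks_all_zero(self):
        genome = random_genome(100_000, seed=18)
        pairs = _pairs_at(genome, [20_000, 60_000])
        results = gc_peak_breakpoint_profile([], pairs, genome, n_resamples=10,
                                             seed=0)
        assert all(r.observed == 0 for r in results)


class TestRepeatEnrichment:
    def test_repeats_inside_windows_enriched(self):
        genome = random_genome(400_000, seed=19)
        positions = list(range(20_000, 380_000, 18_000))
        pairs = _pairs_at(genome, positions, distance=5_000)
        recs = []
        for pair in pairs:  # an L1 inside every breakpoint window
            recs.append(("chr1", pair.left_center - 50, pair.left_center + 50,
                         "L1:Canis"))
            recs.append(("chr1", pair.right_center - 50, pair.right_center + 50,
                         "L1:Canis"))
        repeats = IntervalSet.from_records(recs)
        res = repeat_enrichment(pairs, repeats, genome, n_resamples=200, seed=0)
        r = res[("L1:Canis", 400)]
        assert r.ratio > 1
        assert r.p_value <= 0.01

    def test_uniform_repeats_ratio_near_one(self):
        genome = random_genome(400_000, seed=20)
        rng = np.random.default_rng(21)
        recs = [
            ("chr1", int(s), int(s) + 200, "SINE")
            for s in rng.integers(0, 399_800, size=300)
        ]
        repeats = IntervalSet.from_records(recs)
        pairs = _pairs_at(genome, list(range(20_000, 380_000, 30_000)),
                          distance=5_000)
        res = repeat_enrichment(pairs, repeats, genome, n_resamples=200, seed=1)
        r = res[("SINE", 400)]
        assert 0.5 < r.ratio < 2.0
        assert r.p_value > 0.01

    def test_unknown_family_rejected(self):
        genome = random_genome(50_000, seed=22)
        pairs = _pairs_at(genome, [20_000])
        repeats = IntervalSet.from_records([("chr1", 0, 100, "SINE")])
        with pytest.raises(ValueError, match="LINE9"):
            repeat_enrichment(pairs, repeats, genome, families=["LINE9"])

    def test_ratio_arithmetic(self):
        from canidcnv.breakpoints import EnrichmentResult

        r = EnrichmentResult("x", 10, 5, 1.0, 100, 0.01)
        assert r.ratio == 2.0


def test_gc_fraction_excludes_n():
    assert gc_fraction("GCNN") == 1.0
    assert gc_fraction("NNNN") != gc_fraction("NNNN")  # NaN
    assert gc_fraction("ACGT") == 0.5
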