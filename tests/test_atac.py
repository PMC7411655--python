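"""Depth equalization, union peaks, quantification, and the differential rule."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from epidiff.atac import (
    DOWN,
    NS,
    UP,
    FragmentSet,
    SignalTrack,
    build_union_peaks,
    classify_differential,
    downsample_fragments,
    fragment_size_histogram,
    locus_peak_count,
    quantify_union_peaks,
    replicate_correlation,
)
from epidiff.core import GeneAnnotation, GenomicInterval

from conftest import oracle_differential, oracle_max_coverage, oracle_merge


def iv(s, e):
    return GenomicInterval("chr1", s, e)


def frags(n, rng=None, size=100):
    rng = rng or np.random.default_rng(0)
    starts = rng.integers(0, 10_000, n)
    return FragmentSet([iv(int(s), int(s) + size) for s in starts])


class TestDownsample:
    def test_returns_exact_count_of_input_members(self):
        fs = frags(100)
        out = downsample_fragments(fs, 50, seed=7)
        assert len(out) == 50
        pool = set(fs.fragments)
        assert all(f in pool for f in out.fragments)

    def test_full_target_is_identity(self):
        fs = frags(40)
        out = downsample_fragments(fs, 40, seed=1)
        assert sorted(out.fragments) == sorted(fs.fragments)

    def test_seed_reproducibility_and_divergence(self):
        fs = frags(1000)
        a = downsample_fragments(fs, 500, seed=3)
        b = downsample_fragments(fs, 500, seed=3)
        c = downsample_fragments(fs, 500, seed=4)
        assert a.fragments == b.fragments
        assert a.fragments != c.fragments

    def test_no_upsampling(self):
        with pytest.raises(ValueError):
            downsample_fragments(frags(10), 11, seed=0)


class TestUnionPeaks:
    def test_chain_merge(self):
        a = [iv(100, 200), iv(300, 400)]
        b = [iv(150, 250)]
        assert build_union_peaks(a, b) == [iv(100, 250), iv(300, 400)]

    def test_same_input_both_sides_is_merge_of_one(self):
        a = [iv(10, 50), iv(40, 80), iv(200, 300)]
        assert build_union_peaks(a, a) == build_union_peaks(a, [])

    def test_both_empty(self):
        assert build_union_peaks([], []) == []

    def test_matches_base_mask_oracle(self):
        rng = np.random.default_rng(11)
        length = 100_000
        pool = []
        for _ in range(500):
            s = int(rng.integers(0, length - 1000))
            pool.append(iv(s, s + int(rng.integers(1, 1000))))
        half = len(pool) // 2
        merged = build_union_peaks(pool[:half], pool[half:])
        assert [(m.start, m.end) for m in merged] == oracle_merge(pool, length)


class TestQuantify:
    def make_tracks(self, arr_a, arr_b, tot=1_000_000):
        ta = SignalTrack({"chr1": np.asarray(arr_a, float)}, total_fragments=tot, label="A")
        tb = SignalTrack({"chr1": np.asarray(arr_b, float)}, total_fragments=tot, label="B")
        return ta, tb

    def test_zero_coverage_gives_zero(self):
        ta, tb = self.make_tracks(np.zeros(100), np.zeros(100))
        [q] = quantify_union_peaks([iv(10, 20)], ta, tb)
        assert q.v == {"A": 0.0, "B": 0.0}

    def test_per_million_at_unit_depth(self):
        a = np.zeros(100)
        a[40:60] = 8.0
        ta, tb = self.make_tracks(a, np.zeros(100), tot=1_000_000)
        [q] = quantify_union_peaks([iv(30, 70)], ta, tb)
        assert q.v["A"] == pytest.approx(8.0)

    def test_downsampled_mode_uses_raw_max(self):
        a = np.zeros(100)
        a[10] = 5.0
        ta, tb = self.make_tracks(a, np.zeros(100), tot=123)
        [q] = quantify_union_peaks([iv(0, 100)], ta, tb, mode="downsampled")
        assert q.v["A"] == 5.0

    def test_interval_outside_extent_named_in_error(self):
        ta, tb = self.make_tracks(np.zeros(50), np.zeros(50))
        with pytest.raises(ValueError, match="10-60"):
            quantify_union_peaks([iv(10, 60)], ta, tb)

    def test_matches_per_base_oracle(self):
        rng = np.random.default_rng(5)
        arr = rng.random(5_000) * 10
        ta, tb = self.make_tracks(arr, arr[::-1].copy())
        ivs = []
        for _ in range(50):
            s = int(rng.integers(0, 4_900))
            ivs.append(iv(s, s + int(rng.integers(1, 100))))
        for q in quantify_union_peaks(ivs, ta, tb, mode="downsampled"):
            s, e = q.interval.start, q.interval.end
            assert q.v["A"] == oracle_max_coverage(arr, s, e)
            assert q.v["B"] == oracle_max_coverage(arr[::-1], s, e)


class TestDifferentialRule:
    @pytest.mark.parametrize(
        "vc,vk,status,fold",
        [
            (10.0, 4.0, DOWN, 2.5),
            (0.0, 3.0, UP, math.inf),
            (0.5, 1.5, NS, 3.0),        # fold passes, value filter fails
            (0.0, 0.0, NS, 1.0),
            (3.0, 3.0, NS, 1.0),
            (2.0, 5.0, UP, 2.5),
            (1.0, 2.0, NS, 2.0),        # max exactly at threshold: strict >
            (1.25, 2.5, UP, 2.0),       # fold exactly 2 passes: "at least" is inclusive
        ],
    )
    def test_examples(self, vc, vk, status, fold):
        call = classify_differential(vc, vk)
        assert call.status == status
        assert call.fold == pytest.approx(fold)

    def test_grid_matches_clause_oracle(self):
        vals = np.round(np.arange(0, 10.05, 0.1), 10)
        for vc in vals:
            for vk in vals:
                assert classify_differential(vc, vk).status == oracle_differential(vc, vk)

    @settings(deadline=None, derandomize=True)
    @given(st.floats(0, 100), st.floats(0, 100))
    def test_symmetry_swapping_conditions(self, vc, vk):
        a = classify_differential(vc, vk)
        b = classify_differential(vk, vc)
        swap = {UP: DOWN, DOWN: UP, NS: NS}
        assert b.status == swap[a.status]
        assert b.fold == a.fold or (math.isinf(a.fold) and math.isinf(b.fold))

    @settings(deadline=None, derandomize=True)
    @given(st.floats(0, 50), st.floats(0, 50), st.floats(0.01, 50))
    def test_monotone_in_case_signal(self, vc, vk, bump):
        """Raising the case signal never demotes an up call."""
        if classify_differential(vc, vk).status == UP:
            assert classify_differential(vc, vk + bump).status == UP

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            classify_differential(-1.0, 2.0)


class TestLocusPeakCount:
    gene = GeneAnnotation("g", "g", GenomicInterval("chr1", 10_000, 20_000, "+"))

    def test_peak_inside_flank_counted(self):
        assert locus_peak_count([iv(65_000, 66_000)], self.gene) == 1

    def test_boundary_exclusive(self):
        # window is [0, 70000); a peak starting at 70000 shares no base
        assert locus_peak_count([iv(70_000, 71_000)], self.gene) == 0
        assert locus_peak_count([iv(69_999, 71_000)], self.gene) == 1

    def test_matches_overlap_oracle(self):
        rng = np.random.default_rng(3)
        peaks = []
        for _ in range(100):
            s = int(rng.integers(0, 99_000))
            peaks.append(iv(s, s + int(rng.integers(1, 1000))))
        lo, hi = 10_000 - 50_000, 20_000 + 50_000
        lo = max(0, lo)
        expected = sum(1 for p in peaks if p.start < hi and p.end > lo)
        assert locus_peak_count(peaks, self.gene) == expected


class TestReplicateCorrelation:
    def test_perfect_linearity(self):
        x = [1.0, 2.0, 5.0, 9.0]
        res = replicate_correlation(x, [2 * v for v in x])
        assert res.defined and res.r == pytest.approx(1.0)
        assert res.n == 4

    def test_anticorrelation(self):
        x = [1.0, 2.0, 5.0]
        res = replicate_correlation(x, [10 - v for v in x])
        assert res.r == pytest.approx(-1.0)

    def test_independent_vectors_near_zero(self):
        rng = np.random.default_rng(12)
        res = replicate_correlation(rng.random(10_000), rng.random(10_000))
        assert abs(res.r) < 0.05

    def test_zero_variance_reported_undefined(self):
        res = replicate_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert not res.defined and res.r is None and "variance" in res.reason

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            replicate_correlation([1.0, 2.0], [1.0, 2.0])


class TestFragmentSizeHistogram:
    def test_point_mass(self):
        fs = FragmentSet([iv(0, 100)] * 10)
        h = fragment_size_histogram(fs)
        assert h.counts[99] == 10 and h.counts.sum() == 10 and h.overflow == 0

    def test_two_point_mass(self):
        fs = FragmentSet([iv(0, 80)] * 50 + [iv(0, 200)] * 50)
        h = fragment_size_histogram(fs)
        assert h.counts[79] == 50 and h.counts[199] == 50

    def test_total_conserved_with_overflow(self):
        rng = np.random.default_rng(9)
        sizes = rng.integers(1, 3000, 500)
        fs = FragmentSet([iv(0, int(s)) for s in sizes])
        h = fragment_size_histogram(fs, max_size=2000)
        assert h.total == 500
        assert h.overflow == int((sizes > 2000).sum())
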