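"""Loop summaries, TAD crossing, Wilcoxon test, nucleation classification."""

from itertools import combinations

import numpy as np
import pytest
from scipy import stats

from polyloop.core import Anchor, GenomicInterval, IntervalSet, Loop
from polyloop.loops import (
    anchor_peak_overlap_fraction,
    classify_nucleation,
    compare_distributions,
    summarize_loops,
    tads_crossed,
)
from polyloop.synth import LoopGeneratorSpec, make_loops, mouse_like_genome

from conftest import brute_count_contained, random_intervals


def loop_at(m1, m2, width=1000, chrom="chr1"):
    h = width // 2
    return Loop(
        Anchor(GenomicInterval(chrom, m1 - h, m1 + h), "left"),
        Anchor(GenomicInterval(chrom, m2 - h, m2 + h), "right"),
    )


class TestTadsCrossed:
    def test_three_contained_tads(self):
        tads = IntervalSet(
            [GenomicInterval("chr1", s, s + 1000) for s in (2000, 4000, 6000)]
        )
        lp = loop_at(1000, 9000, width=1000)
        assert tads_crossed(lp, tads) == 3

    def test_straddling_tad_not_counted(self):
        # TAD crosses the left anchor's inner edge -> excluded
        tads = IntervalSet([GenomicInterval("chr1", 1000, 3000)])
        lp = loop_at(1000, 9000, width=1000)  # interior [1500, 8500)
        assert tads_crossed(lp, tads) == 0

    def test_no_interior_returns_zero(self):
        tads = IntervalSet([GenomicInterval("chr1", 0, 10_000)])
        lp = Loop(
            Anchor(GenomicInterval("chr1", 0, 1000), "left"),
            Anchor(GenomicInterval("chr1", 1000, 2000), "right"),
        )
        assert tads_crossed(lp, tads) == 0

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(100):
            tad_list = random_intervals(rng, int(rng.integers(1, 80)),
                                        chroms=("chr1",))
            tads = IntervalSet(tad_list)
            m1 = int(rng.integers(1000, 40_000))
            m2 = m1 + int(rng.integers(1000, 60_000))
            lp = loop_at(m1, m2)
            interior = GenomicInterval("chr1", lp.left.interval.end,
                                       lp.right.interval.start)
            assert tads_crossed(lp, tads) == brute_count_contained(interior, tad_list)

    def test_monotone_under_widening(self, rng):
        tad_list = random_intervals(rng, 60, chroms=("chr1",))
        tads = IntervalSet(tad_list)
        prev = -1
        for half_span in range(2000, 40_000, 4000):
            lp = loop_at(50_000 - half_span, 50_000 + half_span)
            n = tads_crossed(lp, tads)
            assert n >= prev
            prev = n


class TestSummarizeLoops:
    def test_top_half_median(self):
        tads = IntervalSet()
        loops = [loop_at(10_000_000, 10_000_000 + d)
                 for d in (1_000_000, 2_000_000, 3_000_000, 4_000_000)]
        s = summarize_loops(loops, tads, percentile=0.5)
        assert s.top_percentile_median_distance == pytest.approx(3_500_000)
        assert s.median_distance == pytest.approx(2_500_000)

    def test_percentile_one_degenerates_to_overall_median(self):
        tads = IntervalSet()
        loops = [loop_at(1_000_000, 1_000_000 + d)
                 for d in (100_000, 400_000, 900_000)]
        s = summarize_loops(loops, tads, percentile=1.0)
        assert s.top_percentile_median_distance == s.median_distance

    def test_empty_loop_list_rejected(self):
        with pytest.raises(ValueError):
            summarize_loops([], IntervalSet())

    def test_permutation_invariant(self, rng):
        tads = IntervalSet(random_intervals(rng, 40, chroms=("chr1",)))
        loops = [loop_at(int(m), int(m) + int(d))
                 for m, d in zip(rng.integers(5_000, 50_000, 30),
                                 rng.integers(2_000, 80_000, 30))]
        s1 = summarize_loops(loops, tads, percentile=0.2)
        perm = [loops[i] for i in rng.permutation(len(loops))]
        s2 = summarize_loops(perm, tads, percentile=0.2)
        assert s1.median_distance == s2.median_distance
        assert s1.top_percentile_median_distance == s2.top_percentile_median_distance
        assert s1.top_percentile_median_tads == s2.top_percentile_median_tads


def exact_wilcoxon_oracle(a, b):
    """Two-sided p by enumerating every label assignment of the pooled values.

    U is computed directly from pairwise comparisons (ties count half), so
    the oracle shares no code path with the rank-based implementation.
    """
    pooled = list(a) + list(b)
    n1 = len(a)
    n = len(pooled)

    def u_stat(idx_a):
        sa = [pooled[i] for i in idx_a]
        sb = [pooled[i] for i in range(n) if i not in idx_a]
        return sum(
            1.0 if x > y else (0.5 if x == y else 0.0) for x in sa for y in sb
        )

    u_obs = u_stat(frozenset(range(n1)))
    us = [u_stat(frozenset(c)) for c in combinations(range(n), n1)]
    p_le = sum(u <= u_obs + 1e-9 for u in us) / len(us)
    p_ge = sum(u >= u_obs - 1e-9 for u in us) / len(us)
    return u_obs, min(1.0, 2.0 * min(p_le, p_ge))


class TestCompareDistributions:
    def test_identical_samples_give_p_one(self):
        _, p = compare_distributions([1, 2, 3], [1, 2, 3])
        assert p == 1.0

    def test_fully_separated_small_samples(self):
        u, p = compare_distributions([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_all_tied_returns_one(self):
        _, p = compare_distributions([5.0] * 30, [5.0] * 40)
        assert p == 1.0

    def test_exact_matches_enumeration_oracle(self, rng):
        for n1, n2 in [(2, 3), (3, 3), (4, 4), (5, 5), (4, 6), (3, 7)]:
            a = list(rng.integers(0, 6, n1).astype(float))  # ties likely
            b = list(rng.integers(0, 6, n2).astype(float))
            u_impl, p_impl = compare_distributions(a, b)
            u_oracle, p_oracle = exact_wilcoxon_oracle(a, b)
            assert u_impl == pytest.approx(u_oracle)
            assert p_impl == pytest.approx(p_oracle)

    def test_large_sample_agrees_with_scipy_asymptotic(self, rng):
        a = rng.normal(0, 1, 60)
        b = rng.normal(0.4, 1, 50)
        u_impl, p_impl = compare_distributions(a, b)
        ref = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method="asymptotic", use_continuity=True)
        assert u_impl == pytest.approx(ref.statistic)
        assert p_impl == pytest.approx(ref.pvalue, rel=1e-9)

    def test_type_one_error_calibrated(self, rng):
        n_sim, alpha = 1000, 0.05
        rejections = 0
        for _ in range(n_sim):
            a = rng.normal(0, 1, 50)
            b = rng.normal(0, 1, 50)
            _, p = compare_distributions(a, b)
            rejections += p < alpha
        rate = rejections / n_sim
        tol = 3 * np.sqrt(alpha * (1 - alpha) / n_sim)
        assert abs(rate - alpha) < tol


class TestClassifyNucleation:
    def test_everything_covered_gives_all_both(self):
        loops = [loop_at(2_000_000, 5_000_000), loop_at(8_000_000, 12_000_000)]
        nuc = IntervalSet([GenomicInterval("chr1", 0, 20_000_000)])
        c = classify_nucleation(loops, nuc, min_distance=1_000_000)
        assert c.frac_both == 1.0

    def test_empty_set_gives_all_neither(self):
        loops = [loop_at(2_000_000, 5_000_000)]
        c = classify_nucleation(loops, IntervalSet(), min_distance=1_000_000)
        assert c.frac_neither == 1.0
        assert np.isnan(c.frac_one_given_any)

    def test_min_distance_is_strict(self):
        loops = [loop_at(2_000_000, 3_000_000)]  # exactly 1 Mb
        nuc = IntervalSet([GenomicInterval("chr1", 0, 20_000_000)])
        c = classify_nucleation(loops, nuc, min_distance=1_000_000)
        assert c.n_considered == 0

    def test_fractions_sum_to_one(self, rng):
        loops = [loop_at(int(m), int(m) + int(d))
                 for m, d in zip(rng.integers(10_000, 5_000_000, 50),
                                 rng.integers(5_000, 3_000_000, 50))]
        nuc = IntervalSet(random_intervals(rng, 100, chroms=("chr1",),
                                           max_pos=8_000_000, max_len=3_000))
        c = classify_nucleation(loops, nuc, min_distance=0)
        assert c.frac_both + c.frac_one + c.frac_neither == pytest.approx(1.0)


class TestAnchorPeakOverlap:
    def test_tiling_peaks_give_one(self):
        loops = [loop_at(2_000_000, 5_000_000)]
        peaks = IntervalSet([GenomicInterval("chr1", 0, 10_000_000)])
        assert anchor_peak_overlap_fraction(loops, peaks, "per_anchor") == 1.0
        assert anchor_peak_overlap_fraction(loops, peaks, "per_loop") == 1.0

    def test_disjoint_peaks_give_zero(self):
        loops = [loop_at(2_000_000, 5_000_000)]
        peaks = IntervalSet([GenomicInterval("chr2", 0, 10_000_000)])
        assert anchor_peak_overlap_fraction(loops, peaks, "per_anchor") == 0.0

    def test_matches_brute_force(self, rng):
        from conftest import brute_overlaps

        loops = [loop_at(int(m), int(m) + int(d))
                 for m, d in zip(rng.integers(10_000, 90_000, 40),
                                 rng.integers(3_000, 50_000, 40))]
        peak_list = random_intervals(rng, 80, chroms=("chr1",))
        peaks = IntervalSet(peak_list)
        per_anchor = np.mean([
            any(brute_overlaps(anc.interval, p) for p in peak_list)
            for lp in loops for anc in (lp.left, lp.right)
        ])
        assert anchor_peak_overlap_fraction(loops, peaks, "per_anchor") == pytest.approx(
            per_anchor
        )


class TestSyntheticClassSeparation:
    def test_long_class_dominates_short_class(self):
        genome = mouse_like_genome(seed=5)
        spec = LoopGeneratorSpec(n_short=300, n_long=300)
        loops, truth = make_loops(spec, genome, seed=5)
        t = truth.table
        med_long = t.loc[t["mark"] == "H3K27me3", "distance"].median()
        med_short = t.loc[t["mark"] == "H3K27ac", "distance"].median()
        assert med_long > med_short
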