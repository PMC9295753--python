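"""Virtual 4C, loop matching and conservation fractions."""

import numpy as np
import pandas as pd
import pytest

from polyloop.contacts import (
    ContactMatrix,
    conserved_loops,
    match_loops,
    virtual_4c,
)
from polyloop.core import Anchor, GenomicInterval, Loop
from polyloop.synth import (
    LoopGeneratorSpec,
    SyntheticGenomeSpec,
    jittered_loop_set,
    make_contact_matrix,
    make_loops,
    mouse_like_genome,
)


def tiny_matrix(entries, n_bins=20, total=None, chrom="chr1", bin_size=10_000):
    bins = pd.DataFrame(
        {
            "chrom": [chrom] * n_bins,
            "start": np.arange(n_bins) * bin_size,
            "end": (np.arange(n_bins) + 1) * bin_size,
        }
    )
    ii, jj, cc = zip(*entries) if entries else ((), (), ())
    counts = np.array(cc, dtype=np.int64)
    return ContactMatrix(
        bins=bins,
        bin_i=np.array(ii, dtype=np.int64),
        bin_j=np.array(jj, dtype=np.int64),
        count=counts,
        total_pairs=total if total is not None else int(counts.sum()),
        bin_size=bin_size,
    )


def loop_at(m1, m2, width=10_000, chrom="chr1"):
    h = width // 2
    return Loop(
        Anchor(GenomicInterval(chrom, m1 - h, m1 + h), "left"),
        Anchor(GenomicInterval(chrom, m2 - h, m2 + h), "right"),
    )


class TestVirtual4C:
    def test_single_entry_scaling(self):
        m = tiny_matrix([(5, 12, 7)], total=1_000_000)
        vp = GenomicInterval("chr1", 50_000, 60_000)  # bin 5
        prof = virtual_4c(m, vp)
        expected = np.zeros(20)
        expected[12] = 1e6 * 7 / 1_000_000
        assert prof.values == pytest.approx(expected)
        assert list(prof.viewpoint_bins) == [5]

    def test_smoothing_window_one_is_identity(self):
        m = tiny_matrix([(5, 12, 7), (5, 13, 3), (2, 5, 4)])
        vp = GenomicInterval("chr1", 50_000, 60_000)
        p1 = virtual_4c(m, vp, smooth_bins=1)
        assert p1.values == pytest.approx(p1.raw_values)

    def test_even_smoothing_rejected(self):
        m = tiny_matrix([(5, 12, 7)])
        with pytest.raises(ValueError):
            virtual_4c(m, GenomicInterval("chr1", 50_000, 60_000), smooth_bins=2)

    def test_absent_chromosome_rejected(self):
        m = tiny_matrix([(5, 12, 7)])
        with pytest.raises((KeyError, ValueError)):
            virtual_4c(m, GenomicInterval("chrX", 0, 10_000))

    def test_mass_conservation_against_dense_row_sum(self):
        genome = SyntheticGenomeSpec(chrom_sizes={"chrV": 2_000_000},
                                     bin_size=10_000, seed=6)
        m = make_contact_matrix(genome, [], depth=500_000, seed=6)
        vp = GenomicInterval("chrV", 700_000, 710_000)  # bin 70
        prof = virtual_4c(m, vp)
        dense = m.dense_cis("chrV")
        expected_mass = 1e6 * dense[70, :].sum() / m.total_pairs
        assert prof.raw_values.sum() == pytest.approx(expected_mass, abs=1e-9)
        # transpose invariance: column-wise computation gives the same profile
        assert prof.raw_values == pytest.approx(
            1e6 * dense[:, 70] / m.total_pairs, abs=1e-9
        )

    def test_planted_dot_is_profile_maximum_outside_exclusion(self):
        genome = SyntheticGenomeSpec(chrom_sizes={"chrV": 5_000_000},
                                     bin_size=10_000, seed=7)
        vp = GenomicInterval("chrV", 1_000_000, 1_010_000)  # bin 100
        partner = GenomicInterval("chrV", 1_200_000, 1_210_000)  # bin 120
        lp = Loop(Anchor(vp, "left"), Anchor(partner, "right"))
        m = make_contact_matrix(genome, [lp], depth=5_000_000,
                                dot_enrichment=8.0, seed=7)
        prof = virtual_4c(m, vp)
        masked = prof.values.copy()
        masked[95:106] = -np.inf  # +/-5 bins around the viewpoint
        assert int(np.argmax(masked)) == 120


class TestMatchLoops:
    def test_identical_sets_fully_shared(self):
        loops = [loop_at(1_000_000, 3_000_000), loop_at(5_000_000, 9_000_000)]
        res = match_loops(loops, list(loops), slack_bp=0)
        assert res.frac_a_shared == 1.0
        assert res.frac_b_shared == 1.0

    def test_disjoint_sets_share_nothing(self):
        a = [loop_at(1_000_000, 3_000_000)]
        b = [loop_at(40_000_000, 43_000_000)]
        res = match_loops(a, b, slack_bp=10_000)
        assert res.pairs == []
        assert res.frac_a_shared == 0.0

    def test_one_to_one_under_competition(self):
        # two b-loops could match the same a-loop; only one is assigned
        a = [loop_at(1_000_000, 3_000_000)]
        b = [loop_at(1_002_000, 3_002_000), loop_at(1_001_000, 3_001_000)]
        res = match_loops(a, b, slack_bp=10_000)
        assert len(res.pairs) == 1
        assert res.pairs[0] == (0, 1)  # closer candidate wins
        assert res.b_only == [0]

    def test_shared_count_symmetric(self, rng):
        a = [loop_at(int(m), int(m) + int(d))
             for m, d in zip(rng.integers(1_000_000, 30_000_000, 40),
                             rng.integers(200_000, 5_000_000, 40))]
        b = [loop_at(int(m), int(m) + int(d))
             for m, d in zip(rng.integers(1_000_000, 30_000_000, 50),
                             rng.integers(200_000, 5_000_000, 50))]
        ab = match_loops(a, b, slack_bp=50_000)
        ba = match_loops(b, a, slack_bp=50_000)
        assert len(ab.pairs) == len(ba.pairs)

    def test_jitter_within_slack_all_match_beyond_none(self):
        base = [loop_at(m, m + 2_000_000) for m in
                range(1_000_000, 20_000_000, 1_000_000)]
        slack = 10_000
        within = [loop_at(lp.left.midpoint + 4_000, lp.right.midpoint - 4_000)
                  for lp in base]
        res = match_loops(base, within, slack_bp=slack)
        assert len(res.pairs) == len(base)
        # shift beyond 2*slack + both anchor widths: no anchor pair can touch
        far = [loop_at(lp.left.midpoint + 41_000, lp.right.midpoint + 141_000)
               for lp in base]
        res = match_loops(base, far, slack_bp=slack)
        assert res.pairs == []

    def test_candidate_predicate_matches_brute_force(self, rng):
        slack = 20_000
        a = [loop_at(int(m), int(m) + int(d))
             for m, d in zip(rng.integers(1_000_000, 10_000_000, 25),
                             rng.integers(100_000, 2_000_000, 25))]
        b = [loop_at(int(m), int(m) + int(d))
             for m, d in zip(rng.integers(1_000_000, 10_000_000, 25),
                             rng.integers(100_000, 2_000_000, 25))]
        res = match_loops(a, b, slack_bp=slack)

        def anchors_touch(x, y):
            return (x.chrom == y.chrom
                    and x.start - slack < y.end + slack
                    and y.start - slack < x.end + slack)

        # every reported pair satisfies the anchor criterion...
        for ia, ib in res.pairs:
            assert anchors_touch(a[ia].left.interval, b[ib].left.interval)
            assert anchors_touch(a[ia].right.interval, b[ib].right.interval)
        # ...and every a-loop with no candidate at all is unmatched
        matched_a = {ia for ia, _ in res.pairs}
        for ia, la in enumerate(a):
            has_candidate = any(
                anchors_touch(la.left.interval, lb.left.interval)
                and anchors_touch(la.right.interval, lb.right.interval)
                for lb in b
            )
            if not has_candidate:
                assert ia not in matched_a


class TestConservedLoops:
    def test_identical_mapped_set_is_fully_conserved(self):
        loops = [loop_at(1_000_000, 3_000_000), loop_at(5_000_000, 9_000_000)]
        assert conserved_loops(loops, list(loops)) == 1.0

    def test_empty_mapped_set(self):
        assert conserved_loops([loop_at(1_000_000, 3_000_000)], []) == 0.0

    def test_chromosome_style_mismatch_detected(self):
        native = [loop_at(1_000_000, 3_000_000, chrom="chr1")]
        mapped = [loop_at(1_000_000, 3_000_000, chrom="1")]
        with pytest.raises(ValueError, match="normalize"):
            conserved_loops(native, mapped)

    def test_thirty_percent_sharing_recovered(self):
        genome = mouse_like_genome(seed=21)
        spec = LoopGeneratorSpec(n_short=0, n_long=1000)
        loops, _ = make_loops(spec, genome, seed=21)
        mapped, mask = jittered_loop_set(
            loops, genome, shared_fraction=0.30, jitter_bp=5_000, seed=22
        )
        frac = conserved_loops(loops, mapped, slack_bp=10_000)
        tol = 3 * np.sqrt(0.3 * 0.7 / len(loops))
        assert abs(frac - 0.30) < tol
        # at least every truly copied loop must be matched
        assert frac >= mask.mean() - 1e-12
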