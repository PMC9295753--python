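"""Generator contracts: determinism, tilings, planted-parameter recovery."""

import numpy as np
import pandas as pd
import pytest

from polyloop.core import GenomicInterval, IntervalSet
from polyloop.synth import (
    LoopGeneratorSpec,
    SyntheticGenomeSpec,
    make_contact_matrix,
    make_differential_table,
    make_loops,
    make_orca_traces,
    make_signal_track,
    make_sites,
    make_tads_and_compartments,
    mouse_like_genome,
)


class TestMakeLoops:
    def test_no_long_loops_requested(self, small_genome):
        spec = LoopGeneratorSpec(n_short=20, n_long=0)
        loops, truth = make_loops(spec, small_genome, seed=3)
        assert all(lp.mark == "H3K27ac" for lp in loops)
        assert (truth.table["mark"] == "H3K27ac").all()
        assert len(truth.nucleation_points) == 0

    def test_fixed_seed_reproducible(self, small_genome):
        spec = LoopGeneratorSpec(n_short=30, n_long=30)
        loops1, truth1 = make_loops(spec, small_genome, seed=11)
        loops2, truth2 = make_loops(spec, small_genome, seed=11)
        assert loops1 == loops2
        pd.testing.assert_frame_equal(truth1.table, truth2.table)
        assert list(truth1.nucleation_points) == list(truth2.nucleation_points)

    def test_realized_distance_matches_truth_exactly(self, small_genome):
        from polyloop.core import anchor_distance

        spec = LoopGeneratorSpec(n_short=50, n_long=0)
        loops, truth = make_loops(spec, small_genome, seed=2)
        realized = [anchor_distance(lp, "midpoint") for lp in loops]
        assert realized == truth.table["distance"].tolist()

    def test_nucleation_fraction_recovery(self):
        # spec'd recovery experiment: (both, one) = (0.25, 0.37) at n=2000
        genome = mouse_like_genome(seed=9)
        spec = LoopGeneratorSpec(
            n_short=0, n_long=2000,
            frac_nucleation_both=0.25, frac_nucleation_one=0.37,
        )
        _, truth = make_loops(spec, genome, seed=9)
        labels = truth.table["nucleation"]
        frac_any = (labels != "neither").mean()
        target = 0.25 + 0.37
        tol = 3 * np.sqrt(target * (1 - target) / 2000)
        assert abs(frac_any - target) < tol

    def test_anchor_width_must_be_even(self):
        with pytest.raises(ValueError):
            LoopGeneratorSpec(anchor_width=10_001)

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            LoopGeneratorSpec(frac_nucleation_both=0.7, frac_nucleation_one=0.5)


class TestTadsAndCompartments:
    def test_tiling_covers_chromosome(self):
        genome = SyntheticGenomeSpec(chrom_sizes={"chr1": 10_000_000}, seed=4)
        tads, comps = make_tads_and_compartments(genome, seed=4)
        tad_list = tads.on_chrom("chr1")
        assert 5 <= len(tad_list) <= 20
        assert tad_list[0].start == 0
        assert tad_list[-1].end == 10_000_000
        for prev, nxt in zip(tad_list, tad_list[1:]):
            assert prev.end == nxt.start  # no gap, no overlap

    def test_compartment_boundaries_are_tad_boundaries(self, small_genome):
        tads, comps = make_tads_and_compartments(small_genome, seed=8)
        for chrom in small_genome.chroms:
            tad_edges = {t.start for t in tads.on_chrom(chrom)}
            tad_edges |= {t.end for t in tads.on_chrom(chrom)}
            for seg in comps.on_chrom(chrom):
                assert seg.start in tad_edges
                assert seg.end in tad_edges

    def test_compartment_labels_alternate(self, small_genome):
        _, comps = make_tads_and_compartments(small_genome, seed=8)
        for chrom in small_genome.chroms:
            labels = [seg.name for seg in comps.on_chrom(chrom)]
            assert all(l in ("A", "B") for l in labels)
            assert all(x != y for x, y in zip(labels, labels[1:]))


class TestContactMatrix:
    def make_small(self, loops=(), depth=500_000, decay=1.0, seed=0):
        genome = SyntheticGenomeSpec(
            chrom_sizes={"chrV": 2_000_000}, bin_size=10_000, seed=seed
        )
        return genome, make_contact_matrix(
            genome, list(loops), depth=depth, decay_exponent=decay, seed=seed
        )

    def test_stored_upper_triangle_and_symmetric_dense(self):
        _, m = self.make_small(seed=1)
        assert (m.bin_i <= m.bin_j).all()
        dense = m.dense_cis("chrV")
        assert np.array_equal(dense, dense.T)

    def test_distance_decay_monotone_in_expectation(self):
        _, m = self.make_small(depth=5_000_000, seed=2)
        dense = m.dense_cis("chrV")
        n = dense.shape[0]
        by_sep = [
            np.mean([dense[i, i + s] for i in range(n - s)])
            for s in range(0, n, 10)
        ]
        # binned means over many rows: non-increasing up to sampling noise
        smoothed = np.convolve(by_sep, np.ones(3) / 3, mode="valid")
        assert all(x >= y - 0.5 for x, y in zip(smoothed, smoothed[1:]))

    def test_planted_dot_is_local_maximum(self):
        from polyloop.core import Anchor, Loop

        vp = GenomicInterval("chrV", 500_000, 510_000)
        partner = GenomicInterval("chrV", 1_200_000, 1_210_000)
        lp = Loop(Anchor(vp, "left"), Anchor(partner, "right"))
        _, m = self.make_small(loops=[lp], depth=20_000_000, seed=3)
        dense = m.dense_cis("chrV")
        bi, bj = 50, 120
        window = dense[bi - 5 : bi + 6, bj - 5 : bj + 6]
        assert dense[bi, bj] == window.max()

    def test_total_pairs_records_realized_sum(self):
        _, m = self.make_small(seed=4)
        assert m.total_pairs == int(m.count.sum())


class TestSignalTrack:
    def test_no_peaks_gives_constant_background(self):
        genome = SyntheticGenomeSpec(chrom_sizes={"chr1": 100_000}, seed=0)
        track = make_signal_track(IntervalSet(), genome, background=0.25)
        assert len(track) == 1
        assert track.iloc[0]["value"] == 0.25
        assert track.iloc[0]["end"] == 100_000

    def test_isolated_peak_integral(self):
        genome = SyntheticGenomeSpec(chrom_sizes={"chr1": 100_000}, seed=0)
        peaks = IntervalSet([GenomicInterval("chr1", 40_000, 44_000)])
        h, bg = 6.0, 0.5
        track = make_signal_track(peaks, genome, peak_height=h, background=bg)
        sub = track[(track["start"] >= 40_000) & (track["end"] <= 44_000)]
        integral = (sub["value"] * (sub["end"] - sub["start"])).sum()
        w = 4_000
        assert integral == pytest.approx(bg * w + h * w / 2, rel=1e-12)

    def test_track_tiles_chromosome(self):
        genome = SyntheticGenomeSpec(chrom_sizes={"chr1": 50_000}, seed=0)
        peaks = IntervalSet([GenomicInterval("chr1", 10_000, 12_000),
                             GenomicInterval("chr1", 30_000, 31_000)])
        track = make_signal_track(peaks, genome)
        assert track.iloc[0]["start"] == 0
        assert track.iloc[-1]["end"] == 50_000
        for a, b in zip(track.itertuples(), track.iloc[1:].itertuples()):
            assert a.end == b.start


class TestOrcaGenerator:
    BARCODES = ["Hoxa", "Cntr", "Vax2"]

    def test_contact_probability_one_forces_contact(self):
        traces = make_orca_traces(
            200, self.BARCODES, {("Hoxa", "Vax2"): 1.0},
            contact_radius=150, missing_rate=0.0, seed=1,
        )
        from polyloop.orca import pair_distances

        res = pair_distances(traces, "Hoxa", "Vax2")
        assert res.n_informative == 200
        assert (res.distances_nm < 150).all()

    def test_missing_rate_one_drops_everything(self):
        traces = make_orca_traces(
            50, self.BARCODES, {}, missing_rate=1.0, seed=2
        )
        assert len(traces.df) == 0

    def test_determinism(self):
        kw = dict(contact_radius=150, missing_rate=0.1, seed=5)
        t1 = make_orca_traces(100, self.BARCODES, {("Hoxa", "Vax2"): 0.4}, **kw)
        t2 = make_orca_traces(100, self.BARCODES, {("Hoxa", "Vax2"): 0.4}, **kw)
        pd.testing.assert_frame_equal(t1.df, t2.df)

    def test_unknown_pair_rejected(self):
        with pytest.raises(ValueError):
            make_orca_traces(10, self.BARCODES, {("Hoxa", "Nope"): 0.5}, seed=0)


class TestDifferentialTable:
    def setup_inputs(self, seed=0, n=200):
        genome = mouse_like_genome(seed=seed)
        _, comps = make_tads_and_compartments(genome, seed=seed)
        sites = make_sites(genome, n, seed=seed + 1)
        rng = np.random.default_rng(seed + 2)
        flags = rng.random(n) < 0.5
        ezh2 = IntervalSet([iv for iv, f in zip(sites, flags) if f])
        deletion = GenomicInterval("chr6", 52_000_000, 52_700_000)
        return sites, ezh2, comps, deletion

    def test_null_calibration_at_alpha(self):
        sites, ezh2, comps, deletion = self.setup_inputs(seed=3, n=400)
        table, truth = make_differential_table(
            sites, ezh2, comps, deletion, effect_size=0.0, seed=3
        )
        assert not truth["planted"].any()
        alpha = 0.05
        n_sig = (table["padj"] < alpha).sum()
        tol = 3 * np.sqrt(alpha * (1 - alpha) * len(table))
        assert abs(n_sig - alpha * len(table)) < tol

    def test_all_occupied_means_nothing_planted(self):
        sites, _, comps, deletion = self.setup_inputs(seed=4)
        ezh2_all = IntervalSet(list(sites))
        _, truth = make_differential_table(
            sites, ezh2_all, comps, deletion, effect_size=2.0, seed=4
        )
        assert not truth["planted"].any()

    def test_planted_only_in_unoccupied_same_compartment(self):
        sites, ezh2, comps, deletion = self.setup_inputs(seed=5)
        _, truth = make_differential_table(
            sites, ezh2, comps, deletion, effect_size=2.0, seed=5
        )
        planted = truth[truth["planted"]]
        assert len(planted) > 0
        assert not planted["ezh2_occupied"].any()
        assert planted["same_compartment"].all()
        assert not planted["in_deletion"].any()
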