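"""Stitching, scoring, the slope-1 cutoff and the SE/TE partition."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import seconsensus as sc

from conftest import constant_track
from oracles import cutoff_oracle, stitch_oracle


def peaks(*coords, chrom="chr1"):
    return sc.PeakSet(
        intervals=[sc.GenomicInterval(chrom, s, e) for s, e in coords]
    )


class TestStitchPeaks:
    def test_merges_within_and_splits_beyond_distance(self):
        regions = sc.stitch_peaks(
            peaks((0, 1000), (5000, 6000), (20000, 21000)), stitch_distance=12_500
        )
        spans = [(r.interval.start, r.interval.end, r.n_constituents) for r in regions]
        assert spans == [(0, 6000, 2), (20000, 21000, 1)]

    def test_gap_exactly_at_distance_merges(self):
        regions = sc.stitch_peaks(peaks((0, 100), (12_600, 12_700)), 12_500)
        assert len(regions) == 1 and regions[0].interval.end == 12_700

    def test_single_peak_identity(self):
        (r,) = sc.stitch_peaks(peaks((42, 99)), 12_500)
        assert (r.interval.start, r.interval.end, r.n_constituents) == (42, 99, 1)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            sc.stitch_peaks(peaks((0, 10)), -1)

    def test_chromosomes_never_stitch_together(self):
        ps = sc.PeakSet(
            intervals=[
                sc.GenomicInterval("chr1", 0, 100),
                sc.GenomicInterval("chr2", 50, 150),
            ]
        )
        assert len(sc.stitch_peaks(ps, 1_000_000)) == 2

    def test_tss_exclusion_removes_promoter_peaks(self):
        genes = [
            sc.GeneModel("A", sc.GenomicInterval("chr1", 10_000, 20_000, "+"))
        ]
        ps = peaks((9_000, 9_500), (40_000, 41_000))  # first inside TSS +/- 2500
        regions = sc.stitch_peaks(ps, 12_500, tss_exclusion=(genes, 2_500))
        assert [(r.interval.start, r.interval.end) for r in regions] == [
            (40_000, 41_000)
        ]

    @given(
        st.lists(
            st.tuples(st.integers(0, 60_000), st.integers(1, 4_000)),
            min_size=1,
            max_size=60,
        ),
        st.sampled_from([0, 100, 2_500, 12_500]),
    )
    def test_matches_connected_components_oracle(self, raw, d):
        ivs = sorted([(s, s + l) for s, l in raw])
        regions = sc.stitch_peaks(peaks(*ivs), d)
        starts = np.array([s for s, _ in ivs])
        ends = np.array([e for _, e in ivs])
        labels = stitch_oracle(starts, ends, d)
        assert len(regions) == len(set(labels))
        # partition: every peak in exactly one region
        assert sorted(i for r in regions for i in r.constituent_ids) == list(
            range(len(ivs))
        )
        # region spans equal component spans
        got = sorted((r.interval.start, r.interval.end) for r in regions)
        want = sorted(
            (int(starts[labels == k].min()), int(ends[labels == k].max()))
            for k in set(labels)
        )
        assert got == want

    @given(
        st.lists(
            st.tuples(st.integers(0, 100_000), st.integers(1, 5_000)),
            min_size=1,
            max_size=40,
        )
    )
    def test_idempotent_and_gaps_exceed_distance(self, raw):
        d = 12_500
        ivs = sorted([(s, s + l) for s, l in raw])
        regions = sc.stitch_peaks(peaks(*ivs), d)
        spans = [(r.interval.start, r.interval.end) for r in regions]
        for (s0, e0), (s1, e1) in zip(spans, spans[1:]):
            assert s1 - e0 > d
        again = sc.stitch_peaks(peaks(*spans), d)
        assert [(r.interval.start, r.interval.end) for r in again] == spans


class TestFindSECutoff:
    def test_worked_example_against_oracle_then_frozen(self):
        s = [0, 1, 2, 4, 8, 16, 32, 64]
        assert cutoff_oracle(s) == (16.0, 5)
        value, idx = sc.find_se_cutoff(s)
        assert (value, idx) == (16.0, 5)
        assert sum(x > value for x in s) == 2

    def test_linear_curve_yields_no_ses(self):
        value, idx = sc.find_se_cutoff([0, 1, 2, 3, 4])
        assert (value, idx) == (4.0, 4)

    def test_flat_curve_conservative(self):
        value, idx = sc.find_se_cutoff([5, 5, 5, 5])
        assert (value, idx) == (5.0, 3)

    def test_all_zero_degenerate(self):
        value, idx = sc.find_se_cutoff([0.0, 0.0, 0.0])
        assert (value, idx) == (0.0, 2)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            sc.find_se_cutoff([1.0])

    def test_unsorted_rejected(self):
        with pytest.raises(ValueError, match="ascending"):
            sc.find_se_cutoff([3.0, 1.0, 2.0])

    @given(
        st.lists(st.floats(0, 1e6, allow_nan=False), min_size=2, max_size=200),
    )
    def test_matches_bruteforce_oracle(self, values):
        s = sorted(values)
        assert sc.find_se_cutoff(s) == cutoff_oracle(s)


class TestScoreAndCall:
    def test_scoring_and_ranks(self):
        track = sc.SignalTrack(
            bins={"chr1": np.concatenate([np.full(20, 5.0), np.full(20, 1.0)])},
            bin_width=50,
        )
        regions = sc.stitch_peaks(peaks((0, 1000), (1500, 2000)), 0)
        scored = sc.score_stitched(regions, track)
        assert [r.signal for r in scored] == [500.0, 5000.0]
        assert [r.rank for r in scored] == [2, 1]

    def test_zero_track_ties_broken_by_position(self):
        track = sc.SignalTrack(bins={"chr1": np.zeros(100)}, bin_width=50)
        regions = sc.stitch_peaks(peaks((3000, 3100), (0, 100), (1000, 1100)), 0)
        scored = sc.score_stitched(regions, track)
        assert [r.interval.start for r in scored] == [0, 1000, 3000]

    def test_scoring_invariant_to_input_order(self):
        rng = np.random.default_rng(2)
        track = sc.SignalTrack(
            bins={"chr1": rng.uniform(0, 5, 1000)}, bin_width=50
        )
        coords = [(i * 3000, i * 3000 + 500) for i in range(10)]
        a = sc.score_stitched(sc.stitch_peaks(peaks(*coords), 0), track)
        shuffled = [coords[i] for i in rng.permutation(10)]
        b = sc.score_stitched(sc.stitch_peaks(peaks(*shuffled), 0), track)
        assert [(r.interval.start, r.signal) for r in a] == [
            (r.interval.start, r.signal) for r in b
        ]

    def _toy_call(self, scale=1.0):
        # 8 isolated peaks engineered to produce signals [0,1,2,4,8,16,32,64]*100
        signals = [0, 1, 2, 4, 8, 16, 32, 64]
        coords, bins = [], np.zeros(8 * 400)
        for i, s in enumerate(signals):
            start = i * 20_000
            coords.append((start, start + 100))
            bins[start // 50 : start // 50 + 2] = s * scale
        track = sc.SignalTrack(bins={"chr1": bins}, bin_width=50)
        return sc.call_superenhancers(peaks(*coords), track, stitch_distance=12_500)

    def test_composition_on_worked_example(self):
        result = self._toy_call()
        assert len(result.regions) == 8
        assert int(result.is_super.sum()) == 2
        assert result.cutoff_index == 5
        se_signals = sorted(r.signal for r in result.superenhancers)
        assert se_signals == [3200.0, 6400.0]

    def test_membership_invariant_to_track_scaling(self):
        a, b = self._toy_call(1.0), self._toy_call(10.0)
        assert a.is_super.tolist() == b.is_super.tolist()
        assert a.cutoff_index == b.cutoff_index

    def test_equal_signals_yield_zero_ses(self):
        coords = [(i * 30_000, i * 30_000 + 100) for i in range(6)]
        track = constant_track(value=2.0, length=200_000)
        result = sc.call_superenhancers(peaks(*coords), track)
        assert int(result.is_super.sum()) == 0

    @given(
        st.lists(
            st.tuples(st.integers(0, 300), st.integers(1, 40), st.floats(0, 50)),
            min_size=2,
            max_size=40,
        )
    )
    def test_se_set_is_suffix_of_ranking(self, raw):
        bins = np.zeros(6500)
        coords = []
        seen = set()
        for b, l, v in raw:
            if b in seen:
                continue
            seen.add(b)
            coords.append((b * 1000, b * 1000 + l * 10))
            bins[b * 20 : b * 20 + l] = v
        if len(coords) < 2:
            return
        track = sc.SignalTrack(bins={"chr1": bins}, bin_width=50)
        result = sc.call_superenhancers(
            peaks(*sorted(coords)), track, stitch_distance=0
        )
        flags = result.is_super.tolist()
        # suffix property: once True in ascending order, stays True
        assert flags == sorted(flags)
        signals = [r.signal for r in result.regions]
        assert signals == sorted(signals)


class TestConstituentEnhancers:
    def test_contained_peaks_in_order(self):
        se = sc.StitchedRegion(
            interval=sc.GenomicInterval("chr1", 0, 10_000), constituent_ids=[]
        )
        access = peaks((8000, 8400), (100, 300), (2000, 2300), (5000, 5400), (9000, 9400))
        got = sc.constituent_enhancers(se, access)
        assert [iv.start for iv in got] == [100, 2000, 5000, 8000, 9000]

    def test_straddling_peak_included(self):
        se = sc.StitchedRegion(
            interval=sc.GenomicInterval("chr1", 0, 10_000), constituent_ids=[]
        )
        got = sc.constituent_enhancers(se, peaks((9990, 10_050)))
        assert len(got) == 1

    def test_no_overlap_empty(self):
        se = sc.StitchedRegion(
            interval=sc.GenomicInterval("chr1", 0, 100), constituent_ids=[]
        )
        assert sc.constituent_enhancers(se, peaks((200, 300))) == []
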