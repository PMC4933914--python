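import numpy as np
import pytest

from cnvscreen.io import CnvCall, ProbeMap
from cnvscreen.segments import (
    Segment,
    assign_states,
    decompose_segments,
    filter_by_frequency,
    merge_segments_to_cnvrs,
    segment_frequencies,
    snap_to_probes,
)

from _oracles import brute_segments, brute_state_matrix, random_instance


def call(sid, start, end, cn=1, chrom="chr1"):
    return CnvCall(sid, chrom, start, end, cn=cn)


def spans(segs):
    return [(s.start, s.end) for s in segs]


class TestDecompose:
    def test_partial_overlap_gives_three_segments(self):
        segs = decompose_segments([call("S1", 100, 200), call("S2", 150, 300)])
        assert spans(segs) == [(100, 149), (150, 200), (201, 300)]

    def test_single_call_is_identity(self):
        segs = decompose_segments([call("S1", 100, 200)])
        assert spans(segs) == [(100, 200)]

    def test_disjoint_calls_stay_separate(self):
        segs = decompose_segments([call("S1", 100, 200), call("S1", 500, 600)])
        assert spans(segs) == [(100, 200), (500, 600)]

    def test_conservation_of_covered_bases(self):
        rng = np.random.default_rng(42)
        calls, _ = random_instance(rng)
        segs = decompose_segments(calls)
        covered_calls = set()
        for c in calls:
            covered_calls.update(range(c.start, c.end + 1))
        covered_segs = set()
        for s in segs:
            covered_segs.update(range(s.start, s.end + 1))
        assert covered_calls == covered_segs

    def test_segments_refine_cnvrs(self):
        from cnvscreen.cnvr import merge_calls_to_cnvrs

        rng = np.random.default_rng(43)
        calls, _ = random_instance(rng)
        cnvrs = merge_calls_to_cnvrs(calls)
        for s in decompose_segments(calls):
            parents = [r for r in cnvrs if r.start <= s.start and s.end <= r.end]
            assert len(parents) == 1


class TestSnapToProbes:
    PROBES = ProbeMap({"chr1": [100, 150, 210]})

    def test_boundaries_move_to_nearest_probe(self):
        (s,) = snap_to_probes([Segment("x", "chr1", 149, 205)], self.PROBES)
        assert (s.start, s.end) == (150, 210)

    def test_probe_positions_are_fixed_points(self):
        (s,) = snap_to_probes([Segment("x", "chr1", 150, 210)], self.PROBES)
        assert (s.start, s.end) == (150, 210)

    def test_no_probe_map_is_identity(self):
        seg = Segment("x", "chr1", 149, 205)
        assert snap_to_probes([seg], None) == [seg]

    def test_equidistant_tie_goes_lower(self):
        (s,) = snap_to_probes([Segment("x", "chr1", 125, 210)], self.PROBES)
        assert s.start == 100

    def test_degenerate_segment_dropped_with_warning(self):
        segs = [Segment("a", "chr1", 100, 150), Segment("b", "chr1", 151, 160)]
        with pytest.warns(UserWarning, match="degenerate"):
            out = snap_to_probes(segs, self.PROBES)
        # second segment's start must exceed 150 -> probe 210 > snapped end 150
        assert spans(out) == [(100, 150)]

    def test_return_index_tracks_survivors(self):
        segs = [Segment("a", "chr1", 100, 150), Segment("b", "chr1", 151, 160)]
        with pytest.warns(UserWarning):
            out, kept = snap_to_probes(segs, self.PROBES, return_index=True)
        assert kept == [0]


class TestAssignStates:
    def test_states_default_and_capping(self):
        calls = [call("S1", 100, 200, cn=1), call("S3", 100, 200, cn=6)]
        segs = decompose_segments(calls)
        m = assign_states(segs, calls, ["S1", "S2", "S3"])
        assert m.label("S1", segs[0].segment_id) == "A1"
        assert m.label("S2", segs[0].segment_id) == "A2"
        assert m.label("S3", segs[0].segment_id) == "A>4"

    def test_same_sample_overlap_is_error(self):
        calls = [call("S1", 100, 200), call("S1", 150, 300)]
        segs = decompose_segments(calls)
        with pytest.raises(ValueError, match="S1"):
            assign_states(segs, calls, ["S1"])

    def test_matrix_matches_brute_force(self):
        rng = np.random.default_rng(7)
        calls, sample_ids = random_instance(rng)
        segs = decompose_segments(calls)
        m = assign_states(segs, calls, sample_ids)
        want = brute_state_matrix(calls, sample_ids, [(s.chrom, s.start, s.end) for s in segs])
        assert np.array_equal(m.states, want)


class TestSegmentFrequencies:
    def matrix(self, states):
        states = np.asarray(states)
        segs = [Segment(f"g{i}", "chr1", 100 * i + 1, 100 * i + 50) for i in range(states.shape[1])]
        return segs, states

    def test_variant_loss_gain_counting(self):
        from cnvscreen.segments import StateMatrix

        col = [[1], [1], [3], [2], [2], [2], [2], [2], [2], [2]]
        segs, states = self.matrix(col)
        m = StateMatrix([f"S{i}" for i in range(10)], segs, states)
        (f,) = segment_frequencies(m, {"all": [f"S{i}" for i in range(10)]})
        g = f.groups["all"]
        assert g.loss_freq == pytest.approx(0.2)
        assert g.gain_freq == pytest.approx(0.1)
        assert g.variant_freq == pytest.approx(0.3)
        assert g.variant_freq == pytest.approx(1.0 - g.state_freq[2])
        assert sum(g.state_freq) == pytest.approx(1.0)

    def test_all_normal_gives_zero(self):
        from cnvscreen.segments import StateMatrix

        segs, states = self.matrix([[2], [2], [2]])
        m = StateMatrix(["S1", "S2", "S3"], segs, states)
        (f,) = segment_frequencies(m, {"all": ["S1", "S2", "S3"]})
        assert f.groups["all"].variant_freq == 0.0

    def test_empty_group_rejected(self):
        from cnvscreen.segments import StateMatrix

        segs, states = self.matrix([[2]])
        m = StateMatrix(["S1"], segs, states)
        with pytest.raises(ValueError, match="empty"):
            segment_frequencies(m, {"g": []})


class TestFrequencyFilter:
    def freqs(self, per_group):
        from cnvscreen.segments import GroupFrequency, SegmentFrequency

        out = []
        for sid, groups in per_group.items():
            gf = {
                g: GroupFrequency(10, v, v, 0.0, (0.0, v, 1 - v, 0.0, 0.0, 0.0))
                for g, v in groups.items()
            }
            out.append(SegmentFrequency(sid, gf))
        return out

    def test_min_all_keeps_common_segments(self):
        fr = self.freqs({"s1": {"A": 0.06, "B": 0.07}, "s2": {"A": 0.06, "B": 0.04}})
        assert filter_by_frequency(fr, "min_all", 0.05) == {"s1"}

    def test_min_any_strict_high_frequency_rule(self):
        fr = self.freqs({"s1": {"A": 0.11}, "s2": {"A": 0.1}})
        assert filter_by_frequency(fr, "min_any", 0.1, strict=True) == {"s1"}

    def test_max_any_drops_exceeders(self):
        fr = self.freqs({"s1": {"A": 0.2}, "s2": {"A": 0.01}})
        assert filter_by_frequency(fr, "max_any", 0.1, strict=True) == {"s2"}

    def test_unknown_mode(self):
        with pytest.raises(ValueError, match="mode"):
            filter_by_frequency([], "median", 0.5)


class TestMergeSegments:
    SEGS = [
        Segment("a", "chr1", 100, 149),
        Segment("b", "chr1", 150, 200),
        Segment("c", "chr1", 500, 600),
    ]

    def test_adjacent_segments_merge(self):
        (r,) = merge_segments_to_cnvrs({"a", "b"}, self.SEGS)
        assert (r.start, r.end) == (100, 200)

    def test_distant_segments_stay_separate(self):
        regions = merge_segments_to_cnvrs({"a", "c"}, self.SEGS)
        assert [(r.start, r.end) for r in regions] == [(100, 149), (500, 600)]

    def test_empty_selection(self):
        assert merge_segments_to_cnvrs(set(), self.SEGS) == []

    def test_unknown_id_rejected(self):
        with pytest.raises(KeyError, match="unknown"):
            merge_segments_to_cnvrs({"zz"}, self.SEGS)


class TestSegmentationOracle:
    @pytest.mark.parametrize("seed", range(15))
    def test_boundaries_match_per_base_grouping(self, seed):
        rng = np.random.default_rng(1000 + seed)
        calls, _ = random_instance(rng)
        got = [(s.chrom, s.start, s.end) for s in decompose_segments(calls)]
        assert got == brute_segments(calls, 22_000)
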