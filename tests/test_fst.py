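from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cnvscreen.fst import (
    FstResult,
    ScreenConfig,
    breed_differential,
    common_cnvrs,
    fst_scan,
    multiallelic_fst,
    screen_fp_cnvrs,
)
from cnvscreen.pipeline import gender_screen, population_groups, segment_cohort
from cnvscreen.segments import Segment, StateMatrix, segment_frequencies
from cnvscreen.simulate import simulate_cohort, tiny_config

from _oracles import fst_biallelic_exact, fst_direct


def vec(**kw):
    v = [0.0] * 6
    for k, x in kw.items():
        v[int(k[1:])] = x
    return tuple(v)


class TestMultiallelicFst:
    def test_identical_groups_have_zero_fst(self):
        x = vec(a1=0.3, a2=0.5, a3=0.2)
        assert multiallelic_fst(x, 50, x, 150).fst == 0.0

    def test_complete_fixation_gives_one(self):
        r = multiallelic_fst(vec(a0=1.0), 100, vec(a2=1.0), 100)
        assert r.fst == 1.0
        assert r.h_s == 0.0 and r.h_t == pytest.approx(0.5)

    def test_hand_evaluated_example(self):
        r = multiallelic_fst(vec(a2=0.8, a0=0.2), 100, vec(a2=0.95, a0=0.05), 100)
        assert r.h_t == pytest.approx(0.21875, abs=1e-12)
        assert r.h_s == pytest.approx(0.2075, abs=1e-12)
        assert r.fst == pytest.approx(0.051428571428, abs=1e-9)

    def test_monomorphic_identical_groups_define_zero(self):
        r = multiallelic_fst(vec(a2=1.0), 10, vec(a2=1.0), 10)
        assert r.fst == 0.0 and r.h_t == 0.0

    def test_t_vector_is_weighted_average(self):
        r = multiallelic_fst(vec(a1=1.0), 100, vec(a2=1.0), 300)
        assert r.t_vector[1] == pytest.approx(0.25)
        assert sum(r.t_vector) == pytest.approx(1.0)

    def test_input_validation(self):
        with pytest.raises(ValueError, match="sum to 1"):
            multiallelic_fst(vec(a2=0.9), 10, vec(a2=1.0), 10)
        with pytest.raises(ValueError, match="negative"):
            multiallelic_fst((1.2, -0.2, 0, 0, 0, 0), 10, vec(a2=1.0), 10)
        with pytest.raises(ValueError, match="group sizes"):
            multiallelic_fst(vec(a2=1.0), 0, vec(a2=1.0), 10)

    def test_matches_exact_rational_biallelic_form(self):
        # two categories, equal sizes: compare against Fraction arithmetic
        for p_num in range(0, 11):
            for q_num in range(0, 11):
                p, q = Fraction(p_num, 10), Fraction(q_num, 10)
                want = float(fst_biallelic_exact(p, q))
                got = multiallelic_fst(
                    vec(a1=float(p), a2=float(1 - p)), 77, vec(a1=float(q), a2=float(1 - q)), 77
                ).fst
                assert got == pytest.approx(want, abs=1e-12)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(0.01, 1.0), min_size=6, max_size=6),
        st.lists(st.floats(0.01, 1.0), min_size=6, max_size=6),
        st.integers(1, 500),
        st.integers(1, 500),
    )
    def test_bounds_hold_for_random_vectors(self, xw, yw, n_x, n_y):
        x = np.array(xw) / np.sum(xw)
        y = np.array(yw) / np.sum(yw)
        x[0] += 1.0 - x.sum()  # exact renormalisation
        y[0] += 1.0 - y.sum()
        r = multiallelic_fst(x, n_x, y, n_y)
        assert 0.0 <= r.fst <= 1.0
        assert r.h_s <= r.h_t + 1e-12

    def test_monotone_in_variant_frequency_against_fixed_normal(self):
        y = vec(a2=1.0)
        grid = np.linspace(0.0, 1.0, 51)
        values = [multiallelic_fst(vec(a0=f, a2=1.0 - f), 100, y, 100).fst for f in grid]
        assert all(b >= a - 1e-12 for a, b in zip(values, values[1:]))


class TestFstScan:
    def make_matrix(self):
        segs = [Segment("g0", "chr1", 1, 100), Segment("g1", "chr1", 200, 300)]
        # segment g0 fixed loss in females, normal in males; g1 all-normal
        samples = [f"F{i}" for i in range(5)] + [f"M{i}" for i in range(5)]
        states = np.full((10, 2), 2, dtype=np.int8)
        states[:5, 0] = 0
        return StateMatrix(samples, segs, states), samples[:5], samples[5:]

    def test_sex_fixed_segment_scores_one(self):
        m, females, males = self.make_matrix()
        r0, r1 = fst_scan(m, females, males)
        assert r0.fst == 1.0
        assert r1.fst == 0.0

    def test_overlapping_groups_rejected(self):
        m, females, males = self.make_matrix()
        with pytest.raises(ValueError, match="disjoint"):
            fst_scan(m, females, females)

    def test_empty_group_rejected(self):
        m, females, males = self.make_matrix()
        with pytest.raises(ValueError, match="nonempty"):
            fst_scan(m, [], males)


class TestFpScreen:
    def test_planted_artifacts_recovered_with_classes(self, tiny_sim):
        cohort = segment_cohort(tiny_sim.calls, tiny_sim.samples, tiny_sim.probes)
        _, _, fp = gender_screen(cohort, tiny_sim.samples)
        truth = {(r.chrom, r.start, r.end): r.fp_class for r in tiny_sim.truth.fp_regions}
        got = {(r.chrom, r.start, r.end): r.fp_class for r in fp}
        assert got == truth

    def test_direction_labels_follow_class(self, tiny_sim):
        cohort = segment_cohort(tiny_sim.calls, tiny_sim.samples, tiny_sim.probes)
        _, _, fp = gender_screen(cohort, tiny_sim.samples)
        for r in fp:
            if r.fp_class == "Y-like":
                assert r.direction == "loss_in_female"
            else:
                assert r.direction == "gain_in_female"

    def test_cohort_without_artifacts_yields_nothing(self):
        from dataclasses import replace

        cfg = replace(tiny_config(3), planted_fp=(), planted_diff=None)
        sim = simulate_cohort(cfg)
        cohort = segment_cohort(sim.calls, sim.samples, sim.probes)
        _, _, fp = gender_screen(cohort, sim.samples)
        assert fp == []

    def test_missing_sex_group_rejected(self):
        segs = [Segment("g0", "chr1", 1, 100)]
        m = StateMatrix(["A", "B"], segs, np.full((2, 1), 2, dtype=np.int8))
        fst = fst_scan(m, ["A"], ["B"])
        freqs = segment_frequencies(m, {"high": ["A"], "low": ["B"]})
        with pytest.raises(ValueError, match="female"):
            screen_fp_cnvrs(fst, freqs, segs)


def fake_fst(sid, value):
    return FstResult(sid, value, (1, 0, 0, 0, 0, 0), (1, 0, 0, 0, 0, 0), 10, 10, 0.5, 0.0, (1, 0, 0, 0, 0, 0))


class TestBreedDifferential:
    def segs(self, n):
        return [Segment(f"s{i}", "chr1", 1000 * i + 1, 1000 * i + 500) for i in range(n)]

    def test_planted_tail_selected_by_quantile(self):
        rng = np.random.default_rng(0)
        neutral = [fake_fst(f"s{i}", v) for i, v in enumerate(rng.uniform(0, 0.05, 1000))]
        planted = [fake_fst(f"s{i}", 0.5) for i in range(1000, 1006)]
        res = breed_differential(neutral + planted, self.segs(1006))
        assert {f"s{i}" for i in range(1000, 1006)} <= res.segment_ids
        # nearest-rank 99.5% quantile of 1006 values -> rank 1001
        assert res.cutoff == sorted(r.fst for r in neutral + planted)[1000]

    def test_fixed_cutoff_override(self):
        results = [fake_fst("s0", 0.139), fake_fst("s1", 0.14), fake_fst("s2", 0.9)]
        res = breed_differential(results, self.segs(3), ScreenConfig(breed_fst_min=0.14))
        assert res.segment_ids == {"s1", "s2"}
        assert res.cutoff == 0.14

    def test_all_zero_scan_selects_nothing(self):
        results = [fake_fst(f"s{i}", 0.0) for i in range(10)]
        res = breed_differential(results, self.segs(10))
        assert res.segment_ids == frozenset() and res.cnvrs == ()

    def test_fp_intersection_flagged(self, tiny_sim):
        cohort = segment_cohort(tiny_sim.calls, tiny_sim.samples, tiny_sim.probes)
        _, _, fp = gender_screen(cohort, tiny_sim.samples)
        pops = population_groups(tiny_sim.samples)
        res = breed_differential(
            fst_scan(cohort.matrix, pops["NEL"], pops["TAU"]),
            list(cohort.segments),
            fp_cnvrs=fp,
        )
        d = tiny_sim.truth.diff_region
        hits = [r for r in res.cnvrs if r.chrom == d.chrom and r.start <= d.end and d.start <= r.end]
        assert hits and not any(
            flag for r, flag in zip(res.cnvrs, res.fp_overlap) if r in hits
        )


class TestCommonCnvrs:
    def test_shared_polymorphism_retained(self, tiny_sim):
        cohort = segment_cohort(tiny_sim.calls, tiny_sim.samples, tiny_sim.probes)
        pops = population_groups(tiny_sim.samples)
        freqs = segment_frequencies(cohort.matrix, pops)
        res = common_cnvrs(freqs, list(cohort.segments), min_freq=0.05)
        d = tiny_sim.truth.diff_region
        # the planted deletion is frequent in both populations (0.73 / 0.055)
        assert any(r.chrom == d.chrom and r.start <= d.end and d.start <= r.end for r in res.cnvrs)

    def test_needs_two_populations(self):
        from cnvscreen.segments import GroupFrequency, SegmentFrequency

        one_group = [SegmentFrequency("s0", {"A": GroupFrequency(5, 0.2, 0.2, 0.0, (0, 0.2, 0.8, 0, 0, 0))})]
        with pytest.raises(ValueError, match="two populations"):
            common_cnvrs(one_group, [Segment("s0", "chr1", 1, 10)])
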