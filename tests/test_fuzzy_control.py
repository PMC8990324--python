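"""Mamdani controller tests: membership, inference, defuzzification."""

import numpy as np
import pytest

from valenceloop import fuzzy_control as fc
from valenceloop.errors import CalibrationError

from _oracles import centroid_riemann


@pytest.fixture
def simple_mfs():
    return {
        "LowValence": fc.MembershipFunction("trapezoid", (-2, -2, -1, 0.5),
                                            "LowValence"),
        "HighValence": fc.MembershipFunction("trapezoid", (-0.5, 1, 2, 2),
                                             "HighValence"),
    }


@pytest.fixture
def inhibitory(simple_mfs):
    return fc.make_controller("inhibitory", simple_mfs, (-2.0, 2.0))


@pytest.fixture
def excitatory(simple_mfs):
    return fc.make_controller("excitatory", simple_mfs, (-2.0, 2.0))


class TestSmoothInput:
    def test_constant_history(self):
        assert fc.smooth_input(np.full(50, 1.3)) == pytest.approx(1.3)

    def test_short_history_uses_what_exists(self):
        assert fc.smooth_input([2.0, 4.0]) == pytest.approx(3.0)

    def test_step_input_settles_after_window(self):
        h = np.concatenate([np.zeros(30), np.ones(25)])
        # 20-bin window: exactly 20 bins after the step the mean is 1
        vals = [fc.smooth_input(h[:i + 1]) for i in range(len(h))]
        assert vals[49] == pytest.approx(1.0)
        assert vals[48] < 1.0


class TestFuzzify:
    def test_plateau_degree_one(self, simple_mfs):
        d = fc.fuzzify(-1.5, simple_mfs)
        assert d["LowValence"] == 1.0
        assert d["HighValence"] == 0.0

    def test_symmetric_crossover(self):
        mfs = {
            "LowValence": fc.MembershipFunction("trapezoid",
                                                (-2, -2, -1, 1)),
            "HighValence": fc.MembershipFunction("trapezoid",
                                                 (-1, 1, 2, 2)),
        }
        d = fc.fuzzify(0.0, mfs)
        assert d["LowValence"] == pytest.approx(0.5)
        assert d["HighValence"] == pytest.approx(0.5)

    def test_matches_dense_piecewise_linear_oracle(self, simple_mfs):
        v = np.linspace(-3, 3, 1201)
        mf = simple_mfs["LowValence"]
        a, b, c, d = mf.breakpoints
        expected = np.where(v < b, 0.0,
                            np.where(v <= c, 1.0,
                                     np.clip((d - v) / (d - c), 0, 1)))
        assert np.allclose(mf(v), expected)

    def test_clamped_to_universe(self, simple_mfs):
        d = fc.fuzzify(-99.0, simple_mfs, universe_in=(-2.0, 2.0))
        assert d["LowValence"] == 1.0


class TestInfer:
    def test_single_rule_clips_output(self, inhibitory):
        agg = fc.infer({"HighValence": 0.6, "LowValence": 0.0}, inhibitory)
        mu = inhibitory.output_mfs["Inhibition"](inhibitory.out_grid)
        assert np.array_equal(agg, np.minimum(mu, 0.6))

    def test_no_active_rule_gives_zero(self, inhibitory):
        agg = fc.infer({"HighValence": 0.0, "LowValence": 0.0}, inhibitory)
        assert np.all(agg == 0)

    def test_two_rules_equal_brute_force_max_min(self, inhibitory, rng):
        grid = inhibitory.out_grid
        for _ in range(10):
            d_lv, d_hv = rng.random(2)
            agg = fc.infer({"LowValence": d_lv, "HighValence": d_hv},
                           inhibitory)
            brute = np.maximum(
                np.minimum(inhibitory.output_mfs["Neutral"](grid), d_lv),
                np.minimum(inhibitory.output_mfs["Inhibition"](grid), d_hv))
            assert np.array_equal(agg, brute)


class TestDefuzzify:
    def test_symmetric_triangle_centroid(self):
        grid = np.linspace(-1, 1, 20001)
        tri = fc.MembershipFunction("triangle", (0.1, 0.3, 0.5))
        assert fc.defuzzify_centroid(grid, tri(grid)) \
            == pytest.approx(0.3, abs=1e-9)

    def test_clipped_symmetric_trapezoid_keeps_center(self):
        grid = np.linspace(-1, 1, 20001)
        trap = fc.MembershipFunction("trapezoid", (-0.6, -0.4, 0.0, 0.2))
        c = (-0.6 + -0.4 + 0.0 + 0.2) / 4  # symmetric about -0.2
        for h in (0.25, 0.5, 1.0):
            mu = np.minimum(trap(grid), h)
            assert fc.defuzzify_centroid(grid, mu) \
                == pytest.approx(c, abs=1e-9)

    def test_zero_area_returns_zero(self):
        grid = np.linspace(-1, 1, 101)
        assert fc.defuzzify_centroid(grid, np.zeros(101)) == 0.0

    def test_random_aggregates_match_fine_quadrature(self, rng):
        u_max = 0.1
        grid = np.linspace(-u_max, u_max, fc.OUTPUT_GRID_POINTS)
        mfs = fc.default_output_mfs(u_max)
        for _ in range(25):
            d1, d2, d3 = rng.random(3)

            def agg(x):
                return np.maximum.reduce([
                    np.minimum(mfs["Neutral"](x), d1),
                    np.minimum(mfs["Inhibition"](x), d2),
                    np.minimum(mfs["Excitation"](x), d3)])

            u = fc.defuzzify_centroid(grid, agg(grid))
            ref = centroid_riemann(agg, -u_max, u_max)
            assert abs(u - ref) <= 1e-6 * u_max


class TestControlStep:
    def test_warmup_suspends_controller(self, inhibitory):
        assert fc.control_step([5.0], inhibitory, t_s=30.0) == 0.0

    def test_inhibitory_neutral_in_low_valence(self, inhibitory):
        u = fc.control_step(np.full(30, -1.8), inhibitory, t_s=120.0)
        assert u == pytest.approx(0.0, abs=1e-12)

    def test_excitatory_pushes_up_in_low_valence(self, excitatory):
        u = fc.control_step(np.full(30, -1.8), excitatory, t_s=120.0)
        assert u > 0.0

    def test_sign_constraints_over_dense_sweep(self, inhibitory,
                                               excitatory):
        for v in np.linspace(-2.5, 2.5, 201):
            ui = fc.control_step(np.full(25, v), inhibitory, t_s=120.0)
            ue = fc.control_step(np.full(25, v), excitatory, t_s=120.0)
            assert -inhibitory.u_max <= ui <= 0.0
            assert 0.0 <= ue <= excitatory.u_max

    def test_output_continuous_and_monotone(self, inhibitory):
        vs = np.linspace(-2.5, 2.5, 2001)
        us = np.array([fc.control_step([v], inhibitory, t_s=120.0)
                       for v in vs])
        # corrective magnitude grows as v moves into the targeted class
        assert np.all(np.diff(us) <= 1e-12)
        # continuity: no step larger than the sweep resolution implies
        assert np.max(np.abs(np.diff(us))) < 0.01 * inhibitory.u_max


class TestCalibration:
    def test_separated_classes_give_ordered_breakpoints(self, rng):
        lv = rng.normal(-1.0, 0.2, 400)
        hv = rng.normal(1.0, 0.2, 400)
        x = np.concatenate([lv, hv])
        labels = np.array(["LV"] * 400 + ["HV"] * 400)
        mfs, (lo, hi) = fc.calibrate_mfs(x, labels)
        low, high = mfs["LowValence"], mfs["HighValence"]
        assert low.breakpoints[2] == pytest.approx(np.median(lv), abs=1e-9)
        # HighValence only begins above everything seen during LV
        assert high.breakpoints[0] > lv.max()
        assert lo < 0 < hi

    def test_shift_equivariance(self, rng):
        x = np.concatenate([rng.normal(-1, 0.2, 300),
                            rng.normal(1, 0.2, 300)])
        labels = np.array(["LV"] * 300 + ["HV"] * 300)
        mfs1, uni1 = fc.calibrate_mfs(x, labels)
        mfs2, uni2 = fc.calibrate_mfs(x + 5.0, labels)
        for name in ("LowValence", "HighValence"):
            assert np.allclose(np.array(mfs2[name].breakpoints),
                               np.array(mfs1[name].breakpoints) + 5.0)
        assert np.allclose(np.array(uni2), np.array(uni1) + 5.0)

    def test_degenerate_contrast_raises(self):
        x = np.zeros(100)
        labels = np.array(["LV"] * 50 + ["HV"] * 50)
        with pytest.raises(CalibrationError):
            fc.calibrate_mfs(x, labels)
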