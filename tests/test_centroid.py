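"""Strip/curve centroid math and the Centroid Index."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from phagecentroid import (
    AlignmentError,
    DegenerateControlError,
    DegenerateStripError,
    GrowthCurve,
    centroid_index,
    centroid_oracle_dense,
    curve_centroid,
    random_piecewise_curve,
    strip_area,
    strip_centroid,
)


def closed_form_strip_ybar(y0, y1):
    """Height of a trapezoid centroid: (y0^2 + y0 y1 + y1^2) / (3 (y0 + y1)).

    Algebraically identical to the implementation's expression; used as an
    independent cross-check.
    """
    return (y0 * y0 + y0 * y1 + y1 * y1) / (3.0 * (y0 + y1))


class TestStripArea:
    @pytest.mark.parametrize(
        "x0,x1,y0,y1,expect",
        [
            (0, 1, 2, 4, 3.0),          # generic trapezoid
            (0, 1, 0, 0, 0.0),          # zero strip
            (2, 2.25, 0.4, 0.4, 0.1),   # 15-min rectangle
        ],
    )
    def test_examples(self, x0, x1, y0, y1, expect):
        assert strip_area(x0, x1, y0, y1) == pytest.approx(expect, abs=1e-15)

    @pytest.mark.parametrize("args", [(1, 1, 0.2, 0.3), (2, 1, 0.2, 0.3)])
    def test_nonincreasing_x_rejected(self, args):
        with pytest.raises(ValueError):
            strip_area(*args)

    def test_negative_od_rejected(self):
        with pytest.raises(ValueError):
            strip_area(0, 1, -0.1, 0.3)


class TestStripCentroid:
    def test_rectangle_centroid_at_midpoint_half_height(self):
        x, y = strip_centroid(0, 1, 0.5, 0.5)
        assert (x, y) == pytest.approx((0.5, 0.25))

    def test_right_triangle_centroid(self):
        # rising from 0: centroid at 2/3 of the base, 1/3 of the height
        x, y = strip_centroid(0, 1, 0, 0.9)
        assert (x, y) == pytest.approx((2.0 / 3.0, 0.3))

    def test_generic_trapezoid_matches_dense_oracle(self):
        # frozen from the dense-integration oracle for the single strip
        # (0,2)-(1,4): a 2-point curve is one strip
        x, y = strip_centroid(0, 1, 2, 4)
        assert (x, y) == pytest.approx((5.0 / 9.0, 14.0 / 9.0), rel=1e-12)
        oracle = centroid_oracle_dense(GrowthCurve("s", [0.0, 1.0], [2.0, 4.0]), 2000)
        assert (x, y) == pytest.approx((oracle.x_bar, oracle.y_bar), rel=1e-5)

    @given(
        y0=st.floats(0, 5, allow_nan=False),
        y1=st.floats(0, 5, allow_nan=False),
        w=st.floats(0.01, 10, allow_nan=False),
        x0=st.floats(-5, 50, allow_nan=False),
    )
    def test_matches_symmetric_closed_form(self, y0, y1, w, x0):
        if y0 + y1 == 0:
            with pytest.raises(DegenerateStripError):
                strip_centroid(x0, x0 + w, y0, y1)
            return
        xb, yb = strip_centroid(x0, x0 + w, y0, y1)
        assert yb == pytest.approx(closed_form_strip_ybar(y0, y1), rel=1e-12, abs=1e-15)
        assert x0 <= xb <= x0 + w

    def test_degenerate_strip_signals(self):
        with pytest.raises(DegenerateStripError):
            strip_centroid(0, 1, 0, 0)


class TestCurveCentroid:
    def test_rectangle(self):
        c = curve_centroid(GrowthCurve("r", np.arange(4.0), np.full(4, 0.4)))
        assert (c.x_bar, c.y_bar, c.area) == pytest.approx((1.5, 0.2, 1.2))

    def test_single_triangle(self):
        c = curve_centroid(GrowthCurve("t", [0.0, 2.0], [0.0, 0.6]))
        assert (c.x_bar, c.y_bar, c.area) == pytest.approx((4.0 / 3.0, 0.2, 0.6))

    def test_zero_area_flagged_undefined(self):
        c = curve_centroid(GrowthCurve("z", np.arange(5.0), np.zeros(5)))
        assert not c.defined
        assert c.area == 0.0
        assert np.isnan(c.x_bar) and np.isnan(c.y_bar)

    def test_degenerate_strips_excluded_not_fatal(self):
        # leading flat-zero section contributes no strips
        c = curve_centroid(GrowthCurve("d", np.arange(5.0), [0, 0, 0, 1, 1.0]))
        ref = centroid_oracle_dense(GrowthCurve("d", np.arange(5.0), [0, 0, 0, 1, 1.0]), 2000)
        assert (c.x_bar, c.y_bar, c.area) == pytest.approx(
            (ref.x_bar, ref.y_bar, ref.area), rel=1e-5
        )

    def test_negative_ods_rejected(self):
        with pytest.raises(ValueError):
            curve_centroid(GrowthCurve("n", [0.0, 1.0], [-0.1, 0.2]))

    def test_matches_dense_oracle_on_mixed_curve(self, rng):
        curve = GrowthCurve("m", np.linspace(0, 10, 6), [0.1, 0.8, 0.3, 0.0, 0.5, 0.2])
        exact = curve_centroid(curve)
        dense = centroid_oracle_dense(curve, 1000)
        assert exact.x_bar == pytest.approx(dense.x_bar, rel=1e-6)
        assert exact.y_bar == pytest.approx(dense.y_bar, rel=1e-6)
        assert exact.area == pytest.approx(dense.area, rel=1e-9)

    def test_oracle_error_shrinks_quadratically(self, rng):
        curve = random_piecewise_curve(np.linspace(0, 24, 30), rng)
        exact = curve_centroid(curve)
        errs = []
        for m in (10, 100):
            dense = centroid_oracle_dense(curve, m)
            errs.append(abs(dense.x_bar - exact.x_bar) + abs(dense.y_bar - exact.y_bar))
        # refinement x10 should cut the error by ~100; allow a loose factor
        assert errs[1] < errs[0] / 30

    def test_bounds(self, rng, grid96):
        for _ in range(20):
            curve = random_piecewise_curve(grid96, rng)
            c = curve_centroid(curve)
            assert curve.times[0] <= c.x_bar <= curve.times[-1]
            assert 0.0 <= c.y_bar <= curve.ods.max()


class TestCentroidIndex:
    def test_identical_curves_score_zero(self, flat_control):
        assert centroid_index(flat_control, flat_control).ci == 0.0

    def test_complete_suppression_scores_one(self, flat_control):
        dead = flat_control.with_ods(np.zeros(4), "dead")
        res = centroid_index(dead, flat_control)
        assert res.ci == 1.0
        assert not res.treated_centroid.defined

    def test_half_height_scores_half(self, flat_control):
        half = flat_control.with_ods(np.full(4, 0.2), "half")
        assert centroid_index(half, flat_control).ci == pytest.approx(0.5)

    def test_negative_when_treated_outgrows_control(self, flat_control):
        worse = flat_control.with_ods(np.full(4, 0.8), "worse")
        res = centroid_index(worse, flat_control)
        assert res.ci < 0.0
        assert res.treated_centroid.product > res.control_centroid.product

    def test_zero_area_control_rejected(self, flat_control):
        dead = flat_control.with_ods(np.zeros(4), "dead")
        with pytest.raises(DegenerateControlError):
            centroid_index(flat_control, dead)

    def test_zero_xbar_control_rejected(self):
        # single nonzero strip at t=0 with rezeroed time -> x_bar can be 0
        ctrl = GrowthCurve("c", [0.0, 1.0, 2.0], [0.3, 0.0, 0.0])
        # x_bar > 0 here (strip centroid inside (0,1)); shift grid to force
        # the degenerate product instead via a zero y_bar: not constructible
        # with nonneg ODs, so only area-zero controls are degenerate in
        # practice -- assert the guard path via the zero-area case.
        dead = ctrl.with_ods(np.zeros(3), "dead")
        with pytest.raises(DegenerateControlError):
            centroid_index(ctrl, dead)

    def test_mismatched_grids_rejected(self, flat_control):
        other = GrowthCurve("o", np.arange(4.0) + 0.5, np.full(4, 0.3))
        with pytest.raises(AlignmentError):
            centroid_index(other, flat_control)

    def test_common_scaling_invariance(self, rng, grid96):
        ctrl = random_piecewise_curve(grid96, rng, sample_id="c")
        trt = random_piecewise_curve(grid96, rng, sample_id="t")
        base = centroid_index(trt, ctrl).ci
        for k in (0.1, 3.0, 42.0):
            scaled = centroid_index(trt.with_ods(trt.ods * k), ctrl.with_ods(ctrl.ods * k))
            assert abs(scaled.ci - base) <= 1e-12

    def test_suppression_monotonicity(self, rng, grid96):
        ctrl = random_piecewise_curve(grid96, rng, sample_id="c")
        trt = random_piecewise_curve(grid96, rng, sample_id="t")
        scales = [1.0, 0.7, 0.4, 0.1]
        cis = [centroid_index(trt.with_ods(trt.ods * k), ctrl).ci for k in scales]
        # more suppression (smaller k) -> strictly higher CI
        assert all(a < b for a, b in zip(cis, cis[1:]))

    def test_upper_bound_and_sign_rule(self, rng, grid96):
        for _ in range(200):
            ctrl = random_piecewise_curve(grid96, rng, sample_id="c")
            trt = random_piecewise_curve(grid96, rng, sample_id="t")
            cc = curve_centroid(ctrl)
            if not (cc.defined and cc.product > 0):
                continue
            res = centroid_index(trt, ctrl)
            assert res.ci <= 1.0
            if res.treated_centroid.defined:
                assert (res.ci < 0) == (res.treated_centroid.product > cc.product)
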