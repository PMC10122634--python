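"""Contract tests for the passive fibre and tendon force-length curves."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

from mtufit.curves import (
    CurveParameterError,
    FibreCurveParams,
    TendonCurveParams,
    derived_stiffnesses,
    fibre_passive_force,
    make_fibre_curve,
    make_tendon_curve,
    tendon_force,
)

from conftest import draw_admissible_fibre, draw_admissible_tendon


fibre_params = st.builds(
    lambda e0, gap, klow, c: FibreCurveParams(
        eps_zero_f=e0,
        eps_one_f=max(0.5, e0 + gap),
        k_low_scale=klow,
        curviness_f=c,
    ),
    e0=st.floats(-0.5, 0.45),
    gap=st.floats(0.05, 1.0),
    klow=st.floats(0.01, 0.99),
    c=st.floats(0.0, 1.0),
)

tendon_params = st.builds(
    TendonCurveParams,
    eps_one_t=st.floats(0.01, 5.0),
    f_toe_t=st.floats(0.01, 0.99),
    curviness_t=st.floats(0.0, 1.0),
)


class TestAnchors:
    def test_fibre_zero_force_anchor_at_engagement(self):
        p = FibreCurveParams()
        assert fibre_passive_force(1.0 + p.eps_zero_f, p) == pytest.approx(0.0, abs=1e-12)

    def test_fibre_reaches_max_force_at_one_norm_strain(self):
        # with defaults the fibre develops F_max at normalised length 1.70
        assert fibre_passive_force(1.70, FibreCurveParams()) == pytest.approx(1.0, abs=1e-12)

    def test_tendon_slack_and_max_force_anchors(self):
        p = TendonCurveParams()
        assert tendon_force(1.0, p) == pytest.approx(0.0, abs=1e-12)
        assert tendon_force(1.049, p) == pytest.approx(1.0, abs=1e-12)
        assert tendon_force(1.0 + p.eps_toe_t, p) == pytest.approx(p.f_toe_t, abs=1e-9)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(p=fibre_params)
    def test_fibre_anchors_for_any_admissible_params(self, p):
        c = make_fibre_curve(p)
        assert c.value(1.0 + p.eps_zero_f) == pytest.approx(0.0, abs=1e-9)
        assert c.value(1.0 + p.eps_one_f) == pytest.approx(1.0, abs=1e-9)
        # zero below engagement
        assert c.value(1.0 + p.eps_zero_f - 0.2) == 0.0

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(p=tendon_params)
    def test_tendon_anchors_for_any_admissible_params(self, p):
        c = make_tendon_curve(p)
        assert c.value(1.0) == pytest.approx(0.0, abs=1e-9)
        assert c.value(1.0 + p.eps_one_t) == pytest.approx(1.0, abs=1e-9)
        assert c.value(0.95) == 0.0


class TestShape:
    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(p=fibre_params)
    def test_fibre_monotone_non_decreasing(self, p):
        c = make_fibre_curve(p)
        x = np.linspace(0.5, 2.0 + p.eps_one_f, 10_000)
        assert np.all(np.diff(c.value(x)) >= -1e-12)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(p=tendon_params)
    def test_tendon_monotone_non_decreasing(self, p):
        c = make_tendon_curve(p)
        x = np.linspace(0.9, 1.5 + p.eps_one_t, 10_000)
        assert np.all(np.diff(c.value(x)) >= -1e-12)

    def test_linear_extrapolation_beyond_one_norm_force(self):
        fp, tp = FibreCurveParams(), TendonCurveParams()
        fc, tc = make_fibre_curve(fp), make_tendon_curve(tp)
        for c, x1, k in ((fc, 1.70, fp.k_one_f), (tc, 1.049, tp.k_one_t)):
            d = 0.05
            assert c.value(x1 + d) == pytest.approx(1.0 + k * d, rel=1e-12)
            assert c.derivative(x1 + d) == pytest.approx(k, rel=1e-12)

    def test_end_slope_matches_finite_difference_as_step_shrinks(self):
        fp = FibreCurveParams()
        c = make_fibre_curve(fp)
        x1 = 1.0 + fp.eps_one_f
        errs = []
        for hstep in (1e-3, 1e-4, 1e-5):
            fd = (c.value(x1) - c.value(x1 - hstep)) / hstep
            errs.append(abs(fd - fp.k_one_f))
        assert errs[0] > errs[-1]
        assert errs[-1] < 1e-3

    def test_c1_continuity_at_segment_joins(self):
        """Derivative is continuous across every internal breakpoint."""
        for p, make in (
            (FibreCurveParams(), make_fibre_curve),
            (TendonCurveParams(), make_tendon_curve),
        ):
            c = make(p)
            for xb in c._breaks:
                left = c.derivative(xb - 1e-9)
                right = c.derivative(xb + 1e-9)
                assert right == pytest.approx(left, abs=1e-5)

    def test_slope_near_engagement_reaches_low_force_stiffness(self):
        """The slope rises from 0 at engagement to ~K_low just after it."""
        p = FibreCurveParams()
        c = make_fibre_curve(p)
        x0 = 1.0 + p.eps_zero_f
        assert c.derivative(x0) == pytest.approx(0.0, abs=1e-9)
        x_low = c._breaks[1]  # end of the run-in span
        assert c.derivative(x_low) == pytest.approx(p.k_low_f, rel=1e-9)


class TestOracles:
    def test_fibre_value_against_de_casteljau_parametric_oracle(self):
        """Power-basis + Newton inversion agrees with direct de Casteljau
        evaluation of the same control polygon on a dense parameter grid."""
        p = FibreCurveParams()
        c = make_fibre_curve(p)

        def de_casteljau(ctrl, u):
            pts = np.array(ctrl, float)
            for _ in range(len(pts) - 1):
                pts = pts[:-1] + u * (pts[1:] - pts[:-1])
            return pts[0]

        for seg in c.segments:
            # recover control points from power coefficients via sampling
            u = np.linspace(0, 1, 2001)
            xs = np.array([de_casteljau(np.linalg.solve(
                np.array([[__import__("math").comb(5, i) * t**i * (1 - t)**(5 - i)
                           for i in range(6)] for t in np.linspace(0, 1, 6)]),
                [np.polynomial.polynomial.polyval(t, seg.ax)
                 for t in np.linspace(0, 1, 6)]), ui) for ui in u])
            ys = np.array([de_casteljau(np.linalg.solve(
                np.array([[__import__("math").comb(5, i) * t**i * (1 - t)**(5 - i)
                           for i in range(6)] for t in np.linspace(0, 1, 6)]),
                [np.polynomial.polynomial.polyval(t, seg.ay)
                 for t in np.linspace(0, 1, 6)]), ui) for ui in u])
            # oracle: linear interpolation of the dense parametric samples
            for x in np.linspace(seg.x0, seg.x1, 7)[1:-1]:
                y_oracle = np.interp(x, xs, ys)
                assert c.value(x) == pytest.approx(y_oracle, abs=5e-7)

    def test_fibre_value_and_slope_at_midrange_point(self):
        """Value and finite-difference slope agree with a dense-grid scan of
        the same construction at normalised length 1.35."""
        p = FibreCurveParams()
        c = make_fibre_curve(p)
        x = np.linspace(1.349, 1.351, 20001)
        y = c.value(x)
        mid = 10000
        assert c.value(1.35) == pytest.approx(y[mid], abs=1e-12)
        fd = (y[mid + 1] - y[mid - 1]) / (x[mid + 1] - x[mid - 1])
        assert c.derivative(1.35) == pytest.approx(fd, rel=1e-6)

    def test_tendon_inverse_query_via_bisection_oracle(self):
        p = TendonCurveParams()
        c = make_tendon_curve(p)
        length = brentq(lambda x: c.value(x) - 0.5, 1.0, 1.0 + p.eps_one_t, xtol=1e-14)
        assert c.value(length) == pytest.approx(0.5, abs=1e-10)

    def test_fast_value_matches_exact_evaluation(self, rng):
        for _ in range(10):
            fp = FibreCurveParams(**draw_admissible_fibre(rng))
            tp = TendonCurveParams(**draw_admissible_tendon(rng))
            for c, lo, hi in (
                (make_fibre_curve(fp), 0.8, 2.2 + fp.eps_one_f),
                (make_tendon_curve(tp), 0.95, 1.4 + tp.eps_one_t),
            ):
                x = rng.uniform(lo, hi, 500)
                assert np.max(np.abs(c.fast_value(x) - c.value(x))) < 1e-7

    def test_integral_matches_trapezoid(self):
        c = make_fibre_curve(FibreCurveParams())
        x = np.linspace(1.0, 1.9, 200_001)
        assert c.integral(1.9) == pytest.approx(np.trapezoid(c.value(x), x), rel=1e-6)


class TestDependentParameters:
    def test_formulas(self):
        fp = FibreCurveParams(eps_zero_f=0.0, eps_one_f=1.0, k_low_scale=0.5)
        tp = TendonCurveParams()
        k_low, k_one, k_one_t = derived_stiffnesses(fp, tp)
        assert k_low == pytest.approx(0.5)
        assert k_one == pytest.approx(2.0)
        assert k_one_t == pytest.approx(1.375 / 0.049)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(p=fibre_params)
    def test_one_norm_stiffness_always_exceeds_low_force_stiffness(self, p):
        assert p.k_one_f > p.k_low_f


class TestValidation:
    def test_strain_order_violation_rejected(self):
        with pytest.raises(CurveParameterError):
            FibreCurveParams(eps_zero_f=0.8, eps_one_f=0.7)

    def test_nonpositive_tendon_strain_rejected(self):
        with pytest.raises(CurveParameterError):
            TendonCurveParams(eps_one_t=0.0)

    @pytest.mark.parametrize(
        "kwargs",
        [dict(k_low_scale=0.0), dict(k_low_scale=1.0), dict(curviness_f=1.2)],
    )
    def test_fibre_shape_factors_out_of_range_rejected(self, kwargs):
        with pytest.raises(CurveParameterError):
            FibreCurveParams(**kwargs)

    @pytest.mark.parametrize("kwargs", [dict(f_toe_t=1.0), dict(curviness_t=-0.1)])
    def test_tendon_shape_factors_out_of_range_rejected(self, kwargs):
        with pytest.raises(CurveParameterError):
            TendonCurveParams(**kwargs)
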