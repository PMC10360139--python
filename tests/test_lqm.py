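"""Unit and property tests for the LQ survival-curve core."""

import math

import numpy as np
import pytest
from hypothesis import given, settings as hyp_settings, strategies as st
from scipy import optimize

from rbekit.lqm import (
    DegenerateCurveError,
    LQParams,
    curve_l2_distance,
    dose_for_sf,
    fit_lq,
    mean_inactivation_dose,
    propagate_endpoint_error,
    rbe_at_dose,
    rbe_at_iso_survival,
    surviving_fraction,
)


class TestSurvivingFraction:
    @pytest.mark.parametrize(
        "alpha, beta, dose, expected",
        [
            (1.0, 0.0, 0.0, 1.0),
            (0.5, 0.0, math.log(10) / 0.5, 0.1),
            (0.2, 0.05, 2.0, math.exp(-0.6)),
        ],
    )
    def test_values(self, alpha, beta, dose, expected):
        assert surviving_fraction(LQParams(alpha, beta), dose) == pytest.approx(
            expected, rel=1e-12
        )

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError):
            surviving_fraction(LQParams(0.5, 0.0), -1.0)


class TestDoseForSf:
    @pytest.mark.parametrize(
        "alpha, beta, sf, expected",
        [
            (0.5, 0.0, 0.1, math.log(10) / 0.5),
            (0.0, 0.25, math.exp(-1), 2.0),
        ],
    )
    def test_closed_forms(self, alpha, beta, sf, expected):
        assert dose_for_sf(LQParams(alpha, beta), sf) == pytest.approx(expected, rel=1e-12)

    def test_quadratic_root_resubstitutes(self):
        p = LQParams(0.3, 0.03)
        d = dose_for_sf(p, 0.37)
        assert 0.03 * d * d + 0.3 * d + math.log(0.37) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("sf", [0.0, 1.0, 1.5, -0.2])
    def test_invalid_sf(self, sf):
        with pytest.raises(ValueError):
            dose_for_sf(LQParams(0.5, 0.0), sf)

    def test_degenerate_curve(self):
        with pytest.raises(DegenerateCurveError):
            dose_for_sf(LQParams(0.0, 0.0), 0.5)

    @given(
        alpha=st.floats(0.0, 2.0),
        beta=st.floats(0.0, 0.2),
        sf=st.floats(0.01, 0.99),
    )
    @hyp_settings(max_examples=200, derandomize=True)
    def test_roundtrip(self, alpha, beta, sf):
        if alpha + beta == 0.0:
            return
        p = LQParams(alpha, beta)
        assert surviving_fraction(p, dose_for_sf(p, sf)) == pytest.approx(sf, rel=1e-10)


class TestMeanInactivationDose:
    @pytest.mark.parametrize(
        "alpha, beta, expected",
        [
            (1.0, 0.0, 1.0),
            (0.0, 1.0, math.sqrt(math.pi) / 2.0),
        ],
    )
    def test_closed_forms(self, alpha, beta, expected):
        assert mean_inactivation_dose(LQParams(alpha, beta)) == pytest.approx(
            expected, rel=1e-12
        )

    def test_beta_to_zero_limit_continuous(self):
        ref = mean_inactivation_dose(LQParams(1.0, 0.0))
        near = mean_inactivation_dose(LQParams(1.0, 1e-10))
        assert near == pytest.approx(ref, rel=1e-4)

    @pytest.mark.parametrize(
        "alpha, beta", [(0.2, 0.05), (1.5, 0.01), (0.0, 0.3), (0.05, 0.15)]
    )
    def test_quadrature_agreement(self, alpha, beta):
        p = LQParams(alpha, beta)
        closed = mean_inactivation_dose(p)
        quad = mean_inactivation_dose(p, method="quadrature")
        assert quad == pytest.approx(closed, rel=1e-8)

    def test_negative_beta_divergent(self):
        with pytest.raises(ValueError):
            mean_inactivation_dose(LQParams(1.0, -0.01))


class TestCurveL2Distance:
    def test_identical_curves_zero(self):
        p = LQParams(0.4, 0.04)
        assert curve_l2_distance(p, p) == 0.0

    def test_analytic_linear_case(self):
        # integral of (e^-D - e^-2D)^2 = 1/2 - 2/3 + 1/4; MID(meas) = 1/2
        expected = math.sqrt(0.5 - 2.0 / 3.0 + 0.25) / 0.5
        got = curve_l2_distance(LQParams(1.0, 0.0), LQParams(2.0, 0.0))
        assert got == pytest.approx(expected, rel=1e-12)

    def test_normalization_asymmetry(self):
        a, b = LQParams(1.0, 0.0), LQParams(2.0, 0.0)
        d_ab, d_ba = curve_l2_distance(a, b), curve_l2_distance(b, a)
        # numerator symmetric, normalization not: ratio equals MID(a)/MID(b)
        assert d_ab != pytest.approx(d_ba)
        assert d_ab / d_ba == pytest.approx(
            mean_inactivation_dose(a) / mean_inactivation_dose(b), rel=1e-10
        )

    def test_negative_beta_rejected(self):
        with pytest.raises(ValueError):
            curve_l2_distance(LQParams(1.0, -0.01), LQParams(1.0, 0.0))


class TestRBE:
    def test_identity_is_one(self):
        p = LQParams(0.3, 0.03)
        assert rbe_at_iso_survival(p, p, 0.1) == pytest.approx(1.0)
        assert rbe_at_dose(p, p, 2.0) == pytest.approx(1.0)

    def test_linear_curves_scale(self):
        photon, proton = LQParams(0.5, 0.0), LQParams(1.0, 0.0)
        assert rbe_at_iso_survival(photon, proton, 0.1) == pytest.approx(2.0)
        assert rbe_at_dose(photon, proton, 2.0) == pytest.approx(2.0)

    def test_rbe_at_dose_quadratic_inversion(self):
        photon, proton = LQParams(0.3, 0.03), LQParams(0.45, 0.03)
        d = 2.0
        target_sf = surviving_fraction(proton, d)
        d_x = optimize.brentq(
            lambda x: surviving_fraction(photon, x) - target_sf, 1e-6, 100.0
        )
        assert rbe_at_dose(photon, proton, d) == pytest.approx(d_x / d, rel=1e-9)

    def test_nonpositive_dose_rejected(self):
        with pytest.raises(ValueError):
            rbe_at_dose(LQParams(0.3, 0.03), LQParams(0.4, 0.03), 0.0)


class TestErrorPropagation:
    def test_zero_cov_zero_stderr(self):
        p = LQParams(0.3, 0.03, cov=np.zeros((2, 2)))
        assert propagate_endpoint_error(p, 0.1) == 0.0

    def test_linear_curve_delta_method(self):
        sigma = 0.05
        p = LQParams(0.5, 0.0, cov=np.array([[sigma**2, 0.0], [0.0, 0.0]]))
        expected = abs(math.log(0.1)) * sigma / 0.5**2
        assert propagate_endpoint_error(p, 0.1) == pytest.approx(expected, rel=1e-10)

    def test_negative_covariance_shrinks_error(self):
        sa, sb = 0.03, 0.006
        base = np.array([[sa**2, 0.0], [0.0, sb**2]])
        neg = np.array([[sa**2, -0.9 * sa * sb], [-0.9 * sa * sb, sb**2]])
        p0 = LQParams(0.3, 0.03, cov=base)
        p1 = LQParams(0.3, 0.03, cov=neg)
        assert propagate_endpoint_error(p1, 0.1) < propagate_endpoint_error(p0, 0.1)

    def test_missing_cov_rejected(self):
        with pytest.raises(ValueError):
            propagate_endpoint_error(LQParams(0.3, 0.03), 0.1)


class TestFitLQ:
    def test_two_points_interpolate(self):
        fit = fit_lq([1.0, 3.0], [-1.0, -3.0])
        assert fit.alpha == pytest.approx(1.0, abs=1e-12)
        assert fit.beta == pytest.approx(0.0, abs=1e-12)

    def test_noiseless_recovery(self):
        alpha, beta = 0.2, 0.05
        doses = np.array([1.0, 2.0, 4.0, 6.0])
        log_sf = -(alpha * doses + beta * doses**2)
        fit = fit_lq(doses, log_sf)
        assert fit.alpha == pytest.approx(alpha, rel=1e-10)
        assert fit.beta == pytest.approx(beta, rel=1e-10)

    def test_constrained_matches_grid_oracle(self):
        # points whose unconstrained solution has beta < 0
        doses = np.array([1.0, 2.0, 4.0, 8.0])
        log_sf = np.array([-0.9, -1.9, -3.6, -6.9])  # sub-linear curvature
        fit = fit_lq(doses, log_sf, constrain_nonneg=True)
        assert fit.beta == 0.0
        alphas = np.linspace(0.0, 2.0, 200001)
        rss = ((alphas[:, None] * doses + log_sf) ** 2).sum(axis=1)
        assert fit.alpha == pytest.approx(alphas[rss.argmin()], abs=1e-4)

    def test_errors(self):
        with pytest.raises(ValueError):
            fit_lq([2.0], [-1.0])
        with pytest.raises(ValueError):
            fit_lq([2.0, 2.0], [-1.0, -1.1])
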