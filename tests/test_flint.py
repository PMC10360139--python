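"""Tests for the six-parameter endpoint-correlation model."""

import math

import numpy as np
import pytest
from scipy import optimize

from rbekit.flint import (
    EndpointFunctionParams,
    EndpointSet,
    FlintModel,
    TABLE_DEFAULT,
    intercept,
    predict_endpoint,
    predict_proton_curve,
    predict_rbe,
    prediction_uncertainty,
    rbe_iso_survival_single_endpoint,
    reconstruct_alpha_beta_general,
    reconstruct_alpha_beta_two_point,
    slope,
)
from rbekit.lqm import LQParams, dose_for_sf, rbe_at_dose, surviving_fraction


class TestSlopeIntercept:
    def test_slope_at_zero_let_is_c(self):
        assert slope(0.0, TABLE_DEFAULT.sf1_params) == pytest.approx(1.041543)

    def test_flat_slope(self):
        p = EndpointFunctionParams(1.0, 0.0, 0.0)
        assert slope(123.0, p) == 1.0

    def test_half_decay_construction(self):
        p = EndpointFunctionParams(2.0, math.log(2.0), 0.0)
        assert slope(1.0, p) == pytest.approx(1.0, rel=1e-12)

    def test_intercept_values(self):
        assert intercept(0.0, TABLE_DEFAULT.sf1_params) == 0.0
        assert intercept(10.0, TABLE_DEFAULT.sf1_params) == pytest.approx(0.2376115)
        p2 = EndpointFunctionParams(1.0, 0.0, 0.0655)
        assert intercept(2.0, p2) == pytest.approx(0.1310)

    def test_predict_endpoint(self):
        assert predict_endpoint(5.0, 0.0, TABLE_DEFAULT.sf1_params) == pytest.approx(
            5.0 * 1.041543
        )
        ident = EndpointFunctionParams(1.0, 0.0, 0.0)
        assert predict_endpoint(1.0, 7.0, ident) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            predict_endpoint(-1.0, 0.0, ident)

    def test_endpoint_dose_decreases_with_let_when_slope_dominates(self):
        # d(pred)/dLET at 0 = -c*f*d_x + p < 0 when d_x > p/(c*f)
        p = TABLE_DEFAULT.sf1_params
        d_x = 2.0 * p.p / (p.c * p.f)
        lo, hi = predict_endpoint(d_x, 0.0, p), predict_endpoint(d_x, 0.5, p)
        assert hi < lo


class TestTwoPointReconstruction:
    def test_linear_case(self):
        lq = reconstruct_alpha_beta_two_point(1.0, 3.0)
        assert lq.alpha == pytest.approx(1.0, abs=1e-12)
        assert lq.beta == pytest.approx(0.0, abs=1e-12)

    def test_pure_quadratic_case(self):
        lq = reconstruct_alpha_beta_two_point(2.0, 2.0 * math.sqrt(3.0))
        assert lq.alpha == pytest.approx(0.0, abs=1e-12)
        assert lq.beta == pytest.approx(0.25, rel=1e-12)

    @pytest.mark.parametrize(
        "alpha, beta", [(0.3, 0.03), (0.1, 0.08), (1.2, 0.001), (0.0, 0.2)]
    )
    def test_interpolation_roundtrip(self, alpha, beta):
        src = LQParams(alpha, beta)
        d1 = dose_for_sf(src, math.exp(-1.0))
        d2 = dose_for_sf(src, math.exp(-3.0))
        lq = reconstruct_alpha_beta_two_point(d1, d2)
        assert lq.alpha == pytest.approx(alpha, abs=1e-9)
        assert lq.beta == pytest.approx(beta, abs=1e-10)

    def test_clamped_branches_pass_nnls_check(self):
        # d2 > 3*d1 forces beta < 0 unconstrained -> beta = 0 branch
        lq = reconstruct_alpha_beta_two_point(1.0, 3.5)
        assert lq.beta == 0.0
        # d2 < sqrt(3)*d1 forces alpha < 0 -> alpha = 0 branch
        lq = reconstruct_alpha_beta_two_point(2.0, 2.8)
        assert lq.alpha == 0.0

    def test_inverted_points_rejected(self):
        with pytest.raises(ValueError):
            reconstruct_alpha_beta_two_point(3.0, 3.0)


class TestGeneralReconstruction:
    def test_noiseless_exact(self):
        src = LQParams(0.2, 0.05)
        eps = [
            (math.exp(-k), dose_for_sf(src, math.exp(-k))) for k in (1.0, 2.0, 3.0)
        ]
        lq = reconstruct_alpha_beta_general(eps)
        assert lq.alpha == pytest.approx(0.2, rel=1e-10)
        assert lq.beta == pytest.approx(0.05, rel=1e-10)

    def test_two_endpoint_specialization(self):
        d1, d2 = 1.7, 4.1
        a = reconstruct_alpha_beta_two_point(d1, d2)
        b = reconstruct_alpha_beta_general(
            [(math.exp(-1.0), d1), (math.exp(-3.0), d2)]
        )
        assert b.alpha == pytest.approx(a.alpha, rel=1e-12, abs=1e-14)
        assert b.beta == pytest.approx(a.beta, rel=1e-12, abs=1e-14)

    def test_constrained_matches_nnls_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            m = rng.integers(2, 6)
            d = np.sort(rng.uniform(0.5, 12.0, size=m))
            if np.unique(d).size < m:
                continue
            logsf = -rng.uniform(0.2, 5.0, size=m)
            lq = reconstruct_alpha_beta_general(list(zip(np.exp(logsf), d)))
            X = np.column_stack([d, d * d])
            theta, _ = optimize.nnls(X, -logsf)
            assert lq.alpha == pytest.approx(theta[0], abs=1e-6)
            assert lq.beta == pytest.approx(theta[1], abs=1e-6)

    def test_brute_force_argmin_property(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            d = np.sort(rng.uniform(0.5, 10.0, size=4))
            logsf = -rng.uniform(0.2, 4.0, size=4)
            lq = reconstruct_alpha_beta_general(list(zip(np.exp(logsf), d)))

            def rss(t):
                return np.sum((t[0] * d + t[1] * d * d + logsf) ** 2)

            res = optimize.minimize(
                rss, [0.3, 0.03], bounds=[(0, None), (0, None)], method="L-BFGS-B"
            )
            assert rss((lq.alpha, lq.beta)) <= res.fun + 1e-9

    def test_errors(self):
        with pytest.raises(ValueError):
            reconstruct_alpha_beta_general([(0.5, 2.0)])
        with pytest.raises(ValueError):
            reconstruct_alpha_beta_general([(0.5, 2.0), (0.3, 2.0)])


class TestCurvePrediction:
    def test_identity_fixed_point(self, photon_curve):
        proton = predict_proton_curve(photon_curve, 9.9, FlintModel.identity())
        assert proton.alpha == pytest.approx(photon_curve.alpha, rel=1e-9)
        assert proton.beta == pytest.approx(photon_curve.beta, rel=1e-9, abs=1e-12)
        assert predict_rbe(photon_curve, 9.9, FlintModel.identity(), dose=2.0) == pytest.approx(1.0)
        assert predict_rbe(photon_curve, 9.9, FlintModel.identity(), sf=0.1) == pytest.approx(1.0)

    def test_zero_let_pure_linear_photon_gains_curvature(self):
        # c1 != c2 at LET 0 maps a linear curve to a genuinely quadratic one
        photon = LQParams(0.5, 0.0)
        proton = predict_proton_curve(photon, 0.0, TABLE_DEFAULT)
        d1p = 1.041543e00 * dose_for_sf(photon, math.exp(-1.0))
        d2p = 1.045578e00 * dose_for_sf(photon, math.exp(-3.0))
        expected = reconstruct_alpha_beta_two_point(d1p, d2p)
        assert proton.alpha == pytest.approx(expected.alpha, rel=1e-12)
        assert proton.beta == pytest.approx(expected.beta, rel=1e-12)

    def test_rbe_monotone_in_let_for_radioresistant_tissue(self):
        photon = LQParams(0.12, 0.03)  # radioresistant: large D values
        rbes = [
            predict_rbe(photon, let, TABLE_DEFAULT, dose=2.0)
            for let in (0.5, 2.0, 5.0, 10.0, 20.0)
        ]
        assert all(b > a for a, b in zip(rbes, rbes[1:]))

    def test_predicted_endpoint_affine_in_photon_endpoint(self):
        # the defining linearity at fixed LET
        let = 5.0
        d_x = np.array([1.0, 2.0, 4.0, 8.0])
        d_p = predict_endpoint(d_x, let, TABLE_DEFAULT.sf1_params)
        slopes = np.diff(d_p) / np.diff(d_x)
        assert np.allclose(slopes, slopes[0], rtol=1e-12)


class TestSingleEndpointRBE:
    def test_high_dose_limit(self):
        p = TABLE_DEFAULT.sf1_params
        let = 10.0
        limit = math.exp(p.f * let) / p.c
        assert rbe_iso_survival_single_endpoint(1e9, let, p) == pytest.approx(
            limit, rel=1e-6
        )

    def test_sub_unity_for_radiosensitive_cells(self):
        p = TABLE_DEFAULT.sf1_params
        let = 10.0
        s = p.c * math.exp(-p.f * let)
        threshold = p.p * let / (1.0 - s) if s < 1.0 else math.inf
        assert rbe_iso_survival_single_endpoint(0.5 * threshold, let, p) < 1.0
        assert rbe_iso_survival_single_endpoint(2.0 * threshold, let, p) > 1.0


class TestPredictionUncertainty:
    def test_zero_cov_zero_stderr(self, photon_curve):
        model = FlintModel(
            TABLE_DEFAULT.sf1_params, TABLE_DEFAULT.sf2_params, cov=np.zeros((6, 6))
        )
        photon = LQParams(photon_curve.alpha, photon_curve.beta, cov=np.zeros((2, 2)))
        se = prediction_uncertainty(photon, 5.0, model, dose=2.0)
        assert se["alpha_p"] == 0.0 and se["beta_p"] == 0.0 and se["rbe"] == 0.0

    def test_matches_parametric_monte_carlo(self, photon_curve):
        photon = LQParams(photon_curve.alpha, photon_curve.beta, cov=np.zeros((2, 2)))
        let = 9.9
        se = prediction_uncertainty(photon, let, TABLE_DEFAULT, dose=2.0)
        rng = np.random.default_rng(12)
        draws = rng.multivariate_normal(
            TABLE_DEFAULT.theta(), TABLE_DEFAULT.cov, size=10_000
        )
        rbes = []
        for th in draws:
            m = FlintModel.from_theta(th)
            proton = predict_proton_curve(photon_curve, let, m)
            rbes.append(rbe_at_dose(photon_curve, proton, 2.0))
        assert se["rbe"] == pytest.approx(np.std(rbes), rel=0.05)

    def test_stderr_grows_with_let(self, photon_curve):
        # model-parameter uncertainty alone: high LET extrapolates further
        photon = LQParams(photon_curve.alpha, photon_curve.beta, cov=np.zeros((2, 2)))
        # below ~5 keV/um parameter correlations partially cancel; beyond
        # that the band widens monotonically with extrapolation distance
        ses = [
            prediction_uncertainty(photon, let, TABLE_DEFAULT, dose=2.0)["rbe"]
            for let in (5.0, 10.0, 15.0, 25.0, 37.8)
        ]
        assert all(b > a for a, b in zip(ses, ses[1:]))

    def test_missing_cov_rejected(self, photon_curve):
        with pytest.raises(ValueError):
            prediction_uncertainty(photon_curve, 5.0, TABLE_DEFAULT, dose=2.0)


class TestModelContainer:
    def test_yaml_roundtrip(self, tmp_path):
        path = tmp_path / "params.yaml"
        TABLE_DEFAULT.to_yaml(path)
        back = FlintModel.from_yaml(path)
        np.testing.assert_allclose(back.theta(), TABLE_DEFAULT.theta())
        np.testing.assert_allclose(back.cov, TABLE_DEFAULT.cov)

    def test_default_cov_symmetric_and_psd(self):
        cov = TABLE_DEFAULT.cov
        assert np.allclose(cov, cov.T)
        assert np.linalg.eigvalsh(cov).min() > 0

    def test_endpoint_set_validation(self):
        p = EndpointFunctionParams(1.0, 0.0, 0.0)
        with pytest.raises(ValueError):
            EndpointSet(entries=((0.5, p),))
        with pytest.raises(ValueError):
            EndpointSet(entries=((0.5, p), (0.5, p)))
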