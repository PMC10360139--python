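"""Linear-quadratic (LQ) survival-curve mathematics.

The LQ model describes clonogenic survival after a single acute dose D as

    SF(D) = exp(-alpha*D - beta*D**2),

with alpha (Gy^-1) the initial log-linear slope and beta (Gy^-2) the
curvature.  Everything in this module is exact closed-form where a closed
form exists: iso-survival doses are roots of a quadratic, the mean
inactivation dose and curve L2 distances are scaled complementary error
functions, and endpoint uncertainties follow from the delta method using
the (alpha, beta) covariance of the fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import integrate, optimize
from scipy.special import erfcx

from .settings import DEFAULT, NumericSettings

__all__ = [
    "LQParams",
    "EndpointValue",
    "DegenerateCurveError",
    "surviving_fraction",
    "dose_for_sf",
    "mean_inactivation_dose",
    "curve_l2_distance",
    "rbe_at_iso_survival",
    "rbe_at_dose",
    "propagate_endpoint_error",
    "fit_lq",
]


class DegenerateCurveError(ValueError):
    """Raised when alpha = beta = 0 (a flat 'survival curve' kills nothing)."""


@dataclass(frozen=True)
class LQParams:
    """Parameters of one LQ survival curve.

    Parameters
    ----------
    alpha:
        Linear coefficient, Gy^-1.
    beta:
        Quadratic coefficient, Gy^-2.
    cov:
        Optional 2x2 symmetric covariance matrix of (alpha, beta), in
        matching units.  Clonogenic fits typically produce strongly
        negative alpha-beta covariance, which is what makes iso-survival
        doses better determined than alpha or beta individually.
    """

    alpha: float
    beta: float
    cov: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.cov is not None:
            c = np.asarray(self.cov, dtype=float)
            if c.shape != (2, 2):
                raise ValueError("cov must be a 2x2 matrix")
            if not np.allclose(c, c.T):
                raise ValueError("cov must be symmetric")
            if c[0, 0] < 0 or c[1, 1] < 0:
                raise ValueError("cov must have non-negative diagonal")
            object.__setattr__(self, "cov", c)

    @property
    def usable(self) -> bool:
        return self.alpha + self.beta > 0.0

    def require_usable(self) -> None:
        if not self.usable:
            raise DegenerateCurveError(
                "alpha = beta = 0 defines no survival curve"
            )

    @property
    def alpha_beta_ratio(self) -> float:
        """(alpha/beta) in Gy; diverges for beta = 0."""
        if self.beta == 0:
            raise ZeroDivisionError("alpha/beta diverges for beta = 0")
        return self.alpha / self.beta


@dataclass(frozen=True)
class EndpointValue:
    """One radiosensitivity metric: an iso-survival dose or SF at 2 Gy.

    ``sf_level`` is either a survival fraction in (0, 1) — then ``value``
    is the dose D_SF in Gy — or the literal tag ``"SF_2Gy"`` — then
    ``value`` is the surviving fraction after 2 Gy.
    """

    sf_level: float | str
    value: float
    stderr: float | None = None

    def __post_init__(self) -> None:
        if self.sf_level == "SF_2Gy":
            if not (0.0 < self.value <= 1.0):
                raise ValueError("SF_2Gy value must be in (0, 1]")
        else:
            if not (0.0 < float(self.sf_level) < 1.0):
                raise ValueError("sf_level must be in (0, 1)")
            if self.value <= 0:
                raise ValueError("iso-survival dose must be positive")


def surviving_fraction(params: LQParams, dose: float | np.ndarray) -> float | np.ndarray:
    """Survival fraction exp(-alpha*D - beta*D^2) at dose D >= 0 (Gy)."""
    d = np.asarray(dose, dtype=float)
    if np.any(d < 0):
        raise ValueError("dose must be non-negative")
    out = np.exp(-params.alpha * d - params.beta * d * d)
    return float(out) if np.isscalar(dose) or out.ndim == 0 else out


def dose_for_sf(params: LQParams, sf: float) -> float:
    """Dose (Gy) at which the curve reaches survival fraction ``sf``.

    The unique positive root of beta*D^2 + alpha*D + ln(sf) = 0; the
    negative root is discarded.  For beta = 0 this is -ln(sf)/alpha.
    """
    if not (0.0 < sf < 1.0):
        raise ValueError("sf must be in the open interval (0, 1)")
    params.require_usable()
    return float(_dose_for_logsf(params.alpha, params.beta, math.log(sf)))


def _dose_for_logsf(alpha, beta, log_sf):
    """Vectorized positive root of beta*D^2 + alpha*D + log_sf = 0 (log_sf < 0).

    Uses the numerically stable quadratic form 2q/(alpha + sqrt(disc)) with
    q = -log_sf, which degrades gracefully to q/alpha as beta -> 0.
    """
    alpha = np.asarray(alpha, dtype=float)
    beta = np.asarray(beta, dtype=float)
    q = -np.asarray(log_sf, dtype=float)  # > 0
    disc = alpha * alpha + 4.0 * beta * q
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        quad = 2.0 * q / (alpha + np.sqrt(disc))
        lin = q / np.where(alpha > 0, alpha, 1.0)
    # beta == 0 handled separately: alpha**2 can underflow for subnormal alpha
    out = np.where(beta > 0, quad, lin)
    return out if out.ndim else float(out)


def _survival_integral(alpha, beta):
    """G(alpha, beta) = integral_0^inf exp(-alpha*D - beta*D^2) dD.

    Closed form sqrt(pi)/(2*sqrt(beta)) * erfcx(alpha/(2*sqrt(beta))) for
    beta > 0 (erfcx avoids overflow for large alpha); 1/alpha for beta = 0.
    Vectorized over broadcastable alpha, beta.
    """
    alpha = np.asarray(alpha, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if np.any(beta < 0):
        raise ValueError("beta < 0 makes the survival integral divergent")
    with np.errstate(divide="ignore", invalid="ignore"):
        sb = np.sqrt(beta)
        quad_form = 0.5 * math.sqrt(math.pi) / np.where(sb > 0, sb, 1.0)
        quad_form = quad_form * erfcx(np.where(sb > 0, alpha / (2.0 * np.where(sb > 0, sb, 1.0)), 0.0))
        lin_form = np.where(alpha > 0, 1.0 / np.where(alpha > 0, alpha, 1.0), np.inf)
    out = np.where(beta > 0, quad_form, lin_form)
    return out if out.ndim else float(out)


def mean_inactivation_dose(
    params: LQParams, *, settings: NumericSettings = DEFAULT, method: str = "closed_form"
) -> float:
    """Mean inactivation dose, MID = integral_0^inf SF(D) dD, in Gy.

    ``method="quadrature"`` integrates numerically (used as an internal
    cross-check of the closed form); both agree to ``settings.quad_rel_tol``.
    """
    params.require_usable()
    if params.beta < 0:
        raise ValueError("beta < 0: mean inactivation dose diverges")
    if method == "closed_form":
        return float(_survival_integral(params.alpha, params.beta))
    if method == "quadrature":
        # Truncate where SF < sf_truncation; bound the tail analytically by
        # the pure-exponential envelope from the truncation point.
        d_hi = float(_dose_for_logsf(params.alpha, params.beta, math.log(settings.sf_truncation)))
        val, _ = integrate.quad(
            lambda d: math.exp(-params.alpha * d - params.beta * d * d),
            0.0,
            d_hi,
            epsabs=0.0,
            epsrel=settings.quad_rel_tol,
            limit=200,
        )
        slope_at_hi = params.alpha + 2.0 * params.beta * d_hi
        tail_bound = settings.sf_truncation / slope_at_hi
        return float(val + 0.5 * tail_bound)
    raise ValueError(f"unknown method {method!r}")


def _l2_numerator_sq(a1, b1, a2, b2):
    """integral_0^inf (e^{-a1 D - b1 D^2} - e^{-a2 D - b2 D^2})^2 dD, vectorized."""
    val = (
        _survival_integral(2.0 * np.asarray(a1), 2.0 * np.asarray(b1))
        - 2.0 * _survival_integral(np.asarray(a1) + np.asarray(a2), np.asarray(b1) + np.asarray(b2))
        + _survival_integral(2.0 * np.asarray(a2), 2.0 * np.asarray(b2))
    )
    # exact zero for identical curves can round to tiny negatives
    return np.maximum(val, 0.0)


def curve_l2_distance(pred: LQParams, meas: LQParams) -> float:
    """Normalized L2 distance between two survival curves.

    sqrt( integral_0^inf (SF_pred - SF_meas)^2 dD ) divided by the
    *measured* curve's mean inactivation dose.  The numerator is symmetric
    in its arguments; the normalization is not — swapping ``pred`` and
    ``meas`` changes the result.
    """
    pred.require_usable()
    meas.require_usable()
    if pred.beta < 0 or meas.beta < 0:
        raise ValueError("beta < 0 makes the L2 integral divergent")
    num_sq = float(_l2_numerator_sq(pred.alpha, pred.beta, meas.alpha, meas.beta))
    return math.sqrt(num_sq) / mean_inactivation_dose(meas)


def rbe_at_iso_survival(photon: LQParams, proton: LQParams, sf: float) -> float:
    """RBE at an iso-survival level: D_sf(photon) / D_sf(proton)."""
    return dose_for_sf(photon, sf) / dose_for_sf(proton, sf)


def rbe_at_dose(photon: LQParams, proton: LQParams, proton_dose: float) -> float:
    """RBE at a physical proton dose d: D_x / d with SF_x(D_x) = SF_p(d)."""
    if proton_dose <= 0:
        raise ValueError("proton_dose must be positive")
    proton.require_usable()
    photon.require_usable()
    log_sf = -(proton.alpha * proton_dose + proton.beta * proton_dose**2)
    d_x = float(_dose_for_logsf(photon.alpha, photon.beta, log_sf))
    return d_x / proton_dose


def endpoint_gradient(params: LQParams, sf: float) -> np.ndarray:
    """(dD/dalpha, dD/dbeta) of the iso-survival dose, by implicit
    differentiation of beta*D^2 + alpha*D + ln(sf) = 0."""
    d = dose_for_sf(params, sf)
    denom = params.alpha + 2.0 * params.beta * d
    return np.array([-d / denom, -d * d / denom])


def propagate_endpoint_error(params: LQParams, sf: float) -> float:
    """Delta-method standard error (Gy) of D_sf from the (alpha, beta) covariance.

    Both gradient components are negative, so the negative alpha-beta
    covariance typical of LQ fits *reduces* the endpoint error relative to
    ignoring it — the statistical fact that makes iso-survival doses less
    noisy than alpha and beta themselves.
    """
    if params.cov is None:
        raise ValueError("params.cov is required for error propagation")
    g = endpoint_gradient(params, sf)
    var = float(g @ params.cov @ g)
    return math.sqrt(max(var, 0.0))


def fit_lq(
    doses: Sequence[float],
    log_sf: Sequence[float],
    weights: Sequence[float] | None = None,
    constrain_nonneg: bool = True,
) -> LQParams:
    """Least-squares LQ fit in log-survival space.

    Solves min_{alpha,beta} sum w_i (alpha*D_i + beta*D_i^2 + logSF_i)^2,
    optionally constrained to alpha, beta >= 0 (the common radiobiology
    convention).  Returns parameters with the covariance estimated from the
    fit Jacobian and residual variance (zero when the fit interpolates).
    """
    d = np.asarray(doses, dtype=float)
    y = -np.asarray(log_sf, dtype=float)
    if d.size < 2:
        raise ValueError("need at least 2 points to fit alpha and beta")
    if np.unique(d).size < 2:
        raise ValueError("doses must include at least 2 distinct values")
    X = np.column_stack([d, d * d])
    if weights is not None:
        w = np.sqrt(np.asarray(weights, dtype=float))
        Xw, yw = X * w[:, None], y * w
    else:
        Xw, yw = X, y
    if constrain_nonneg:
        theta, _ = optimize.nnls(Xw, yw)
    else:
        theta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = yw - Xw @ theta
    dof = d.size - 2
    sigma2 = float(resid @ resid) / dof if dof > 0 else 0.0
    cov = sigma2 * np.linalg.inv(Xw.T @ Xw)
    cov = 0.5 * (cov + cov.T)
    return LQParams(alpha=float(theta[0]), beta=float(theta[1]), cov=cov)
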