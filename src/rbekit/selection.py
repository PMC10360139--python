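"""Candidate LET-function registry, BIC scoring and model-structure search.

Three nested questions are answered here, each by penalized fit quality:

1. Which LET-dependent *slope* and *intercept* functions best describe how
   the photon-proton endpoint correlation changes with beam quality?
   (``function_grid_search``: a 7x7 grid of candidate-family combinations,
   each fitted by relative-square-distance nonlinear least squares.)
2. Which *set of survival endpoints* should the model carry?
   (``endpoint_combination_search``: every 2-6 subset of the six
   radiosensitivity metrics, scored by the summed curve-space L2 distance.)
3. Given the winning structure — exponential slope, linear intercept, two
   endpoints at SF e^-1 and e^-3 — what are the six parameter values and
   their covariance?  (``fit_full_model``.)

The Bayesian information criterion uses the Gaussian-residual convention
BIC = n*ln(objective/n) + k*ln(n) with n the number of paired experiments
(survival curves, not dose points) and k the total free-parameter count.
Only BIC differences ever matter for ranking.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import gammaln

from . import dataset as ds
from .dataset import PairedExperiment
from .flint import FlintModel
from .lqm import _dose_for_logsf, _l2_numerator_sq, _survival_integral
from .settings import DEFAULT, NumericSettings

__all__ = [
    "CandidateFamily",
    "FitReport",
    "SLOPE_FAMILIES",
    "INTERCEPT_FAMILIES",
    "bic",
    "fit_endpoint_function",
    "function_grid_search",
    "endpoint_combination_search",
    "fit_full_model",
]

_PENALTY = 1e4  # residual magnitude for out-of-domain parameter regions
# Constant shift inside sqrt-distance residuals: sum (sqrt(d_i + eps))^2 =
# sum d_i + n*eps shares its minimizer with sum d_i while keeping the
# residual gradient bounded when a curve distance passes through zero.
_L2_EPS = 1e-12


# ---------------------------------------------------------------------------
# Candidate families
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CandidateFamily:
    """One candidate LET-function family for the slope or intercept role.

    ``eval(let, theta)`` maps an LET array and parameter vector to values,
    returning NaN outside the family's domain (poles of the gamma
    function, logarithms of non-positive arguments); fitting code turns
    NaNs into large penalty residuals.
    """

    role: str
    form_id: str
    label: str
    param_names: tuple[str, ...]
    eval: Callable[[np.ndarray, np.ndarray], np.ndarray]
    base_start: tuple[float, ...]
    multimodal: bool = False

    @property
    def k(self) -> int:
        return len(self.param_names)


def _gamma_safe(x):
    """Gamma(x) for x > 0, NaN elsewhere (avoids poles at 0, -1, ...)."""
    x = np.asarray(x, dtype=float)
    with np.errstate(invalid="ignore", over="ignore"):
        out = np.where(x > 0, np.exp(gammaln(np.where(x > 0, x, 1.0))), np.nan)
    return out


def _s_exp(L, t):
    c, f = t
    with np.errstate(over="ignore"):
        return c * np.exp(-f * L)


def _s_exp_off(L, t):
    c, f, g = t
    with np.errstate(over="ignore"):
        return c * np.exp(-f * L) + g


def _s_gauss(L, t):
    c, f, h, g = t
    with np.errstate(over="ignore", invalid="ignore"):
        return c * np.exp(-f * L - h * L * L) + g


def _s_lin_exp(L, t):
    c, h, f, g = t
    with np.errstate(over="ignore", invalid="ignore"):
        return (c + h * L) * np.exp(-f * L) + g


def _s_log_exp(L, t):
    c, h, f, g = t
    arg = L - h
    with np.errstate(invalid="ignore", divide="ignore", over="ignore"):
        out = np.where(arg > 0, c * np.log(np.where(arg > 0, arg, 1.0)) * np.exp(-f * L) + g, np.nan)
    return out


def _s_inv_gamma(L, t):
    c, f, h, g = t
    return c / _gamma_safe(f * L + h + 1.0) + g


def _s_poisson(L, t):
    c, k, f, h, g = t
    x = f * (L - h)
    with np.errstate(invalid="ignore", over="ignore"):
        num = np.where(
            (x + 1.0 > 0) & (k > 0),
            np.exp(x * np.log(np.where(k > 0, k, 1.0)) - k - gammaln(np.where(x + 1.0 > 0, x + 1.0, 1.0))),
            np.nan,
        )
    return c * num + g


def _i_const(L, t):
    return np.full_like(np.asarray(L, dtype=float), t[0])


def _i_linear(L, t):
    return t[0] * L


def _i_affine(L, t):
    return t[0] + t[1] * L


def _i_quadratic(L, t):
    return t[0] + t[1] * L + t[2] * L * L


def _i_exp(L, t):
    with np.errstate(over="ignore"):
        return t[0] * np.exp(t[1] * L)


def _i_exp_off(L, t):
    with np.errstate(over="ignore"):
        return t[0] * np.exp(t[1] * L) + t[2]


def _i_expdecay_linear(L, t):
    with np.errstate(over="ignore", invalid="ignore"):
        return t[0] * np.exp(-t[1] * L) + t[2] * L + t[3]


SLOPE_FAMILIES: dict[str, CandidateFamily] = {
    fam.form_id: fam
    for fam in [
        CandidateFamily("slope", "exp", "c*e^(-f*L)", ("c", "f"), _s_exp, (1.0, 0.03)),
        CandidateFamily("slope", "exp_offset", "c*e^(-f*L)+g", ("c", "f", "g"), _s_exp_off, (1.0, 0.03, 0.0)),
        CandidateFamily("slope", "gaussian", "c*e^(-f*L-h*L^2)+g", ("c", "f", "h", "g"), _s_gauss, (1.0, 0.03, 1e-4, 0.0), True),
        CandidateFamily("slope", "linear_times_exp", "(c+h*L)*e^(-f*L)+g", ("c", "h", "f", "g"), _s_lin_exp, (1.0, 0.0, 0.03, 0.0), True),
        CandidateFamily("slope", "log_times_exp", "c*ln(L-h)*e^(-f*L)+g", ("c", "h", "f", "g"), _s_log_exp, (0.3, -2.0, 0.03, 0.5), True),
        CandidateFamily("slope", "inverse_gamma", "c/Gamma(f*L+h+1)+g", ("c", "f", "h", "g"), _s_inv_gamma, (1.0, 0.03, 0.0, 0.0), True),
        CandidateFamily("slope", "poisson_like", "c*k^(f*(L-h))*e^(-k)/Gamma(f*(L-h)+1)+g", ("c", "k", "f", "h", "g"), _s_poisson, (2.7, 1.0, 0.03, 0.0, 0.0), True),
    ]
}

INTERCEPT_FAMILIES: dict[str, CandidateFamily] = {
    fam.form_id: fam
    for fam in [
        CandidateFamily("intercept", "const", "m", ("m",), _i_const, (0.0,)),
        CandidateFamily("intercept", "linear", "p*L", ("p",), _i_linear, (0.02,)),
        CandidateFamily("intercept", "affine", "m+p*L", ("m", "p"), _i_affine, (0.0, 0.02)),
        CandidateFamily("intercept", "quadratic", "m+p*L+q*L^2", ("m", "p", "q"), _i_quadratic, (0.0, 0.02, 0.0)),
        CandidateFamily("intercept", "exp", "q*e^(s*L)", ("q", "s"), _i_exp, (0.1, 0.01), True),
        CandidateFamily("intercept", "exp_offset", "q*e^(s*L)+m", ("q", "s", "m"), _i_exp_off, (0.1, 0.01, 0.0), True),
        CandidateFamily("intercept", "expdecay_linear", "q*e^(-s*L)+p*L+m", ("q", "s", "p", "m"), _i_expdecay_linear, (0.1, 0.01, 0.02, 0.0), True),
    ]
}


@dataclass
class FitReport:
    """Outcome of one model fit, with the penalized-fit-quality metadata."""

    params: dict[str, float]
    objective: str
    objective_value: float
    n: int
    k: int
    bic: float
    stderr: dict[str, float] | None = None
    cov: np.ndarray | None = None
    chi2_nu: float | None = None
    converged: bool = True
    extra: dict = field(default_factory=dict)


def bic(objective_value: float, n: int, k: int, *, floor: float = 1e-12) -> float:
    """Gaussian-residual BIC: n*ln(objective/n) + k*ln(n); smaller is better.

    A non-positive objective (noiseless data fit exactly) is floored to
    keep the logarithm finite.
    """
    if n <= k:
        raise ValueError("BIC requires n > k")
    obj = max(float(objective_value), floor)
    return n * math.log(obj / n) + k * math.log(n)


def _multistarts(
    families: Sequence[CandidateFamily], settings: NumericSettings
) -> list[np.ndarray]:
    """Fixed multi-start list: the analytic base start plus log-uniform
    perturbations when any family has shape parameters."""
    base = np.concatenate([np.asarray(f.base_start, dtype=float) for f in families])
    starts = [base]
    if any(f.multimodal for f in families):
        rng = np.random.default_rng(settings.multistart_seed)
        for _ in range(settings.n_multistart):
            scale = rng.uniform(0.2, 5.0, size=base.size)
            sign_flip = rng.random(base.size) < 0.15
            pert = base * scale + rng.normal(0.0, 0.05, size=base.size)
            pert[sign_flip] *= -1.0
            starts.append(pert)
    return starts


def _least_squares_multistart(
    residual: Callable[[np.ndarray], np.ndarray],
    starts: Sequence[np.ndarray],
    max_nfev: int = 2000,
    **kwargs,
) -> tuple[optimize.OptimizeResult | None, bool]:
    best = None
    converged = False
    kwargs.setdefault("method", "trf")
    for x0 in starts:
        r0 = residual(np.asarray(x0, dtype=float))
        if not np.all(np.isfinite(r0)):
            continue
        try:
            res = optimize.least_squares(residual, x0, max_nfev=max_nfev, **kwargs)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
            converged = converged or res.status > 0
    return best, converged


# Curve-space objectives have long, poorly scaled valleys in (c, f, p);
# Levenberg-Marquardt with tight tolerances tracks them reliably.
_LM_OPTS = dict(method="lm", ftol=1e-11, xtol=1e-11, gtol=1e-11)


def _fit_cov(res: optimize.OptimizeResult, n: int, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Parameter covariance sigma^2 * (J^T J)^-1 from the final Jacobian."""
    J = res.jac
    rss = 2.0 * res.cost
    dof = max(n - k, 1)
    sigma2 = rss / dof
    JtJ = J.T @ J
    try:
        cov = sigma2 * np.linalg.inv(JtJ)
    except np.linalg.LinAlgError:
        cov = sigma2 * np.linalg.pinv(JtJ)
    return cov, np.sqrt(np.maximum(np.diag(cov), 0.0))


# ---------------------------------------------------------------------------
# Single-endpoint function fitting (relative-square objective)
# ---------------------------------------------------------------------------

def fit_endpoint_function(
    records: Sequence[PairedExperiment],
    endpoint: float | str,
    slope_family: str | CandidateFamily = "exp",
    intercept_family: str | CandidateFamily = "linear",
    settings: NumericSettings = DEFAULT,
    _cache: dict | None = None,
) -> FitReport:
    """Fit one endpoint's slope/intercept LET laws by relative least squares.

    Minimizes sum_i ((pred_i - meas_i)/meas_i)^2 where
    pred = slope(LET)*photon_endpoint + intercept(LET).  Multi-modal
    families get the fixed multi-start list; families nesting the plain
    exponential slope additionally start from the exponential fit with the
    extra parameters at their neutral values, which guarantees the nested
    objective never beats the richer family's.
    """
    sf = SLOPE_FAMILIES[slope_family] if isinstance(slope_family, str) else slope_family
    itf = (
        INTERCEPT_FAMILIES[intercept_family]
        if isinstance(intercept_family, str)
        else intercept_family
    )
    if _cache is not None and (sf.form_id, itf.form_id) in _cache:
        return _cache[(sf.form_id, itf.form_id)]
    x, y, L = ds.endpoint_arrays(records, endpoint)
    ks, ki = sf.k, itf.k
    n, k = x.size, ks + ki

    def residual(theta: np.ndarray) -> np.ndarray:
        pred = sf.eval(L, theta[:ks]) * x + itf.eval(L, theta[ks:])
        r = (pred - y) / y
        bad = ~np.isfinite(r)
        if bad.any():
            r[bad] = _PENALTY
        return r

    starts = _multistarts([sf, itf], settings)
    if sf.form_id != "exp":
        # seed from the nested exponential fit (extra params neutral)
        nested = fit_endpoint_function(records, endpoint, "exp", itf, settings, _cache)
        seed = np.concatenate([np.asarray(sf.base_start, dtype=float), [nested.params[p] for p in itf.param_names]])
        seed[0] = nested.params["c"]
        f_pos = sf.param_names.index("f")
        seed[f_pos] = nested.params["f"]
        if "g" in sf.param_names:
            seed[sf.param_names.index("g")] = 0.0
        starts.append(seed)
    if itf.form_id in ("affine", "quadratic", "exp_offset", "expdecay_linear"):
        # neutral-extra seed from the simpler intercept member
        simple = "const" if itf.form_id in ("exp_offset",) else "linear"
        nested = fit_endpoint_function(records, endpoint, sf, simple, settings, _cache)
        seed = np.concatenate(
            [[nested.params[p] for p in sf.param_names], np.asarray(itf.base_start, dtype=float)]
        )
        if itf.form_id == "affine":
            seed[ks:] = [0.0, nested.params["p"]]
        elif itf.form_id == "quadratic":
            seed[ks:] = [0.0, nested.params["p"], 0.0]
        elif itf.form_id == "expdecay_linear":
            seed[ks:] = [0.0, 0.01, nested.params["p"], 0.0]
        else:  # exp_offset: q=0 start degenerates; keep tiny q
            seed[ks:] = [1e-6, 0.01, nested.params["m"]]
        starts.append(seed)

    # BIC needs ~0.1 resolution; modest tolerances keep the 49-cell grid fast
    res, converged = _least_squares_multistart(
        residual, starts, max_nfev=120, method="lm", ftol=1e-9, xtol=1e-9, gtol=1e-9
    )
    if res is None:
        return FitReport({}, "relative_sq_endpoint", math.inf, n, k, math.inf, converged=False)
    rss = 2.0 * res.cost
    cov, se = _fit_cov(res, n, k)
    names = list(sf.param_names) + list(itf.param_names)
    report = FitReport(
        params=dict(zip(names, map(float, res.x))),
        objective="relative_sq_endpoint",
        objective_value=float(rss),
        n=n,
        k=k,
        bic=bic(rss, n, k),
        stderr=dict(zip(names, map(float, se))),
        cov=cov,
        converged=converged,
        extra={"slope_family": sf.form_id, "intercept_family": itf.form_id},
    )
    if _cache is not None:
        _cache[(sf.form_id, itf.form_id)] = report
    return report


def function_grid_search(
    records: Sequence[PairedExperiment],
    endpoint: float | str = 0.10,
    settings: NumericSettings = DEFAULT,
) -> tuple[pd.DataFrame, dict[tuple[str, str], FitReport]]:
    """BIC matrix over all 7x7 slope/intercept family combinations.

    Returns the BIC DataFrame (rows: slope families, columns: intercept
    families) and the per-cell fit reports; the argmin combination is in
    ``reports[df.stack().idxmin()]``.
    """
    reports: dict[tuple[str, str], FitReport] = {}
    cache: dict = {}
    mat = pd.DataFrame(
        index=list(SLOPE_FAMILIES), columns=list(INTERCEPT_FAMILIES), dtype=float
    )
    for s_id in SLOPE_FAMILIES:
        for i_id in INTERCEPT_FAMILIES:
            rep = fit_endpoint_function(records, endpoint, s_id, i_id, settings, cache)
            reports[(s_id, i_id)] = rep
            mat.loc[s_id, i_id] = rep.bic
    return mat, reports


# ---------------------------------------------------------------------------
# Curve-space objective machinery (vectorized over records)
# ---------------------------------------------------------------------------

def _reconstruct_vec(D: np.ndarray, logsf: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized constrained zero-intercept LQ reconstruction.

    D, logsf: (n_records, n_endpoints).  Returns alpha, beta arrays with
    the negative-parameter fallbacks applied row-wise.
    """
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        s2 = np.sum(D**2, axis=1)
        s3 = np.sum(D**3, axis=1)
        s4 = np.sum(D**4, axis=1)
        sdl = np.sum(D * logsf, axis=1)
        sd2l = np.sum(D * D * logsf, axis=1)
        den = s3 * s3 - s2 * s4
        alpha = (s4 * sdl - s3 * sd2l) / den
        beta = (s2 * sd2l - s3 * sdl) / den
        a_b0 = np.maximum(-sdl / s2, 0.0)
        b_a0 = np.maximum(-sd2l / s4, 0.0)
    neg_a, neg_b = alpha < 0.0, beta < 0.0
    both = neg_a & neg_b
    out_a = np.where(neg_b, a_b0, np.where(neg_a, 0.0, alpha))
    out_b = np.where(neg_b, 0.0, np.where(neg_a, b_a0, beta))
    if np.any(both):
        rss_b0 = np.sum((a_b0[:, None] * D + logsf) ** 2, axis=1)
        rss_a0 = np.sum((b_a0[:, None] * D * D + logsf) ** 2, axis=1)
        use_a0 = both & (rss_a0 < rss_b0)
        out_a = np.where(use_a0, 0.0, out_a)
        out_b = np.where(use_a0, b_a0, out_b)
    return out_a, out_b


def _l2_dist_vec(a_pred, b_pred, a_meas, b_meas, mid_meas) -> np.ndarray:
    num_sq = _l2_numerator_sq(a_pred, b_pred, a_meas, b_meas)
    return np.sqrt(num_sq) / mid_meas


class _CurveData:
    """Precomputed arrays for curve-space objectives on one dataset."""

    def __init__(self, records: Sequence[PairedExperiment], sf_levels: Sequence[float | str]):
        self.levels = tuple(sf_levels)
        self.L = np.array([r.let_d for r in records])
        self.a_meas = np.array([r.proton.alpha for r in records])
        self.b_meas = np.array([r.proton.beta for r in records])
        self.mid_meas = _survival_integral(self.a_meas, self.b_meas)
        ax = np.array([r.photon.alpha for r in records])
        bx = np.array([r.photon.beta for r in records])
        cols = []
        self.is_sf2gy = []
        for lev in self.levels:
            if lev == "SF_2Gy":
                cols.append(np.exp(-(ax * 2.0 + bx * 4.0)))
                self.is_sf2gy.append(True)
            else:
                cols.append(_dose_for_logsf(ax, bx, math.log(float(lev))))
                self.is_sf2gy.append(False)
        self.x = np.column_stack(cols)  # photon endpoint values
        self.n = len(records)
        # measured RBE at 2 Gy (for the RSS objective)
        log_sf_p2 = -(self.a_meas * 2.0 + self.b_meas * 4.0)
        self.rbe2_meas = _dose_for_logsf(ax, bx, log_sf_p2) / 2.0
        self.ax, self.bx = ax, bx

    def predicted_curves(self, slope_vals: np.ndarray, int_vals: np.ndarray):
        """slope_vals/int_vals: (n_records, n_endpoints) -> (alpha_p, beta_p, ok)."""
        pred = slope_vals * self.x + int_vals
        D = np.empty_like(pred)
        logsf = np.empty_like(pred)
        ok = np.ones(self.n, dtype=bool)
        for j, (lev, is_sf) in enumerate(zip(self.levels, self.is_sf2gy)):
            if is_sf:
                sfp = np.clip(pred[:, j], 1e-9, 1.0 - 1e-9)
                ok &= pred[:, j] > 0
                D[:, j] = 2.0
                logsf[:, j] = np.log(sfp)
            else:
                ok &= pred[:, j] > 0
                D[:, j] = np.where(pred[:, j] > 0, pred[:, j], 1.0)
                logsf[:, j] = math.log(float(lev))
        a_p, b_p = _reconstruct_vec(D, logsf)
        ok &= np.isfinite(a_p) & np.isfinite(b_p) & (a_p + b_p > 0)
        return a_p, b_p, ok


def _curve_residual_factory(
    data: _CurveData,
    slope_fams: Sequence[CandidateFamily],
    int_fams: Sequence[CandidateFamily],
    objective: str,
):
    """Residual vector whose squared sum is the dataset objective.

    ``l2_curve``: residual_i = sqrt(normalized L2 distance_i), so the sum
    of squares is the summed per-experiment distance.  ``rss_rbe2gy``:
    residual_i = predicted - measured RBE at 2 Gy.
    """
    ks = [f.k for f in slope_fams]
    ki = [f.k for f in int_fams]

    def residual(theta: np.ndarray) -> np.ndarray:
        pos = 0
        slope_vals = np.empty((data.n, len(slope_fams)))
        int_vals = np.empty((data.n, len(int_fams)))
        for j, fam in enumerate(slope_fams):
            slope_vals[:, j] = fam.eval(data.L, theta[pos : pos + ks[j]])
            pos += ks[j]
        for j, fam in enumerate(int_fams):
            int_vals[:, j] = fam.eval(data.L, theta[pos : pos + ki[j]])
            pos += ki[j]
        if not np.all(np.isfinite(slope_vals)) or not np.all(np.isfinite(int_vals)):
            return np.full(data.n, _PENALTY)
        a_p, b_p, ok = data.predicted_curves(slope_vals, int_vals)
        out = np.full(data.n, _PENALTY)
        if objective == "l2_curve":
            d = _l2_dist_vec(a_p[ok], b_p[ok], data.a_meas[ok], data.b_meas[ok], data.mid_meas[ok])
            out[ok] = np.sqrt(d + _L2_EPS)
        elif objective == "rss_rbe2gy":
            log_sf_p2 = -(a_p[ok] * 2.0 + b_p[ok] * 4.0)
            rbe2 = _dose_for_logsf(data.ax[ok], data.bx[ok], log_sf_p2) / 2.0
            out[ok] = rbe2 - data.rbe2_meas[ok]
        else:
            raise ValueError(f"unknown objective {objective!r}")
        return np.nan_to_num(out, nan=_PENALTY, posinf=_PENALTY, neginf=-_PENALTY)

    return residual


def endpoint_combination_search(
    records: Sequence[PairedExperiment],
    intercept_family: str = "linear",
    sizes: Sequence[int] = (2, 3, 4, 5, 6),
    settings: NumericSettings = DEFAULT,
) -> dict:
    """Joint-fit BIC for every endpoint subset of each requested size.

    Each endpoint in a subset carries its own exponential slope (c, f) and
    its own intercept parameters; the joint fit minimizes the summed
    normalized L2 curve distance, with (alpha_p, beta_p) reconstructed
    from the subset's predicted endpoints.  Returns per-subset reports,
    the per-size minima, and the overall best subset.
    """
    itf = INTERCEPT_FAMILIES[intercept_family]
    sfam = SLOPE_FAMILIES["exp"]
    results: dict[tuple, FitReport] = {}
    for size in sizes:
        for subset in itertools.combinations(ds.SF_LEVELS, size):
            data = _CurveData(records, subset)
            slope_fams = [sfam] * size
            int_fams = [itf] * size
            residual = _curve_residual_factory(data, slope_fams, int_fams, "l2_curve")
            start = np.concatenate(
                [np.asarray(sfam.base_start, dtype=float) for _ in range(size)]
                + [np.asarray(itf.base_start, dtype=float) for _ in range(size)]
            )
            # parameter packing order is all slopes then all intercepts
            res, converged = _least_squares_multistart(residual, [start], max_nfev=1200, **_LM_OPTS)
            n = data.n
            k = size * (sfam.k + itf.k)
            if res is None:
                results[subset] = FitReport({}, "l2_curve", math.inf, n, k, math.inf, converged=False)
                continue
            obj = max(2.0 * res.cost - n * _L2_EPS, 0.0)
            names = [f"{p}{j+1}" for j in range(size) for p in sfam.param_names]
            names += [f"{p}{j+1}" for j in range(size) for p in itf.param_names]
            results[subset] = FitReport(
                params=dict(zip(names, map(float, res.x))),
                objective="l2_curve",
                objective_value=float(obj),
                n=n,
                k=k,
                bic=bic(obj, n, k),
                converged=converged,
                extra={"subset": subset, "intercept_family": intercept_family},
            )
    by_size = {
        size: min(
            (rep for sub, rep in results.items() if len(sub) == size),
            key=lambda r: r.bic,
        )
        for size in sizes
    }
    best_subset = min(results, key=lambda s: results[s].bic)
    return {"reports": results, "min_bic_by_size": by_size, "best_subset": best_subset}


# ---------------------------------------------------------------------------
# The final six-parameter fit
# ---------------------------------------------------------------------------

_SF1 = math.exp(-1.0)
_SF2 = math.exp(-3.0)


def fit_full_model(
    records: Sequence[PairedExperiment],
    objective: str = "l2_curve",
    settings: NumericSettings = DEFAULT,
    x0: Sequence[float] | None = None,
) -> tuple[FlintModel, FitReport]:
    """Fit the six-parameter two-endpoint model (SF e^-1 and e^-3).

    ``objective="l2_curve"`` minimizes the summed normalized L2 distance
    between predicted and measured survival curves; ``"rss_rbe2gy"``
    minimizes the residual sum of squares of RBE at 2 Gy.  The parameter
    covariance comes from the final Jacobian and residual variance; the
    fit is deterministic given the fixed start.
    """
    data = _CurveData(records, (_SF1, _SF2))
    sfam, itf = SLOPE_FAMILIES["exp"], INTERCEPT_FAMILIES["linear"]
    residual = _curve_residual_factory(data, [sfam, sfam], [itf, itf], objective)

    def reorder(theta6):  # (c1,f1,p1,c2,f2,p2) -> packing (c1,f1,c2,f2,p1,p2)
        return np.array([theta6[0], theta6[1], theta6[3], theta6[4], theta6[2], theta6[5]])

    def residual_model(theta6):
        return residual(reorder(theta6))

    start = np.asarray(x0, dtype=float) if x0 is not None else np.array(
        [1.0, 0.03, 0.02, 1.0, 0.03, 0.02]
    )
    res, converged = _least_squares_multistart(residual_model, [start], max_nfev=2000, **_LM_OPTS)
    if res is None:
        raise RuntimeError("six-parameter fit failed from the fixed start")
    # Near-interpolating data defeat Gauss-Newton steps (the sqrt-distance
    # residual gradient diverges as every distance -> 0): polish with a
    # direct-search pass and restart LM from the polished point so the
    # final Jacobian is evaluated at the true optimum.
    near_zero = 2.0 * res.cost < 5e-3 * data.n  # mean distance below 5e-3
    if near_zero or res.status == 0:
        # Gauss-Newton alone crawls (or stalls) when the data are close to
        # interpolable, so alternate direct-search and LM passes until the
        # objective stops improving; noisy stalls get one cheap cycle.
        obj_fn = lambda th: float(np.sum(residual_model(th) ** 2))
        cycles, maxiter = (4, 2000) if near_zero else (1, 600)
        for _ in range(cycles):
            if 2.0 * res.cost < 1e-9 * data.n:
                break
            before = 2.0 * res.cost
            nm = optimize.minimize(
                obj_fn, res.x, method="Nelder-Mead",
                options=dict(maxiter=maxiter, xatol=1e-12, fatol=1e-14),
            )
            start_next = nm.x if nm.fun < before else res.x
            res2, conv2 = _least_squares_multistart(
                residual_model, [start_next], max_nfev=2000, **_LM_OPTS
            )
            if res2 is not None and res2.cost < res.cost:
                res, converged = res2, converged or conv2
            if before - 2.0 * res.cost < 1e-6 * max(before, 1e-12):
                break
    n, k = data.n, 6
    obj = 2.0 * res.cost
    if objective == "l2_curve":
        obj = max(obj - n * _L2_EPS, 0.0)
    cov, se = _fit_cov(res, n, k)
    names = ["c1", "f1", "p1", "c2", "f2", "p2"]
    chi2 = None
    if objective == "rss_rbe2gy":
        sigma = settings.global_rbe_sigma * data.rbe2_meas
        r = residual_model(res.x)
        chi2 = float(np.sum((r / sigma) ** 2)) / max(n - k, 1)
    report = FitReport(
        params=dict(zip(names, map(float, res.x))),
        objective=objective,
        objective_value=float(obj),
        n=n,
        k=k,
        bic=bic(obj, n, k),
        stderr=dict(zip(names, map(float, se))),
        cov=cov,
        chi2_nu=chi2,
        converged=converged,
    )
    model = FlintModel.from_theta(res.x, cov=0.5 * (cov + cov.T))
    return model, report
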