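"""Comparison empirical proton-RBE models and head-to-head retraining.

Three published empirical models predict the proton LQ parameters from
the photon ones and the dose-weighted LET through the asymptotic RBE
ratios

    RBE_max = alpha_p / alpha_x        (low-dose limit)
    RBE_min = sqrt(beta_p / beta_x)    (high-dose limit):

- Wedenberg: RBE_max = 1 + q * LET / (alpha/beta)_x, RBE_min = 1.
- McNamara:  RBE_max = p0 + p1 * LET / (alpha/beta)_x,
             RBE_min = p2 + p3 * sqrt((alpha/beta)_x) * LET.
- Mairani:   nonlinear in LET and (alpha/beta)_x-dependent,
             RBE_max = 1 + (k1/(alpha/beta)_x) * LET * exp(-k2*LET),
             RBE_min = 1 + k3 * LET.
             (Coefficient defaults here are package baselines, not
             original-publication values; see the shipped YAML.)

All three require beta_x > 0: the (alpha/beta)_x ratio diverges otherwise,
which is one reason beta <= 0 records are filtered from training data.
Each model can be retrained on a paired-experiment dataset under either a
curve-space L2 objective or an RBE-at-2-Gy residual-sum-of-squares
objective, and compared against the two-endpoint correlation model on
identical residual definitions.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import optimize

from . import selection
from .dataset import PairedExperiment
from .lqm import LQParams, rbe_at_dose
from .selection import FitReport, _CurveData, bic
from .settings import DEFAULT, NumericSettings

__all__ = [
    "BenchmarkModelSpec",
    "published_spec",
    "benchmark_predict",
    "retrain",
    "compare_models",
]

MODEL_IDS = ("wedenberg", "mcnamara", "mairani")


def _load_baselines() -> dict:
    path = importlib.resources.files("rbekit.data") / "benchmark_coefficients.yaml"
    return yaml.safe_load(path.read_text())


@dataclass(frozen=True)
class BenchmarkModelSpec:
    """One comparison model: identifier plus named coefficients."""

    model_id: str
    params: dict[str, float]

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_IDS:
            raise ValueError(f"unknown model_id {self.model_id!r}")
        expected = {"wedenberg": ("q",), "mcnamara": ("p0", "p1", "p2", "p3"),
                    "mairani": ("k1", "k2", "k3")}[self.model_id]
        if tuple(self.params) != expected:
            raise ValueError(f"{self.model_id} expects parameters {expected}")

    @property
    def k(self) -> int:
        return len(self.params)

    def theta(self) -> np.ndarray:
        return np.array(list(self.params.values()), dtype=float)

    def with_theta(self, theta: Sequence[float]) -> "BenchmarkModelSpec":
        return replace(self, params=dict(zip(self.params, map(float, theta))))


def published_spec(model_id: str) -> BenchmarkModelSpec:
    """The shipped baseline coefficients for one comparison model."""
    doc = _load_baselines()
    return BenchmarkModelSpec(model_id=model_id, params=dict(doc[model_id]))


def _rbe_ratios(spec: BenchmarkModelSpec, abx, let):
    """(RBE_max, RBE_min) arrays for photon (alpha/beta)_x and LET arrays."""
    abx = np.asarray(abx, dtype=float)
    let = np.asarray(let, dtype=float)
    p = spec.params
    if spec.model_id == "wedenberg":
        rmax = 1.0 + p["q"] * let / abx
        rmin = np.ones_like(rmax)
    elif spec.model_id == "mcnamara":
        rmax = p["p0"] + p["p1"] * let / abx
        rmin = p["p2"] + p["p3"] * np.sqrt(abx) * let
    else:  # mairani
        rmax = 1.0 + (p["k1"] / abx) * let * np.exp(-p["k2"] * let)
        rmin = 1.0 + p["k3"] * let
    return rmax, rmin


def benchmark_predict(
    spec: BenchmarkModelSpec, photon: LQParams, let: float, dose: float
) -> tuple[LQParams, float]:
    """Predicted proton curve and RBE at a proton dose for one model.

    alpha_p = alpha_x * RBE_max and beta_p = beta_x * RBE_min^2; the RBE
    follows from iso-effect inversion of the photon LQ curve.
    """
    if photon.beta <= 0:
        raise ZeroDivisionError(
            "benchmark models need beta_x > 0: (alpha/beta)_x diverges"
        )
    rmax, rmin = _rbe_ratios(spec, photon.alpha_beta_ratio, let)
    proton = LQParams(alpha=photon.alpha * float(rmax), beta=photon.beta * float(rmin) ** 2)
    return proton, rbe_at_dose(photon, proton, dose)


def _predicted_curves_vec(spec, theta, data: _CurveData):
    s = spec.with_theta(theta)
    abx = data.ax / data.bx
    rmax, rmin = _rbe_ratios(s, abx, data.L)
    a_p = data.ax * rmax
    b_p = data.bx * rmin**2
    ok = np.isfinite(a_p) & np.isfinite(b_p) & (b_p >= 0) & (a_p + b_p > 0)
    return a_p, b_p, ok


def _benchmark_residual_factory(spec, data: _CurveData, objective: str):
    def residual(theta):
        a_p, b_p, ok = _predicted_curves_vec(spec, theta, data)
        out = np.full(data.n, selection._PENALTY)
        if objective == "l2_curve":
            d = selection._l2_dist_vec(
                a_p[ok], b_p[ok], data.a_meas[ok], data.b_meas[ok], data.mid_meas[ok]
            )
            out[ok] = np.sqrt(d + selection._L2_EPS)
        elif objective == "rss_rbe2gy":
            log_sf = -(a_p[ok] * 2.0 + b_p[ok] * 4.0)
            from .lqm import _dose_for_logsf

            rbe2 = _dose_for_logsf(data.ax[ok], data.bx[ok], log_sf) / 2.0
            out[ok] = rbe2 - data.rbe2_meas[ok]
        else:
            raise ValueError(f"unknown objective {objective!r}")
        return np.nan_to_num(out, nan=selection._PENALTY, posinf=selection._PENALTY)

    return residual


def _require_positive_beta_x(records: Sequence[PairedExperiment]) -> None:
    if any(r.photon.beta <= 0 for r in records):
        raise ZeroDivisionError(
            "dataset contains beta_x <= 0 records; filter before retraining"
        )


def retrain(
    spec: BenchmarkModelSpec,
    records: Sequence[PairedExperiment],
    objective: str = "rss_rbe2gy",
    settings: NumericSettings = DEFAULT,
) -> tuple[BenchmarkModelSpec, FitReport]:
    """Refit a comparison model's coefficients on a paired dataset.

    Starts from the spec's current coefficients, so the minimized
    objective can never exceed the baseline's.  chi2/nu is reported for
    the RSS objective using a per-record sigma of
    ``settings.global_rbe_sigma`` relative to the measured RBE at 2 Gy.
    """
    _require_positive_beta_x(records)
    data = _CurveData(records, (math.exp(-1.0), math.exp(-3.0)))
    residual = _benchmark_residual_factory(spec, data, objective)
    res = optimize.least_squares(residual, spec.theta(), max_nfev=4000, **selection._LM_OPTS)
    n, k = data.n, spec.k
    obj = 2.0 * res.cost
    if objective == "l2_curve":
        obj = max(obj - n * selection._L2_EPS, 0.0)
    cov, se = selection._fit_cov(res, n, k)
    chi2 = None
    if objective == "rss_rbe2gy":
        sigma = settings.global_rbe_sigma * data.rbe2_meas
        chi2 = float(np.sum((res.fun / sigma) ** 2)) / max(n - k, 1)
    fitted = spec.with_theta(res.x)
    report = FitReport(
        params=dict(fitted.params),
        objective=objective,
        objective_value=float(obj),
        n=n,
        k=k,
        bic=bic(obj, n, k),
        stderr=dict(zip(fitted.params, map(float, se))),
        cov=cov,
        chi2_nu=chi2,
        converged=res.status > 0,
        extra={"model_id": spec.model_id},
    )
    return fitted, report


def _flint_reports(records, settings) -> dict[str, FitReport]:
    _, rep_l2 = selection.fit_full_model(records, objective="l2_curve", settings=settings)
    _, rep_rss = selection.fit_full_model(records, objective="rss_rbe2gy", settings=settings)
    return {"l2_curve": rep_l2, "rss_rbe2gy": rep_rss}


def compare_models(
    records: Sequence[PairedExperiment],
    models: Sequence[str] = ("flint",) + MODEL_IDS,
    objectives: Sequence[str] = ("rss_rbe2gy", "l2_curve"),
    max_let: float | None = None,
    settings: NumericSettings = DEFAULT,
) -> pd.DataFrame:
    """Head-to-head comparison table of retrained models.

    One row per model with chi2/nu (RSS objective) and the BIC under each
    requested objective; ``max_let`` optionally restricts the dataset to
    LET_d below a threshold (as done when comparing against models that
    were originally trained on narrower LET ranges), which changes n and
    therefore every BIC.
    """
    if max_let is not None:
        records = [r for r in records if r.let_d < max_let]
    rows = []
    for model_id in models:
        row: dict = {"model": model_id, "n": len(records)}
        if model_id == "flint":
            reps = {
                obj: selection.fit_full_model(records, objective=obj, settings=settings)[1]
                for obj in objectives
            }
        else:
            spec = published_spec(model_id)
            reps = {
                obj: retrain(spec, records, objective=obj, settings=settings)[1]
                for obj in objectives
            }
        for obj, rep in reps.items():
            row[f"bic_{obj}"] = rep.bic
            if rep.chi2_nu is not None:
                row["chi2_nu_rbe2gy"] = rep.chi2_nu
        rows.append(row)
    return pd.DataFrame(rows)
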