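"""The six-parameter endpoint-correlation proton RBE model.

Cell radiosensitivity to protons is linearly correlated with
radiosensitivity to x-rays at fixed beam quality: an iso-survival dose
transforms as

    D_SF,proton = slope(LET) * D_SF,x-ray + intercept(LET),
    slope(LET) = c * exp(-f * LET),      intercept(LET) = p * LET,

with LET the dose-weighted LET in keV/um.  Carrying two survival
endpoints, SF1 = e^-1 and SF2 = e^-3 (roughly 37% and 5% survival), gives
six parameters (c1, f1, p1, c2, f2, p2); the predicted proton
(alpha, beta) then follow in closed form from the zero-intercept
log-survival regression through the two predicted endpoint doses, with
non-negativity enforced by the constrained single-parameter solutions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .lqm import LQParams, dose_for_sf, rbe_at_dose, rbe_at_iso_survival

__all__ = [
    "EndpointFunctionParams",
    "FlintModel",
    "EndpointSet",
    "TABLE_DEFAULT",
    "slope",
    "intercept",
    "predict_endpoint",
    "reconstruct_alpha_beta_two_point",
    "reconstruct_alpha_beta_general",
    "predict_proton_curve",
    "predict_rbe",
    "rbe_iso_survival_single_endpoint",
    "prediction_uncertainty",
]


@dataclass(frozen=True)
class EndpointFunctionParams:
    """(c, f, p) of one endpoint's slope/intercept law.

    c is the dimensionless zero-LET slope, f the slope decay rate per
    (keV/um), and p the intercept rate in Gy per (keV/um).
    """

    c: float
    f: float
    p: float

    def as_array(self) -> np.ndarray:
        return np.array([self.c, self.f, self.p])


@dataclass(frozen=True)
class FlintModel:
    """Two-endpoint, six-parameter model with optional 6x6 covariance.

    Covariance ordering is (c1, f1, p1, c2, f2, p2), endpoint 1 being
    SF = e^-1 and endpoint 2 being SF = e^-3.
    """

    sf1_params: EndpointFunctionParams
    sf2_params: EndpointFunctionParams
    cov: np.ndarray | None = None

    SF1: float = math.exp(-1.0)
    SF2: float = math.exp(-3.0)

    def __post_init__(self) -> None:
        if self.cov is not None:
            c = np.asarray(self.cov, dtype=float)
            if c.shape != (6, 6) or not np.allclose(c, c.T):
                raise ValueError("cov must be a symmetric 6x6 matrix")
            object.__setattr__(self, "cov", c)

    def theta(self) -> np.ndarray:
        return np.concatenate([self.sf1_params.as_array(), self.sf2_params.as_array()])

    @classmethod
    def from_theta(cls, theta: Sequence[float], cov: np.ndarray | None = None) -> "FlintModel":
        t = np.asarray(theta, dtype=float)
        return cls(
            sf1_params=EndpointFunctionParams(*t[:3]),
            sf2_params=EndpointFunctionParams(*t[3:6]),
            cov=cov,
        )

    @classmethod
    def identity(cls) -> "FlintModel":
        """The fixed-point model: proton curve = photon curve, RBE = 1."""
        one = EndpointFunctionParams(1.0, 0.0, 0.0)
        return cls(sf1_params=one, sf2_params=one)

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "c1": float(self.sf1_params.c),
            "f1": float(self.sf1_params.f),
            "p1": float(self.sf1_params.p),
            "c2": float(self.sf2_params.c),
            "f2": float(self.sf2_params.f),
            "p2": float(self.sf2_params.p),
        }
        if self.cov is not None:
            doc["covariance"] = [[float(v) for v in row] for row in self.cov]
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FlintModel":
        doc = yaml.safe_load(Path(path).read_text())
        cov = np.array(doc["covariance"]) if "covariance" in doc else None
        return cls.from_theta(
            [doc[k] for k in ("c1", "f1", "p1", "c2", "f2", "p2")], cov=cov
        )


@dataclass(frozen=True)
class EndpointSet:
    """2-6 (sf_level, EndpointFunctionParams) pairs with distinct levels."""

    entries: tuple[tuple[float, EndpointFunctionParams], ...]

    def __post_init__(self) -> None:
        levels = [lv for lv, _ in self.entries]
        if not (2 <= len(levels) <= 6):
            raise ValueError("EndpointSet needs 2-6 endpoints")
        if len(set(levels)) != len(levels):
            raise ValueError("sf levels must be distinct")
        if any(not (0.0 < lv < 1.0) for lv in levels):
            raise ValueError("sf levels must be in (0, 1)")


def slope(let, params: EndpointFunctionParams):
    """LET-dependent slope c * exp(-f * LET) of the endpoint correlation."""
    return params.c * np.exp(-params.f * np.asarray(let, dtype=float))


def intercept(let, params: EndpointFunctionParams):
    """LET-dependent intercept p * LET (Gy) of the endpoint correlation."""
    return params.p * np.asarray(let, dtype=float)


def predict_endpoint(d_x, let, params: EndpointFunctionParams):
    """Predicted proton iso-survival dose slope(LET)*D_x + intercept(LET)."""
    d_x = np.asarray(d_x, dtype=float)
    if np.any(d_x <= 0):
        raise ValueError("photon endpoint dose must be positive")
    out = slope(let, params) * d_x + intercept(let, params)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Closed-form (alpha, beta) reconstruction from predicted endpoints
# ---------------------------------------------------------------------------

def reconstruct_alpha_beta_two_point(d1: float, d2: float) -> LQParams:
    """LQ parameters through (d1, e^-1) and (d2, e^-3), constrained >= 0.

    Closed form of the zero-intercept log-survival regression specialized
    to log SF of -1 and -3.  If the unconstrained beta is negative it is
    clamped to zero and alpha refit alone (and symmetrically for alpha);
    when the unconstrained solution is feasible the returned curve passes
    exactly through both points.
    """
    if not (d1 > 0 and d2 > 0):
        raise ValueError("endpoint doses must be positive")
    if d2 <= d1:
        raise ValueError(
            "the e^-3 dose must exceed the e^-1 dose for a non-negative LQ curve"
        )
    s1, s2, s3, s4 = (d1**k + d2**k for k in (1, 2, 3, 4))
    sdl = -(d1 + 3.0 * d2)  # sum D*logSF
    sd2l = -(d1**2 + 3.0 * d2**2)  # sum D^2*logSF
    den = s3 * s3 - s2 * s4
    alpha = (s4 * sdl - s3 * sd2l) / den
    beta = (s2 * sd2l - s3 * sdl) / den
    if beta < 0.0:
        return LQParams(alpha=-sdl / s2, beta=0.0)
    if alpha < 0.0:
        return LQParams(alpha=0.0, beta=-sd2l / s4)
    return LQParams(alpha=alpha, beta=beta)


def reconstruct_alpha_beta_general(endpoints: Sequence[tuple[float, float]]) -> LQParams:
    """LQ parameters from >= 2 (sf, dose) endpoints, constrained >= 0.

    Normal-equation solution of min sum_i (alpha*D_i + beta*D_i^2 + ln SF_i)^2
    (a zero-intercept regression: SF(0) = 1 is built in).  A negative
    unconstrained parameter triggers the single-parameter constrained
    solution for the other; if both come out negative (possible only for
    pathological inputs) the constrained branch with the smaller residual
    wins.
    """
    if len(endpoints) < 2:
        raise ValueError("need at least 2 endpoints")
    sf = np.array([e[0] for e in endpoints], dtype=float)
    d = np.array([e[1] for e in endpoints], dtype=float)
    if np.any(d <= 0):
        raise ValueError("endpoint doses must be positive")
    if np.unique(d).size < 2:
        raise ValueError("endpoint doses must be distinct")
    if np.any(sf <= 0) or np.any(sf >= 1):
        raise ValueError("sf values must be in (0, 1)")
    logsf = np.log(sf)
    s2, s3, s4 = (np.sum(d**k) for k in (2, 3, 4))
    sdl = float(np.sum(d * logsf))
    sd2l = float(np.sum(d * d * logsf))
    den = s3 * s3 - s2 * s4
    alpha = (s4 * sdl - s3 * sd2l) / den
    beta = (s2 * sd2l - s3 * sdl) / den
    if alpha >= 0.0 and beta >= 0.0:
        return LQParams(alpha=alpha, beta=beta)
    cand = []
    if beta < 0.0:
        cand.append(LQParams(alpha=max(-sdl / s2, 0.0), beta=0.0))
    if alpha < 0.0:
        cand.append(LQParams(alpha=0.0, beta=max(-sd2l / s4, 0.0)))

    def rss(lq: LQParams) -> float:
        r = lq.alpha * d + lq.beta * d * d + logsf
        return float(r @ r)

    return min(cand, key=rss)


def predict_proton_curve(photon: LQParams, let: float, model: FlintModel) -> LQParams:
    """Predicted proton LQ curve for a photon curve at a given LET_d.

    Maps the photon doses at SF e^-1 and e^-3 through each endpoint's
    slope/intercept law, then reconstructs (alpha_p, beta_p) through the
    two predicted points.
    """
    if let < 0:
        raise ValueError("LET must be non-negative")
    d1x = dose_for_sf(photon, model.SF1)
    d2x = dose_for_sf(photon, model.SF2)
    d1p = predict_endpoint(d1x, let, model.sf1_params)
    d2p = predict_endpoint(d2x, let, model.sf2_params)
    return reconstruct_alpha_beta_two_point(d1p, d2p)


def predict_rbe(
    photon: LQParams,
    let: float,
    model: FlintModel,
    *,
    dose: float | None = None,
    sf: float | None = None,
) -> float:
    """RBE of the predicted proton curve against the photon reference.

    Exactly one of ``dose`` (iso-dose RBE at a physical proton dose, Gy)
    or ``sf`` (iso-survival RBE at a survival level) must be given.
    """
    if (dose is None) == (sf is None):
        raise ValueError("specify exactly one of dose= or sf=")
    proton = predict_proton_curve(photon, let, model)
    if dose is not None:
        return rbe_at_dose(photon, proton, dose)
    return rbe_at_iso_survival(photon, proton, sf)


def rbe_iso_survival_single_endpoint(
    d_x: float, let: float, params: EndpointFunctionParams
) -> float:
    """Iso-survival RBE of a single-endpoint model.

    RBE = D_x / D_p = 1 / (c*e^{-f*LET} + p*LET / D_x): the algebraic form
    showing RBE rises with photon radioresistance (large D_x) and drops
    below unity for sufficiently radiosensitive cells when the intercept
    term dominates.
    """
    if d_x <= 0:
        raise ValueError("photon endpoint dose must be positive")
    return 1.0 / (float(slope(let, params)) + float(intercept(let, params)) / d_x)


# ---------------------------------------------------------------------------
# Uncertainty propagation
# ---------------------------------------------------------------------------

def _predict_outputs(theta8: np.ndarray, let: float, model: FlintModel,
                     dose: float | None, sf: float | None) -> np.ndarray:
    m = FlintModel.from_theta(theta8[:6])
    photon = LQParams(alpha=float(theta8[6]), beta=float(theta8[7]))
    proton = predict_proton_curve(photon, let, m)
    if dose is not None:
        rbe = rbe_at_dose(photon, proton, dose)
    else:
        rbe = rbe_at_iso_survival(photon, proton, sf)
    return np.array([proton.alpha, proton.beta, rbe])


def prediction_uncertainty(
    photon: LQParams,
    let: float,
    model: FlintModel,
    *,
    dose: float | None = None,
    sf: float | None = None,
    rel_step: float = 1e-6,
) -> dict[str, float]:
    """Delta-method standard errors of (alpha_p, beta_p, RBE).

    Propagates the model's 6x6 parameter covariance and the photon curve's
    (alpha, beta) covariance (assumed independent of each other) through
    the prediction by central finite differences.  The 95% confidence band
    convention is +/- 1.96 standard errors.
    """
    if model.cov is None:
        raise ValueError("model covariance is required")
    if photon.cov is None:
        raise ValueError("photon covariance is required")
    if (dose is None) == (sf is None):
        raise ValueError("specify exactly one of dose= or sf=")
    theta = np.concatenate([model.theta(), [photon.alpha, photon.beta]])
    C = np.zeros((8, 8))
    C[:6, :6] = model.cov
    C[6:, 6:] = photon.cov
    J = np.zeros((3, 8))
    for j in range(8):
        h = rel_step * max(abs(theta[j]), 1e-3)
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h
        tm[j] -= h
        J[:, j] = (
            _predict_outputs(tp, let, model, dose, sf)
            - _predict_outputs(tm, let, model, dose, sf)
        ) / (2.0 * h)
    var = np.einsum("ij,jk,ik->i", J, C, J)
    se = np.sqrt(np.maximum(var, 0.0))
    return {"alpha_p": float(se[0]), "beta_p": float(se[1]), "rbe": float(se[2])}


# ---------------------------------------------------------------------------
# Shipped default parameters (L2-norm fit to the compiled training data)
# ---------------------------------------------------------------------------

def _default_model() -> FlintModel:
    se = np.array(
        [2.439889e-02, 7.931656e-03, 9.021992e-03, 5.593340e-02, 1.341988e-02, 3.257196e-02]
    )
    cov = np.diag(se**2)
    off = {
        (0, 1): 1.072615e-04,
        (0, 2): 6.169650e-05,
        (0, 3): 1.783393e-04,
        (0, 4): -2.609667e-05,
        (0, 5): -8.508367e-05,
        (1, 2): 6.242400e-05,
        (1, 3): -4.298168e-05,
        (1, 4): -2.548386e-05,
        (1, 5): -6.796549e-05,
        (2, 3): -6.503621e-05,
        (2, 4): -2.627735e-05,
        (2, 5): -7.880709e-05,
        (3, 4): 3.983314e-04,
        (3, 5): 6.113882e-04,
        (4, 5): 4.084385e-04,
    }
    for (i, j), v in off.items():
        cov[i, j] = cov[j, i] = v
    return FlintModel(
        sf1_params=EndpointFunctionParams(c=1.041543e00, f=4.708586e-02, p=2.376115e-02),
        sf2_params=EndpointFunctionParams(c=1.045578e00, f=3.213278e-02, p=6.550494e-02),
        cov=cov,
    )


#: Published six-parameter fit (with full covariance) shipped as the default.
TABLE_DEFAULT: FlintModel = _default_model()
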