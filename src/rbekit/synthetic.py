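"""Synthetic paired photon/proton survival datasets.

The generator emulates the statistical structure of compiled survival-data
tables: per-cell-line photon LQ parameters drawn from log-normal
radiosensitivity distributions, proton endpoint doses produced by the
LET-dependent slope/intercept law with multiplicative log-normal noise,
and proton (alpha, beta) obtained by the same two-point reconstruction the
model uses.  Records deliberately violating each data-quality exclusion
rule can be appended to exercise the filtering machinery.

What it does *not* emulate: dose-point-level survival scatter (records
are already LQ-summarized), inter-laboratory assay differences, and the
heavy-tailed LET estimation error of literature compilations — so tests
passing on these data show correctness of the fitting machinery, not
robustness to every pathology of real compilations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
import numpy as np

from .dataset import PairedExperiment
from .flint import FlintModel, predict_endpoint
from .lqm import LQParams

__all__ = ["GeneratorConfig", "generate"]

_SF1, _SF2 = math.exp(-1.0), math.exp(-3.0)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition parameters of the synthetic-data generator.

    Defaults mirror the experimental regime the model targets: proton
    LET_d on the in-house grid {1.2, 2.6, 9.9} keV/um (set ``let_range``
    for a 0.5-37.8 keV/um continuum instead), photon D_37% log-normal
    with median 2.5 Gy, photon (alpha/beta)_x log-normal with median
    10 Gy, and 10% multiplicative noise on the proton endpoint doses.
    """

    n_cell_lines: int = 30
    let_values: tuple[float, ...] | None = (1.2, 2.6, 9.9)
    let_range: tuple[float, float] | None = None
    true_params: FlintModel = field(default_factory=FlintModel.identity)
    photon_d37_median: float = 2.5
    photon_d37_log_sd: float = 0.35
    photon_ab_ratio_median: float = 10.0
    photon_ab_ratio_log_sd: float = 0.5
    endpoint_noise_cv: float = 0.10
    endpoint_noise_corr: float = 0.8
    seed: int = 0
    contamination: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_cell_lines <= 0:
            raise ValueError("n_cell_lines must be positive")
        if (self.let_values is None) == (self.let_range is None):
            raise ValueError("specify exactly one of let_values or let_range")
        for name in ("photon_d37_median", "photon_d37_log_sd",
                     "photon_ab_ratio_median", "photon_ab_ratio_log_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.endpoint_noise_cv < 0:
            raise ValueError("endpoint_noise_cv must be non-negative")
        if not (-1.0 < self.endpoint_noise_corr < 1.0):
            raise ValueError("endpoint_noise_corr must be in (-1, 1)")


CONTAMINATION_RULES = (
    "beta_nonpositive",
    "hypoxic",
    "radioresistant_d10",
    "viability_assay",
    "high_let",
    "low_energy_photon",
)


def _photon_from_d37_ab(d37: float, ab_ratio: float) -> LQParams:
    """Photon (alpha, beta) with the requested D at SF e^-1 and alpha/beta.

    Solves alpha*D + beta*D^2 = 1 with alpha = ab_ratio * beta, and
    attaches a plausible fitted-parameter covariance (relative errors
    with the strongly negative alpha-beta correlation typical of LQ fits).
    """
    beta = 1.0 / (ab_ratio * d37 + d37 * d37)
    alpha = ab_ratio * beta
    sa, sb = 0.10 * alpha, 0.25 * beta
    rho = -0.8
    cov = np.array([[sa * sa, rho * sa * sb], [rho * sa * sb, sb * sb]])
    return LQParams(alpha=alpha, beta=beta, cov=cov)


def _one_record(rng, cfg: GeneratorConfig, cell_line: str, let: float) -> tuple[PairedExperiment, int]:
    sigma = math.sqrt(math.log(1.0 + cfg.endpoint_noise_cv**2))
    rho = cfg.endpoint_noise_corr
    resampled = 0
    while True:
        d37 = cfg.photon_d37_median * math.exp(rng.normal(0.0, cfg.photon_d37_log_sd))
        ab = cfg.photon_ab_ratio_median * math.exp(rng.normal(0.0, cfg.photon_ab_ratio_log_sd))
        photon = _photon_from_d37_ab(d37, ab)
        d1x = _dose_at(photon, 1.0)
        d2x = _dose_at(photon, 3.0)
        m1 = predict_endpoint(d1x, let, cfg.true_params.sf1_params)
        m2 = predict_endpoint(d2x, let, cfg.true_params.sf2_params)
        # noise on the two endpoint doses of one record is strongly
        # correlated: both derive from the same fitted survival curve
        z1 = rng.normal()
        z2 = rho * z1 + math.sqrt(1.0 - rho * rho) * rng.normal()
        d1p = m1 * math.exp(sigma * z1)
        d2p = m2 * math.exp(sigma * z2)
        # only pairs strictly inside the alpha>0, beta>0 interpolation
        # region sqrt(3)*d1 < d2 < 3*d1 yield records that survive the
        # beta<=0 exclusion rule; others (the law itself predicts
        # near-linear curves at high LET) are redrawn wholesale, the same
        # selection the exclusion filter applies to real compilations
        if math.sqrt(3.0) * d1p < d2p < 3.0 * d1p:
            break
        resampled += 1
        if resampled > 5000:
            raise RuntimeError(
                f"no clean draw at LET {let:g} keV/um; true_params admit no "
                "strictly-positive-beta records there"
            )
    from .flint import reconstruct_alpha_beta_two_point

    proton = reconstruct_alpha_beta_two_point(d1p, d2p)
    sa, sb = 0.10 * max(proton.alpha, 1e-6), 0.25 * max(proton.beta, 1e-6)
    cov = np.array([[sa * sa, -0.8 * sa * sb], [-0.8 * sa * sb, sb * sb]])
    proton = LQParams(alpha=proton.alpha, beta=proton.beta, cov=cov)
    return (
        PairedExperiment(
            cell_line=cell_line,
            photon=photon,
            proton=proton,
            let_d=let,
            photon_source="6 MV",
            assay="clonogenic",
            oxygenation="normoxic",
            source_tag="synthetic",
        ),
        resampled,
    )


def _dose_at(lq: LQParams, neg_logsf: float) -> float:
    disc = lq.alpha**2 + 4.0 * lq.beta * neg_logsf
    return 2.0 * neg_logsf / (lq.alpha + math.sqrt(disc))


def _contaminated(rng, cfg: GeneratorConfig, rule: str, idx: int) -> PairedExperiment:
    from dataclasses import replace

    let = 5.0
    rec, _ = _one_record(rng, cfg, f"CONTAM-{rule}-{idx}", let)
    if rule == "beta_nonpositive":
        bad = LQParams(alpha=rec.proton.alpha, beta=-0.01)
        return replace(rec, proton=bad, source_tag=f"contamination:{rule}")
    if rule == "hypoxic":
        return replace(rec, oxygenation="hypoxic", source_tag=f"contamination:{rule}")
    if rule == "radioresistant_d10":
        resistant = LQParams(alpha=0.04, beta=0.0004)  # D_10% ~ 45 Gy
        return replace(rec, photon=resistant, source_tag=f"contamination:{rule}")
    if rule == "viability_assay":
        return replace(rec, assay="viability", source_tag=f"contamination:{rule}")
    if rule == "high_let":
        return replace(rec, let_d=45.0, source_tag=f"contamination:{rule}")
    if rule == "low_energy_photon":
        return replace(rec, photon_source="180 kVp", source_tag=f"contamination:{rule}")
    raise ValueError(f"unknown contamination rule {rule!r}")


def generate(config: GeneratorConfig) -> tuple[list[PairedExperiment], dict]:
    """Generate a paired dataset plus a ground-truth sidecar.

    Deterministic for a fixed ``config.seed``.  The sidecar records the
    generating six-parameter vector, the per-rule contamination counts,
    and how many endpoint draws were rejected by the interpolation-region
    constraint.
    """
    rng = np.random.default_rng(config.seed)
    records: list[PairedExperiment] = []
    n_resampled = 0
    if config.let_values is not None:
        combos = [
            (f"CL{i:04d}", let)
            for i in range(config.n_cell_lines)
            for let in config.let_values
        ]
    else:
        lo, hi = config.let_range
        combos = [
            (f"CL{i:04d}", float(rng.uniform(lo, hi))) for i in range(config.n_cell_lines)
        ]
    for cell_line, let in combos:
        rec, resampled = _one_record(rng, config, cell_line, let)
        records.append(rec)
        n_resampled += resampled
    for rule, count in config.contamination.items():
        if rule not in CONTAMINATION_RULES:
            raise ValueError(f"unknown contamination rule {rule!r}")
        for i in range(count):
            records.append(_contaminated(rng, config, rule, i))
    truth = {
        "theta": [float(v) for v in config.true_params.theta()],
        "n_clean": len(combos),
        "n_resampled_draws": n_resampled,
        "contamination": dict(config.contamination),
        "seed": config.seed,
    }
    return records, truth
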