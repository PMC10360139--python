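"""Quantitative self-checks of the modelling pipeline.

Each function runs one simulation- or property-based study end to end —
generating its own inputs, running the package's estimators, and measuring
the result — and returns plain numbers.  They are the package's verifiable
claims: closed forms agree with quadrature, constrained reconstructions
match an independent non-negative least-squares solver, the six-parameter
fit recovers known truth at realistic noise, the structure search
identifies the generating model family, and the cross-validation /
bootstrap machinery is calibrated.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import optimize

from . import selection, synthetic, validation
from .flint import (
    FlintModel,
    TABLE_DEFAULT,
    predict_proton_curve,
    predict_rbe,
    reconstruct_alpha_beta_general,
    reconstruct_alpha_beta_two_point,
    rbe_iso_survival_single_endpoint,
)
from .lqm import LQParams, dose_for_sf, mean_inactivation_dose, surviving_fraction
from .settings import NumericSettings

__all__ = [
    "lq_roundtrip_study",
    "mid_quadrature_study",
    "two_point_worked_example",
    "reconstruction_agreement_study",
    "identity_fixed_point_study",
    "parameter_recovery_study",
    "grid_search_ranking_study",
    "combination_search_study",
    "loocv_noiseless_study",
    "bootstrap_coverage_study",
    "subunity_rbe_study",
]


def lq_roundtrip_study(n_alpha: int = 21, n_beta: int = 21, n_sf: int = 21) -> dict:
    """Max relative dose<->SF round-trip error over an (alpha, beta, sf) grid."""
    worst = 0.0
    count = 0
    for alpha in np.linspace(0.0, 2.0, n_alpha):
        for beta in np.linspace(0.0, 0.2, n_beta):
            if alpha + beta == 0.0:
                continue
            p = LQParams(alpha, beta)
            for sf in np.linspace(0.01, 0.99, n_sf):
                back = surviving_fraction(p, dose_for_sf(p, sf))
                worst = max(worst, abs(back - sf) / sf)
                count += 1
    return {"max_rel_err": worst, "n": count}


def mid_quadrature_study(n_cases: int = 50, seed: int = 0) -> dict:
    """Max relative disagreement of the closed-form mean inactivation dose
    against adaptive quadrature on random curves."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_cases):
        p = LQParams(rng.uniform(0.0, 1.5), rng.uniform(0.001, 0.2))
        closed = mean_inactivation_dose(p)
        quad = mean_inactivation_dose(p, method="quadrature")
        worst = max(worst, abs(quad - closed) / closed)
    return {"max_rel_err": worst, "n": n_cases}


def two_point_worked_example() -> dict:
    """Closed-form reconstruction through (1 Gy, e^-1) and (3 Gy, e^-3)."""
    lq = reconstruct_alpha_beta_two_point(1.0, 3.0)
    return {"alpha": lq.alpha, "beta": abs(lq.beta), "n": 2}


def reconstruction_agreement_study(n_sets: int = 1000, seed: int = 1) -> dict:
    """Max |difference| between the constrained closed-form reconstruction
    and an independent non-negative least-squares solve on random endpoint
    sets (2-5 endpoints, random doses and survival levels)."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    done = 0
    while done < n_sets:
        m = int(rng.integers(2, 6))
        d = np.sort(rng.uniform(0.5, 12.0, size=m))
        if np.unique(d).size < m:
            continue
        logsf = -rng.uniform(0.2, 5.0, size=m)
        lq = reconstruct_alpha_beta_general(list(zip(np.exp(logsf), d)))
        X = np.column_stack([d, d * d])
        theta, _ = optimize.nnls(X, -logsf)
        worst = max(worst, abs(lq.alpha - theta[0]), abs(lq.beta - theta[1]))
        done += 1
    return {"max_abs_dev": worst, "n": n_sets}


def identity_fixed_point_study(n_cases: int = 100, seed: int = 2) -> dict:
    """Max deviation of the identity-parameter model from a perfect fixed
    point (proton curve = photon curve, RBE = 1) over random inputs."""
    rng = np.random.default_rng(seed)
    ident = FlintModel.identity()
    worst = 0.0
    for _ in range(n_cases):
        photon = LQParams(rng.uniform(0.05, 1.5), rng.uniform(0.005, 0.15))
        let = float(rng.uniform(0.0, 37.8))
        proton = predict_proton_curve(photon, let, ident)
        worst = max(
            worst,
            abs(proton.alpha - photon.alpha) / photon.alpha,
            abs(proton.beta - photon.beta) / photon.beta,
            abs(predict_rbe(photon, let, ident, dose=float(rng.uniform(0.5, 5.0))) - 1.0),
            abs(predict_rbe(photon, let, ident, sf=float(rng.uniform(0.02, 0.9))) - 1.0),
        )
    return {"max_dev": worst, "n": n_cases}


def parameter_recovery_study(
    n_replicates: int = 100,
    n_pairs: int = 397,
    noise_cv: float = 0.10,
    seed: int = 3,
) -> dict:
    """Fraction of replicates recovering each parameter within 3 SE.

    Each replicate generates a fresh paired dataset (LET_d uniform on
    0.5-37.8 keV/um, multiplicative endpoint noise) from the shipped
    six-parameter values, refits the model, and compares fitted-vs-true
    against the fit's own standard errors.  Returns the per-parameter
    within-3-SE rates and their minimum.
    """
    truth = TABLE_DEFAULT.theta()
    names = ["c1", "f1", "p1", "c2", "f2", "p2"]
    ss = np.random.SeedSequence(seed)
    hits = np.zeros(6)
    for child in ss.spawn(n_replicates):
        rep_seed = int(child.generate_state(1)[0] % (2**31 - 1))
        cfg = synthetic.GeneratorConfig(
            n_cell_lines=n_pairs,
            let_values=None,
            let_range=(0.5, 37.8),
            true_params=TABLE_DEFAULT,
            endpoint_noise_cv=noise_cv,
            seed=rep_seed,
        )
        records, _ = synthetic.generate(cfg)
        model, rep = selection.fit_full_model(records)
        se = np.array([rep.stderr[n] for n in names])
        hits += np.abs(model.theta() - truth) < 3.0 * se
    rates = hits / n_replicates
    return {
        "rates": dict(zip(names, rates.tolist())),
        "min_rate": float(rates.min()),
        "n": n_replicates,
    }


def grid_search_ranking_study(
    n_replicates: int = 50, n_pairs: int = 397, seed: int = 4
) -> dict:
    """Fraction of replicates in which the 7x7 slope/intercept BIC grid
    ranks the generating combination (exponential slope, linear intercept)
    first for the D_10% endpoint."""
    settings = NumericSettings(n_multistart=4)
    ss = np.random.SeedSequence(seed)
    top1 = 0
    for child in ss.spawn(n_replicates):
        rep_seed = int(child.generate_state(1)[0] % (2**31 - 1))
        cfg = synthetic.GeneratorConfig(
            n_cell_lines=n_pairs,
            let_values=None,
            let_range=(0.5, 37.8),
            true_params=TABLE_DEFAULT,
            seed=rep_seed,
        )
        records, _ = synthetic.generate(cfg)
        mat, _ = selection.function_grid_search(records, 0.10, settings=settings)
        if mat.stack().idxmin() == ("exp", "linear"):
            top1 += 1
    return {"top1_rate": top1 / n_replicates, "n": n_replicates}


def combination_search_study(n_pairs: int = 60, seed: int = 5) -> dict:
    """Size of the endpoint subset minimizing BIC in the combination search
    (the parsimonious two-endpoint structure should win on data generated
    by an LQ-consistent law)."""
    cfg = synthetic.GeneratorConfig(
        n_cell_lines=n_pairs,
        let_values=None,
        let_range=(0.5, 37.8),
        true_params=TABLE_DEFAULT,
        seed=seed,
    )
    records, _ = synthetic.generate(cfg)
    out = selection.endpoint_combination_search(records, "linear")
    best_bic_by_size = {s: r.bic for s, r in out["min_bic_by_size"].items()}
    return {
        "best_subset_size": len(out["best_subset"]),
        "min_bic_by_size": best_bic_by_size,
        "n": n_pairs,
    }


def loocv_noiseless_study(n_pairs: int = 12, seed: int = 6) -> dict:
    """Max |percent deviation| of leave-one-out predictions on noiseless
    data generated by the fitted family (self-consistency)."""
    cfg = synthetic.GeneratorConfig(
        n_cell_lines=n_pairs,
        let_values=None,
        let_range=(0.5, 30.0),
        true_params=TABLE_DEFAULT,
        endpoint_noise_cv=0.0,
        seed=seed,
    )
    records, _ = synthetic.generate(cfg)
    devs = validation.loocv(records)
    return {
        "max_abs_pct_dev": max(abs(d.percent_deviation) for d in devs),
        "n": len(devs),
    }


def bootstrap_coverage_study(
    n_devs: int = 2000, sd: float = 10.0, n_boot: int = 2000, seed: int = 7
) -> dict:
    """Coverage of the bootstrapped 68.3% interval on known-distribution
    deviations, checked against a large fresh sample; also verifies
    seed-reproducibility."""
    rng = np.random.default_rng(seed)
    devs = rng.normal(0.0, sd, size=n_devs)
    est = validation.bootstrap_intervals(devs, level=68.3, n_boot=n_boot, seed=seed)
    est2 = validation.bootstrap_intervals(devs, level=68.3, n_boot=n_boot, seed=seed)
    fresh = rng.normal(0.0, sd, size=200_000)
    coverage = float(np.mean((fresh >= est.lower) & (fresh <= est.upper)))
    return {
        "coverage": coverage,
        "reproducible": (est.lower, est.upper) == (est2.lower, est2.upper),
        "lower": est.lower,
        "upper": est.upper,
        "n": n_devs,
    }


def subunity_rbe_study(n_let: int = 20, n_dose: int = 40) -> dict:
    """Agreement rate between the algebraic sub-unity condition
    D < p*LET/(1 - c*e^{-f*LET}) and direct evaluation of the
    single-endpoint iso-survival RBE over a parameter grid."""
    p = TABLE_DEFAULT.sf1_params
    agree = 0
    total = 0
    for let in np.linspace(1.0, 37.8, n_let):
        s = p.c * math.exp(-p.f * let)
        if s >= 1.0:
            continue
        threshold = p.p * let / (1.0 - s)
        for d_x in np.linspace(0.1 * threshold, 3.0 * threshold, n_dose):
            if abs(d_x - threshold) < 1e-9 * threshold:
                continue
            rbe = rbe_iso_survival_single_endpoint(float(d_x), float(let), p)
            total += 1
            agree += (rbe < 1.0) == (d_x < threshold)
    return {"agreement_rate": agree / total, "n": total}
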