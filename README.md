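# rbekit

Empirical proton relative biological effectiveness (RBE) modelling for
radiobiology and treatment-plan evaluation.

Clinical proton therapy still plans with a fixed RBE of 1.1, even though
RBE is known to rise with the beam's dose-weighted linear energy transfer
(LET_d) and to depend on each cell line's intrinsic radiosensitivity.
`rbekit` implements an empirical model built on a robust observation: a
cell line's proton iso-survival doses are *linearly* correlated with its
photon iso-survival doses, with slope and intercept that vary smoothly
with LET_d:

    D_SF,proton = c · e^(−f·LET) · D_SF,x-ray + p · LET

Carrying two survival endpoints, SF₁ = e⁻¹ (≈37%) and SF₂ = e⁻³ (≈5%),
gives a six-parameter model (c₁, f₁, p₁, c₂, f₂, p₂).  From a photon
linear-quadratic (LQ) curve SF(D) = exp(−αD − βD²) and a LET_d value, the
model predicts the two proton endpoint doses and reconstructs α_proton
and β_proton in closed form (a zero-intercept log-survival regression
with α, β ≥ 0 enforced), hence the full proton survival curve and RBE at
any dose or survival level.  Because endpoints like D₁₀% are far better
determined than α and β themselves (their errors largely cancel through
the strongly negative α–β covariance of LQ fits), the trends the model
learns are much less noisy than the α(LET), β(LET) trends earlier
empirical models rely on.

The package covers the full workflow around that prediction:

- **`rbekit.lqm`** — LQ survival-curve mathematics: survival fractions,
  iso-survival doses, mean inactivation dose (MID), normalized L2 curve
  distances, RBE, delta-method error propagation, LQ fitting.
- **`rbekit.dataset`** — PIDE-style paired-experiment CSV I/O, the
  standard data-quality exclusion rules (β ≤ 0, hypoxia, extreme
  radioresistance, viability assays, LET_d > 37.8 keV/µm, < 200 kVp photon
  references), radiosensitivity metrics and photon–proton correlations.
- **`rbekit.flint`** — the six-parameter model itself, shipped with the
  published parameter values and full covariance, plus prediction bands.
- **`rbekit.selection`** — candidate LET-function families (7 slope × 7
  intercept), BIC scoring, the endpoint-combination search, and the final
  six-parameter fit under curve-space L2 or RBE₂Gy objectives.
- **`rbekit.benchmarks`** — the Wedenberg, McNamara and Mairani
  comparison models, retrainable on any dataset under both objectives.
- **`rbekit.validation`** — leave-one-out cross-validation and bootstrap
  prediction intervals.
- **`rbekit.synthetic`** — a generator of realistic paired survival
  datasets with known ground truth, used throughout the test suite.
- **`rbekit.voxel`** — voxel-wise RBE-weighted dose maps from
  co-registered dose and LET_d grids.

## Worked example

```python
from rbekit import LQParams, TABLE_DEFAULT, predict_proton_curve, predict_rbe
from rbekit.flint import prediction_uncertainty
import numpy as np

photon = LQParams(alpha=0.3, beta=0.03)        # photon LQ fit, Gy^-1 / Gy^-2
proton = predict_proton_curve(photon, 9.9, TABLE_DEFAULT)
rbe = predict_rbe(photon, 9.9, TABLE_DEFAULT, dose=2.0)
print(f"alpha_p = {proton.alpha:.4f} Gy^-1, beta_p = {proton.beta:.4f} Gy^-2")
print(f"RBE at 2 Gy = {rbe:.4f}")

se = prediction_uncertainty(
    LQParams(0.3, 0.03, cov=np.zeros((2, 2))), 9.9, TABLE_DEFAULT, dose=2.0
)
print(f"95% band: {rbe - 1.96*se['rbe']:.4f} .. {rbe + 1.96*se['rbe']:.4f}")
```

prints

```
alpha_p = 0.4815 Gy^-1, beta_p = 0.0148 Gy^-2
RBE at 2 Gy = 1.3430
95% band: 1.2820 .. 1.4039
```

i.e. for a typical tumour-like cell line ((α/β)ₓ = 10 Gy) in a
9.9 keV/µm proton field, the model predicts an RBE at 2 Gy of ≈1.34 —
well above the clinical 1.1 — with a ±4.6% model-parameter band.

The same prediction is available from the shell, along with dataset
filtering, model fitting, comparison and grid application:

```sh
rbekit predict --alpha-x 0.3 --beta-x 0.03 --let 9.9 --dose 2
rbekit simulate --seed 7 --out synth.csv
rbekit filter --in synth.csv --out kept.csv --report report.json
rbekit fit --in kept.csv --objective l2 --out params.yaml
rbekit compare --in kept.csv --models flint,wedenberg,mcnamara,mairani
rbekit gridapply --dose dose.txt --let let.txt --alpha-x 0.12 --beta-x 0.03 \
    --model flint --fractions 27 --out rwd.txt
```

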