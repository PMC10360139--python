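# Methods

## The model

Clonogenic survival after a single dose D is described by the linear-
quadratic (LQ) model SF(D) = exp(−αD − βD²), α in Gy⁻¹, β in Gy⁻².  The
central empirical regularity the package encodes is that iso-survival
doses transform linearly between radiation qualities: at fixed
dose-weighted LET (LET_d, keV/µm),

    D_SF,proton = slope(LET) · D_SF,x-ray + intercept(LET),

with slope(LET) = c·e^(−f·LET) (dimensionless; c is the zero-LET slope, f
a decay rate per keV/µm) and intercept(LET) = p·LET (Gy; p in Gy·µm/keV).
Two survival endpoints are carried, SF₁ = e⁻¹ and SF₂ = e⁻³, chosen
because their log-survival values (−1, −3) remove the logarithm from the
reconstruction algebra.  That yields six parameters
(c₁, f₁, p₁, c₂, f₂, p₂); the shipped defaults are the published training
fit with its full 6×6 covariance.

Given predicted endpoint doses D_i with log-survival values L_i, the
proton curve follows from the zero-intercept regression
min Σ(αD_i + βD_i² + L_i)² — "zero-intercept" because SF(0) = 1 is exact.
The normal-equation solution is closed-form; if the unconstrained α or β
is negative it is set to zero and the other parameter refit alone
(single-parameter closed forms), matching the universal α ≥ 0, β ≥ 0
fitting convention.  With two endpoints and a feasible unconstrained
solution the curve passes exactly through both points; β < 0 occurs
exactly when D₂ > 3·D₁ and α < 0 exactly when D₂ < √3·D₁, so the
"both-negative" branch is impossible for two points and resolved by
smaller residual in the general case.

RBE is a derived quantity: at survival level s it is the ratio of photon
to proton dose reaching s; at a physical proton dose d it is D_x/d where
the photon dose D_x matches the proton survival at d (a quadratic
inversion).  For a single endpoint the iso-survival RBE reduces to
1/(c·e^(−f·LET) + p·LET/D_x), which rises with photon radioresistance and
drops below 1 when D_x < p·LET/(1 − c·e^(−f·LET)) — the model's
distinctive sub-unity prediction for extremely radiosensitive cells.

## Curve distances and objectives

Model fitting minimizes one of two documented objectives over the
training records:

- **Curve-space L2** (default): per record,
  sqrt(∫₀^∞ (SF_pred − SF_meas)² dD) divided by the *measured* curve's
  mean inactivation dose MID = ∫₀^∞ SF dD; the dataset objective is the
  *sum* of these per-record distances.  Which curve normalizes, the
  integration range (all positive doses), and the summation convention
  are deliberate design choices isolated in one function
  (`lqm.curve_l2_distance`) so they can be swapped.  All integrals are
  closed-form via the scaled complementary error function (erfcx), which
  is overflow-safe; β < 0 makes them divergent, which is one reason such
  records are excluded from training data.
- **RBE₂Gy RSS**: the residual sum of squares of predicted minus measured
  RBE at a 2 Gy proton dose, the clinically typical fraction size.

Model quality is compared with the Gaussian-residual Bayesian information
criterion BIC = n·ln(objective/n) + k·ln(n), where n counts *paired
experiments* (survival curves, matching the per-experiment distance
metric) and k counts free parameters; only BIC differences matter, and a
non-positive objective is floored at 1e−12 to keep the logarithm finite.
The reduced chi-squared for the RSS objective uses σ_i = 10% of each
measured RBE₂Gy by default (configurable); per-record σ from (α, β)
covariances is used where available in the endpoint error propagation,
but a global relative σ is the documented default for RBE because most
compiled records lack covariances.

## Numerical choices

- Iso-survival doses use the numerically stable quadratic root
  2q/(α + √(α² + 4βq)), with β = 0 handled separately (the α² term can
  underflow for subnormal α).  The negative root is discarded; α = β = 0
  is rejected everywhere as a degenerate curve.
- Curve-space fits use Levenberg–Marquardt on residuals √(d_i + ε) with
  ε = 1e−12: the constant shift leaves the minimizer of Σd_i unchanged
  while bounding the residual gradient where a distance passes through
  zero; ε·n is subtracted from reported objectives.  Near-interpolating
  data (all distances → 0) defeat Gauss–Newton steps, so the
  six-parameter fit adds a Nelder–Mead polish plus LM restart whenever
  the objective is very small or the iteration cap was hit.  The fit is
  deterministic: one fixed start (1, 0.03, 0.02, 1, 0.03, 0.02).
- Parameter covariances are σ²(JᵀJ)⁻¹ with σ² = objective/(n − k) from
  the final Jacobian — for the L2 objective this treats √distance as the
  Gaussian residual, a documented convention.  Prediction bands propagate
  the 6×6 model covariance and the photon (α, β) covariance (assumed
  independent) by central finite differences; 95% bands are ±1.96 SE.
- Candidate-family fits (7 slope × 7 intercept forms, including offset
  exponentials, Gaussian, logarithmic, inverse-gamma and Poisson-like
  shapes) minimize the relative square endpoint distance
  Σ((pred−meas)/meas)², which makes BIC rankings invariant under uniform
  dose rescaling.  Families with shape parameters (h, k, s) get 16
  log-uniform multi-starts from a fixed seed (bit-for-bit reproducible
  grids); every family nesting a simpler one is additionally seeded from
  the nested fit with the extra parameters neutral, which guarantees
  nested-objective monotonicity.  Out-of-domain evaluations (gamma poles,
  logs of non-positive arguments) return large penalty residuals rather
  than raising.

## Data-quality filters

Training records are excluded when: β ≤ 0 in either radiation quality
(divergent integrals and α/β ratios; applied to *either* quality as the
stricter reading); oxygenation is hypoxic (OER-inflated RBE); photon or
proton D₁₀% exceeds 40 Gy (the LQ extrapolation is untrustworthy at such
doses — implemented as a reusable threshold rather than a hard-coded
cell-line name, with an explicit name list also supported); survival was
measured by viability rather than clonogenic assay; LET_d exceeds
37.8 keV/µm (strict inequality — the boundary value is kept); or the
photon reference is a kVp source below 200 kVp (parsed from the source
descriptor; megavoltage and Co-60/Cs-137 pass, unparseable descriptors
are kept because the rule targets known low-energy x-ray sources).
A record failing several rules is counted once per rule but excluded
once, so kept + uniquely-excluded = total.

## The synthetic-data generator

The generator emulates the structure of compiled paired survival tables.
Per record: a photon D₃₇ (dose at SF e⁻¹) is drawn log-normal (median
2.5 Gy, log-SD 0.35) and an (α/β)ₓ ratio log-normal (median 10 Gy,
log-SD 0.5), fixing the photon curve; the proton endpoint doses follow
the slope/intercept law at the record's LET_d with multiplicative
log-normal noise (CV 10% by default).  Noise on the two endpoints of one
record is correlated (ρ = 0.8) because both derive from the same fitted
survival curve — independent noise would be unphysical and makes the
implied curvature far noisier than real data.  The proton (α, β) then
come from the same two-point reconstruction the model uses.  Draws whose
realized endpoint pair leaves the strict α > 0, β > 0 interpolation
region (√3·D₁ < D₂ < 3·D₁) are redrawn wholesale and counted: at high
LET the law itself predicts near-linear curves, and this rejection
mirrors the β ≤ 0 exclusion a real compilation undergoes.  LET_d comes
either from the three-point in-house grid {1.2, 2.6, 9.9} keV/µm
(default) or uniformly from a 0.5–37.8 keV/µm continuum.  Contamination
records violating each exclusion rule can be appended for filter tests.

What the generator does *not* emulate: dose-point-level survival scatter
(records arrive LQ-summarized), inter-laboratory assay and LET-estimation
differences, and any misspecification of the slope/intercept law itself.
Tests passing on these data therefore demonstrate correctness and
calibration of the estimation machinery under the model's own
assumptions, not robustness to every pathology of literature data.

## Validation machinery

Leave-one-out cross-validation treats one paired experiment as the unit:
each fold refits the six parameters from the fixed start on n−1 records
and predicts the held-out record's RBE at dose levels {0.5, 1, 2, 5} Gy;
deviations are 100·(pred − meas)/meas.  Prediction intervals are
percentile bootstrap (default 10,000 resamples, mandatory seed): each
resample's central-interval endpoints are averaged, giving asymmetric
intervals that are reproducible by seed.  Deviations are pooled across
LET by default.  Interval width typically shrinks with dose level —
higher doses pin survival down better — and the per-dose-level summary
flags whether that monotonicity holds.

## Comparison models

Wedenberg (RBE_max = 1 + q·LET/(α/β)ₓ, RBE_min = 1, q = 0.434 Gy·µm/keV)
and McNamara (RBE_max = 0.99064 + 0.35605·LET/(α/β)ₓ, RBE_min = 1.1012 −
0.0038703·√(α/β)ₓ·LET) use their original published coefficients.  The
Mairani-style model is implemented in the documented nonlinear form
RBE_max = 1 + (k₁/(α/β)ₓ)·LET·e^(−k₂·LET), RBE_min = 1 + k₃·LET, with
package-chosen default coefficients (clearly labelled as such in the
shipped YAML): since every head-to-head comparison retrains all models on
the same data under the same objectives, the retrained coefficients —
not the baselines — carry the comparison.  All three models require
βₓ > 0 because (α/β)ₓ appears in their forms.  Comparisons can restrict
the LET range (< 30 or < 20 keV/µm) to match the ranges the original
models were trained on; this changes n and hence every BIC.

## Problem sizes in the shipped studies

The self-check studies (`rbekit.qc`, driven by `scripts/acceptance.py`
and the test suite) use: 1,000 random endpoint sets for the
reconstruction/NNLS agreement; 100 replicates of n = 397 pairs (the
training-data scale) at 10% noise for parameter recovery; 50 replicates
of n = 397 pairs for the family-ranking study and a single n = 60 dataset
for the endpoint-combination search, sizes at which the BIC
discrimination of interest is already decisive; a 12-record noiseless
dataset for LOOCV self-consistency; and 2,000 known-distribution
deviations for bootstrap coverage.  The replicated searches run with 4
multi-starts per multi-modal family (the fixed-seed nested-fit seeding
makes additional starts redundant there; the package default remains 16).

## Known limitations

- The shipped default parameters apply to protons with LET_d up to
  37.8 keV/µm; beyond that they extrapolate.
- The model needs photon LQ parameters as input; in a clinical setting
  these are rarely patient-specific.
- Voxel application evaluates RBE at per-fraction dose with a single
  tissue (α, β) per call and performs no smoothing, interpolation, or
  in-vivo (hypoxia, immune) modelling; dose/LET grids must be
  co-registered upstream.
- The exact residual and σ conventions behind published goodness-of-fit
  tables are not fully specified in the source material, so absolute BIC
  and χ²/ν values are convention-sensitive; rankings are the robust
  comparison.
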