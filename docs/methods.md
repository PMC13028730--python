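# Methods

## Structural model

One oral dose `D` (mg/kg) splits into two gut depots. Depot 1 holds
`F1·D` and empties with first-order rate ka₁ from dose time; depot 2
holds `(1−F1)·D` and empties with rate ka₂ starting at the lag `Tlag₂`.
Both feed a central compartment (apparent volume V₁, L/kg) that exchanges
with a peripheral compartment (Q, V₂) and is cleared linearly (CL,
L/h/kg). The solution is the sum of two tri-exponential terms in the
macro rate constants λ₁ > λ₂ > 0, the roots of
`s² − (k₁₀+k₁₂+k₂₁)s + k₁₀·k₂₁` with `k₁₀ = CL/V₁`, `k₁₂ = Q/V₁`,
`k₂₁ = Q/V₂`, each term time-shifted by its path's start and zero before
it. The terminal log-slope is `min(λ₂, ka₁, ka₂)`, so slow absorption
produces flip-flop kinetics — relevant here because the typical ka₁
(0.086 h⁻¹) is of the same order as λ₂.

Units are canonical throughout: time h, concentration µg/mL (≡ mg/L),
dose mg/kg, volumes L/kg, clearances L/h/kg. Dosing per kilogram makes
body weight cancel against the per-kg volumes; weight is retained only as
a candidate covariate. Clearance printed in mL/min(/kg) converts as
0.1 mL/min/kg = 0.006 L/h/kg, which makes the model's AUC = dose/CL ≈ 33
µg·h/mL consistent with the non-compartmental exposures — the check that
fixes the unit convention. Because dosing is oral, CL, Q and the volumes
are apparent (CL/F parameterisation); absolute bioavailability is not
identifiable from oral data and is treated as 1 inside the model.

**Numerical choices.** When an absorption rate coincides with a
disposition root the partial-fraction coefficients cancel catastrophic-
ally; instead of a separate confluent-limit branch, the rate is nudged
off the root by a relative 10⁻⁸ before evaluation. Both the induced model
perturbation and the residual cancellation error are O(10⁻⁸), far below
the 10⁻⁵ agreement the test suite enforces against the ODE oracle — a
four-state initial-value integration (LSODA, rtol 10⁻¹⁰) that ships
permanently as the independent cross-check, never as the production path.
The batched prediction used in estimation is a numba-compiled kernel with
a pure-numpy fallback; a test asserts the two agree to machine precision.

## Hierarchical model and estimation

Individual parameters are lognormal:
`P_i = P_pop · exp(β·x_i) · exp(η_i)`, `η_i ~ N(0, ω²)`, independently per
parameter (no η correlations). The published ω values are interpreted as
standard deviations of the log parameters (the printed "%" labels cannot
be percent CVs, since several exceed 1). F1 is bounded, so its
variability and covariate effects act on the logit scale with ω_F1
reinterpreted accordingly — a documented deviation, since the source
analysis does not state F1's distribution. Covariates: the formulation
indicator (1 for the nanocapsule arm) acts multiplicatively,
`P·exp(β)`; body weight and age enter as power models on the ratio to
the study median. Residual error is proportional,
`y = f·(1 + b·ε)`; additive and combined variants are available as
configuration options for error-model comparison but the final model is
proportional. The final-model IIV structure has random effects on every
parameter except Q.

**SAEM.** One chain; the E-step proposes each subject's transformed
parameters with (i) an independent draw from the current prior and
(ii) componentwise random-walk Metropolis sweeps whose scales adapt
toward 30–40% acceptance during exploration. The M-step updates the
linear-in-transform parts (typical values, covariate coefficients, ω) in
closed form from stochastically smoothed sufficient statistics, the
proportional error coefficient from smoothed squared relative residuals,
and the no-variability parameter (Q) by a damped one-dimensional Newton
step on the complete-data likelihood. Defaults: 500 exploration
iterations (step 1) then 200 smoothing iterations with step
`1/(k−K₁)^0.7`; during exploration the variances may shrink by at most 5%
per iteration (anti-collapse guard) and ω is floored at 10⁻⁴ with a
warning. Everything is deterministic given the seed. A model with no
random effects at all degenerates to ordinary maximum likelihood and is
fitted directly by Nelder–Mead + BFGS instead.

**Parameter bounds.** Estimation constrains each parameter to a plausible
physiological domain (e.g. absorption rates ≤ 50 h⁻¹, lag ≤ 24 h). The
bound on ka₂ matters: a depot that empties entirely between two sampling
times is indistinguishable from an instantaneous input, so the likelihood
is flat in ka₂ upward of a few h⁻¹ and an unconstrained fit drifts to
arbitrarily large values (with the published ω_ka2 = 1.28 many simulated
dogs genuinely absorb that fast). Estimates at the bound are reported
as-is; they indicate the ridge, not a converged interior optimum.

**Likelihood, EBEs, standard errors.** Empirical Bayes estimates are
per-subject conditional modes (L-BFGS with batched finite-difference
gradients). The marginal −2LL uses importance sampling with a Gaussian
proposal at the mode (covariance from a batched finite-difference
Hessian), or a Laplace approximation; with the large ω values of this
model both carry approximation error of several points, which is why no
absolute −2LL is used as an acceptance quantity and why covariate
decisions do not rest on raw likelihood differences (below). RSEs come
from a linearised (FO around the EBEs) Fisher information with delta-
method transformation to the natural scale.

## Covariate search

The forward/backward stepwise search uses the conditional two-stage
likelihood-ratio statistic: regress the per-subject posterior-mean
deviations of a parameter (chain means from the E-step, not EBE modes —
the per-subject lag/rate posteriors are multimodal under sparse sampling
and modes collapse to the prior) on the candidate covariate and take
`n·log(SS0/SS1)` as the −2LL drop. Computed from a fit that does not
contain the candidate, subjects are exchangeable with respect to the
covariate under the null, so the statistic is χ²₁-calibrated regardless
of shrinkage, and it is deterministic given the fit. Each forward round
admits every candidate above the χ²₁(0.05) threshold 3.84 at once and
refits; the backward pass rescans each retained coefficient against a
shortened refit *without* it and removes those below χ²₁(0.01) = 6.63.
Direct marginal-likelihood differences between separately fitted models
were rejected for this role: with ω values above 1 the combination of
stochastic fit-to-fit variation and Laplace/importance-sampling bias
produces ΔOFV noise an order of magnitude above the decision thresholds.

A known limitation: a formulation effect on V₁ is structurally confounded
with the true V₂ effect at realistic sample sizes — peripheral-volume
misfit leaks into V₁'s individual estimates through Q, and with
ω_V1 = 1.44 genuine finite-sample arm imbalances of ~0.7 on the log scale
occur in roughly a tenth of simulated studies. Selection experiments
therefore use formulation on Tlag₂/V₂/CL plus weight and age power
effects (the candidate covariates of the source analysis) as the decoy
set.

## Non-compartmental analysis

λz is fitted by log-linear least squares over contiguous terminal windows
of 3–6 points strictly after Tmax, best adjusted R² winning and ties
going to more points; profiles peaking too late fall back to the last
three points. AUC is linear trapezoidal with a (0, 0) origin prepended
for oral profiles (a log-down variant exists behind a flag);
AUC₀₋∞ adds `C_last/λz`, AUMC the matching analytic tail, and t½, CL/F,
Vd/F, MRT follow by definition. Group comparison uses Welch's t-test by
default (Student's pooled test behind a flag); F_rel is the ratio of
arm-mean AUC₀₋∞ and absolute bioavailability requires a user-supplied
intravenous reference exposure — it is never hard-coded.

## Diagnostics

Population predictions use covariate-adjusted typical values; individual
predictions plug in the EBEs; IWRES standardises by the fitted error
model at the individual prediction. η-shrinkage is `100·(1 − SD(η̂)/ω)`.
The VPC simulates replicate studies with the original design and
covariates, binning at the exact nominal times (all subjects share the
schedule), with 90% prediction bands around the 10th/50th/90th
percentiles. NPDE decorrelates each subject's observation vector with the
simulated mean and Cholesky factor and maps rank probabilities through
the inverse normal. The bootstrap resamples subjects with replacement
within each formulation arm (preserving the two-arm balance), refits each
replicate from the final estimates with a shortened schedule (exploration
200 / smoothing 100 — disclosed in the result metadata), and reports
medians with 5th/95th percentiles.

## Virtual study generator

The generator is the package's standing replacement for the raw study
data. Defaults reproduce the published design exactly — 9 dogs per arm,
0.2 mg/kg, sampling at {0.5, 1, 2, 4, 6, 8, 12, 24, 36, 48, 60} h,
weights uniform on 10.5–16.6 kg, ages uniform on 9–48 months — and the
generating parameters are the published population estimates (ka₁ 0.086,
ka₂ 1.82 h⁻¹, F1 0.85, Tlag₂ 1.22 h, CL 0.006 L/h/kg, V₁ 0.049, Q 0.24,
V₂ 0.134 L/kg; β_Tlag₂ 0.74, β_V₂ 1.11; ω = {0.38, 1.28, 0.67, 0.38,
0.32, 1.44, 0.65}; b 0.19). Proportional noise that would produce a
non-positive concentration is redrawn pointwise (configurable), matching
a dataset in which every observation sits above the quantification limit.
The default design yields 198 observations; the real study reported 196
from the same design, and which two samples were missing is not stated —
the generator produces the complete grid. Weight and age are simulated
but do not influence concentrations; they exist to exercise the covariate
search's null behaviour. What the generator does **not** emulate: missing
samples, assay error structure beyond proportional Gaussian noise,
between-occasion variability, enterohepatic recirculation mechanisms
(the double peak is phenomenological), or food/surgery effects — so
passing tests certify the estimation machinery under the model's own
assumptions, not robustness to real-data violations of them.

## Problem sizes used in the checks

Parameter recovery runs at 100 dogs per arm with the study schedule —
large enough that the well-determined parameters (CL, F1, b, ka₁, Tlag₂)
recover within their published relative standard errors, while ka₂ and V₁
(printed RSEs 51% and 56%, bootstrap intervals spanning an order of
magnitude) remain weakly identified, as in the source analysis. Covariate
selection-consistency experiments use 20 replicates of 50 dogs/arm with
effects and 50 effect-free replicates of 30 dogs/arm; bootstrap coverage
uses 200 replicates on a 100-dog study; NPDE calibration uses ≥500
observations, where the pooled variance of the rank-based statistic is
stable despite within-subject dependence. Analytic/ODE equivalence is
checked on 1000 log-uniform draws spanning ±10× the typical values.

## Known limitations

- ka₂, ω_ka₂, V₁ and ω_V₁ are weakly identified under the 11-point
  schedule; their estimates (and anything downstream of their EBEs)
  should be read with the bootstrap intervals, not the point values.
- The importance-sampling/Laplace marginal likelihood carries
  points-level approximation error at ω > 1; AIC comparisons across
  structurally different models are indicative, not exact.
- External validation against the published literature datasets is out of
  scope (their digitised mean profiles are not shipped);
  `external_validate` accepts any user-supplied mean-profile CSV in the
  canonical format.
- The MPE%/RMSE% formulas are the relative-error forms (root taken over
  the mean squared relative error), consistent with percent-scale
  reporting.
- The source table prints ka₂'s unit as hours; it is treated as a
  first-order rate constant (h⁻¹) throughout, as the model diagram
  defines it. Likewise Q is taken as per-kilogram (L/h/kg) for
  dimensional consistency with the per-kg volumes.
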