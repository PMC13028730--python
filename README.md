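# pkstudy

Population pharmacokinetics of orally administered meloxicam in dogs,
comparing a free-drug solution with polymer nanocapsules (NC). The package
implements the full analysis workflow for a two-arm single-dose study —
non-compartmental analysis, nonlinear mixed-effects estimation, model
diagnostics and external validation — together with a virtual-study
generator that reproduces the statistical structure of the design
(18 female dogs, 9 per arm, 0.2 mg/kg orally, plasma sampled at
0.5–60 h), so every method can be exercised and checked end to end.

It is intended for pharmacometricians and veterinary-PK researchers who
want a transparent, scriptable reimplementation of this analysis rather
than a GUI tool.

## The model

Plasma kinetics follow a two-compartment disposition with **dual
first-order oral absorption**: a fraction F1 of the dose is absorbed with
rate constant ka₁ from dose time, the remaining 1 − F1 with rate ka₂
after a lag Tlag₂ — a phenomenological description of the secondary
absorption peak seen after oral meloxicam. With central volume V₁,
peripheral volume V₂, inter-compartmental clearance Q and linear
clearance CL (all apparent, per kg), the concentration is the sum of two
time-shifted tri-exponential terms with macro rate constants λ₁, λ₂
solving s² − (k₁₀+k₁₂+k₂₁)s + k₁₀k₂₁ = 0.

Between-subject variability is lognormal,

    P_i = P_pop · exp(β·x_i) · exp(η_i),   η_i ~ N(0, ω²),

with covariate effects β (formulation indicator; optional power models on
body weight and age), logit-scale variability for the bounded F1, and
proportional residual error y = f·(1 + b·ε). The final model carries
random effects on every parameter except Q and formulation effects on
Tlag₂ and V₂.

Estimation is **SAEM** (stochastic-approximation EM with a
Metropolis-within-Gibbs E-step), the marginal likelihood is computed by
importance sampling or a Laplace approximation around the empirical Bayes
estimates, and standard errors come from a linearised Fisher information.
Diagnostics include goodness-of-fit residuals (IWRES), η-shrinkage,
visual predictive checks, normalized prediction distribution errors and a
stratified nonparametric bootstrap; external predictive performance is
quantified by MPE% and RMSE% on the relative scale.

## Worked example

```python
from pkstudy import (SaemConfig, fit_saem, group_compare, nca_dataset,
                     simulate_study)
from pkstudy.cli import default_init

data, truth = simulate_study(n_per_arm=20, seed=5)   # virtual study
nca = group_compare(nca_dataset(data, on_error="skip"))
print(f"F_rel = {nca.frel:.2f}")

fit = fit_saem(data, default_init("final"),
               SaemConfig(k1=300, k2=200, seed=4, ll_method="laplace"))
print(fit.estimates.theta["cl"], fit.estimates.beta, fit.estimates.b)
```

prints (elided):

```
F_rel = 1.69
0.00571  {'tlag2~form': 0.64, 'v2~form': 0.9}  0.188
```

The fitted clearance 0.0057 L/h/kg is the generating 0.006 within 5%; the
formulation coefficients estimate the generating 0.74 (lag) and 1.11
(peripheral volume) from 40 dogs; b ≈ 0.19 recovers the 19% proportional
noise. (F_rel from model-free NCA is noisy at this sample size — the
terminal-slope extrapolation dominates its variance; the model-based fit
is the stable instrument.) `examples/` contains one narrative script per capability
(simulation, NCA, fitting, diagnostics, external validation), and the
`pkstudy` console command wires the same steps into a shell pipeline
(`pkstudy pipeline --outdir run1` runs simulate → NCA → fit → VPC/NPDE →
bootstrap → validation and writes a manifest with seeds and hashes).

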