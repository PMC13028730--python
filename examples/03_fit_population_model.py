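"""Fit the final population model to a simulated study by SAEM.

The final model: two-compartment kinetics with dual first-order oral
absorption (lag on the second path), lognormal inter-individual
variability on all parameters except Q, formulation effects on Tlag2 and
V2, and proportional residual error.  The fit starts from neutral values,
not the generating truth.
"""

from pkstudy import PopulationModel, SaemConfig, fit_saem, simulate_study

data, _ = simulate_study(n_per_arm=20, seed=5)
init = PopulationModel(
    theta={"ka1": 0.1, "ka2": 1.0, "f1": 0.8, "tlag2": 1.0,
           "cl": 0.01, "v1": 0.1, "q": 0.2, "v2": 0.2},
    omega={p: 0.3 for p in ("ka1", "ka2", "f1", "tlag2", "cl", "v1", "v2")},
    beta={"tlag2~form": 0.0, "v2~form": 0.0},
    b=0.2,
)
fit = fit_saem(data, init, SaemConfig(k1=300, k2=200, seed=4,
                                      ll_method="laplace"))

print(f"-2LL = {fit.minus2ll:.1f}   AIC = {fit.aic:.1f}   "
      f"converged: {fit.converged}")
print(f"{'parameter':10s} {'estimate':>9s} {'RSE%':>6s} {'omega':>6s} {'shrink%':>8s}")
for p in ("ka1", "ka2", "f1", "tlag2", "cl", "v1", "q", "v2"):
    om = fit.estimates.omega.get(p)
    sh = fit.eta_shrinkage_pct.get(p)
    print(f"{p:10s} {fit.estimates.theta[p]:9.4f} "
          f"{fit.rse_pct.get(p, float('nan')):6.1f} "
          f"{om if om is not None else float('nan'):6.2f} "
          f"{sh if sh is not None else float('nan'):8.1f}")
print("formulation effects:",
      {k: round(v, 2) for k, v in fit.estimates.beta.items()})
print(f"proportional error b = {fit.estimates.b:.3f}")
# Generating values: CL 0.006 L/h/kg, F1 0.85, Tlag2 1.22 h with a 0.74
# formulation coefficient (NC lag 2.55 h), V2 0.134 with coefficient 1.11.
# Ka2 often runs to its upper bound on small studies: a fast second
# absorption emptying between two sampling times is not identifiable, so
# the likelihood is flat in that direction (see docs/methods.md).
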