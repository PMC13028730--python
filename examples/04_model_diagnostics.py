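"""Diagnostics for a fitted population model: GOF, VPC, NPDE, bootstrap.

On well-specified data the individual weighted residuals and the
normalized prediction distribution errors are approximately standard
normal, the observed percentiles sit inside the simulated VPC bands, and
the bootstrap interval covers the generating clearance.
"""

from pkstudy import (SaemConfig, bootstrap, fit_saem, individual_predictions,
                     npde, shrinkage, simulate_study, vpc)
from pkstudy.cli import default_init

data, _ = simulate_study(n_per_arm=9, seed=21)
fit = fit_saem(data, default_init("final"),
               SaemConfig(k1=250, k2=150, seed=22, ll_method="laplace"))

preds = individual_predictions(fit, data)
print(f"IWRES mean {preds['iwres'].mean():+.3f}, SD {preds['iwres'].std():.3f} "
      "(≈0 and ≈1 for a well-specified model)")
print("eta-shrinkage %:", {k: round(v) for k, v in shrinkage(fit).items()})

v = vpc(fit, data, n_sim=300, seed=23)
inside = ((v.observed[50] >= v.band_lo[50]) & (v.observed[50] <= v.band_hi[50]))
print(f"VPC: observed median inside 90% band in {inside.mean():.0%} of bins")

nd = npde(fit, data, n_sim=300, seed=24)
print(f"NPDE mean {nd['npde'].mean():+.3f}, variance {nd['npde'].var():.3f}")

boot = bootstrap(data, fit.estimates, n_boot=50, seed=25)
print(f"bootstrap CL: median {boot.median['cl']:.4f}, "
      f"90% interval [{boot.p5['cl']:.4f}, {boot.p95['cl']:.4f}] "
      f"({boot.n_success}/{boot.n_boot} replicates converged)")
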