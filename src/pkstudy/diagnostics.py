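"""Model evaluation: predictions, residuals, shrinkage, VPC, NPDE, bootstrap.

All simulation-based diagnostics resimulate the original study design
(same subjects, covariates and sampling times) from the fitted model and
are deterministic given their seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import FREE, NC, PKDataset
from .popfit import (PARAM_NAMES, FitResult, PopulationModel, SaemConfig,
                     _Problem, fit_saem)

__all__ = [
    "VPCResult", "BootstrapResult",
    "individual_predictions", "shrinkage", "vpc", "npde", "bootstrap",
    "plot_vpc", "plot_gof",
]


@dataclass(frozen=True)
class VPCResult:
    """Observed percentiles per nominal time bin with simulated bands.

    ``observed[q]`` is the empirical q-th percentile per bin;
    ``band_lo[q]``/``band_hi[q]`` bound the central prediction interval of
    that percentile across the simulated replicate studies, and
    ``band_mid[q]`` is its simulated median.
    """

    bins: np.ndarray
    quantiles: tuple
    observed: dict
    band_lo: dict
    band_mid: dict
    band_hi: dict
    n_sim: int
    pi_level: float

    def to_frame(self) -> pd.DataFrame:
        rows = {"time": self.bins}
        for q in self.quantiles:
            rows[f"obs_p{q}"] = self.observed[q]
            rows[f"sim_p{q}_lo"] = self.band_lo[q]
            rows[f"sim_p{q}_mid"] = self.band_mid[q]
            rows[f"sim_p{q}_hi"] = self.band_hi[q]
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class BootstrapResult:
    """Percentile summary of the bootstrap replicate estimates."""

    median: dict
    p5: dict
    p95: dict
    n_success: int
    n_boot: int
    replicates: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        names = list(self.median)
        return pd.DataFrame({
            "parameter": names,
            "median": [self.median[n] for n in names],
            "p5": [self.p5[n] for n in names],
            "p95": [self.p95[n] for n in names],
        })


def _phi_matrix(prob: _Problem, model: PopulationModel, etas=None) -> np.ndarray:
    mu = model.mu_vector()
    phi = np.column_stack([
        prob.X[p] @ np.concatenate(
            [[mu[i]], [model.beta[k] for k in prob.beta_keys
                       if k.partition("~")[0] == p]])
        for i, p in enumerate(PARAM_NAMES)])
    if etas is not None:
        omega = model.omega_vector()
        iiv = [i for i in range(len(PARAM_NAMES)) if omega[i] > 0]
        phi[:, iiv] += etas
    return phi


def individual_predictions(fit: FitResult, data: PKDataset) -> pd.DataFrame:
    """Population and individual predictions with IWRES per observation.

    Population predictions use the covariate-adjusted typical parameters;
    individual predictions plug in the empirical Bayes etas.  IWRES is the
    residual standardised by the fitted error model at the individual
    prediction: ``(obs − ipred) / (b·ipred)`` for proportional error.
    """
    if fit.ebes.empty:
        raise ValueError("fit carries no EBEs; rerun with compute_ebes=True")
    model = fit.estimates
    prob = _Problem(model, data)
    omega = model.omega_vector()
    iiv_names = [PARAM_NAMES[i] for i in range(len(PARAM_NAMES)) if omega[i] > 0]
    ebes = fit.ebes.set_index("subject_id").loc[prob.subject_ids, iiv_names]
    phi_pop = _phi_matrix(prob, model)
    phi_ind = _phi_matrix(prob, model, etas=ebes.to_numpy())
    f_pop = prob.predict(phi_pop)
    f_ind = prob.predict(phi_ind)
    if model.error_model == "proportional":
        sd = model.b * f_ind
    elif model.error_model == "additive":
        sd = np.full_like(f_ind, model.a)
    else:
        sd = np.sqrt(model.a ** 2 + (model.b * f_ind) ** 2)
    rows = []
    for s in range(prob.n):
        for j in np.flatnonzero(prob.mask[s]):
            rows.append({
                "subject_id": prob.subject_ids[s],
                "time": prob.times[s, j],
                "obs": prob.y[s, j],
                "pred_pop": f_pop[s, j],
                "pred_ind": f_ind[s, j],
                "iwres": (prob.y[s, j] - f_ind[s, j]) / sd[s, j],
            })
    return pd.DataFrame(rows)


def shrinkage(fit: FitResult) -> dict:
    """η-shrinkage per parameter: ``100·(1 − SD(eta_EBE)/omega)``.

    Parameters without IIV are reported as NaN (not applicable).
    """
    out = {}
    for p in PARAM_NAMES:
        w = fit.estimates.omega.get(p, 0.0)
        if w <= 0:
            out[p] = float("nan")
        elif p in fit.eta_shrinkage_pct:
            out[p] = fit.eta_shrinkage_pct[p]
        else:
            sd = float(fit.ebes[p].std(ddof=1))
            out[p] = 100.0 * (1.0 - sd / w)
    return out


def _simulate_matrix(prob: _Problem, model: PopulationModel, n_sim: int, rng,
                     redraw_negative: bool = True) -> np.ndarray:
    """(n_sim, n_subjects, m) simulated observations under the design."""
    omega = model.omega_vector()
    iiv = [i for i in range(len(PARAM_NAMES)) if omega[i] > 0]
    phi0 = _phi_matrix(prob, model)
    out = np.empty((n_sim, prob.n, prob.times.shape[1]))
    for r in range(n_sim):
        phi = phi0.copy()
        phi[:, iiv] += rng.standard_normal((prob.n, len(iiv))) * omega[iiv]
        f = prob.predict(phi)
        eps = rng.standard_normal(f.shape)
        if model.error_model == "proportional":
            y = f * (1.0 + model.b * eps)
        elif model.error_model == "additive":
            y = f + model.a * eps
        else:
            y = f + np.sqrt(model.a ** 2 + (model.b * f) ** 2) * eps
        if redraw_negative:
            for _ in range(100):
                bad = (y <= 0) & prob.mask
                if not bad.any():
                    break
                eps = rng.standard_normal(f.shape)
                if model.error_model == "proportional":
                    y2 = f * (1.0 + model.b * eps)
                elif model.error_model == "additive":
                    y2 = f + model.a * eps
                else:
                    y2 = f + np.sqrt(model.a ** 2 + (model.b * f) ** 2) * eps
                y = np.where(bad, y2, y)
        out[r] = y
    return out


def vpc(fit: FitResult, data: PKDataset, n_sim: int = 1000, seed: int = 0,
        quantiles=(10, 50, 90), pi_level: float = 90.0) -> VPCResult:
    """Visual predictive check over the nominal sampling-time bins.

    Simulates ``n_sim`` replicate studies with the original design and
    covariates, then compares the observed 10th/50th/90th percentiles per
    nominal time against the central ``pi_level``% interval of the same
    percentile across replicates.  Bins are the exact nominal times (all
    subjects share the schedule; no smoothing).
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    model = fit.estimates
    prob = _Problem(model, data)
    rng = np.random.default_rng(seed)
    sims = _simulate_matrix(prob, model, n_sim, rng)

    flat_t = prob.times[prob.mask]
    flat_y = prob.y[prob.mask]
    bins = np.unique(flat_t)
    lo_q, hi_q = (100 - pi_level) / 2, 100 - (100 - pi_level) / 2
    observed, band_lo, band_mid, band_hi = {}, {}, {}, {}
    sim_flat = sims[:, prob.mask]          # (n_sim, n_obs)
    for q in quantiles:
        obs_q = np.array([np.percentile(flat_y[flat_t == t], q) for t in bins])
        sim_q = np.stack([
            np.array([np.percentile(sim_flat[r][flat_t == t], q) for t in bins])
            for r in range(n_sim)])
        observed[q] = obs_q
        band_lo[q] = np.percentile(sim_q, lo_q, axis=0)
        band_mid[q] = np.percentile(sim_q, 50, axis=0)
        band_hi[q] = np.percentile(sim_q, hi_q, axis=0)
    return VPCResult(bins=bins, quantiles=tuple(quantiles), observed=observed,
                     band_lo=band_lo, band_mid=band_mid, band_hi=band_hi,
                     n_sim=n_sim, pi_level=pi_level)


def npde(fit: FitResult, data: PKDataset, n_sim: int = 1000,
         seed: int = 0) -> pd.DataFrame:
    """Normalized prediction distribution errors per observation.

    Per subject, ``n_sim`` replicate observation vectors are simulated;
    observed and simulated vectors are decorrelated with the simulated
    mean and covariance (Cholesky), and the npde is the inverse-normal of
    the rank-based probability of each decorrelated observation.  Under a
    correct model the npde are approximately standard normal.
    """
    if n_sim < 2:
        raise ValueError("n_sim must be >= 2 (ranks are undefined otherwise)")
    model = fit.estimates
    prob = _Problem(model, data)
    rng = np.random.default_rng(seed)
    sims = _simulate_matrix(prob, model, n_sim, rng)
    rows = []
    for s in range(prob.n):
        idx = np.flatnonzero(prob.mask[s])
        y = prob.y[s, idx]
        ys = sims[:, s, :][:, idx]                 # (n_sim, m_i)
        mean = ys.mean(axis=0)
        cov = np.cov(ys, rowvar=False)
        cov = np.atleast_2d(cov)
        jitter = 0.0
        for _ in range(6):
            try:
                L = np.linalg.cholesky(cov + jitter * np.eye(len(idx)))
                break
            except np.linalg.LinAlgError:
                jitter = max(jitter * 10, 1e-10 * np.trace(cov) / len(idx))
        else:
            raise np.linalg.LinAlgError("simulated covariance not factorizable")
        if jitter:
            warnings.warn(f"subject {prob.subject_ids[s]}: singular simulated "
                          f"covariance, jittered by {jitter:.2e}")
        y_dec = np.linalg.solve(L, y - mean)
        ys_dec = np.linalg.solve(L, (ys - mean).T).T
        pd_prob = (ys_dec < y_dec).mean(axis=0)
        pd_prob = np.clip(pd_prob, 1.0 / (2 * n_sim), 1.0 - 1.0 / (2 * n_sim))
        values = stats.norm.ppf(pd_prob)
        for j, t in zip(range(len(idx)), prob.times[s, idx]):
            rows.append({"subject_id": prob.subject_ids[s], "time": t,
                         "obs": y[j], "npde": values[j]})
    return pd.DataFrame(rows)


def bootstrap(data: PKDataset, init: PopulationModel, n_boot: int = 1000,
              seed: int = 0, config: SaemConfig | None = None,
              stratify: bool = True) -> BootstrapResult:
    """Nonparametric bootstrap of the population estimates.

    Subjects are resampled with replacement — within each formulation arm
    when ``stratify`` (preserves the arm balance of the design) — and the
    model is refit per replicate.  Refits start from ``init`` (typically
    the final estimates) with a shortened SAEM schedule; the replicate
    schedule and seeds are recorded in the result.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    cfg = config or SaemConfig(k1=200, k2=100)
    cfg = replace(cfg, ll_method="none", compute_rse=False, compute_ebes=False)
    rng = np.random.default_rng(seed)
    df = data.to_frame()
    subj = df.drop_duplicates("ID")
    arms = {arm: subj.loc[subj["FORM"] == arm, "ID"].to_list() for arm in (FREE, NC)}
    all_ids = subj["ID"].to_list()

    rows = []
    n_success = 0
    for r in range(n_boot):
        if stratify:
            ids = [i for arm_ids in arms.values() if arm_ids
                   for i in rng.choice(arm_ids, size=len(arm_ids), replace=True)]
        else:
            ids = list(rng.choice(all_ids, size=len(all_ids), replace=True))
        resample = data.subset(ids, relabel=True)
        try:
            fit = fit_saem(resample, init, replace(cfg, seed=cfg.seed + 7919 * r))
        except Exception as exc:   # a replicate may fail; record and move on
            warnings.warn(f"bootstrap replicate {r} failed: {exc}")
            continue
        n_success += 1
        est = fit.estimates
        row = {"replicate": r}
        row.update({p: est.theta[p] for p in PARAM_NAMES})
        row.update({f"beta:{k}": v for k, v in est.beta.items()})
        row.update({f"omega:{p}": w for p, w in est.omega.items()})
        row["b"] = est.b
        if est.error_model != "proportional":
            row["a"] = est.a
        rows.append(row)
    if not rows:
        raise RuntimeError("all bootstrap replicates failed")
    reps = pd.DataFrame(rows).set_index("replicate")
    median = {c: float(np.percentile(reps[c], 50)) for c in reps.columns}
    p5 = {c: float(np.percentile(reps[c], 5)) for c in reps.columns}
    p95 = {c: float(np.percentile(reps[c], 95)) for c in reps.columns}
    return BootstrapResult(median=median, p5=p5, p95=p95,
                           n_success=n_success, n_boot=n_boot,
                           replicates=reps.reset_index())


# ---------------------------------------------------------------------------
# plotting (file output; numbers are always available via to_frame)
# ---------------------------------------------------------------------------

def plot_vpc(result: VPCResult, path) -> None:
    """VPC figure: observed percentiles over simulated bands."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 5))
    colors = {result.quantiles[0]: "C0", result.quantiles[1]: "C1",
              result.quantiles[-1]: "C0"}
    for q in result.quantiles:
        ax.fill_between(result.bins, result.band_lo[q], result.band_hi[q],
                        alpha=0.25, color=colors.get(q, "C2"))
        ax.plot(result.bins, result.band_mid[q], "--", color=colors.get(q, "C2"),
                lw=1)
        ax.plot(result.bins, result.observed[q], "-", color=colors.get(q, "C2"),
                lw=2, label=f"observed p{q}")
    ax.set_xlabel("time (h)")
    ax.set_ylabel("concentration (µg/mL)")
    ax.set_title(f"Visual predictive check ({result.n_sim} simulations, "
                 f"{result.pi_level:.0f}% PI)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_gof(preds: pd.DataFrame, path) -> None:
    """Goodness-of-fit panel: obs vs predictions and IWRES vs time."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(12, 4))
    for ax, col, label in ((axes[0], "pred_pop", "population prediction"),
                           (axes[1], "pred_ind", "individual prediction")):
        ax.plot(preds[col], preds["obs"], "o", ms=3, alpha=0.6)
        lim = [0, max(preds["obs"].max(), preds[col].max()) * 1.05]
        ax.plot(lim, lim, "k-", lw=1)
        ax.set_xlabel(label)
        ax.set_ylabel("observed (µg/mL)")
    axes[2].plot(preds["time"], preds["iwres"], "o", ms=3, alpha=0.6)
    axes[2].axhline(0, color="k", lw=1)
    axes[2].set_xlabel("time (h)")
    axes[2].set_ylabel("IWRES")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
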