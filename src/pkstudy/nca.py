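"""Non-compartmental analysis of single-oral-dose concentration profiles.

Per-subject exposure metrics (AUC, Cmax, Tmax, λz, t½, CL/F, Vd/F, MRT)
with group summaries, a two-sample t-test per metric, relative
bioavailability from the arm AUC means, and optionally absolute
bioavailability against a user-supplied intravenous reference.

Terminal-slope selection follows standard practice: log-linear regression
over contiguous terminal subsets of 3–6 points strictly after Tmax, picking
the best adjusted R² and breaking ties toward more points.  AUC uses the
linear trapezoidal rule with a zero-concentration origin prepended for
oral profiles; a log-down variant is available behind a flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import FREE, NC, PKDataset

__all__ = [
    "NCAResult", "GroupSummary", "EstimationError",
    "fit_lambda_z", "auc_trapezoid", "nca_single", "nca_dataset", "group_compare",
]


class EstimationError(ValueError):
    """The profile does not support the requested estimate."""


@dataclass(frozen=True)
class NCAResult:
    """One subject's non-compartmental metrics (canonical units)."""

    subject_id: int
    formulation: str
    auc_0_t: float       # µg·h/mL
    auc_0_inf: float     # µg·h/mL
    auc_ext_pct: float   # %
    cmax: float          # µg/mL
    tmax: float          # h
    lambda_z: float      # 1/h
    t_half: float        # h
    cl_f: float          # L/h/kg
    vd_f: float          # L/kg
    mrt: float           # h
    n_lambda_points: int
    lambda_r2adj: float

    @property
    def cl_f_ml_min_kg(self) -> float:
        """Clearance in the mL/min/kg reporting convention."""
        return self.cl_f * 1000.0 / 60.0

    def to_dict(self) -> dict:
        return asdict(self)


_METRICS = ["auc_0_t", "auc_0_inf", "auc_ext_pct", "cmax", "tmax",
            "lambda_z", "t_half", "cl_f", "vd_f", "mrt"]


@dataclass(frozen=True)
class GroupSummary:
    """Arm-wise mean ± SD per metric with t-test p-values and F_rel."""

    means: dict          # arm -> {metric: mean}
    sds: dict            # arm -> {metric: sd}
    p_values: dict       # metric -> two-sided p
    frel: float          # mean AUC0-inf ratio, test (NC) / reference (FREE)
    f_abs: dict | None   # arm -> absolute F, if an IV reference was given
    n: dict              # arm -> subject count

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for m in _METRICS:
            rows.append({
                "metric": m,
                f"mean_{FREE}": self.means[FREE][m], f"sd_{FREE}": self.sds[FREE][m],
                f"mean_{NC}": self.means[NC][m], f"sd_{NC}": self.sds[NC][m],
                "p_value": self.p_values[m],
            })
        return pd.DataFrame(rows)


def auc_trapezoid(times, conc, method: str = "linear",
                  prepend_zero: bool = True) -> float:
    """AUC from zero to the last observation (µg·h/mL).

    Linear trapezoidal by default; ``method="log-down"`` uses the
    logarithmic rule on strictly declining positive segments.  For oral
    single-dose profiles a (0, 0) origin point is prepended unless the
    profile already starts at t = 0.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(conc, dtype=float)
    if t.size != c.size or t.size < 2:
        raise EstimationError("need at least two (time, concentration) points")
    if np.any(np.diff(t) <= 0):
        raise EstimationError("times must be strictly increasing")
    if prepend_zero and t[0] > 0:
        t = np.concatenate([[0.0], t])
        c = np.concatenate([[0.0], c])
    dt = np.diff(t)
    c0, c1 = c[:-1], c[1:]
    lin = 0.5 * dt * (c0 + c1)
    if method == "linear":
        return float(np.sum(lin))
    if method == "log-down":
        down = (c1 < c0) & (c1 > 0) & (c0 > 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            logseg = dt * (c0 - c1) / np.log(c0 / c1)
        return float(np.sum(np.where(down, logseg, lin)))
    raise ValueError(f"unknown AUC method {method!r}")


def fit_lambda_z(times, conc, min_points: int = 3, max_points: int = 6):
    """Terminal elimination rate constant λz by log-linear regression.

    Candidate subsets are the contiguous terminal windows of
    ``min_points``..``max_points`` observations strictly after Tmax; the
    window with the highest adjusted R² wins, ties toward more points.
    Profiles that peak too late to leave ``min_points`` observations after
    Tmax (slow-absorption individuals) fall back to the last
    ``min_points`` observations, Tmax included.

    Returns ``(lambda_z, n_points, r2adj)``.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(conc, dtype=float)
    if t.size < min_points:
        raise EstimationError(
            f"need ≥{min_points} observations for λz, have {t.size}")
    if np.any(c <= 0):
        raise EstimationError("λz fit requires strictly positive concentrations")
    i_max = int(np.argmax(c))
    t_term, c_term = t[i_max + 1:], c[i_max + 1:]
    if t_term.size < min_points:
        t_term, c_term = t[-min_points:], c[-min_points:]
    best = None
    logc = np.log(c_term)
    for n in range(min_points, min(max_points, t_term.size) + 1):
        x, y = t_term[-n:], logc[-n:]
        slope, intercept = np.polyfit(x, y, 1)
        if slope >= 0:
            continue
        yhat = slope * x + intercept
        ss_res = float(np.sum((y - yhat) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        r2adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
        # strict '>' prefers the later (larger-n) candidate on exact ties
        if best is None or r2adj >= best[2] - 1e-12:
            best = (-slope, n, r2adj)
    if best is None:
        raise EstimationError("no terminal window with a negative slope")
    return best


def nca_single(times, conc, dose_per_kg: float, subject_id: int = 0,
               formulation: str = FREE, auc_method: str = "linear") -> NCAResult:
    """Full non-compartmental workup of one subject's profile.

    Cmax/Tmax are the observed maximum (first occurrence on ties);
    AUC0–∞ adds the tail C_last/λz; MRT uses AUMC with the matching
    analytic tail; CL/F, Vd/F and t½ follow by definition.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(conc, dtype=float)
    lambda_z, n_pts, r2adj = fit_lambda_z(t, c)
    auc_t = auc_trapezoid(t, c, method=auc_method)
    c_last, t_last = float(c[-1]), float(t[-1])
    auc_inf = auc_t + c_last / lambda_z
    # AUMC: trapezoid on t*C plus the analytic tail of an exponential decay
    aumc_t = auc_trapezoid(t, t * c, method="linear")
    aumc_inf = aumc_t + c_last * t_last / lambda_z + c_last / lambda_z**2
    i_max = int(np.argmax(c))
    cl_f = dose_per_kg / auc_inf
    return NCAResult(
        subject_id=subject_id,
        formulation=formulation,
        auc_0_t=auc_t,
        auc_0_inf=auc_inf,
        auc_ext_pct=100.0 * (auc_inf - auc_t) / auc_inf,
        cmax=float(c[i_max]),
        tmax=float(t[i_max]),
        lambda_z=lambda_z,
        t_half=float(np.log(2.0) / lambda_z),
        cl_f=cl_f,
        vd_f=cl_f / lambda_z,
        mrt=aumc_inf / auc_inf,
        n_lambda_points=n_pts,
        lambda_r2adj=r2adj,
    )


def nca_dataset(data: PKDataset, auc_method: str = "linear",
                on_error: str = "raise") -> list[NCAResult]:
    """Per-subject NCA over a whole dataset.

    ``on_error="skip"`` drops subjects whose terminal slope is not
    estimable (with a warning) instead of raising.
    """
    out = []
    for s in data.subjects():
        try:
            out.append(nca_single(s["times"], s["conc"], s["dose_per_kg"],
                                  subject_id=s["subject_id"],
                                  formulation=s["formulation"],
                                  auc_method=auc_method))
        except EstimationError:
            if on_error != "skip":
                raise
            warnings.warn(f"subject {s['subject_id']}: terminal slope not "
                          "estimable, excluded from NCA")
    return out


def group_compare(results, test: str = "welch",
                  iv_ref_auc: float | None = None,
                  iv_ref_dose: float | None = None) -> GroupSummary:
    """Arm summaries, per-metric t-tests, F_rel and optional absolute F.

    ``test`` selects Welch's unequal-variance t-test (default) or the
    pooled-variance Student test (``"student"``).  F_rel is the ratio of
    mean AUC0–∞, NC over FREE.  If an intravenous reference exposure is
    supplied, absolute F per arm is
    (AUC_oral/dose_oral) / (AUC_iv/dose_iv) on the arm means.
    """
    by_arm = {arm: [r for r in results if r.formulation == arm] for arm in (FREE, NC)}
    for arm, rs in by_arm.items():
        if len(rs) < 2:
            raise EstimationError(f"need ≥2 subjects in arm {arm}, have {len(rs)}")
    values = {arm: {m: np.array([getattr(r, m) for r in rs]) for m in _METRICS}
              for arm, rs in by_arm.items()}
    means = {arm: {m: float(v[m].mean()) for m in _METRICS} for arm, v in values.items()}
    sds = {arm: {m: float(v[m].std(ddof=1)) for m in _METRICS} for arm, v in values.items()}
    p_values = {}
    for m in _METRICS:
        a, b = values[FREE][m], values[NC][m]
        if np.allclose(a, a[0]) and np.allclose(b, b[0]) and np.isclose(a[0], b[0]):
            p_values[m] = 1.0
            continue
        res = stats.ttest_ind(a, b, equal_var=(test == "student"))
        p_values[m] = float(res.pvalue)
    frel = means[NC]["auc_0_inf"] / means[FREE]["auc_0_inf"]
    f_abs = None
    if iv_ref_auc is not None and iv_ref_dose is not None:
        iv_ratio = iv_ref_auc / iv_ref_dose
        f_abs = {}
        for arm, rs in by_arm.items():
            # auc * cl_f recovers each subject's dose_per_kg by construction
            dose = float(np.mean([r.auc_0_inf * r.cl_f for r in rs]))
            f_abs[arm] = (means[arm]["auc_0_inf"] / dose) / iv_ratio
    return GroupSummary(means=means, sds=sds, p_values=p_values, frel=frel,
                        f_abs=f_abs, n={arm: len(rs) for arm, rs in by_arm.items()})


def results_to_frame(results, summary: GroupSummary | None = None) -> pd.DataFrame:
    """Tabulate per-subject results; append arm mean/SD rows if a summary
    is given (for the results CSV)."""
    df = pd.DataFrame([r.to_dict() for r in results])
    if summary is not None:
        for arm in (FREE, NC):
            for stat_name, src in (("mean", summary.means), ("sd", summary.sds)):
                row = {"subject_id": f"{arm}_{stat_name}", "formulation": arm}
                row.update({m: src[arm][m] for m in _METRICS})
                df = pd.concat([df, pd.DataFrame([row])], ignore_index=True)
    return df
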