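"""Virtual dog-study generator.

Standing replacement for the raw study data: a parallel two-arm single
oral dose design (free vs. nanoencapsulated meloxicam, 0.2 mg/kg, nine
dogs per arm, plasma sampled at 0.5–60 h) with individual kinetic
parameters drawn from the hierarchical lognormal model and proportional
observation noise.  The default generating parameters are the published
population estimates for this study design, so datasets drawn here carry
the statistical structure the estimation machinery assumes.

Body weight and age are simulated (uniform over the study's ranges) but do
not influence concentrations — they exist to exercise the covariate
search's null behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dataio import CANONICAL_COLUMNS, FREE, NC, PKDataset, StudyDesign
from .popfit import PARAM_NAMES, PopulationModel, apply_covariates, _typical_phi, \
    _from_internal
from .structural import predict_concentration, concentration_profiles

__all__ = ["SimulationConfig", "default_truth", "simulate_study",
           "simulate_external_means"]


def default_truth() -> PopulationModel:
    """Default generating model: the published population estimates.

    Clearance is 0.1 mL/min/kg = 0.006 L/h/kg; omegas are standard
    deviations of the log (logit for F1) parameters; the formulation
    covariate acts multiplicatively on Tlag2 (beta 0.74) and V2 (beta 1.11).
    """
    return PopulationModel(
        theta={"ka1": 0.086, "ka2": 1.82, "f1": 0.85, "tlag2": 1.22,
               "cl": 0.006, "v1": 0.049, "q": 0.24, "v2": 0.134},
        omega={"ka1": 0.38, "ka2": 1.28, "f1": 0.67, "tlag2": 0.38,
               "cl": 0.32, "v1": 1.44, "v2": 0.65},
        beta={"tlag2~form": 0.74, "v2~form": 1.11},
        b=0.19,
    )


@dataclass
class SimulationConfig:
    """Study design, generating model and seed for one virtual study."""

    design: StudyDesign = field(default_factory=StudyDesign)
    truth: PopulationModel = field(default_factory=default_truth)
    seed: int = 20260925
    #: redraw the noise term for any point that would go non-positive
    #: (keeps all observations above zero, like the assay's LOQ behaviour)
    truncate_negative: str = "redraw"   # or "keep"

    def __post_init__(self):
        if self.truncate_negative not in ("redraw", "keep"):
            raise ValueError("truncate_negative must be 'redraw' or 'keep'")


def _draw_arm(cfg: SimulationConfig, formulation: str, n: int, rng,
              first_id: int):
    """Individual parameter draws and noisy profiles for one arm."""
    model = cfg.truth
    design = cfg.design
    times = np.asarray(design.sampling_times, dtype=float)
    weights = rng.uniform(*design.weight_range, size=n)
    ages = rng.uniform(*design.age_range, size=n)

    phi_typ = _typical_phi(model, formulation)
    omega = model.omega_vector()
    eta = rng.standard_normal((n, len(PARAM_NAMES))) * omega
    phi = phi_typ[None, :] + eta
    naturals = {p: _from_internal(p, phi[:, i]) for i, p in enumerate(PARAM_NAMES)}
    f = concentration_profiles(*[naturals[p] for p in PARAM_NAMES],
                               design.dose_per_kg, times)

    eps = rng.standard_normal(f.shape)
    if model.error_model == "proportional":
        conc = f * (1.0 + model.b * eps)
        if cfg.truncate_negative == "redraw":
            for _ in range(1000):
                bad = conc <= 0
                if not bad.any():
                    break
                eps = rng.standard_normal(f.shape)
                conc = np.where(bad, f * (1.0 + model.b * eps), conc)
    else:
        sd = np.sqrt(model.a ** 2 + (model.b * f) ** 2
                     if model.error_model == "combined" else model.a ** 2)
        conc = f + sd * eps
        if cfg.truncate_negative == "redraw":
            for _ in range(1000):
                bad = conc <= 0
                if not bad.any():
                    break
                eps = rng.standard_normal(f.shape)
                conc = np.where(bad, f + sd * eps, conc)

    rows, truth_rows = [], []
    for j in range(n):
        sid = first_id + j
        rows.append({"ID": sid, "TIME": 0.0, "AMT": design.dose_per_kg,
                     "DV": np.nan, "EVID": 1, "FORM": formulation,
                     "WT": weights[j], "AGE": ages[j]})
        for t, c in zip(times, conc[j]):
            rows.append({"ID": sid, "TIME": float(t), "AMT": np.nan,
                         "DV": float(c), "EVID": 0, "FORM": formulation,
                         "WT": weights[j], "AGE": ages[j]})
        truth_rows.append({"subject_id": sid, "formulation": formulation,
                           **{p: float(naturals[p][j]) for p in PARAM_NAMES},
                           **{f"eta_{p}": float(eta[j, i])
                              for i, p in enumerate(PARAM_NAMES)
                              if omega[i] > 0}})
    return rows, truth_rows


def simulate_study(config: SimulationConfig | None = None,
                   n_per_arm: int | None = None, seed: int | None = None):
    """Simulate one virtual study.

    Returns ``(dataset, truth)`` where ``truth`` is a DataFrame recording
    every realised individual parameter set (for recovery tests).
    Deterministic given the config seed.
    """
    cfg = config or SimulationConfig()
    if n_per_arm is not None:
        cfg = replace(cfg, design=replace(cfg.design, n_per_arm=n_per_arm))
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    rng = np.random.default_rng(cfg.seed)
    n = cfg.design.n_per_arm
    rows_f, truth_f = _draw_arm(cfg, FREE, n, rng, first_id=1)
    rows_n, truth_n = _draw_arm(cfg, NC, n, rng, first_id=n + 1)
    df = pd.DataFrame(rows_f + rows_n, columns=CANONICAL_COLUMNS)
    return PKDataset(df), pd.DataFrame(truth_f + truth_n)


def simulate_external_means(config: SimulationConfig | None = None,
                            n_profiles: int = 2, noise_pct: float = 0.0,
                            times=None, seed: int | None = None) -> PKDataset:
    """Typical (eta = 0) arm-mean profiles for external-validation runs.

    Emulates literature mean-profile datasets: ``n_profiles`` profiles
    alternate between the two formulation arms, each the covariate-adjusted
    typical prediction at the sampling schedule (or ``times``), optionally
    perturbed by ``noise_pct`` percent multiplicative Gaussian noise.
    """
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    times = np.asarray(cfg.design.sampling_times if times is None else times,
                       dtype=float)
    rows = []
    mid_wt = float(np.mean(cfg.design.weight_range))
    mid_age = float(np.mean(cfg.design.age_range))
    for j in range(n_profiles):
        form = FREE if j % 2 == 0 else NC
        p = apply_covariates(cfg.truth, form)
        conc = predict_concentration(p, cfg.design.dose_per_kg, times)
        if noise_pct > 0:
            for _ in range(1000):
                noisy = conc * (1.0 + (noise_pct / 100.0)
                                * rng.standard_normal(conc.shape))
                if np.all(noisy > 0):
                    break
            conc = noisy
        sid = j + 1
        rows.append({"ID": sid, "TIME": 0.0, "AMT": cfg.design.dose_per_kg,
                     "DV": np.nan, "EVID": 1, "FORM": form,
                     "WT": mid_wt, "AGE": mid_age})
        for t, c in zip(times, conc):
            rows.append({"ID": sid, "TIME": float(t), "AMT": np.nan,
                         "DV": float(c), "EVID": 0, "FORM": form,
                         "WT": mid_wt, "AGE": mid_age})
    return PKDataset(pd.DataFrame(rows, columns=CANONICAL_COLUMNS))
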