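"""External predictive-performance metrics.

Mean prediction error (signed bias) and root-mean-square prediction error
on the relative scale, in percent:

    MPE%  = (1/N) · Σ (C_pred − C_obs) / C_obs · 100
    RMSE% = sqrt( (1/N) · Σ ((C_pred − C_obs) / C_obs)² ) · 100

RMSE is the root of the mean squared relative error (the percent scale of
the reported values makes this the consistent reading).  External
validation predicts a mean-profile dataset with the final population
parameters fixed and all random effects at zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataio import PKDataset
from .popfit import FitResult, PopulationModel, apply_covariates
from .structural import predict_concentration

__all__ = ["PredictionPairs", "mpe_percent", "rmse_percent", "external_validate"]


@dataclass(frozen=True)
class PredictionPairs:
    """Aligned observed/predicted concentration vectors (µg/mL)."""

    c_obs: np.ndarray
    c_pred: np.ndarray

    def __post_init__(self):
        obs = np.asarray(self.c_obs, dtype=float)
        pred = np.asarray(self.c_pred, dtype=float)
        if obs.shape != pred.shape or obs.ndim != 1:
            raise ValueError("c_obs and c_pred must be 1-D and equal length")
        if np.any(obs <= 0):
            raise ValueError("relative errors require strictly positive c_obs")
        object.__setattr__(self, "c_obs", obs)
        object.__setattr__(self, "c_pred", pred)

    @property
    def n(self) -> int:
        return self.c_obs.size


def mpe_percent(pairs: PredictionPairs) -> float:
    """Mean (signed) relative prediction error in percent."""
    rel = (pairs.c_pred - pairs.c_obs) / pairs.c_obs
    return float(np.mean(rel) * 100.0)


def rmse_percent(pairs: PredictionPairs) -> float:
    """Root-mean-square relative prediction error in percent."""
    rel = (pairs.c_pred - pairs.c_obs) / pairs.c_obs
    return float(np.sqrt(np.mean(rel ** 2)) * 100.0)


def external_validate(fit: FitResult | PopulationModel,
                      dataset: PKDataset) -> tuple[float, float]:
    """(MPE%, RMSE%) of fixed-parameter population predictions.

    The final estimates are used as-is (no refitting, etas = 0); each
    profile is predicted with its own dose, times and formulation
    covariate.
    """
    model = fit.estimates if isinstance(fit, FitResult) else fit
    obs, pred = [], []
    for s in dataset.subjects():
        p = apply_covariates(model, s["formulation"],
                             weight=s["weight"], age=s["age"])
        f = predict_concentration(p, s["dose_per_kg"], s["times"])
        obs.append(s["conc"])
        pred.append(f)
    pairs = PredictionPairs(np.concatenate(obs), np.concatenate(pred))
    return mpe_percent(pairs), rmse_percent(pairs)
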