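import numpy as np
import pytest

from pkstudy import (PopulationModel, SaemConfig, SimulationConfig,
                     StructuralParams, default_truth, fit_saem, simulate_study)


@pytest.fixture(scope="session")
def truth() -> PopulationModel:
    return default_truth()


@pytest.fixture(scope="session")
def typical_free(truth) -> StructuralParams:
    """Typical kinetic parameters of the reference (free drug) arm."""
    return StructuralParams(**truth.theta)


@pytest.fixture(scope="session")
def paper_design_study():
    """One virtual study with the published design (9 dogs/arm, 11 times)."""
    return simulate_study(SimulationConfig(seed=20260925))


def generic_init(with_covariates: bool = True) -> PopulationModel:
    """Neutral starting model used by fitting tests (not the truth)."""
    return PopulationModel(
        theta={"ka1": 0.1, "ka2": 1.0, "f1": 0.8, "tlag2": 1.0,
               "cl": 0.01, "v1": 0.1, "q": 0.2, "v2": 0.2},
        omega={p: 0.3 for p in ("ka1", "ka2", "f1", "tlag2", "cl", "v1", "v2")},
        beta={"tlag2~form": 0.0, "v2~form": 0.0} if with_covariates else {},
        b=0.2,
    )


@pytest.fixture(scope="session")
def fitted_small_study(paper_design_study):
    """A quick SAEM fit of the paper-design study, shared across tests."""
    data, _ = paper_design_study
    cfg = SaemConfig(k1=200, k2=100, seed=11, ll_method="laplace")
    return data, fit_saem(data, generic_init(), cfg)
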