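"""Predictions, shrinkage, VPC, NPDE and bootstrap behaviour."""

import numpy as np
import pandas as pd
import pytest

from pkstudy import (FitResult, SaemConfig, SimulationConfig, StudyDesign,
                     bootstrap, fit_saem, individual_predictions, npde,
                     shrinkage, simulate_study, vpc)
from pkstudy.popfit import PARAM_NAMES

from conftest import generic_init


def _fit_shell(model, ebes=None):
    return FitResult(estimates=model, rse_pct={}, minus2ll=np.nan, aic=np.nan,
                     ebes=ebes if ebes is not None else pd.DataFrame(),
                     eta_shrinkage_pct={}, converged=True,
                     trace=pd.DataFrame(), config=SaemConfig())


class TestIndividualPredictions:
    def test_zero_noise_gives_zero_iwres(self, truth):
        gen = truth.copy(omega={}, b=0.0)
        data, _ = simulate_study(SimulationConfig(truth=gen, seed=1))
        model = gen.copy(b=0.19)  # any b: residuals are exactly zero anyway
        preds = individual_predictions(_fit_shell(model, pd.DataFrame(
            {"subject_id": data.subject_ids})), data)
        np.testing.assert_allclose(preds["iwres"], 0.0, atol=1e-10)
        np.testing.assert_allclose(preds["pred_ind"], preds["pred_pop"],
                                   rtol=1e-12)

    def test_missing_ebes_error(self, truth, paper_design_study):
        data, _ = paper_design_study
        with pytest.raises(ValueError, match="EBE"):
            individual_predictions(_fit_shell(truth.copy(omega={"cl": 0.3})), data)

    def test_iwres_calibration_on_well_specified_fit(self, fitted_small_study):
        data, fit = fitted_small_study
        preds = individual_predictions(fit, data)
        assert -0.2 < preds["iwres"].mean() < 0.2
        assert 0.8 < preds["iwres"].std() < 1.2


class TestShrinkage:
    def _shell_with_etas(self, truth, etas):
        ebes = pd.DataFrame({"subject_id": range(1, len(etas) + 1), "cl": etas})
        model = truth.copy(omega={"cl": 0.32})
        return _fit_shell(model, ebes)

    def test_zero_when_ebe_spread_equals_omega(self, truth):
        rng = np.random.default_rng(0)
        etas = rng.normal(0, 1, 200)
        etas = (etas - etas.mean()) / etas.std(ddof=1) * 0.32
        fit = self._shell_with_etas(truth, etas)
        assert shrinkage(fit)["cl"] == pytest.approx(0.0, abs=1e-9)

    def test_full_when_all_ebes_zero(self, truth):
        fit = self._shell_with_etas(truth, np.zeros(50))
        assert shrinkage(fit)["cl"] == pytest.approx(100.0)
        assert np.isnan(shrinkage(fit)["q"])

    def test_rich_design_shrinks_little_for_cl(self, fitted_small_study):
        _, fit = fitted_small_study
        assert shrinkage(fit)["cl"] < 30.0


class TestVPC:
    def test_nsim_zero_errors(self, truth, fitted_small_study):
        data, fit = fitted_small_study
        with pytest.raises(ValueError):
            vpc(fit, data, n_sim=0)

    def test_percentile_ordering_every_bin(self, fitted_small_study):
        data, fit = fitted_small_study
        res = vpc(fit, data, n_sim=60, seed=4)
        for q_lo, q_hi in ((10, 50), (50, 90)):
            assert np.all(res.observed[q_lo] <= res.observed[q_hi])
            assert np.all(res.band_mid[q_lo] <= res.band_mid[q_hi])
        assert np.all(res.band_lo[50] <= res.band_hi[50])
        assert res.bins.tolist() == sorted(res.bins.tolist())

    def test_seed_reproducibility(self, fitted_small_study):
        data, fit = fitted_small_study
        a = vpc(fit, data, n_sim=40, seed=5)
        b = vpc(fit, data, n_sim=40, seed=5)
        for q in a.quantiles:
            np.testing.assert_array_equal(a.band_lo[q], b.band_lo[q])

    def test_self_simulated_data_inside_bands(self, truth):
        """Data drawn from the model itself: observed medians should sit
        inside the simulated 90% band in most bins."""
        data, _ = simulate_study(n_per_arm=9, seed=33)
        res = vpc(_fit_shell(truth), data, n_sim=300, seed=6)
        inside = ((res.observed[50] >= res.band_lo[50])
                  & (res.observed[50] <= res.band_hi[50]))
        assert inside.mean() >= 0.8


class TestNPDE:
    def test_nsim_one_errors(self, fitted_small_study):
        data, fit = fitted_small_study
        with pytest.raises(ValueError):
            npde(fit, data, n_sim=1)

    def test_relabelling_invariance(self, truth):
        data, _ = simulate_study(n_per_arm=3, seed=44)
        res1 = npde(_fit_shell(truth), data, n_sim=80, seed=7)
        relabeled = data.subset(data.subject_ids, relabel=True)
        res2 = npde(_fit_shell(truth), relabeled, n_sim=80, seed=7)
        np.testing.assert_allclose(res1["npde"], res2["npde"])

    def test_roughly_standard_normal_on_self_simulated_data(self, truth):
        # ≥500 observations: pooled variance of the rank-based npde is
        # stable despite within-subject dependence
        data, _ = simulate_study(n_per_arm=25, seed=55)
        res = npde(_fit_shell(truth), data, n_sim=500, seed=8)
        assert abs(res["npde"].mean()) < 0.15
        assert 0.8 < res["npde"].var() < 1.2


class TestBootstrap:
    def test_nboot_zero_errors(self, truth, paper_design_study):
        data, _ = paper_design_study
        with pytest.raises(ValueError):
            bootstrap(data, truth, n_boot=0)

    def test_degenerate_resample_reproduces_fit(self, truth):
        """With one subject per arm the stratified resample is always the
        original study, so the replicate equals a direct refit."""
        data, _ = simulate_study(n_per_arm=1, seed=66)
        cfg = SaemConfig(k1=60, k2=40, seed=123)
        init = generic_init()
        res = bootstrap(data, init, n_boot=1, seed=0, config=cfg)
        from dataclasses import replace
        direct = fit_saem(data, init, replace(cfg, seed=cfg.seed,
                                              ll_method="none",
                                              compute_rse=False,
                                              compute_ebes=False))
        for p in PARAM_NAMES:
            assert res.replicates[p].iloc[0] == direct.estimates.theta[p]

    def test_percentile_ordering_and_interval_shrinkage(self, truth):
        cfg = SaemConfig(k1=60, k2=40, seed=9)
        widths = {}
        for n_arm in (10, 40):
            data, _ = simulate_study(n_per_arm=n_arm, seed=77)
            res = bootstrap(data, generic_init(), n_boot=20, seed=10, config=cfg)
            assert res.p5["cl"] <= res.median["cl"] <= res.p95["cl"]
            widths[n_arm] = res.p95["cl"] - res.p5["cl"]
            assert res.n_success == 20
        assert widths[40] < widths[10]
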