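"""Hierarchical model, covariate machinery, likelihood and SAEM estimation."""

import numpy as np
import pandas as pd
import pytest

from pkstudy import (NC, PopulationModel, SaemConfig, SimulationConfig,
                     StudyDesign, apply_covariates, covariate_search, fit_saem,
                     loglikelihood, sample_individual, simulate_study)
from pkstudy.popfit import PARAM_NAMES

from conftest import generic_init


class TestCovariateModel:
    def test_formulation_effect_on_lag(self, truth):
        free = apply_covariates(truth, "FREE")
        nc = apply_covariates(truth, "NC")
        assert free.tlag2 == pytest.approx(1.22)
        assert nc.tlag2 == pytest.approx(1.22 * np.exp(0.74), rel=1e-12)
        assert round(nc.tlag2, 1) == 2.6  # ≈ 2.55 h reported for the NC arm

    def test_formulation_effect_on_v2(self, truth):
        nc = apply_covariates(truth, "NC")
        assert nc.v2 == pytest.approx(0.134 * np.exp(1.11), rel=1e-12)
        assert nc.v2 == pytest.approx(0.406, rel=5e-3)

    def test_zero_beta_is_identity(self, truth):
        m = truth.copy(beta={"tlag2~form": 0.0})
        assert apply_covariates(m, "NC").tlag2 == pytest.approx(1.22)

    def test_unknown_level_errors(self, truth):
        with pytest.raises(ValueError):
            apply_covariates(truth, "IV")

    def test_weight_power_model(self, truth):
        m = truth.copy(beta={"cl~weight": 0.75},
                       covariate_refs={"weight": 13.0})
        heavy = apply_covariates(m, "FREE", weight=26.0)
        assert heavy.cl == pytest.approx(0.006 * 2 ** 0.75, rel=1e-12)
        with pytest.raises(ValueError):
            apply_covariates(m, "FREE")  # weight required but missing


class TestSampling:
    def test_zero_omega_reproduces_typical(self, truth):
        m = truth.copy(omega={})
        ind = sample_individual(m, NC, rng=0)
        typ = apply_covariates(m, NC)
        assert ind.realized == typ
        assert all(v == 0.0 for v in ind.eta.values())

    def test_lognormal_median_is_typical_value(self, truth):
        rng = np.random.default_rng(123)
        ka1 = [sample_individual(truth, "FREE", rng=rng).realized.ka1
               for _ in range(10_000)]
        assert np.median(ka1) == pytest.approx(0.086, rel=0.02)

    def test_eta_mean_zero_on_log_scale(self, truth):
        rng = np.random.default_rng(5)
        devs = [np.log(sample_individual(truth, "FREE", rng=rng).realized.cl / 0.006)
                for _ in range(4000)]
        assert abs(np.mean(devs)) < 3 * 0.32 / np.sqrt(4000)


class TestLikelihood:
    def test_no_iiv_matches_closed_form(self, truth):
        """With no random effects the marginal likelihood is the Gaussian
        proportional-error likelihood at the typical prediction, exactly."""
        m = truth.copy(omega={})
        data, _ = simulate_study(SimulationConfig(
            design=StudyDesign(n_per_arm=1), truth=m, seed=77))
        from pkstudy.structural import StructuralParams, predict_concentration
        total = 0.0
        for s in data.subjects():
            f = predict_concentration(apply_covariates(m, s["formulation"]),
                                      s["dose_per_kg"], s["times"])
            sd = m.b * f
            total += np.sum(((s["conc"] - f) / sd) ** 2 + np.log(2 * np.pi * sd**2))
        assert loglikelihood(m, data, method="is", seed=3) == pytest.approx(
            total, abs=0.1)

    def test_tiny_omega_approaches_closed_form(self, truth):
        m = truth.copy(omega={"cl": 1e-4})
        data, _ = simulate_study(SimulationConfig(
            design=StudyDesign(n_per_arm=1), truth=truth.copy(omega={}), seed=78))
        exact = loglikelihood(truth.copy(omega={}), data)
        assert loglikelihood(m, data, method="is", n_samples=2000,
                             seed=4) == pytest.approx(exact, abs=0.1)

    def test_duplicated_subjects_double_minus2ll(self, truth):
        data, _ = simulate_study(SimulationConfig(
            design=StudyDesign(n_per_arm=1), truth=truth, seed=9))
        doubled = data.subset([1, 1, 2, 2], relabel=True)
        one = loglikelihood(truth, data, method="is", n_samples=2000, seed=5)
        two = loglikelihood(truth, doubled, method="is", n_samples=2000, seed=6)
        assert two == pytest.approx(2 * one, rel=0.02)

    def test_truth_dominates_perturbed_model(self, truth):
        data, _ = simulate_study(n_per_arm=25, seed=31)
        bad = truth.copy(theta={**truth.theta, "cl": truth.theta["cl"] * 3})
        assert (loglikelihood(truth, data, method="laplace")
                < loglikelihood(bad, data, method="laplace"))

    def test_subject_order_invariance(self, truth):
        data, _ = simulate_study(n_per_arm=3, seed=12)
        reordered = data.subset(list(reversed(data.subject_ids)), relabel=True)
        assert loglikelihood(truth, data, method="laplace") == pytest.approx(
            loglikelihood(truth, reordered, method="laplace"), rel=1e-9)


class TestSaem:
    def test_near_noiseless_identifiability(self, truth):
        """No IIV, tiny proportional noise, rich sampling: the fixed effects
        are recovered tightly."""
        dense = StudyDesign(n_per_arm=5, sampling_times=tuple(
            np.round(np.concatenate([np.arange(0.25, 12, 0.5),
                                     np.arange(12, 97, 4.0)]), 3)))
        gen = truth.copy(omega={}, beta={}, b=0.002)
        data, _ = simulate_study(SimulationConfig(design=dense, truth=gen, seed=21))
        init = generic_init(with_covariates=False).copy(omega={})
        fit = fit_saem(data, init, SaemConfig(seed=22, ll_method="none",
                                              compute_rse=False,
                                              compute_ebes=False))
        for p in PARAM_NAMES:
            assert fit.estimates.theta[p] == pytest.approx(
                gen.theta[p], rel=0.01), p
        assert fit.estimates.b == pytest.approx(0.002, rel=0.15)

    def test_seed_reproducibility_bitwise(self, paper_design_study):
        data, _ = paper_design_study
        cfg = SaemConfig(k1=60, k2=40, seed=99, ll_method="none",
                         compute_rse=False, compute_ebes=False)
        a = fit_saem(data, generic_init(), cfg)
        b = fit_saem(data, generic_init(), cfg)
        assert a.estimates.theta == b.estimates.theta
        assert a.estimates.omega == b.estimates.omega
        assert a.estimates.beta == b.estimates.beta
        assert a.estimates.b == b.estimates.b

    def test_aic_definition(self, fitted_small_study):
        _, fit = fitted_small_study
        assert fit.aic - fit.minus2ll == pytest.approx(
            2 * fit.estimates.n_parameters)
        assert fit.estimates.n_parameters == 18

    def test_covariate_model_beats_null_on_covariate_data(self, truth):
        data, _ = simulate_study(n_per_arm=12, seed=41)
        cfg = SaemConfig(k1=150, k2=100, seed=42, ll_method="laplace",
                         compute_rse=False, compute_ebes=False)
        with_cov = fit_saem(data, generic_init(True), cfg)
        without = fit_saem(data, generic_init(False), cfg)
        assert without.minus2ll - with_cov.minus2ll > 3.84

    def test_fit_reports_rse_and_shrinkage(self, fitted_small_study):
        _, fit = fitted_small_study
        assert 0 < fit.rse_pct["cl"] < 100
        assert set(fit.eta_shrinkage_pct) == set(fit.estimates.omega)
        assert all(v <= 100.0 for v in fit.eta_shrinkage_pct.values())
        assert len(fit.ebes) == 18
        assert len(fit.trace) == fit.config.k1 + fit.config.k2

    def test_fit_result_json_round_trip(self, fitted_small_study):
        import json
        _, fit = fitted_small_study
        payload = json.loads(fit.to_json())
        m = PopulationModel(**payload["estimates"])
        assert m.theta == pytest.approx(fit.estimates.theta)


class TestCovariateSearch:
    def test_empty_candidates_returns_base(self, paper_design_study):
        data, _ = paper_design_study
        cfg = SaemConfig(k1=50, k2=30, seed=1, ll_method="laplace")
        fit, log = covariate_search(data, generic_init(False), [], cfg)
        assert fit.estimates.beta == {}
        assert [entry["step"] for entry in log] == ["base"]

    def test_true_effects_selected(self, truth):
        data, _ = simulate_study(n_per_arm=15, seed=71)
        cfg = SaemConfig(k1=120, k2=80, seed=72, ll_method="laplace")
        fit, log = covariate_search(
            data, generic_init(False),
            ["tlag2~form", "v2~form", "cl~form", "v1~form"], cfg)
        assert set(fit.estimates.beta) == {"tlag2~form", "v2~form"}
        assert any("delta_ofv" in entry for entry in log)
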