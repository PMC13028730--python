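"""Non-compartmental metrics against closed-form profiles and the model."""

import numpy as np
import pytest

from pkstudy import (FREE, NC, EstimationError, NCAResult, auc_trapezoid,
                     fit_lambda_z, group_compare, nca_single,
                     predict_auc_inf, predict_concentration)

SCHEDULE = np.array([0.5, 1, 2, 4, 6, 8, 12, 24, 36, 48, 60], dtype=float)


class TestLambdaZ:
    def test_monoexponential_is_exact(self):
        conc = 2.0 * np.exp(-0.1 * SCHEDULE)
        lam, n, r2adj = fit_lambda_z(SCHEDULE, conc)
        assert lam == pytest.approx(0.1, rel=1e-10)
        assert r2adj == pytest.approx(1.0)
        assert n >= 3

    def test_half_life_formula(self):
        conc = np.exp(-0.0462 * SCHEDULE)
        lam, _, _ = fit_lambda_z(SCHEDULE, conc)
        assert np.log(2) / lam == pytest.approx(15.0, rel=1e-3)

    def test_too_few_points_errors(self):
        with pytest.raises(EstimationError):
            fit_lambda_z([1.0, 2.0], [1.0, 0.5])

    def test_rising_tail_errors(self):
        t = np.array([1, 2, 4, 8, 12.0])
        with pytest.raises(EstimationError):
            fit_lambda_z(t, np.array([1.0, 0.9, 1.0, 1.1, 1.2]))


class TestAUC:
    def test_constant_profile(self):
        t = np.array([0.0, 2.0, 5.0, 10.0])
        assert auc_trapezoid(t, np.full(4, 3.0)) == pytest.approx(30.0)

    def test_exponential_dense_grid(self):
        t = np.linspace(0, 100, 2000)
        assert auc_trapezoid(t, np.exp(-0.1 * t)) == pytest.approx(10.0, rel=1e-3)

    def test_single_point_errors(self):
        with pytest.raises(EstimationError):
            auc_trapezoid([1.0], [1.0])

    def test_unsorted_times_error(self):
        with pytest.raises(EstimationError):
            auc_trapezoid([1.0, 0.5, 2.0], [1.0, 2.0, 0.5])

    def test_origin_prepended_for_oral_profiles(self):
        # first trapezoid rises from (0, 0), not from the first sample
        t = np.array([1.0, 2.0])
        c = np.array([2.0, 2.0])
        assert auc_trapezoid(t, c) == pytest.approx(1.0 + 2.0)

    def test_log_down_variant_below_linear_on_decline(self):
        t = np.array([0.0, 2.0, 4.0])
        c = np.exp(-0.5 * t)
        lin = auc_trapezoid(t, c)
        logd = auc_trapezoid(t, c, method="log-down")
        assert logd < lin
        assert logd == pytest.approx(2.0 * (1 - np.exp(-2.0)), rel=1e-6)


class TestSingleSubject:
    def test_cmax_tmax_argmax(self):
        t = np.array([0.5, 1, 2, 4, 6, 8, 12, 24, 36.0])
        c = np.array([0.5, 1.0, 1.33, 1.2, 1.0, 0.8, 0.5, 0.2, 0.08])
        res = nca_single(t, c, 0.2)
        assert res.tmax == 2.0
        assert res.cmax == 1.33

    def test_model_consistency_dense_grid(self, typical_free):
        """NCA on a dense noise-free model profile recovers dose/CL."""
        t = np.concatenate([np.linspace(0.05, 60, 400), np.linspace(61, 600, 300)])
        c = predict_concentration(typical_free, 0.2, t)
        res = nca_single(t, c, 0.2)
        assert res.auc_0_inf == pytest.approx(predict_auc_inf(typical_free, 0.2),
                                              rel=0.01)
        assert res.auc_ext_pct < 100.0
        assert res.auc_0_inf >= res.auc_0_t

    def test_derived_metric_identities(self):
        t = SCHEDULE
        c = 2.0 * np.exp(-0.05 * t)
        res = nca_single(t, c, 0.2)
        assert res.t_half == pytest.approx(np.log(2) / res.lambda_z)
        assert res.cl_f == pytest.approx(0.2 / res.auc_0_inf)
        assert res.vd_f == pytest.approx(res.cl_f / res.lambda_z)
        assert res.cl_f_ml_min_kg == pytest.approx(res.cl_f * 1000 / 60)

    def test_extrapolated_fraction_shrinks_with_longer_sampling(self, typical_free):
        t_long = np.linspace(0.5, 120, 60)
        c_long = predict_concentration(typical_free, 0.2, t_long)
        short = nca_single(t_long[:30], c_long[:30], 0.2)
        long = nca_single(t_long, c_long, 0.2)
        assert long.auc_ext_pct < short.auc_ext_pct

    def test_unit_rescaling(self):
        t = SCHEDULE
        c = 2.0 * np.exp(-0.05 * t)
        a = nca_single(t, c, 0.2)
        b = nca_single(t, 10 * c, 0.2)
        assert b.cmax == pytest.approx(10 * a.cmax)
        assert b.auc_0_inf == pytest.approx(10 * a.auc_0_inf)
        assert b.lambda_z == pytest.approx(a.lambda_z)
        assert b.tmax == a.tmax
        assert b.mrt == pytest.approx(a.mrt)


def _toy_result(sid, form, auc):
    """NCAResult with a chosen AUC0-inf; other metrics filled consistently."""
    lam = 0.05
    return NCAResult(subject_id=sid, formulation=form, auc_0_t=0.9 * auc,
                     auc_0_inf=auc, auc_ext_pct=10.0, cmax=1.0, tmax=2.0,
                     lambda_z=lam, t_half=np.log(2) / lam, cl_f=0.2 / auc,
                     vd_f=0.2 / auc / lam, mrt=20.0, n_lambda_points=4,
                     lambda_r2adj=0.99)


class TestGroupCompare:
    def test_identical_arms(self):
        res = ([_toy_result(i, FREE, 30.0 + (i % 3)) for i in range(9)]
               + [_toy_result(9 + i, NC, 30.0 + (i % 3)) for i in range(9)])
        summary = group_compare(res)
        assert summary.frel == pytest.approx(1.0)
        assert summary.p_values["auc_0_inf"] == pytest.approx(1.0, abs=1e-9)

    def test_separated_arms_significant(self):
        rng = np.random.default_rng(7)
        res = ([_toy_result(i, FREE, rng.normal(10, 1)) for i in range(9)]
               + [_toy_result(9 + i, NC, rng.normal(20, 1)) for i in range(9)])
        summary = group_compare(res)
        assert summary.p_values["auc_0_inf"] < 1e-3
        assert summary.frel == pytest.approx(2.0, rel=0.1)

    def test_absolute_bioavailability_from_iv_reference(self):
        res = ([_toy_result(i, FREE, 30.0 + i * 0.1) for i in range(3)]
               + [_toy_result(10 + i, NC, 32.0 + i * 0.1) for i in range(3)])
        # IV reference with the same dose and AUC equal to the FREE mean -> F ≈ 1
        summary = group_compare(res, iv_ref_auc=30.1, iv_ref_dose=0.2)
        assert summary.f_abs[FREE] == pytest.approx(1.0, rel=1e-6)
        assert summary.f_abs[NC] == pytest.approx(32.1 / 30.1, rel=1e-6)

    def test_one_small_arm_errors(self):
        with pytest.raises(EstimationError):
            group_compare([_toy_result(1, FREE, 30.0)]
                          + [_toy_result(2, NC, 30.0), _toy_result(3, NC, 31.0)])
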