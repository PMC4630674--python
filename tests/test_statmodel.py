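"""Linearization families, mixed-effects fits, LRT, Nakagawa R², prediction."""

import numpy as np
import pandas as pd
import pytest

from locogait.statmodel import (LmmFit, fit_linearization, fit_lmm,
                                likelihood_ratio_test, predict_param,
                                r2_nakagawa)


def _lmm_data(rng, n_sub=12, n_obs=40, b_speed=3.0, b_weight=0.05,
              intercept_sd=0.5, resid_sd=0.3, extra_noise_col=False):
    rows = []
    for s in range(n_sub):
        b0 = rng.normal(0, intercept_sd)
        speed = rng.uniform(0.1, 0.5, n_obs)
        weight = rng.uniform(12, 30)
        y = 2.0 + b_speed * speed + b_weight * weight + b0 \
            + rng.normal(0, resid_sd, n_obs)
        d = {"subject": f"s{s}", "speed": speed, "weight": weight, "y": y}
        if extra_noise_col:
            d["noise"] = rng.normal(size=n_obs)
        rows.append(pd.DataFrame(d))
    return pd.concat(rows, ignore_index=True)


class TestLinearization:
    def test_exact_linear_data(self):
        v = np.linspace(0.1, 0.5, 50)
        fit = fit_linearization(v, 2.0 * v + 1.0)
        assert fit.family == "linear"
        np.testing.assert_allclose(fit.coefficients, [1.0, 2.0], atol=1e-9)
        assert fit.r_squared == pytest.approx(1.0)

    def test_power_family_recovered_from_noisy_data(self):
        rng = np.random.default_rng(0)
        v = rng.uniform(0.05, 0.5, 200)
        y = 2.0 * v ** 0.7 + rng.normal(0, 0.02, 200)
        fit = fit_linearization(v, y)
        assert fit.family == "power"
        assert fit.coefficients[1] == pytest.approx(0.7, abs=0.05)

    def test_constant_data_degenerate_linear(self):
        v = np.linspace(0.1, 0.5, 30)
        fit = fit_linearization(v, np.full(30, 7.0))
        assert fit.family == "linear" and fit.degenerate

    def test_nonpositive_values_skip_log_families(self):
        v = np.linspace(0.1, 0.5, 30)
        y = np.linspace(-1.0, 1.0, 30)
        fit = fit_linearization(v, y)
        assert all(f not in dict(fit.ranking)
                   for f in ("exponential", "power"))

    def test_back_transform_round_trip(self):
        rng = np.random.default_rng(1)
        v = rng.uniform(0.1, 0.5, 100)
        y = 1.5 * np.exp(2.0 * v) * np.exp(rng.normal(0, 0.01, 100))
        fit = fit_linearization(v, y)
        lin = fit.transform(v, y)
        np.testing.assert_allclose(fit.back_transform(lin), y, rtol=1e-9)


class TestFitLmm:
    def test_single_subject_raises(self):
        df = pd.DataFrame({"subject": "a", "speed": np.arange(10.0),
                           "y": np.arange(10.0)})
        with pytest.raises(ValueError, match="2 subjects"):
            fit_lmm(df, "y", ["speed"])

    def test_collinear_design_raises_naming_terms(self):
        rng = np.random.default_rng(2)
        df = _lmm_data(rng)
        df["weight2"] = 2.0 * df["weight"]
        with pytest.raises(ValueError, match="collinear"):
            fit_lmm(df, "y", ["weight", "weight2"])

    def test_zero_random_variance_matches_ols(self):
        rng = np.random.default_rng(3)
        df = _lmm_data(rng, intercept_sd=0.0, n_sub=10, n_obs=60)
        fit = fit_lmm(df, "y", ["speed", "weight"])
        assert fit.random_intercept_var == pytest.approx(0.0, abs=1e-3)
        X = np.column_stack([np.ones(len(df)), df.speed, df.weight])
        beta, *_ = np.linalg.lstsq(X, df.y.to_numpy(), rcond=None)
        assert fit.coefficients["speed"] == pytest.approx(beta[1], abs=0.02)
        assert fit.coefficients["weight"] == pytest.approx(beta[2], abs=0.02)

    def test_parameter_recovery_within_two_se(self):
        # small design for speed; the full 30-subject x 100-stride coverage
        # check lives in the acceptance suite
        hits = 0
        n_rep = 30
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            df = _lmm_data(rng, n_sub=15, n_obs=40)
            fit = fit_lmm(df, "y", ["speed", "weight"])
            ok = (abs(fit.coefficients["speed"] - 3.0)
                  <= 2 * fit.coefficient_se["speed"]
                  and abs(fit.coefficients["weight"] - 0.05)
                  <= 2 * fit.coefficient_se["weight"])
            hits += ok
        assert hits / n_rep >= 0.75

    def test_adding_covariate_never_decreases_loglik(self):
        rng = np.random.default_rng(4)
        df = _lmm_data(rng, extra_noise_col=True)
        small = fit_lmm(df, "y", ["speed"])
        big = fit_lmm(df, "y", ["speed", "noise"])
        assert big.log_likelihood >= small.log_likelihood - 1e-6


class TestLikelihoodRatio:
    def test_identical_models_statistic_zero(self):
        rng = np.random.default_rng(5)
        df = _lmm_data(rng)
        fit = fit_lmm(df, "y", ["speed"])
        out = likelihood_ratio_test(fit, fit)
        assert out["statistic"] == 0.0 and out["p_value"] == 1.0

    def test_non_nested_models_raise(self):
        rng = np.random.default_rng(6)
        df = _lmm_data(rng, extra_noise_col=True)
        a = fit_lmm(df, "y", ["speed"])
        b = fit_lmm(df, "y", ["noise"])
        with pytest.raises(ValueError, match="nested"):
            likelihood_ratio_test(a, b)

    def test_strong_effect_always_detected(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            df = _lmm_data(rng, b_speed=5.0)
            nested = fit_lmm(df, "y", ["weight"])
            full = fit_lmm(df, "y", ["weight", "speed"])
            out = likelihood_ratio_test(nested, full)
            assert out["p_value"] < 1e-3

    def test_null_covariate_type_one_error_calibrated(self):
        rejections = 0
        n_rep = 200
        for seed in range(n_rep):
            rng = np.random.default_rng(10_000 + seed)
            df = _lmm_data(rng, n_sub=8, n_obs=25, extra_noise_col=True)
            nested = fit_lmm(df, "y", ["speed"])
            full = fit_lmm(df, "y", ["speed", "noise"])
            if likelihood_ratio_test(nested, full)["p_value"] < 0.05:
                rejections += 1
        assert 0.02 <= rejections / n_rep <= 0.09


class TestR2Nakagawa:
    def test_direct_formula(self):
        fit = LmmFit(fixed_terms=["speed"], coefficients={}, coefficient_se={},
                     random_intercept_var=1.0, random_slope_var=None,
                     residual_var=1.0, log_likelihood=0.0, n_obs=10,
                     n_subjects=2,
                     fitted_fixed=np.array([0.0, 2 * np.sqrt(2)]))
        # var_fixed = 2 -> marginal 0.5, conditional 0.75
        marg, cond = r2_nakagawa(fit)
        assert marg == pytest.approx(0.5, abs=1e-12)
        assert cond == pytest.approx(0.75, abs=1e-12)

    def test_no_random_variance_marginal_equals_conditional(self):
        rng = np.random.default_rng(7)
        df = _lmm_data(rng, intercept_sd=0.0)
        fit = fit_lmm(df, "y", ["speed", "weight"])
        marg, cond = r2_nakagawa(fit)
        assert cond - marg == pytest.approx(0.0, abs=0.01)

    def test_generative_marginal_r2_recovered(self):
        rng = np.random.default_rng(8)
        # choose variances for a known marginal R²
        df = _lmm_data(rng, n_sub=30, n_obs=80, b_speed=3.0, b_weight=0.0,
                       intercept_sd=0.3, resid_sd=0.3)
        fit = fit_lmm(df, "y", ["speed"])
        var_fixed = np.var(3.0 * df.speed.to_numpy())
        want = var_fixed / (var_fixed + 0.3 ** 2 + 0.3 ** 2)
        marg, _ = r2_nakagawa(fit)
        assert marg == pytest.approx(want, abs=0.05)


class TestPrediction:
    def _fit(self):
        rng = np.random.default_rng(9)
        df = _lmm_data(rng, n_sub=10, n_obs=50, resid_sd=0.05)
        return fit_lmm(df, "y", ["speed", "weight"])

    def test_linear_prediction_arithmetic(self):
        fit = self._fit()
        got = predict_param(fit, speed=0.3, weight=20.0)
        want = (fit.coefficients["intercept"] + fit.coefficients["speed"] * 0.3
                + fit.coefficients["weight"] * 20.0)
        assert got[0] == pytest.approx(want, abs=1e-12)

    def test_weight_difference_scales_with_coefficient(self):
        fit = self._fit()
        p1 = predict_param(fit, 0.3, 18.0)
        p2 = predict_param(fit, 0.3, 26.0)
        assert (p2 - p1)[0] == pytest.approx(
            8.0 * fit.coefficients["weight"], abs=1e-9)

    def test_recovery_of_generative_fixed_curve(self):
        fit = self._fit()
        speeds = np.linspace(0.15, 0.45, 5)
        pred = predict_param(fit, speeds, weight=20.0)
        want = 2.0 + 3.0 * speeds + 0.05 * 20.0
        np.testing.assert_allclose(pred, want, atol=0.25)
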