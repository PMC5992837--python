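"""OLS / AR(1)-ML fitting, diagnostics, model selection and slope derivation."""

import numpy as np
import pandas as pd
import pytest
from scipy.linalg import toeplitz
from scipy.stats import multivariate_normal

import priceits as p
from priceits.estimation import EstimationError, ar1_loglik, _profile_fit


class TestOLS:
    def test_zero_noise_recovers_beta_exactly(self, X, Xc, study_beta):
        fit = p.fit_ols(Xc @ study_beta, X)
        np.testing.assert_allclose(fit.beta.to_numpy(), study_beta, rtol=1e-8)

    def test_matches_normal_equations_on_small_instance(self):
        rng = np.random.default_rng(4)
        Xs = rng.normal(size=(10, 3))
        y = rng.normal(size=10)
        fit = p.fit_ols(y, Xs)
        Xc = np.column_stack([np.ones(10), Xs])
        beta_direct = np.linalg.solve(Xc.T @ Xc, Xc.T @ y)
        np.testing.assert_allclose(fit.beta.to_numpy(), beta_direct, rtol=1e-10)

    def test_translation_equivariance(self, X, Xc, study_beta):
        rng = np.random.default_rng(5)
        y = Xc @ study_beta + rng.normal(0, 1, 54)
        f0, f1 = p.fit_ols(y, X), p.fit_ols(y + 17.5, X)
        assert f1.beta.iloc[0] - f0.beta.iloc[0] == pytest.approx(17.5, abs=1e-8)
        np.testing.assert_allclose(f1.beta.iloc[1:], f0.beta.iloc[1:], atol=1e-8)

    def test_singular_design_names_dependent_columns(self, X):
        Xbad = X.copy()
        Xbad["dup"] = 2 * Xbad["time"]
        with pytest.raises(EstimationError, match="singular"):
            p.fit_ols(np.arange(54.0), Xbad)

    def test_missing_outcome_months_are_an_error(self, X):
        y = np.arange(54.0)
        y[10] = np.nan
        with pytest.raises(EstimationError, match="missing"):
            p.fit_ols(y, X)


class TestAR1ML:
    def test_loglik_agrees_with_dense_toeplitz_oracle(self, X, Xc, study_beta, ar1_oracle):
        for seed, rho in ((0, 0.4), (1, -0.5), (2, 0.0)):
            y = ar1_oracle(Xc, study_beta, rho, 0.7, np.random.default_rng(seed))
            fit = p.fit_ar1_ml(y, X)
            cov = fit.sigma2 / (1 - fit.rho**2) * toeplitz(fit.rho ** np.arange(54))
            oracle = multivariate_normal(mean=Xc @ fit.beta.to_numpy(), cov=cov).logpdf(y)
            assert fit.loglik == pytest.approx(oracle, abs=1e-6)
            # and the optimum cannot be beaten on a rho grid
            grid = [_profile_fit(r, y, Xc)[2] for r in np.linspace(-0.9, 0.9, 19)]
            assert fit.loglik >= max(grid) - 1e-8

    def test_reduces_to_ols_when_errors_are_iid(self, X, Xc, study_beta):
        rng = np.random.default_rng(6)
        y = Xc @ study_beta + rng.normal(0, 0.6, 54)
        ols, ar1 = p.fit_ols(y, X), p.fit_ar1_ml(y, X)
        assert abs(ar1.rho) < 0.35
        assert np.all(np.abs(ar1.beta - ols.beta) < 2 * ols.se)

    def test_profile_beta_is_continuous_at_rho_zero(self, X, Xc, study_beta):
        rng = np.random.default_rng(7)
        y = Xc @ study_beta + rng.normal(0, 0.6, 54)
        ols = p.fit_ols(y, X)
        for rho in (1e-6, 1e-4, 1e-3):
            beta_rho, *_ = _profile_fit(rho, y, Xc)
            np.testing.assert_allclose(beta_rho, ols.beta.to_numpy(), rtol=1e-2)

    def test_rho_recovery_at_larger_n(self, ar1_oracle):
        # 500 series of length 200 at rho = 0.5; mean rho-hat near truth
        sched = p.InterventionSchedule(n_months=200)
        X = p.build_design_matrix(sched)
        Xc = np.column_stack([np.ones(200), X.to_numpy(float)])
        beta = np.array([10.0, 0.1, -1.0, 0.05, -2.0, 0.1, -0.5])
        rng = np.random.default_rng(8)
        rhos = [
            p.fit_ar1_ml(ar1_oracle(Xc, beta, 0.5, 1.0, rng), X).rho
            for _ in range(500)
        ]
        # O(1/n) detrending bias plus MC error stays inside 0.05
        assert abs(np.mean(rhos) - 0.5) < 0.05

    def test_short_series_rejected(self):
        with pytest.raises(EstimationError):
            p.fit_ar1_ml(np.arange(8.0), np.arange(8.0).reshape(-1, 1))

    def test_loglik_function_matches_direct_density(self, Xc, study_beta):
        # the likelihood evaluator itself, at arbitrary (not fitted) parameters
        rng = np.random.default_rng(9)
        y = Xc @ study_beta + rng.normal(0, 1, 54)
        rho, s2 = 0.3, 1.21
        cov = s2 / (1 - rho**2) * toeplitz(rho ** np.arange(54))
        oracle = multivariate_normal(mean=Xc @ study_beta, cov=cov).logpdf(y)
        got = ar1_loglik(study_beta, rho, s2, y, Xc)
        assert got == pytest.approx(oracle, abs=1e-8)


class TestDurbinWatson:
    @pytest.mark.parametrize(
        "resid, expected",
        [
            ((1, -1, 1, -1), 3.0),  # sum diff^2 = 12, sum e^2 = 4
            ((1, 2, 3, 4), 3 / 30),  # hand arithmetic
        ],
    )
    def test_hand_computable_values(self, resid, expected):
        assert p.durbin_watson(resid) == pytest.approx(expected)

    def test_white_noise_mean_is_two(self):
        rng = np.random.default_rng(10)
        dws = [p.durbin_watson(rng.standard_normal(200)) for _ in range(2000)]
        assert np.mean(dws) == pytest.approx(2.0, abs=0.05)

    def test_all_zero_residuals_undefined(self):
        with pytest.raises(EstimationError):
            p.durbin_watson(np.zeros(10))

    def test_pvalue_is_scale_invariant_and_calibrated(self, X):
        resid = np.random.default_rng(14).standard_normal(54)
        # the statistic (hence its p-value) is invariant to residual scaling
        assert p.durbin_watson(resid) == pytest.approx(p.durbin_watson(100 * resid))
        p_low = p.dw_pvalue(1.7, X, n_sim=2000, seed=3)
        assert p.dw_pvalue(1.7, X, n_sim=2000, seed=3) == p_low  # seeded
        assert 0 < p_low < 0.2  # positively autocorrelated side
        # near the null centre the tail probability is large
        assert p.dw_pvalue(2.2, X, n_sim=2000, seed=3) > 0.3


class TestModelSelection:
    def test_tie_goes_to_ols(self, X, Xc, study_beta):
        rng = np.random.default_rng(11)
        y = Xc @ study_beta + rng.normal(0, 0.6, 54)
        ols, ar1 = p.fit_ols(y, X), p.fit_ar1_ml(y, X)
        ar1.aic = ols.aic  # constructed tie
        assert p.select_model(ols, ar1).method == "OLS"

    def test_mismatched_inputs_rejected(self, X, Xc, study_beta):
        rng = np.random.default_rng(12)
        y1 = Xc @ study_beta + rng.normal(0, 0.6, 54)
        y2 = Xc @ study_beta + rng.normal(0, 0.6, 54)
        with pytest.raises(EstimationError):
            p.select_model(p.fit_ols(y1, X), p.fit_ar1_ml(y2, X))

    def test_dw_pvalue_recorded_on_selection(self, X, Xc, study_beta):
        rng = np.random.default_rng(13)
        y = Xc @ study_beta + rng.normal(0, 0.6, 54)
        chosen = p.select_model(p.fit_ols(y, X), p.fit_ar1_ml(y, X), dw_p=0.42)
        assert chosen.dw_pvalue == 0.42


class TestWhiteNoise:
    def test_iid_gaussian_residuals_pass(self):
        e = np.random.default_rng(2).standard_normal(54)
        assert p.white_noise_check(e, max_lag=12).passed

    def test_strong_ar1_fails_at_lag_one(self, ar1_oracle):
        Xc = np.ones((54, 1))
        e = ar1_oracle(Xc, np.zeros(1), 0.8, 1.0, np.random.default_rng(1))
        report = p.white_noise_check(e, max_lag=6)
        assert not report.passed and report.acf[0] > report.bound

    def test_alternating_sequence_fails_with_negative_lag1(self):
        report = p.white_noise_check(np.tile([1.0, -1.0], 27), max_lag=6)
        assert not report.passed and report.acf[0] < -0.9

    def test_max_lag_precondition(self):
        with pytest.raises(EstimationError):
            p.white_noise_check(np.arange(10.0), max_lag=5)


class TestSegmentSlopes:
    def test_constant_price_cost_slopes_match_published_text(self):
        # pre-cut slope 0.229+0.049 = 0.278 (~0.28); post 0.489 (~0.49)
        ss = p.segment_slopes((6.240, 0.229, -2.264, 0.049, 0.384, 0.211, -0.856))
        assert ss.post_opip_slope == pytest.approx(0.278)
        assert ss.post_sps_slope == pytest.approx(0.489)

    def test_reduced_patient_count_slope_reversal(self):
        ss = p.segment_slopes((1129486, 4909, -6604, 532, 7296, -7523, -64306))
        assert ss.post_opip_slope == pytest.approx(5441)
        assert ss.post_sps_slope == pytest.approx(-2082)

    def test_all_zero_coefficients_give_flat_segments(self):
        ss = p.segment_slopes(np.zeros(7))
        assert (ss.baseline_slope, ss.post_opip_slope, ss.post_sps_slope) == (0, 0, 0)
        assert (ss.opip_level_change, ss.sps_level_change) == (0, 0)
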