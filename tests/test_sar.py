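"""Spatial lag / spatial error ML estimation, selection, and effect transforms."""

import numpy as np
import pytest
import statsmodels.api as sm

from greensar.sar import (LogDeterminant, SARFit, concentrated_loglik_slm,
                          fit_sem, fit_slm, pct_per_iqr, select_model, total_effect)
from greensar.synthetic_city import SyntheticCityConfig, generate_city, simulate_pollution


def make_fit(rho, beta, cov=None, model="SLM", n=100):
    p = len(beta)
    cov = cov if cov is not None else np.eye(p + 2) * 1e-4
    return SARFit(model=model, rho_or_lambda=rho, beta=np.asarray(beta, float),
                  sigma2=1.0, loglik=0.0, covariance=cov,
                  residuals=np.zeros(n), converged=True, n=n)


@pytest.fixture(scope="module")
def lag_data(city400):
    y = np.log(city400.pollutants["no2"].to_numpy())
    return y, city400.design, city400.weights


class TestFitSLM:
    def test_reduces_to_ols_at_rho_zero(self, lag_data):
        y, X, swm = lag_data
        logdet = LogDeterminant(swm.W)
        Wy = swm.W @ y
        ll0, beta_std, sigma2, _ = concentrated_loglik_slm(0.0, y, Wy, X, logdet)
        ols = sm.OLS(y, X).fit()
        assert ll0 == pytest.approx(ols.llf, abs=1e-8)
        # profile at rho=0 equals the OLS closed form (X passed unstandardized)
        beta_ols = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(beta_std, beta_ols, atol=1e-10)

    def test_optimum_matches_grid_search(self, lag_data):
        y, X, swm = lag_data
        fit = fit_slm(y, X, swm, compute_se=False)
        logdet = LogDeterminant(swm.W)
        Wy = swm.W @ y
        grid = np.linspace(-0.999, 0.999, 2001)
        lls = [concentrated_loglik_slm(r, y, Wy, X, logdet)[0] for r in grid]
        assert abs(fit.rho - grid[int(np.argmax(lls))]) <= 0.001

    def test_parameter_recovery(self):
        hits_rho = hits_b1 = 0
        for s in range(5):
            cfg = SyntheticCityConfig(n_points=400, extent=(1500.0, 1500.0),
                                      rho_true=0.5,
                                      beta_true=(0.0, -0.08, 0.05, -0.02, 0.08, 0.12),
                                      seed=100 + s)
            city = generate_city(cfg)
            y = np.log(city.pollutants["pm25"].to_numpy())
            fit = fit_slm(y, city.design, city.weights)
            hits_rho += abs(fit.rho - 0.5) <= 0.1
            hits_b1 += abs(fit.beta[1] - (-0.08)) <= 2 * fit.se_beta(1)
        assert hits_rho >= 4 and hits_b1 >= 4

    def test_covariance_symmetric_positive(self, lag_data):
        y, X, swm = lag_data
        fit = fit_slm(y, X, swm)
        C = fit.covariance
        np.testing.assert_allclose(C, C.T, atol=1e-10)
        assert (np.diag(C)[:-1] > 0).all()
        assert fit.converged

    def test_scaling_covariate_leaves_pct_unchanged(self, lag_data):
        y, X, swm = lag_data
        fit = fit_slm(y, X, swm)
        X2 = X.copy()
        X2[:, 1] = X2[:, 1] * 10.0
        fit2 = fit_slm(y, X2, swm)
        assert fit2.beta[1] == pytest.approx(fit.beta[1] / 10.0, rel=1e-6)
        iqr = 12.0
        a = pct_per_iqr(fit, iqr).pct_diff
        b = pct_per_iqr(fit2, iqr * 10.0).pct_diff
        assert a == pytest.approx(b, rel=1e-5)

    def test_rejects_bad_inputs(self, lag_data):
        y, X, swm = lag_data
        with pytest.raises(ValueError, match="intercept"):
            fit_slm(y, X[:, 1:], swm)
        with pytest.raises(ValueError, match="finite"):
            fit_slm(np.r_[y[:-1], np.nan], X, swm)


class TestFitSEM:
    def test_reduces_to_ols_at_lambda_zero(self, lag_data):
        from greensar.sar import concentrated_loglik_sem

        _, X, swm = lag_data
        rng = np.random.default_rng(8)
        beta = np.array([1.0, -0.05, 0.1, 0.0, 0.05, 0.1])
        y = X @ beta + 0.1 * rng.standard_normal(X.shape[0])
        logdet = LogDeterminant(swm.W)
        ll0, beta_prof, _, _ = concentrated_loglik_sem(0.0, y, swm.W @ y, X,
                                                       swm.W @ X, logdet)
        ols = sm.OLS(y, X).fit()
        assert ll0 == pytest.approx(ols.llf, abs=1e-8)
        np.testing.assert_allclose(beta_prof, ols.params, atol=1e-10)

    def test_lambda_recovery(self, lag_data):
        _, X, swm = lag_data
        hits = 0
        for s in range(5):
            rng = np.random.default_rng(50 + s)
            eps = simulate_pollution(
                swm, np.column_stack([np.ones(X.shape[0]), np.zeros(X.shape[0])]),
                [0.0, 0.0], rho=0.6, sigma_eps=0.3, seed=50 + s)
            beta = np.array([1.0, -0.05, 0.1, 0.0, 0.05, 0.1])
            y = X @ beta + eps
            fit = fit_sem(y, X, swm, compute_se=False)
            hits += abs(fit.rho_or_lambda - 0.6) <= 0.15
        assert hits >= 4

    def test_grid_search_agreement(self, lag_data):
        y, X, swm = lag_data
        from greensar.sar import concentrated_loglik_sem

        fit = fit_sem(y, X, swm, compute_se=False)
        logdet = LogDeterminant(swm.W)
        Wy, WX = swm.W @ y, swm.W @ X
        grid = np.linspace(-0.999, 0.999, 2001)
        lls = [concentrated_loglik_sem(r, y, Wy, X, WX, logdet)[0] for r in grid]
        assert abs(fit.rho_or_lambda - grid[int(np.argmax(lls))]) <= 0.001


class TestLogDeterminant:
    def test_eig_equals_sparse_lu(self, weights200):
        ld_eig = LogDeterminant(weights200.W, mode="eig")
        ld_lu = LogDeterminant(weights200.W, mode="lu")
        for rho in (-0.9, -0.3, 0.0, 0.4, 0.8, 0.95):
            assert ld_eig(rho) == pytest.approx(ld_lu(rho), abs=1e-8)


class TestSelectModel:
    def test_prefers_lag_model_on_lag_dgp(self, lag_data):
        y, X, swm = lag_data
        slm = fit_slm(y, X, swm)
        sem = fit_sem(y, X, swm)
        sel = select_model(slm, sem, swm)
        assert sel.choice in {"SLM", "SEM"}
        assert sel.moran_slm.p_analytic > 0.05  # SLM residuals are clean

    def test_lag_dgp_selects_slm_majority(self):
        wins = 0
        for s in range(5):
            cfg = SyntheticCityConfig(n_points=300, extent=(1300.0, 1300.0),
                                      rho_true=0.6, seed=300 + s)
            city = generate_city(cfg)
            y = np.log(city.pollutants["no2"].to_numpy())
            slm = fit_slm(y, city.design, city.weights)
            sem = fit_sem(y, city.design, city.weights)
            wins += select_model(slm, sem, city.weights).choice == "SLM"
        assert wins >= 4

    def test_tie_broken_toward_slm(self, lag_data):
        y, X, swm = lag_data
        slm = fit_slm(y, X, swm)
        twin = SARFit(model="SEM", rho_or_lambda=slm.rho, beta=slm.beta,
                      sigma2=slm.sigma2, loglik=slm.loglik, covariance=slm.covariance,
                      residuals=slm.residuals, converged=True, n=slm.n)
        assert select_model(slm, twin, swm).choice == "SLM"

    def test_unconverged_fit_aborts_selection(self, lag_data):
        y, X, swm = lag_data
        slm = fit_slm(y, X, swm)
        bad = SARFit(model="SEM", rho_or_lambda=0.0, beta=slm.beta, sigma2=1.0,
                     loglik=0.0, covariance=slm.covariance, residuals=slm.residuals,
                     converged=False, n=slm.n)
        with pytest.raises(RuntimeError, match="unconverged"):
            select_model(slm, bad, swm)


class TestTotalEffect:
    def test_identity_when_rho_zero(self):
        fit = make_fit(0.0, [0.5, 1.0])
        assert total_effect(fit).value == 1.0

    def test_spillover_arithmetic(self):
        fit = make_fit(0.5, [0.0, 2.0])
        assert total_effect(fit).value == pytest.approx(4.0, abs=1e-12)

    def test_delta_method_matches_parametric_bootstrap(self, lag_data):
        y, X, swm = lag_data
        fit = fit_slm(y, X, swm)
        te = total_effect(fit)
        mean = np.array([fit.rho, fit.beta[1]])
        cov = fit.covariance[np.ix_([0, 2], [0, 2])]
        draws = np.random.default_rng(1).multivariate_normal(mean, cov, size=2000)
        boot = draws[:, 1] / (1 - draws[:, 0])
        assert te.se == pytest.approx(boot.std(ddof=1), rel=0.10)

    def test_requires_slm_and_stationarity(self):
        with pytest.raises(ValueError, match="spatial lag"):
            total_effect(make_fit(0.0, [1.0, 1.0], model="SEM"))
        with pytest.raises(ValueError, match="rho"):
            total_effect(make_fit(1.0, [1.0, 1.0]))


class TestPctPerIQR:
    def test_zero_coefficient_gives_zero_pct(self):
        eff = pct_per_iqr(make_fit(0.2, [0.0, 0.0]), iqr=5.0)
        assert eff.pct_diff == 0.0

    def test_log_transform_analytic_inverse(self):
        iqr = 2.0
        b = np.log(0.9) / iqr
        eff = pct_per_iqr(make_fit(0.0, [0.0, b]), iqr=iqr)
        assert eff.pct_diff == pytest.approx(-10.0, abs=1e-10)

    def test_matches_direct_formula(self, lag_data):
        y, X, swm = lag_data
        fit = fit_slm(y, X, swm)
        iqr = 11.3
        eff = pct_per_iqr(fit, iqr)
        assert eff.pct_diff == pytest.approx(100 * (np.exp(fit.beta[1] * iqr) - 1), abs=1e-10)
        assert eff.ci_low <= eff.pct_diff <= eff.ci_high

    def test_total_effect_variant_and_linear_scale(self, lag_data):
        y, X, swm = lag_data
        fit = fit_slm(y, X, swm)
        tot = pct_per_iqr(fit, 10.0, use_total=True)
        assert tot.pct_diff == pytest.approx(
            100 * (np.exp(total_effect(fit).value * 10.0) - 1), abs=1e-8)
        lin = pct_per_iqr(fit, 10.0, scale="linear", ybar=3.0)
        assert lin.pct_diff == pytest.approx(100 * fit.beta[1] * 10.0 / 3.0, abs=1e-10)

    def test_parameter_errors(self):
        fit = make_fit(0.0, [0.0, 1.0])
        with pytest.raises(ValueError, match="iqr"):
            pct_per_iqr(fit, 0.0)
        with pytest.raises(ValueError, match="ybar"):
            pct_per_iqr(fit, 1.0, scale="linear")
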