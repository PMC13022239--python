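import numpy as np
import pandas as pd
import pytest
from scipy.linalg import toeplitz
from scipy.stats import multivariate_normal

from pigwater.armax import (
    ModelSpec,
    ParameterSet,
    acf,
    correlogram,
    css_estimate,
    exact_loglik,
    fit_ml,
    information_criteria,
    min_root_modulus,
    pacf,
    prune_coefficients,
    select_order,
    simulate_armax,
    wald_tests,
)


def _dense_loglik(phi, theta, mu, sigma2, y):
    """Independent oracle: multivariate-normal log-density from ARMA
    autocovariances (statsmodels arma_acovf)."""
    from statsmodels.tsa.arima_process import arma_acovf

    p = max(phi, default=0)
    q = max(theta, default=0)
    ar = np.zeros(p + 1)
    ar[0] = 1.0
    for l, v in phi.items():
        ar[l] = -v
    ma = np.zeros(q + 1)
    ma[0] = 1.0
    for l, v in theta.items():
        ma[l] = v
    acov = arma_acovf(ar, ma, nobs=len(y), sigma2=sigma2)
    return multivariate_normal.logpdf(y - mu, cov=toeplitz(acov))


class TestSimulate:
    def test_white_noise_reduction(self):
        spec = ModelSpec()
        y = simulate_armax(spec, ParameterSet(mu=3.0, sigma2=4.0), None, 20_000, seed=0)
        assert y.mean() == pytest.approx(3.0, abs=0.05)
        assert y.var() == pytest.approx(4.0, rel=0.05)

    def test_ma1_lag1_autocorrelation(self):
        th = 0.5
        spec = ModelSpec(ma_lags=(1,))
        y = simulate_armax(spec, ParameterSet(theta={1: th}), None, 50_000, seed=1)
        assert acf(y, 1)[1] == pytest.approx(th / (1 + th**2), abs=0.01)

    def test_ar1_autocorrelation_decay(self):
        spec = ModelSpec(ar_lags=(1,))
        y = simulate_armax(spec, ParameterSet(phi={1: 0.5}), None, 50_000, seed=2)
        rho = acf(y, 3)
        for k in (1, 2, 3):
            assert rho[k] == pytest.approx(0.5**k, abs=0.02)

    def test_nonstationary_rejected_with_modulus(self):
        spec = ModelSpec(ar_lags=(1,))
        with pytest.raises(ValueError, match="root modulus"):
            simulate_armax(spec, ParameterSet(phi={1: 1.05}), None, 100)


class TestCSS:
    def test_ar1_matches_ols_normal_equations(self):
        spec = ModelSpec(ar_lags=(1,))
        y = simulate_armax(spec, ParameterSet(mu=1.0, phi={1: 0.5}), None, 800, seed=3)
        est = css_estimate(spec, y)
        A = np.column_stack([np.ones(len(y) - 1), y[:-1]])
        c, phi = np.linalg.lstsq(A, y[1:], rcond=None)[0]
        assert est.phi[1] == pytest.approx(phi, abs=1e-6)
        assert est.mu * (1 - est.phi[1]) == pytest.approx(c, abs=1e-6)

    def test_white_noise_mu_is_sample_mean(self):
        y = np.random.default_rng(4).normal(5.0, 1.0, 300)
        est = css_estimate(ModelSpec(), y)
        assert est.mu == pytest.approx(y.mean(), abs=1e-8)

    def test_ar1_consistency(self):
        spec = ModelSpec(ar_lags=(1,))
        y = simulate_armax(spec, ParameterSet(phi={1: 0.5}), None, 5000, seed=5)
        est = css_estimate(spec, y)
        assert est.phi[1] == pytest.approx(0.5, abs=0.05)

    def test_css_and_ml_agree_on_long_series(self):
        spec = ModelSpec(ar_lags=(1,))
        y = simulate_armax(spec, ParameterSet(mu=2.0, phi={1: 0.6}), None, 10_000, seed=6)
        c = css_estimate(spec, y)
        m = fit_ml(spec, y)
        assert abs(c.phi[1] - m.params.phi[1]) < 0.02


class TestExactLoglik:
    @pytest.mark.parametrize("case", [
        {"spec": ModelSpec(ar_lags=(1,), ma_lags=(1,)),
         "params": ParameterSet(mu=2.0, phi={1: 0.5}, theta={1: 0.3}, sigma2=1.7)},
        {"spec": ModelSpec(ar_lags=(1, 3), ma_lags=(2,), intercept=True),
         "params": ParameterSet(mu=-1.0, phi={1: 0.4, 3: 0.2}, theta={2: -0.35}, sigma2=0.6)},
        {"spec": ModelSpec(ma_lags=(1, 2)),
         "params": ParameterSet(mu=0.0, theta={1: 0.4, 2: 0.25}, sigma2=2.5)},
    ])
    def test_matches_dense_mvn_oracle(self, case):
        spec, params = case["spec"], case["params"]
        y = simulate_armax(spec, params, None, 40, seed=7)
        ll = exact_loglik(spec, params, y)
        oracle = _dense_loglik(params.phi, params.theta, params.mu, params.sigma2, y)
        assert ll == pytest.approx(oracle, abs=1e-6)

    def test_missing_values_match_subset_oracle(self):
        spec = ModelSpec(ar_lags=(1,), ma_lags=(1,))
        params = ParameterSet(mu=1.0, phi={1: 0.6}, theta={1: -0.2}, sigma2=1.2)
        y = simulate_armax(spec, params, None, 40, seed=8)
        y_miss = y.copy()
        miss = [5, 6, 20]
        y_miss[miss] = np.nan
        ll = exact_loglik(spec, params, y_miss)
        # oracle: drop the missing rows/cols from the dense covariance
        from statsmodels.tsa.arima_process import arma_acovf

        acov = arma_acovf(np.r_[1, -0.6], np.r_[1, -0.2], nobs=40, sigma2=1.2)
        keep = [i for i in range(40) if i not in miss]
        cov = toeplitz(acov)[np.ix_(keep, keep)]
        oracle = multivariate_normal.logpdf(y[keep] - 1.0, cov=cov)
        assert ll == pytest.approx(oracle, abs=1e-6)

    def test_white_noise_closed_form(self):
        y = np.array([0.3, -1.2, 0.8, 2.0])
        params = ParameterSet(mu=0.5, sigma2=2.0)
        ll = exact_loglik(ModelSpec(), params, y)
        closed = -0.5 * np.sum(np.log(2 * np.pi * 2.0) + (y - 0.5) ** 2 / 2.0)
        assert ll == pytest.approx(closed, abs=1e-12)

    def test_location_invariance(self):
        spec = ModelSpec(ar_lags=(1,))
        params = ParameterSet(mu=1.0, phi={1: 0.5}, sigma2=1.0)
        y = simulate_armax(spec, params, None, 60, seed=9)
        shifted = ParameterSet(mu=101.0, phi={1: 0.5}, sigma2=1.0)
        assert exact_loglik(spec, params, y) == pytest.approx(
            exact_loglik(spec, shifted, y + 100.0), abs=1e-8)

    def test_invalid_sigma2(self):
        with pytest.raises(ValueError):
            ParameterSet(sigma2=0.0)


class TestFitML:
    def test_ar1_recovery_within_3_se(self):
        spec = ModelSpec(ar_lags=(1,))
        y = simulate_armax(spec, ParameterSet(mu=0.0, phi={1: 0.5}), None, 500, seed=10)
        f = fit_ml(spec, y)
        assert f.converged
        assert abs(f.params.phi[1] - 0.5) < 3 * f.se["ar1"]
        assert f.loglik >= exact_loglik(spec, css_estimate(spec, y), y) - 1e-6

    def test_deterministic_refit(self):
        spec = ModelSpec(ar_lags=(1,), ma_lags=(1,))
        y = simulate_armax(spec, ParameterSet(phi={1: 0.4}, theta={1: 0.3}), None, 300, seed=11)
        f1 = fit_ml(spec, y)
        f2 = fit_ml(spec, y)
        assert f1.params.vector(spec).tolist() == f2.params.vector(spec).tolist()
        assert f1.loglik == f2.loglik

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            fit_ml(ModelSpec(ar_lags=(1,)), np.ones(100))

    def test_missing_values_handled(self):
        spec = ModelSpec(ar_lags=(1,))
        y = simulate_armax(spec, ParameterSet(mu=1.0, phi={1: 0.6}), None, 600, seed=12)
        y[::7] = np.nan
        f = fit_ml(spec, y)
        assert f.converged
        assert f.nobs == int(np.isfinite(y).sum())
        assert abs(f.params.phi[1] - 0.6) < 3 * f.se["ar1"]


class TestWald:
    def test_published_ratio(self):
        """z for an estimate of 1.1045 with SE 0.1008 is 10.957."""
        spec = ModelSpec(ar_lags=(1,))
        f = _make_fitted(spec, {"ar1": (1.1045, 0.1008)})
        tab = wald_tests(f)
        assert tab.loc["ar1", "z"] == pytest.approx(10.957, abs=1e-3)

    def test_zero_estimate_p_one(self):
        f = _make_fitted(ModelSpec(ar_lags=(1,)), {"ar1": (0.0, 0.2)})
        assert wald_tests(f).loc["ar1", "p"] == pytest.approx(1.0)

    def test_p_values_in_unit_interval(self):
        spec = ModelSpec(ar_lags=(1,), ma_lags=(1,))
        y = simulate_armax(spec, ParameterSet(phi={1: 0.5}, theta={1: 0.2}), None, 400, seed=13)
        tab = wald_tests(fit_ml(spec, y))
        assert ((tab["p"] >= 0) & (tab["p"] <= 1)).all()

    def test_zero_se_rejected(self):
        f = _make_fitted(ModelSpec(ar_lags=(1,)), {"ar1": (0.5, 0.0)})
        with pytest.raises(ValueError):
            wald_tests(f)


def _make_fitted(spec, entries, intercept_se=1.0):
    """Minimal FittedModel stub for Wald/prune unit checks."""
    from pigwater.armax import FittedModel

    params = ParameterSet()
    se = {}
    if spec.intercept:
        se["mu"] = intercept_se
    for name, (est, s) in entries.items():
        se[name] = s
        if name.startswith("ar"):
            params.phi[int(name[2:])] = est
        elif name.startswith("ma"):
            params.theta[int(name[2:])] = est
        else:
            params.eta[name] = est
    return FittedModel(spec=spec, params=params, cov=np.eye(spec.n_free), se=se,
                       loglik=0.0, nobs=100, aic=0.0, aicc=0.0, bic=0.0,
                       residuals=np.zeros(1), std_residuals=np.zeros(1), converged=True,
                       n_iter=1, min_root_modulus=2.0, near_boundary=False)


class TestPrune:
    def test_all_significant_unchanged(self):
        spec = ModelSpec(ar_lags=(1,))
        y = simulate_armax(spec, ParameterSet(phi={1: 0.6}), None, 1000, seed=14)
        f = fit_ml(spec, y)
        assert prune_coefficients(f) == spec

    def test_spurious_ar2_pruned_in_majority(self):
        """Fitting AR(2) to AR(1) data prunes lag 2 in >= 80% of replicates."""
        true = ModelSpec(ar_lags=(1,))
        fit_spec = ModelSpec(ar_lags=(1, 2))
        pruned = 0
        n_rep = 100
        for r in range(n_rep):
            y = simulate_armax(true, ParameterSet(phi={1: 0.6}), None, 1000, seed=100 + r)
            new = prune_coefficients(fit_ml(fit_spec, y))
            pruned += 2 not in new.ar_lags
        assert pruned >= 0.8 * n_rep

    def test_noise_regressor_pruned_in_majority(self):
        rng = np.random.default_rng(15)
        true = ModelSpec(ar_lags=(1,))
        pruned = 0
        n_rep = 50
        for r in range(n_rep):
            y = simulate_armax(true, ParameterSet(mu=1.0, phi={1: 0.5}), None, 800,
                               seed=500 + r)
            X = pd.DataFrame({"junk": rng.normal(size=800)})
            spec = ModelSpec(ar_lags=(1,), regressors=("junk",))
            new = prune_coefficients(fit_ml(spec, y, X))
            pruned += "junk" not in new.regressors
        assert pruned >= 0.8 * n_rep

    def test_prune_everything_warns_and_returns_white_noise(self):
        spec = ModelSpec(ar_lags=(1,))
        f = _make_fitted(spec, {"ar1": (0.01, 0.5)})
        with pytest.warns(RuntimeWarning, match="all terms pruned"):
            new = prune_coefficients(f)
        assert new.ar_lags == () and new.ma_lags == () and new.regressors == ()


class TestInformationCriteria:
    def test_zero_case(self):
        aic, aicc, bic = information_criteria(0.0, 0, 100)
        assert aic == 0.0 and bic == 0.0

    def test_arithmetic(self):
        aic, aicc, bic = information_criteria(-100.0, 5, 100)
        assert aic == pytest.approx(210.0)
        assert aicc == pytest.approx(210.6383, abs=1e-4)
        assert bic == pytest.approx(223.0259, abs=1e-4)

    def test_aicc_undefined_for_tiny_n(self):
        _, aicc, _ = information_criteria(-10.0, 5, 6)
        assert np.isnan(aicc)

    def test_bic_at_least_aic_for_n_ge_8(self):
        for n in (8, 50, 1000):
            aic, _, bic = information_criteria(-20.0, 3, n)
            assert bic >= aic


class TestSelectOrder:
    GRID = [ModelSpec(ar_lags=tuple(range(1, p + 1)), ma_lags=tuple(range(1, q + 1)))
            for p in (0, 1, 2) for q in (0, 1, 2)]

    def test_white_noise_selects_empty_model_majority(self):
        """BIC order selection (consistent for true order) picks (0,0) on
        white noise in >= 70% of replicates."""
        hits = 0
        n_rep = 25
        for r in range(n_rep):
            y = np.random.default_rng(700 + r).normal(size=500)
            best, table = select_order(y, None, self.GRID, criterion="bic")
            hits += best.ar_lags == () and best.ma_lags == ()
        assert hits >= 0.7 * n_rep

    def test_ar1_data_selects_ar_term_majority(self):
        hits = 0
        n_rep = 20
        for r in range(n_rep):
            y = simulate_armax(ModelSpec(ar_lags=(1,)), ParameterSet(phi={1: 0.8}), None,
                               500, seed=800 + r)
            best, _ = select_order(y, None, self.GRID, criterion="bic")
            hits += len(best.ar_lags) >= 1
        assert hits >= 0.9 * n_rep

    def test_tie_breaks_to_fewer_parameters(self):
        from unittest import mock

        specs = [ModelSpec(ar_lags=(1, 2)), ModelSpec(ar_lags=(1,))]
        fake = []
        for s in specs:
            f = _make_fitted(s, {f"ar{l}": (0.1, 0.1) for l in s.ar_lags})
            f.aic = f.bic = f.aicc = 100.0
            fake.append(f)
        with mock.patch("pigwater.armax.fit_ml", side_effect=fake):
            best, _ = select_order(np.zeros(10), None, specs)
        assert best == specs[1]


class TestCorrelogram:
    def test_rho0_is_one_and_bounded(self, rng):
        x = rng.normal(size=400)
        res = correlogram(x, 20)
        assert res.acf[0] == 1.0
        assert np.all(np.abs(res.acf) <= 1.0 + 1e-12)
        assert res.band == pytest.approx(1.96 / np.sqrt(400))

    def test_acf_matches_bruteforce(self, rng):
        x = rng.normal(size=300)
        rho = acf(x, 10)
        xc = x - x.mean()
        c0 = (xc @ xc) / 300
        for k in range(1, 11):
            brute = np.sum(xc[:-k] * xc[k:]) / 300 / c0
            assert rho[k] == pytest.approx(brute, abs=1e-12)

    def test_ar1_pacf_cuts_off_after_lag_one(self):
        y = simulate_armax(ModelSpec(ar_lags=(1,)), ParameterSet(phi={1: 0.6}), None,
                           10_000, seed=16)
        res = correlogram(y, 5)
        assert res.pacf[1] == pytest.approx(0.6, abs=0.05)
        assert np.all(np.abs(res.pacf[2:]) < res.band)

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError):
            acf(np.ones(50), 5)

    def test_pacf_matches_ols_regression(self, rng):
        """Durbin-Levinson PACF at lag k equals the last coefficient of an
        OLS autoregression of order k."""
        x = rng.normal(size=2000).cumsum() * 0.01 + rng.normal(size=2000)
        res = pacf(x, 4)
        xc = x - x.mean()
        for k in (2, 3, 4):
            rows = np.column_stack([xc[k - j - 1: len(xc) - j - 1] for j in range(k)])
            beta = np.linalg.lstsq(rows, xc[k:], rcond=None)[0]
            assert res[k] == pytest.approx(beta[-1], abs=0.02)
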