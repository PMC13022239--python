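"""Subset-constrained ARMAX estimation.

The model implemented here is regression with ARMA errors: for hourly
consumption :math:`y_t`, regressor row :math:`x_t` and innovation variance
:math:`\\sigma^2`,

.. math::

    y_t = \\mu + x_t' \\eta + e_t, \\qquad
    e_t = \\sum_{i \\in A} \\phi_i e_{t-i}
        + \\varepsilon_t + \\sum_{j \\in M} \\vartheta_j \\varepsilon_{t-j},

with :math:`\\varepsilon_t \\sim N(0, \\sigma^2)` i.i.d., and where only the
*active* lag sets A and M carry free coefficients (a subset model; all other
lags are fixed to zero).  Estimation follows the classical two-stage scheme:
conditional sum of squares (CSS) provides starting values, then the exact
Gaussian likelihood — evaluated by a state-space innovations recursion with
the stationary initial distribution, skipping missing hours — is maximised
numerically.  Wald tests, single-pass pruning of insignificant terms, and
AIC/AICc/BIC order selection complete the toolbox.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ._filter import arma_recursion, css_residuals, filter_pass

__all__ = [
    "ModelSpec",
    "ParameterSet",
    "FittedModel",
    "CorrelogramResult",
    "ar_poly",
    "ma_poly",
    "min_root_modulus",
    "check_stationary_invertible",
    "simulate_armax",
    "css_estimate",
    "exact_loglik",
    "fit_ml",
    "wald_tests",
    "prune_coefficients",
    "information_criteria",
    "select_order",
    "acf",
    "pacf",
    "correlogram",
]

#: root-modulus margin below which AR/MA polynomials are treated as
#: non-stationary / non-invertible during optimisation
ROOT_MARGIN = 1.001


# ---------------------------------------------------------------------------
# model description
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelSpec:
    """Structure of a subset ARMAX model.

    ``ar_lags`` / ``ma_lags`` are the active (non-zero) lags; the model
    orders p and q are their maxima.  ``regressors`` names the exogenous
    columns of the design matrix, entering contemporaneously
    (``exog_lag = 0``).
    """

    ar_lags: tuple = ()
    ma_lags: tuple = ()
    regressors: tuple = ()
    intercept: bool = True
    exog_lag: int = 0

    def __post_init__(self):
        object.__setattr__(self, "ar_lags", tuple(sorted(int(l) for l in self.ar_lags)))
        object.__setattr__(self, "ma_lags", tuple(sorted(int(l) for l in self.ma_lags)))
        object.__setattr__(self, "regressors", tuple(self.regressors))
        if any(l < 1 for l in self.ar_lags) or any(l < 1 for l in self.ma_lags):
            raise ValueError("lags must be >= 1")
        if len(set(self.ar_lags)) != len(self.ar_lags) or len(set(self.ma_lags)) != len(self.ma_lags):
            raise ValueError("duplicate lags")
        if self.exog_lag != 0:
            raise NotImplementedError("only contemporaneous exogenous terms (exog_lag = 0) are supported")

    @property
    def p(self) -> int:
        return max(self.ar_lags) if self.ar_lags else 0

    @property
    def q(self) -> int:
        return max(self.ma_lags) if self.ma_lags else 0

    @property
    def n_free(self) -> int:
        """Free coefficients excluding sigma^2."""
        return int(self.intercept) + len(self.regressors) + len(self.ar_lags) + len(self.ma_lags)

    def param_names(self) -> list:
        names = []
        if self.intercept:
            names.append("mu")
        names.extend(self.regressors)
        names.extend(f"ar{l}" for l in self.ar_lags)
        names.extend(f"ma{l}" for l in self.ma_lags)
        return names


@dataclass
class ParameterSet:
    """Coefficients of a subset ARMAX model (sparse phi/theta maps)."""

    mu: float = 0.0
    phi: dict = field(default_factory=dict)
    theta: dict = field(default_factory=dict)
    eta: dict = field(default_factory=dict)
    sigma2: float = 1.0

    def __post_init__(self):
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be > 0")

    def vector(self, spec: ModelSpec) -> np.ndarray:
        """Pack into the free-parameter vector order used by the optimiser."""
        x = []
        if spec.intercept:
            x.append(self.mu)
        x.extend(self.eta.get(name, 0.0) for name in spec.regressors)
        x.extend(self.phi.get(l, 0.0) for l in spec.ar_lags)
        x.extend(self.theta.get(l, 0.0) for l in spec.ma_lags)
        return np.asarray(x, dtype=float)

    @classmethod
    def from_vector(cls, spec: ModelSpec, x, sigma2: float = 1.0) -> "ParameterSet":
        x = np.asarray(x, dtype=float)
        i = 0
        mu = 0.0
        if spec.intercept:
            mu = float(x[0])
            i = 1
        k = len(spec.regressors)
        eta = {name: float(v) for name, v in zip(spec.regressors, x[i : i + k])}
        i += k
        phi = {l: float(v) for l, v in zip(spec.ar_lags, x[i : i + len(spec.ar_lags)])}
        i += len(spec.ar_lags)
        theta = {l: float(v) for l, v in zip(spec.ma_lags, x[i:])}
        return cls(mu=mu, phi=phi, theta=theta, eta=eta, sigma2=sigma2)


# ---------------------------------------------------------------------------
# polynomials and state-space building blocks
# ---------------------------------------------------------------------------


def ar_poly(params: ParameterSet, p: int | None = None) -> np.ndarray:
    """Coefficients of phi(z) = 1 - sum phi_i z^i, ascending powers."""
    p = max(params.phi, default=0) if p is None else p
    c = np.zeros(p + 1)
    c[0] = 1.0
    for lag, v in params.phi.items():
        c[lag] = -v
    return c


def ma_poly(params: ParameterSet, q: int | None = None) -> np.ndarray:
    """Coefficients of theta(z) = 1 + sum theta_j z^j, ascending powers."""
    q = max(params.theta, default=0) if q is None else q
    c = np.zeros(q + 1)
    c[0] = 1.0
    for lag, v in params.theta.items():
        c[lag] = v
    return c


def min_root_modulus(poly: np.ndarray) -> float:
    """Smallest modulus among the roots of a polynomial in ascending powers.

    Returns +inf for a constant polynomial (no roots: degenerate AR/MA part).
    """
    c = np.trim_zeros(np.asarray(poly, dtype=float), "b")
    if c.size <= 1:
        return math.inf
    roots = np.roots(c[::-1])
    return float(np.min(np.abs(roots)))


def check_stationary_invertible(params: ParameterSet, margin: float = ROOT_MARGIN):
    """Raise ValueError (reporting the offending root modulus) if the AR part
    is not stationary or the MA part not invertible to within ``margin``."""
    m_ar = min_root_modulus(ar_poly(params))
    if m_ar <= margin:
        raise ValueError(f"AR polynomial not stationary: min root modulus {m_ar:.6f} <= {margin}")
    m_ma = min_root_modulus(ma_poly(params))
    if m_ma <= margin:
        raise ValueError(f"MA polynomial not invertible: min root modulus {m_ma:.6f} <= {margin}")
    return m_ar, m_ma


def _phic_rvec(spec: ModelSpec, params: ParameterSet):
    r = max(spec.p, spec.q + 1, 1)
    phic = np.zeros(r)
    for lag, v in params.phi.items():
        phic[lag - 1] = v
    rvec = np.zeros(r)
    rvec[0] = 1.0
    for lag, v in params.theta.items():
        rvec[lag] = v
    return phic, rvec


def _stationary_cov(phic: np.ndarray, rvec: np.ndarray) -> np.ndarray:
    """Stationary state covariance P solving P = T P T' + R R' by doubling."""
    r = phic.shape[0]
    T = np.zeros((r, r))
    T[:, 0] = phic
    if r > 1:
        T[:-1, 1:] = np.eye(r - 1)
    S = np.outer(rvec, rvec)
    A = T.copy()
    for _ in range(60):
        inc = A @ S @ A.T
        S = S + inc
        nrm = np.abs(inc).max()
        if not np.isfinite(nrm) or nrm > 1e12:
            raise ValueError("stationary covariance diverged (non-stationary AR part)")
        if nrm < 1e-14 * max(1.0, np.abs(S).max()):
            break
        A = A @ A
    return 0.5 * (S + S.T)


def _mean_vector(spec: ModelSpec, params: ParameterSet, X: pd.DataFrame | None, n: int) -> np.ndarray:
    m = np.full(n, params.mu if spec.intercept else 0.0, dtype=float)
    for name in spec.regressors:
        if X is None or name not in X:
            raise KeyError(f"design matrix is missing regressor '{name}'")
        m = m + params.eta.get(name, 0.0) * np.asarray(X[name], dtype=float)
    return m


def _filter_once(spec: ModelSpec, params: ParameterSet, y: np.ndarray, X: pd.DataFrame | None):
    y = np.asarray(y, dtype=float)
    mean = _mean_vector(spec, params, X, y.shape[0])
    w = y - mean
    obs = np.isfinite(w)
    wf = np.where(obs, w, 0.0)
    phic, rvec = _phic_rvec(spec, params)
    P0 = _stationary_cov(phic, rvec)
    return filter_pass(wf, obs, phic, rvec, P0) + (mean, phic, rvec)


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------


def simulate_armax(
    spec: ModelSpec,
    params: ParameterSet,
    X: pd.DataFrame | None,
    n: int,
    burn_in: int = 2000,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Simulate ``n`` values of the regression-with-ARMA-errors model.

    Gaussian innovations N(0, sigma^2); ``burn_in`` pre-sample steps of the
    noise recursion are discarded so the error process starts near its
    stationary distribution.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    check_stationary_invertible(params)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p, q = spec.p, spec.q
    phi_full = np.zeros(p + 1)
    for lag, v in params.phi.items():
        phi_full[lag] = v
    theta_full = np.zeros(q + 1)
    for lag, v in params.theta.items():
        theta_full[lag] = v
    eps = rng.normal(0.0, math.sqrt(params.sigma2), size=n + burn_in)
    noise = arma_recursion(eps, phi_full, theta_full, p, q)[burn_in:]
    return _mean_vector(spec, params, X, n) + noise


# ---------------------------------------------------------------------------
# estimation
# ---------------------------------------------------------------------------


def _css_objective(spec: ModelSpec, y: np.ndarray, X: pd.DataFrame | None):
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    p, q = spec.p, spec.q

    def fun(x):
        params = ParameterSet.from_vector(spec, x)
        mean = _mean_vector(spec, params, X, n)
        w = y - mean
        obs = np.isfinite(w)
        wf = np.where(obs, w, 0.0)
        phi_full = np.zeros(p + 1)
        for lag, v in params.phi.items():
            phi_full[lag] = v
        theta_full = np.zeros(q + 1)
        for lag, v in params.theta.items():
            theta_full[lag] = v
        # keep the MA recursion from exploding for wildly non-invertible trials
        if q > 0 and min_root_modulus(ma_poly(params)) <= 1.0 - 1e-8:
            return 1e12
        e, count = css_residuals(wf, obs, phi_full, theta_full, p)
        if count == 0:
            return 1e12
        return float(np.dot(e, e))

    return fun


def _ols_start(spec: ModelSpec, y: np.ndarray, X: pd.DataFrame | None) -> np.ndarray:
    """OLS of y on (1, X) for starting values; ARMA coefficients start at 0."""
    y = np.asarray(y, dtype=float)
    obs = np.isfinite(y)
    cols = []
    if spec.intercept:
        cols.append(np.ones(y.shape[0]))
    for name in spec.regressors:
        cols.append(np.asarray(X[name], dtype=float))
    x0 = np.zeros(spec.n_free)
    if cols:
        A = np.column_stack(cols)
        rowok = obs & np.isfinite(A).all(axis=1)
        beta, *_ = np.linalg.lstsq(A[rowok], y[rowok], rcond=None)
        x0[: beta.shape[0]] = beta
    return x0


def css_estimate(spec: ModelSpec, y, X: pd.DataFrame | None = None) -> ParameterSet:
    """Conditional-least-squares estimate (pre-sample errors zero, first p
    observations conditioned on); sigma^2 is the residual mean square."""
    y = np.asarray(y, dtype=float)
    nobs = int(np.isfinite(y).sum())
    if nobs <= spec.n_free + max(spec.p, spec.q):
        raise ValueError("series too short for the requested specification")
    if np.nanstd(y) == 0:
        raise ValueError("constant series: zero-variance input")
    fun = _css_objective(spec, y, X)
    x0 = _ols_start(spec, y, X)
    if spec.n_free == 0:
        x = x0
    else:
        res = optimize.minimize(fun, x0, method="L-BFGS-B", options={"maxiter": 500, "ftol": 1e-14, "gtol": 1e-10})
        if not res.success and not np.isfinite(res.fun):
            raise RuntimeError(f"CSS optimisation failed: {res.message}")
        x = res.x
    params = ParameterSet.from_vector(spec, x)
    mean = _mean_vector(spec, params, X, y.shape[0])
    w = y - mean
    obs = np.isfinite(w)
    wf = np.where(obs, w, 0.0)
    phi_full = np.zeros(spec.p + 1)
    for lag, v in params.phi.items():
        phi_full[lag] = v
    theta_full = np.zeros(spec.q + 1)
    for lag, v in params.theta.items():
        theta_full[lag] = v
    e, count = css_residuals(wf, obs, phi_full, theta_full, spec.p)
    params.sigma2 = float(np.dot(e, e) / max(count, 1))
    if params.sigma2 <= 0:
        params.sigma2 = float(np.nanvar(y)) or 1.0
    return params


def exact_loglik(spec: ModelSpec, params: ParameterSet, y, X: pd.DataFrame | None = None) -> float:
    """Exact Gaussian log-likelihood via the innovations recursion with the
    stationary initial state; missing observations are skipped (prediction
    without update)."""
    if params.sigma2 <= 0:
        raise ValueError("sigma2 must be > 0")
    check_stationary_invertible(params, margin=1.0)
    sumlogF, ssq, nobs, *_ = _filter_once(spec, params, y, X)
    if nobs == 0:
        raise ValueError("no observed values")
    ll = -0.5 * (nobs * math.log(2 * math.pi * params.sigma2) + sumlogF + ssq / params.sigma2)
    if not np.isfinite(ll):
        raise FloatingPointError("non-finite likelihood")
    return float(ll)


def _concentrated_nll(spec: ModelSpec, y: np.ndarray, X: pd.DataFrame | None):
    """Negative profile log-likelihood with sigma^2 concentrated out, plus a
    penalty pushing the optimiser back inside the stationarity/invertibility
    region (root modulus > ROOT_MARGIN)."""
    y = np.asarray(y, dtype=float)

    def fun(x):
        params = ParameterSet.from_vector(spec, x)
        m_ar = min_root_modulus(ar_poly(params, spec.p))
        m_ma = min_root_modulus(ma_poly(params, spec.q))
        m = min(m_ar, m_ma)
        if m <= ROOT_MARGIN:
            return 1e8 * (1.0 + (ROOT_MARGIN - m))
        try:
            sumlogF, ssq, nobs, *_ = _filter_once(spec, params, y, X)
        except ValueError:
            return 1e8
        if nobs == 0 or ssq <= 0:
            return 1e8
        sigma2 = ssq / nobs
        nll = 0.5 * (nobs * math.log(2 * math.pi) + nobs * math.log(sigma2) + sumlogF + nobs)
        return nll if np.isfinite(nll) else 1e8

    return fun


def _central_gradient(fun, x, rel_step=1e-6):
    """Central-difference gradient with per-coordinate relative steps.

    The profile likelihood of near-unit-root subset models is flat in several
    directions; the default forward-difference gradient of the optimiser is
    too noisy there to converge reliably.
    """
    g = np.empty_like(x)
    for i in range(x.size):
        h = rel_step * max(1.0, abs(x[i]))
        xp = x.copy(); xp[i] += h
        xm = x.copy(); xm[i] -= h
        g[i] = (fun(xp) - fun(xm)) / (2 * h)
    return g


def _minimize_nll(nll, x0):
    """Quasi-Newton with accurate numeric gradient, then a simplex polish and,
    if the polish moved, one more quasi-Newton round; returns the best point."""
    opts = {"maxiter": 2000, "ftol": 1e-13, "gtol": 1e-9}
    jac = lambda x: _central_gradient(nll, x)  # noqa: E731
    res = optimize.minimize(nll, x0, method="L-BFGS-B", jac=jac, options=opts)
    best_x, best_f = (res.x, res.fun) if res.fun <= nll(x0) else (x0, nll(x0))
    success = bool(res.success)
    n_iter = int(res.nit)
    k = x0.size
    nm = optimize.minimize(nll, best_x, method="Nelder-Mead", options={
        "maxfev": max(2000, 200 * k), "fatol": 1e-10, "xatol": 1e-8, "adaptive": True})
    if nm.fun < best_f - 1e-9:
        res2 = optimize.minimize(nll, nm.x, method="L-BFGS-B", jac=jac, options=opts)
        if res2.fun <= nm.fun:
            best_x, best_f = res2.x, res2.fun
            success = success or bool(res2.success)
        else:
            best_x, best_f = nm.x, nm.fun
        n_iter += int(nm.nit) + int(res2.nit)
    success = success or bool(nm.success)
    if not success:
        # a stationary point with a flat direction can make the line search
        # report failure; accept it if the gradient is numerically zero
        success = bool(np.max(np.abs(jac(best_x))) < 1e-3)
    return best_x, best_f, success, n_iter


def _numerical_hessian(fun, x, rel_step=1e-4):
    """Central-difference Hessian with per-coordinate relative steps."""
    k = x.shape[0]
    h = rel_step * np.maximum(1.0, np.abs(x))
    H = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            xpp = x.copy(); xpp[i] += h[i]; xpp[j] += h[j]
            xpm = x.copy(); xpm[i] += h[i]; xpm[j] -= h[j]
            xmp = x.copy(); xmp[i] -= h[i]; xmp[j] += h[j]
            xmm = x.copy(); xmm[i] -= h[i]; xmm[j] -= h[j]
            H[i, j] = H[j, i] = (fun(xpp) - fun(xpm) - fun(xmp) + fun(xmm)) / (4 * h[i] * h[j])
    return H


@dataclass
class FittedModel:
    """Result of a maximum-likelihood ARMAX fit."""

    spec: ModelSpec
    params: ParameterSet
    cov: np.ndarray
    se: dict
    loglik: float
    nobs: int
    aic: float
    aicc: float
    bic: float
    residuals: np.ndarray
    std_residuals: np.ndarray
    converged: bool
    n_iter: int
    min_root_modulus: float
    near_boundary: bool
    filter_state: tuple = None  # (a_end, P_end) predicted state for t = n

    @property
    def k_params(self) -> int:
        """Free parameters counted by the information criteria (incl. sigma^2)."""
        return self.spec.n_free + 1

    def coef_table(self) -> pd.DataFrame:
        names = self.spec.param_names()
        est = self.params.vector(self.spec)
        se = np.array([self.se[n] for n in names])
        return pd.DataFrame({"term": names, "estimate": est, "se": se}).set_index("term")


def fit_ml(spec: ModelSpec, y, X: pd.DataFrame | None = None, init: ParameterSet | str = "auto") -> FittedModel:
    """CSS-initialised exact maximum-likelihood fit.

    The reported log-likelihood is never below the likelihood at the CSS
    starting values; standard errors come from the inverse of the
    central-difference observed information of the concentrated likelihood.
    """
    y = np.asarray(y, dtype=float)
    if np.nanstd(y) == 0:
        raise ValueError("constant series: zero-variance input")
    if init == "auto":
        init = css_estimate(spec, y, X)
    x0 = init.vector(spec)
    nll = _concentrated_nll(spec, y, X)
    # if the CSS start violates the root margin, shrink the ARMA part until valid
    shrink = 1.0
    while nll(x0) >= 1e7 and shrink > 1e-3:
        shrink *= 0.7
        trial = replace(init)
        trial.phi = {l: v * shrink for l, v in init.phi.items()}
        trial.theta = {l: v * shrink for l, v in init.theta.items()}
        x0 = trial.vector(spec)
    if spec.n_free > 0:
        x, _, converged, n_iter = _minimize_nll(nll, x0)
    else:
        x = x0
        converged = True
        n_iter = 0
    params = ParameterSet.from_vector(spec, x)
    sumlogF, ssq, nobs, v, F, a_end, P_end, mean, phic, rvec = _filter_once(spec, params, y, X)
    sigma2 = ssq / nobs
    params.sigma2 = float(sigma2)
    loglik = -0.5 * (nobs * math.log(2 * math.pi) + nobs * math.log(sigma2) + sumlogF + nobs)
    m_ar = min_root_modulus(ar_poly(params, spec.p))
    m_ma = min_root_modulus(ma_poly(params, spec.q))
    m_min = min(m_ar, m_ma)

    names = spec.param_names()
    if spec.n_free > 0:
        H = _numerical_hessian(nll, x)
        try:
            cov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(H)
            converged = False
        diag = np.diag(cov).copy()
        if np.any(diag <= 0):
            cov = np.linalg.pinv(_numerical_hessian(nll, x, rel_step=1e-3))
            diag = np.diag(cov).copy()
        se = {n_: (math.sqrt(d) if d > 0 else math.nan) for n_, d in zip(names, diag)}
    else:
        cov = np.zeros((0, 0))
        se = {}

    ic = information_criteria(loglik, spec.n_free + 1, nobs)
    fitted = FittedModel(
        spec=spec,
        params=params,
        cov=cov,
        se=se,
        loglik=float(loglik),
        nobs=int(nobs),
        aic=ic[0],
        aicc=ic[1],
        bic=ic[2],
        residuals=v,
        std_residuals=v / np.sqrt(F * sigma2),
        converged=converged,
        n_iter=n_iter,
        min_root_modulus=float(m_min),
        near_boundary=bool(m_min < ROOT_MARGIN * 1.0005),
        filter_state=(a_end, P_end),
    )
    if not converged:
        warnings.warn("maximum-likelihood optimisation did not report convergence", RuntimeWarning)
    return fitted


# ---------------------------------------------------------------------------
# inference and model selection
# ---------------------------------------------------------------------------


def wald_tests(fitted: FittedModel) -> pd.DataFrame:
    """Per-coefficient z = estimate/SE and two-sided normal p-value."""
    tab = fitted.coef_table()
    if (tab["se"] <= 0).any() or tab["se"].isna().any():
        raise ValueError("standard errors must be positive for Wald tests")
    tab["z"] = tab["estimate"] / tab["se"]
    tab["p"] = 2 * stats.norm.sf(np.abs(tab["z"]))
    return tab


def prune_coefficients(fitted: FittedModel, alpha: float = 0.05) -> ModelSpec:
    """Drop ARMA lags and regressors with Wald p > alpha in one pass.

    The intercept is always retained.  Pruning everything leaves a
    white-noise-with-intercept specification (with a warning).
    """
    if not fitted.converged:
        raise ValueError("refusing to prune a non-converged fit")
    tab = wald_tests(fitted)
    spec = fitted.spec
    keep = tab.index[tab["p"] <= alpha]
    ar = tuple(l for l in spec.ar_lags if f"ar{l}" in keep)
    ma = tuple(l for l in spec.ma_lags if f"ma{l}" in keep)
    reg = tuple(r for r in spec.regressors if r in keep)
    if not ar and not ma and not reg:
        warnings.warn("all terms pruned; returning white-noise specification", RuntimeWarning)
    return ModelSpec(ar_lags=ar, ma_lags=ma, regressors=reg, intercept=spec.intercept)


def prune_until_stable(fitted: FittedModel, y, X=None, alpha: float = 0.05, max_rounds: int = 10) -> FittedModel:
    """Iterative prune-and-refit (off by default in the pipeline)."""
    current = fitted
    for _ in range(max_rounds):
        new_spec = prune_coefficients(current, alpha)
        if new_spec == current.spec:
            return current
        current = fit_ml(new_spec, y, X)
    return current


def information_criteria(loglik: float, k: int, n: int):
    """AIC, AICc, BIC.  AICc is NaN when n <= k + 1 (undefined)."""
    aic = -2.0 * loglik + 2.0 * k
    aicc = aic + 2.0 * k * (k + 1) / (n - k - 1) if n > k + 1 else math.nan
    bic = -2.0 * loglik + k * math.log(n)
    return aic, aicc, bic


def select_order(y, X: pd.DataFrame | None, grid, criterion: str = "aic"):
    """Fit every specification in ``grid`` and return the criterion-minimising
    one plus the full score table.  Ties break to fewer free parameters, then
    to lower MA order; non-converging specifications are excluded."""
    criterion = criterion.lower()
    if criterion not in {"aic", "aicc", "bic"}:
        raise ValueError(f"unknown criterion '{criterion}'")
    grid = list(grid)
    if not grid:
        raise ValueError("empty specification grid")
    rows = []
    fits = {}
    for i, spec in enumerate(grid):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                f = fit_ml(spec, y, X)
        except Exception as exc:  # noqa: BLE001 - any failing spec is logged and skipped
            rows.append({"index": i, "spec": spec, "aic": math.nan, "aicc": math.nan,
                         "bic": math.nan, "converged": False, "error": str(exc)})
            continue
        rows.append({"index": i, "spec": spec, "aic": f.aic, "aicc": f.aicc, "bic": f.bic,
                     "converged": f.converged, "error": ""})
        if f.converged:
            fits[i] = f
    table = pd.DataFrame(rows)
    ok = table[table["converged"]]
    if ok.empty:
        raise RuntimeError("no specification converged")
    order = sorted(
        ok.index,
        key=lambda idx: (
            round(ok.loc[idx, criterion], 10),
            grid[ok.loc[idx, "index"]].n_free,
            grid[ok.loc[idx, "index"]].q,
        ),
    )
    best = grid[ok.loc[order[0], "index"]]
    return best, table


# ---------------------------------------------------------------------------
# correlograms
# ---------------------------------------------------------------------------


@dataclass
class CorrelogramResult:
    lags: np.ndarray
    acf: np.ndarray
    pacf: np.ndarray
    band: float  # 1.96 / sqrt(n)


def acf(x, max_lag: int) -> np.ndarray:
    """Sample autocorrelations rho_0..rho_max_lag with denominator n."""
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    n = x.shape[0]
    if n <= max_lag:
        raise ValueError("series length must exceed max_lag")
    xc = x - x.mean()
    c0 = np.dot(xc, xc) / n
    if c0 == 0:
        raise ValueError("constant series: autocorrelation undefined")
    out = np.empty(max_lag + 1)
    out[0] = 1.0
    for k in range(1, max_lag + 1):
        out[k] = np.dot(xc[:-k], xc[k:]) / n / c0
    return out


def pacf(x, max_lag: int) -> np.ndarray:
    """Partial autocorrelations via the Durbin-Levinson recursion."""
    rho = acf(x, max_lag)
    out = np.empty(max_lag + 1)
    out[0] = 1.0
    phi_prev = np.zeros(0)
    for k in range(1, max_lag + 1):
        if k == 1:
            phi_k = rho[1]
            phi_prev = np.array([phi_k])
        else:
            num = rho[k] - np.dot(phi_prev, rho[k - 1 : 0 : -1])
            den = 1.0 - np.dot(phi_prev, rho[1:k])
            phi_k = num / den
            phi_new = phi_prev - phi_k * phi_prev[::-1]
            phi_prev = np.append(phi_new, phi_k)
        out[k] = phi_k
    return out


def correlogram(x, max_lag: int) -> CorrelogramResult:
    x = np.asarray(x, dtype=float)
    n = int(np.isfinite(x).sum())
    return CorrelogramResult(
        lags=np.arange(max_lag + 1),
        acf=acf(x, max_lag),
        pacf=pacf(x, max_lag),
        band=1.96 / math.sqrt(n),
    )
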