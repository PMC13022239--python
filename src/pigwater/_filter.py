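"""Numba kernels for the ARMA state-space innovations filter and CSS recursion.

The ARMA(p, q) error process e_t is cast in the Harvey state-space form with
state dimension r = max(p, q + 1):

    alpha_{t+1} = T alpha_t + R eps_{t+1},   e_t = Z alpha_t,  Z = (1, 0, ..., 0)

where T has the AR coefficients in its first column and an identity block on
the superdiagonal, and R = (1, theta_1, ..., theta_{r-1})'.  The filter below
exploits that structure so each step costs O(r^2) instead of O(r^3), which is
what makes exact-likelihood refits of the lag-24 subset model cheap.

All kernels run with sigma^2 = 1; the innovation variance is concentrated out
of the likelihood by the caller.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def filter_pass(w, obs, phic, rvec, P0):
    """One pass of the Kalman filter over the de-meaned series ``w``.

    Parameters
    ----------
    w : float64[n]
        Series minus regression mean (NaN where missing).
    obs : bool[n]
        True where w is observed.
    phic : float64[r]
        First column of the transition matrix (AR coefficients, zero-padded).
    rvec : float64[r]
        Innovation loading (1, theta_1, ..., theta_{r-1}).
    P0 : float64[r, r]
        Stationary initial state covariance (unit innovation variance).

    Returns
    -------
    sumlogF, ssq, nobs, v, F, a_end, P_end
        Sum of log innovation variances, sum of squared scaled innovations,
        number of observations used, per-step innovations and variances
        (NaN innovation where missing), and the one-step-ahead predicted
        state mean/covariance for time n (the first forecast step).
    """
    r = phic.shape[0]
    n = w.shape[0]
    a = np.zeros(r)
    anew = np.zeros(r)
    P = P0.copy()
    TP = np.empty((r, r))
    Pn = np.empty((r, r))
    v = np.empty(n)
    F = np.empty(n)
    sumlogF = 0.0
    ssq = 0.0
    nobs = 0
    for t in range(n):
        # TP = T @ P using the companion structure of T
        for i in range(r):
            for j in range(r):
                val = phic[i] * P[0, j]
                if i + 1 < r:
                    val += P[i + 1, j]
                TP[i, j] = val
        Ft = P[0, 0]
        F[t] = Ft
        if obs[t] and Ft > 0.0:
            vt = w[t] - a[0]
            v[t] = vt
            sumlogF += np.log(Ft)
            ssq += vt * vt / Ft
            nobs += 1
            a0 = a[0]
            for i in range(r):
                ta = phic[i] * a0
                if i + 1 < r:
                    ta += a[i + 1]
                anew[i] = ta + TP[i, 0] / Ft * vt
            for i in range(r):
                for j in range(r):
                    val = phic[j] * TP[i, 0]
                    if j + 1 < r:
                        val += TP[i, j + 1]
                    Pn[i, j] = val + rvec[i] * rvec[j] - TP[i, 0] * TP[j, 0] / Ft
        else:
            v[t] = np.nan
            a0 = a[0]
            for i in range(r):
                ta = phic[i] * a0
                if i + 1 < r:
                    ta += a[i + 1]
                anew[i] = ta
            for i in range(r):
                for j in range(r):
                    val = phic[j] * TP[i, 0]
                    if j + 1 < r:
                        val += TP[i, j + 1]
                    Pn[i, j] = val + rvec[i] * rvec[j]
        for i in range(r):
            a[i] = anew[i]
            for j in range(i, r):
                s = 0.5 * (Pn[i, j] + Pn[j, i])
                P[i, j] = s
                P[j, i] = s
    return sumlogF, ssq, nobs, v, F, a, P


@njit(cache=True)
def predict_ahead(a, P, phic, rvec, h):
    """Iterate the prediction step h-1 further times, collecting the
    signal mean and variance at horizons 1..h (unit innovation variance)."""
    r = phic.shape[0]
    mean = np.empty(h)
    var = np.empty(h)
    ac = a.copy()
    Pc = P.copy()
    TP = np.empty((r, r))
    anew = np.empty(r)
    Pn = np.empty((r, r))
    for step in range(h):
        mean[step] = ac[0]
        var[step] = Pc[0, 0]
        if step == h - 1:
            break
        for i in range(r):
            for j in range(r):
                val = phic[i] * Pc[0, j]
                if i + 1 < r:
                    val += Pc[i + 1, j]
                TP[i, j] = val
        a0 = ac[0]
        for i in range(r):
            ta = phic[i] * a0
            if i + 1 < r:
                ta += ac[i + 1]
            anew[i] = ta
        for i in range(r):
            for j in range(r):
                val = phic[j] * TP[i, 0]
                if j + 1 < r:
                    val += TP[i, j + 1]
                Pn[i, j] = val + rvec[i] * rvec[j]
        for i in range(r):
            ac[i] = anew[i]
            for j in range(r):
                Pc[i, j] = Pn[i, j]
    return mean, var


@njit(cache=True)
def css_residuals(w, obs, phi_full, theta_full, p):
    """Conditional-sum-of-squares residual recursion.

    Pre-sample residuals are zero and the first ``p`` observations are
    conditioned on.  Steps whose own value or any required lagged value is
    missing contribute a zero residual and are not counted.
    """
    n = w.shape[0]
    q = theta_full.shape[0] - 1
    e = np.zeros(n)
    count = 0
    for t in range(p, n):
        if not obs[t]:
            continue
        ok = True
        s = w[t]
        for i in range(1, p + 1):
            if phi_full[i] != 0.0:
                if not obs[t - i]:
                    ok = False
                    break
                s -= phi_full[i] * w[t - i]
        if not ok:
            continue
        for j in range(1, q + 1):
            if theta_full[j] != 0.0 and t - j >= 0:
                s -= theta_full[j] * e[t - j]
        e[t] = s
        count += 1
    return e, count


@njit(cache=True)
def arma_recursion(eps, phi_full, theta_full, p, q):
    """Generate an ARMA noise path from innovations ``eps`` (burn-in included)."""
    n = eps.shape[0]
    x = np.zeros(n)
    for t in range(n):
        s = eps[t]
        for j in range(1, q + 1):
            if t - j >= 0:
                s += theta_full[j] * eps[t - j]
        for i in range(1, p + 1):
            if t - i >= 0:
                s += phi_full[i] * x[t - i]
        x[t] = s
    return x
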