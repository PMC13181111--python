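"""Numba-compiled numerical kernels.

Two hot loops live here: the coordinate-descent path solver for
L1-penalized logistic regression (the workhorse of nodewise Ising
estimation, called thousands of times inside permutation and bootstrap
procedures) and the single-site Gibbs sweep.  Both operate on plain
float64/int8 arrays; all orchestration, validation and bookkeeping stay
in the pure-Python callers.

The path solver uses the standard proximal-Newton scheme: an outer
iteratively-reweighted least-squares approximation of the logistic
loss, an inner cyclic coordinate descent with soft thresholding on the
penalized quadratic, warm starts along a decreasing penalty grid.  The
objective solved at penalty ``lam`` is

    (1/n) * sum_i w_i * [-y_i eta_i + log(1 + exp(eta_i))] + lam * ||beta||_1

with an unpenalized intercept, where ``w`` are row multiplicities
(identical predictor/response rows are collapsed to one weighted row by
the caller; the fit is exactly that of the expanded data).
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: hard cap on |coefficient|; guards against runaway estimates under
#: perfect separation inside resamples
COEF_CAP = 15.0
_WEIGHT_FLOOR = 1e-5


@njit(cache=True)
def _log1pexp(x: float) -> float:
    # numerically stable log(1 + exp(x))
    if x > 0.0:
        return x + np.log1p(np.exp(-x))
    return np.log1p(np.exp(x))


@njit(cache=True)
def lasso_logistic_path(X, y, w, lambdas, tol, max_iter):
    """Fit the full penalty path for one nodewise logistic regression.

    Parameters
    ----------
    X : (m, q) float64
        Collapsed predictor rows.
    y : (m,) float64
        Binary response per collapsed row.
    w : (m,) float64
        Row multiplicities; ``n = w.sum()``.
    lambdas : (L,) float64
        Penalty grid, strictly decreasing.
    tol : float
        Convergence tolerance on parameter changes.
    max_iter : int
        Cap on outer IRLS iterations per penalty value.

    Returns
    -------
    coefs : (L, q), intercepts : (L,), logliks : (L,), n_active : (L,)
        ``logliks`` are unpenalized log-likelihoods of the penalized
        solutions (plug-in convention, used by EBIC).
    """
    m, q = X.shape
    L = lambdas.shape[0]
    n = w.sum()

    # `tol` bounds the objective suboptimality; the loops below stop on
    # parameter/linear-predictor changes, whose squared magnitude enters
    # the quadratic objective with curvature <= 1/4, so these looser
    # derived thresholds still meet the objective tolerance
    inner_tol = 1000.0 * tol
    outer_tol = 5000.0 * tol

    coefs = np.zeros((L, q))
    intercepts = np.zeros(L)
    logliks = np.zeros(L)
    n_active = np.zeros(L, dtype=np.int64)

    beta = np.zeros(q)
    # start at the null model: intercept = logit(ybar)
    ybar = (w * y).sum() / n
    if ybar < 1e-12:
        ybar = 1e-12
    if ybar > 1.0 - 1e-12:
        ybar = 1.0 - 1e-12
    b0 = np.log(ybar / (1.0 - ybar))
    eta = np.full(m, b0)

    r = np.zeros(m)
    v = np.zeros(m)
    z = np.zeros(m)
    col_ss = np.zeros(q)

    for l in range(L):
        lam = lambdas[l]
        for outer in range(max_iter):
            # IRLS working response and weights
            for i in range(m):
                p_i = 1.0 / (1.0 + np.exp(-eta[i]))
                var = p_i * (1.0 - p_i)
                if var < _WEIGHT_FLOOR:
                    var = _WEIGHT_FLOOR
                v[i] = w[i] * var / n
                z[i] = eta[i] + (y[i] - p_i) / var
            for j in range(q):
                s = 0.0
                for i in range(m):
                    s += v[i] * X[i, j] * X[i, j]
                col_ss[j] = s
            vsum = v.sum()
            # residual of the current linear predictor
            for i in range(m):
                r[i] = z[i] - eta[i]
            # cyclic coordinate descent on the penalized quadratic
            for inner in range(200):
                max_delta = 0.0
                num = 0.0
                for i in range(m):
                    num += v[i] * r[i]
                d = num / vsum
                if d != 0.0:
                    b0 += d
                    for i in range(m):
                        r[i] -= d
                    if abs(d) > max_delta:
                        max_delta = abs(d)
                for j in range(q):
                    if col_ss[j] <= 0.0:
                        continue
                    bj = beta[j]
                    num = col_ss[j] * bj
                    for i in range(m):
                        num += v[i] * X[i, j] * r[i]
                    if num > lam:
                        bj_new = (num - lam) / col_ss[j]
                    elif num < -lam:
                        bj_new = (num + lam) / col_ss[j]
                    else:
                        bj_new = 0.0
                    if bj_new > COEF_CAP:
                        bj_new = COEF_CAP
                    elif bj_new < -COEF_CAP:
                        bj_new = -COEF_CAP
                    d = bj_new - bj
                    if d != 0.0:
                        beta[j] = bj_new
                        for i in range(m):
                            r[i] -= d * X[i, j]
                        if abs(d) > max_delta:
                            max_delta = abs(d)
                if max_delta < inner_tol:
                    break
            # eta of the updated model; r = z - eta by construction
            max_eta_change = 0.0
            for i in range(m):
                eta_new = z[i] - r[i]
                if abs(eta_new - eta[i]) > max_eta_change:
                    max_eta_change = abs(eta_new - eta[i])
                eta[i] = eta_new
            if max_eta_change < outer_tol:
                break
        for j in range(q):
            # snap numerically-zero coefficients (KKT boundary ties at
            # the path start) so the null model really is on the path
            if abs(beta[j]) < 1e-8:
                coefs[l, j] = 0.0
            else:
                coefs[l, j] = beta[j]
                n_active[l] += 1
        intercepts[l] = b0
        ll = 0.0
        for i in range(m):
            ll += w[i] * (y[i] * eta[i] - _log1pexp(eta[i]))
        logliks[l] = ll
    return coefs, intercepts, logliks, n_active


@njit(cache=True)
def gibbs_chain(W, tau, init, unif, burn_in, thin, n_keep):
    """Run a Gibbs chain and return ``n_keep`` thinned post-burn-in states."""
    p = tau.shape[0]
    x = init.copy()
    out = np.empty((n_keep, p), dtype=np.int8)
    kept = 0
    total = burn_in + n_keep * thin
    for sweep in range(total):
        for i in range(p):
            eta = tau[i]
            for j in range(p):
                if x[j] == 1:
                    eta += W[i, j]
            # W[i,i] is 0 so self-term never contributes
            prob = 1.0 / (1.0 + np.exp(-eta))
            x[i] = 1 if unif[sweep, i] < prob else 0
        if sweep >= burn_in and (sweep - burn_in) % thin == thin - 1:
            out[kept] = x
            kept += 1
    return out
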