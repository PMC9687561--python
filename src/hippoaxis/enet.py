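"""Weighted logistic elastic-net path solver.

Coordinate-descent on the penalized weighted logistic likelihood

    -(1/n) sum_i w_i [y_i eta_i - log(1 + exp(eta_i))]
        + lambda * (alpha ||beta||_1 + (1 - alpha)/2 ||beta||_2^2)

with an unpenalized intercept, solved by IRLS (proximal Newton) with
cyclic coordinate descent on the working least-squares problem and warm
starts along a descending lambda path — the standard regularization-path
strategy for generalized linear models.  The nested cross-validation in
the modelling layer needs thousands of warm-started path fits per
cohort, so the inner loops are JIT-compiled.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_PMIN = 1e-5  # probability clip during IRLS, as in standard path solvers


def lambda_path(X: np.ndarray, y: np.ndarray, w: np.ndarray, alpha: float,
                n_lambda: int = 100, min_ratio: float = 1e-4) -> np.ndarray:
    """Descending lambda grid from the smallest all-zero-coefficient value.

    lambda_max = max_j |(1/n) sum_i w_i x_ij (y_i - ybar_w)| / alpha.
    """
    if not 0 < alpha <= 1:
        raise ValueError("mixing alpha must lie in (0, 1]")
    wsum = float(np.sum(w))
    ybar = float(np.sum(w * y) / wsum)
    grad = np.abs(X.T @ (w * (y - ybar))) / wsum
    lam_max = float(grad.max()) / alpha
    if lam_max <= 0:
        lam_max = 1e-3
    return np.geomspace(lam_max, lam_max * min_ratio, n_lambda)


@njit(cache=True, fastmath=True)
def _cd_sweep(X, wq, r, beta, xv, l1, l2, active_only, active):
    """One coordinate-descent sweep; returns the largest coefficient move."""
    n, p = X.shape
    db_max = 0.0
    for j in range(p):
        if active_only and not active[j]:
            continue
        if xv[j] + l2 <= 0:
            continue
        num = xv[j] * beta[j]
        for i in range(n):
            num += wq[i] * X[i, j] * r[i]
        if num > l1:
            bj = (num - l1) / (xv[j] + l2)
        elif num < -l1:
            bj = (num + l1) / (xv[j] + l2)
        else:
            bj = 0.0
        d = bj - beta[j]
        if d != 0.0:
            for i in range(n):
                r[i] -= d * X[i, j]
            beta[j] = bj
            active[j] = bj != 0.0
            if abs(d) > db_max:
                db_max = abs(d)
        elif bj != 0.0:
            active[j] = True
    return db_max


@njit(cache=True, fastmath=True)
def enet_logistic_path(X, y, w, alpha, lambdas, tol=1e-5, max_irls=10, max_cd=50):
    """Fit the full lambda path with warm starts.

    Returns (intercepts (K,), coefficients (K, p)).  ``w`` are
    observation weights normalized to sum n.  Each IRLS step runs one
    full coordinate sweep followed by active-set sweeps to convergence.
    """
    n, p = X.shape
    K = len(lambdas)
    wtot = 0.0
    for i in range(n):
        wtot += w[i]
    wn = w / wtot  # weights normalized to sum 1: rescaling w is a no-op
    b0s = np.zeros(K)
    betas = np.zeros((K, p))
    beta = np.zeros(p)
    active = np.zeros(p, dtype=np.bool_)
    # intercept-only start: weighted log-odds
    ybar = 0.0
    wsum = 0.0
    for i in range(n):
        ybar += wn[i] * y[i]
        wsum += wn[i]
    ybar /= wsum
    if ybar < _PMIN:
        ybar = _PMIN
    if ybar > 1 - _PMIN:
        ybar = 1 - _PMIN
    b0 = np.log(ybar / (1 - ybar))
    eta = np.empty(n)
    wq = np.empty(n)
    r = np.empty(n)
    xv = np.empty(p)
    for k in range(K):
        lam = lambdas[k]
        l1 = lam * alpha
        l2 = lam * (1.0 - alpha)
        for _irls in range(max_irls):
            for i in range(n):
                e = b0
                for j in range(p):
                    if beta[j] != 0.0:
                        e += X[i, j] * beta[j]
                eta[i] = e
            for i in range(n):
                pr = 1.0 / (1.0 + np.exp(-eta[i]))
                if pr < _PMIN:
                    pr = _PMIN
                if pr > 1 - _PMIN:
                    pr = 1 - _PMIN
                q = pr * (1.0 - pr)
                wq[i] = wn[i] * q
                r[i] = (y[i] - pr) / q
            for j in range(p):
                s = 0.0
                for i in range(n):
                    s += wq[i] * X[i, j] * X[i, j]
                xv[j] = s
            wqs = 0.0
            for i in range(n):
                wqs += wq[i]

            db_irls = 0.0
            for sweep in range(max_cd):
                full = sweep == 0
                db = _cd_sweep(X, wq, r, beta, xv, l1, l2, not full, active)
                num0 = 0.0
                for i in range(n):
                    num0 += wq[i] * r[i]
                d0 = num0 / wqs
                b0 += d0
                for i in range(n):
                    r[i] -= d0
                if abs(d0) > db:
                    db = abs(d0)
                if db > db_irls:
                    db_irls = db
                if db < tol:
                    if full:
                        break
                    # converged on the active set: verify with a full sweep
                    db2 = _cd_sweep(X, wq, r, beta, xv, l1, l2, False, active)
                    if db2 < tol:
                        break
            if db_irls < 10 * tol:
                break
        b0s[k] = b0
        for j in range(p):
            betas[k, j] = beta[j]
    return b0s, betas


@njit(cache=True)
def binomial_deviance_path(b0s, betas, Xv, yv, wv):
    """Weighted binomial deviance of each path solution on held-out data."""
    K = len(b0s)
    nv, p = Xv.shape
    dev = np.zeros(K)
    for k in range(K):
        d = 0.0
        for i in range(nv):
            e = b0s[k]
            for j in range(p):
                e += Xv[i, j] * betas[k, j]
            pr = 1.0 / (1.0 + np.exp(-e))
            if pr < _PMIN:
                pr = _PMIN
            if pr > 1 - _PMIN:
                pr = 1 - _PMIN
            if yv[i] > 0.5:
                d += -2.0 * wv[i] * np.log(pr)
            else:
                d += -2.0 * wv[i] * np.log(1.0 - pr)
        dev[k] = d
    return dev


def predict_proba(b0: float, beta: np.ndarray, X: np.ndarray) -> np.ndarray:
    eta = b0 + X @ beta
    return 1.0 / (1.0 + np.exp(-eta))
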