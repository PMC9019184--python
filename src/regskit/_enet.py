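"""Elastic-net penalized logistic regression, solved along a lambda path.

Minimises, for labels y in {0,1} and an n × p design X (already standardized):

    -(1/n) · loglik(b0, beta) + lam · [ a·||beta||_1 + (1-a)/2·||beta||_2^2 ]

by iteratively reweighted least squares with cyclic coordinate descent on the
penalized weighted working response, warm-started along a decreasing lambda
sequence and using an active-set strategy (full sweeps only to admit new
coordinates).  This is the classical path algorithm for sparse generalized
linear models; it is written here because signature training needs thousands
of warm-started path fits (one per cross-validation fold × mixing value)
inside tight time budgets.

Probabilities are clipped to [1e-5, 1 - 1e-5] inside the IRLS loop to keep
the working weights bounded away from zero under (quasi-)separation.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["lambda_max", "logistic_enet_path", "standardize"]


def standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column-standardize; zero-variance columns get scale 1 (stay at zero)."""
    center = X.mean(axis=0)
    scale = X.std(axis=0)
    scale = np.where(scale > 0, scale, 1.0)
    return (X - center) / scale, center, scale


def lambda_max(X: np.ndarray, y: np.ndarray, alpha: float) -> float:
    """Smallest lambda at which every coefficient is zero (standardized X)."""
    n = len(y)
    grad = X.T @ (y - y.mean()) / n
    return float(np.max(np.abs(grad)) / max(alpha, 1e-3))


def lambda_path(lmax: float, n_lambda: int = 100, min_ratio: float = 0.01) -> np.ndarray:
    """Log-spaced decreasing lambda sequence from lambda_max downward."""
    return np.exp(np.linspace(np.log(lmax), np.log(lmax * min_ratio), n_lambda))


@njit(cache=True)
def _cd_wls(X, w, r, beta, active, lam_l1, lam_l2, full_sweep, tol, n):
    """One pass of coordinate descent on the weighted working residual.

    Updates ``beta`` and the residual ``r`` in place; returns (max squared
    weighted change, number of newly activated coordinates).
    """
    p = X.shape[1]
    max_delta = 0.0
    newly_active = 0
    for j in range(p):
        if not full_sweep and not active[j]:
            continue
        xj = X[:, j]
        # weighted inner products
        num = 0.0
        den = 0.0
        for i in range(n):
            num += w[i] * xj[i] * r[i]
            den += w[i] * xj[i] * xj[i]
        num = num / n + (den / n) * beta[j]
        den = den / n + lam_l2
        # soft threshold
        if num > lam_l1:
            bj = (num - lam_l1) / den
        elif num < -lam_l1:
            bj = (num + lam_l1) / den
        else:
            bj = 0.0
        diff = bj - beta[j]
        if diff != 0.0:
            for i in range(n):
                r[i] -= xj[i] * diff
            d2 = (den) * diff * diff
            if d2 > max_delta:
                max_delta = d2
            if not active[j] and bj != 0.0:
                active[j] = True
                newly_active += 1
            beta[j] = bj
    return max_delta, newly_active


@njit(cache=True)
def _path_kernel(X, y, alpha, lambdas, tol, max_outer, max_inner):
    n, p = X.shape
    L = lambdas.shape[0]
    coefs = np.zeros((L, p))
    intercepts = np.zeros(L)

    ybar = y.mean()
    if ybar < 1e-9:
        ybar = 1e-9
    if ybar > 1.0 - 1e-9:
        ybar = 1.0 - 1e-9
    b0 = np.log(ybar / (1.0 - ybar))
    beta = np.zeros(p)
    active = np.zeros(p, dtype=np.bool_)
    eta = np.full(n, b0)

    pvec = np.empty(n)
    w = np.empty(n)
    z = np.empty(n)
    r = np.empty(n)

    for l in range(L):
        lam = lambdas[l]
        lam_l1 = lam * alpha
        lam_l2 = lam * (1.0 - alpha)
        for _outer in range(max_outer):
            # quadratic approximation at current (b0, beta)
            for i in range(n):
                pi = 1.0 / (1.0 + np.exp(-eta[i]))
                if pi < 1e-5:
                    pi = 1e-5
                if pi > 1.0 - 1e-5:
                    pi = 1.0 - 1e-5
                pvec[i] = pi
                w[i] = pi * (1.0 - pi)
                z[i] = eta[i] + (y[i] - pi) / w[i]
                r[i] = z[i] - eta[i]
            wsum = w.sum()
            outer_delta = 0.0
            for inner in range(max_inner):
                full = inner == 0
                max_delta, newly = _cd_wls(X, w, r, beta, active, lam_l1, lam_l2, full, tol, n)
                # intercept
                num = 0.0
                for i in range(n):
                    num += w[i] * r[i]
                db0 = num / wsum
                if db0 != 0.0:
                    b0 += db0
                    for i in range(n):
                        r[i] -= db0
                    d2 = (wsum / n) * db0 * db0
                    if d2 > max_delta:
                        max_delta = d2
                if max_delta > outer_delta:
                    outer_delta = max_delta
                if max_delta < tol:
                    if full and newly == 0:
                        break
                    # converged on the active set: one confirming full sweep
                    max_delta, newly = _cd_wls(
                        X, w, r, beta, active, lam_l1, lam_l2, True, tol, n
                    )
                    if max_delta < tol and newly == 0:
                        break
            # eta = b0 + X beta == z - r
            for i in range(n):
                eta[i] = z[i] - r[i]
            if outer_delta < tol:
                break
        coefs[l, :] = beta
        intercepts[l] = b0
    return intercepts, coefs


def logistic_enet_path(
    X: np.ndarray,
    y: np.ndarray,
    alpha: float,
    lambdas: np.ndarray,
    tol: float = 1e-8,
    max_outer: int = 30,
    max_inner: int = 300,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit the elastic-net logistic path on a standardized design.

    Returns ``(intercepts, coefs)`` with shapes (L,) and (L, p), one row per
    lambda (decreasing order expected).
    """
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.ascontiguousarray(y, dtype=np.float64)
    lambdas = np.ascontiguousarray(lambdas, dtype=np.float64)
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must be in (0, 1]")
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X and y have incompatible shapes")
    return _path_kernel(X, y, alpha, lambdas, tol, max_outer, max_inner)
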