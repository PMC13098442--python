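"""Generalized estimating equations for clustered binary outcomes.

A small, purpose-built GEE engine for marginal linear-probability models
(identity link) with binomial working variance and an exchangeable working
correlation — the configuration used for paired multi-reader comparisons
where all reader-by-phase outcomes for one sample form a cluster.

Estimation is Fisher scoring on the estimating equation

    sum_i  X_i' V_i^{-1} (y_i - X_i beta) = 0,
    V_i = A_i^{1/2} R(rho) A_i^{1/2},  A_i = diag(mu_ij (1 - mu_ij)),

with rho re-estimated each iteration by the method of moments from
Pearson residuals, and the variance of beta-hat reported through the
robust (sandwich) estimator, which stays valid when the working
correlation is wrong. The exchangeable inverse is applied in closed form
(Sherman-Morrison), so clusters of any size cost O(n) per iteration.

Numerical guards: fitted probabilities are clipped away from {0, 1} for
the working variance only (the residuals use the unclipped mean), and rho
is kept inside the positive-definite range for the largest cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

_MU_EPS = 1e-8


@dataclass
class GEEFit:
    """Raw engine output: coefficients with sandwich covariance."""

    beta: np.ndarray
    robust_cov: np.ndarray
    rho: float
    scale: float
    n_clusters: int
    n_obs: int
    converged: bool
    n_iter: int
    flags: list[str] = field(default_factory=list)


def _exchangeable_solve(r: np.ndarray, rho: float) -> np.ndarray:
    """R(rho)^{-1} r for the exchangeable correlation, in closed form."""
    n = len(r)
    if n == 1 or rho == 0.0:
        return r.copy()
    denom = 1.0 + (n - 1) * rho
    return (r - (rho / denom) * r.sum()) / (1.0 - rho)


def fit_gee(
    y: np.ndarray,
    X: np.ndarray,
    clusters: np.ndarray,
    rho: Optional[float] = None,
    variance: str = "binomial",
    tol: float = 1e-12,
    max_iter: int = 200,
) -> GEEFit:
    """Fit an identity-link GEE.

    Parameters
    ----------
    y, X
        Outcome vector (binary, as floats) and design matrix.
    clusters
        Cluster label per observation; correlation is modeled within
        clusters only.
    rho
        Fix the working correlation at this value instead of estimating
        it (``rho=0`` gives the independence working model).
    variance
        ``binomial`` for mu(1-mu) working variance, ``constant`` for a
        Gaussian-style working variance of 1.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(y):
        raise ValueError("X and y lengths differ")
    clusters = np.asarray(clusters)
    _, cluster_idx = np.unique(clusters, return_inverse=True)
    n_clusters = cluster_idx.max() + 1
    groups = [np.flatnonzero(cluster_idx == g) for g in range(n_clusters)]
    sizes = np.array([len(g) for g in groups])
    n_obs, p = X.shape
    max_n = sizes.max()

    flags: list[str] = []
    estimate_rho = rho is None
    rho_hat = 0.0 if estimate_rho else float(rho)

    # independence-model start (OLS)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    converged = False
    scale = 1.0
    for it in range(1, max_iter + 1):
        mu = X @ beta
        if variance == "binomial":
            var = np.clip(mu * (1.0 - mu), _MU_EPS, None)
        else:
            var = np.ones(n_obs)
        resid = y - mu
        pearson = resid / np.sqrt(var)
        dof = max(n_obs - p, 1)
        scale = float(pearson @ pearson) / dof

        if estimate_rho and max_n > 1:
            num = 0.0
            n_pairs = 0
            for g in groups:
                e = pearson[g]
                s = e.sum()
                num += (s * s - e @ e) / 2.0
                n_pairs += len(g) * (len(g) - 1) // 2
            denom = scale * max(n_pairs - p, 1)
            rho_hat = num / denom if denom > 0 else 0.0
            lo = -1.0 / (max_n - 1) + 1e-6
            rho_hat = float(np.clip(rho_hat, lo, 0.999))

        B = np.zeros((p, p))
        u = np.zeros(p)
        for g in groups:
            a_inv_sqrt = 1.0 / np.sqrt(var[g])
            Xw = X[g] * a_inv_sqrt[:, None]          # A^{-1/2} X_i
            rw = resid[g] * a_inv_sqrt               # A^{-1/2} r_i
            Xs = np.column_stack([_exchangeable_solve(Xw[:, j], rho_hat) for j in range(p)])
            B += Xw.T @ Xs
            u += Xs.T @ rw
        step = np.linalg.solve(B, u)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break

    if not converged:
        flags.append(f"non-convergence after {max_iter} iterations (final step reported)")

    # sandwich covariance at the final iterate
    mu = X @ beta
    if variance == "binomial":
        var = np.clip(mu * (1.0 - mu), _MU_EPS, None)
    else:
        var = np.ones(n_obs)
    resid = y - mu
    B = np.zeros((p, p))
    M = np.zeros((p, p))
    for g in groups:
        a_inv_sqrt = 1.0 / np.sqrt(var[g])
        Xw = X[g] * a_inv_sqrt[:, None]
        rw = resid[g] * a_inv_sqrt
        Xs = np.column_stack([_exchangeable_solve(Xw[:, j], rho_hat) for j in range(p)])
        B += Xw.T @ Xs
        s_i = Xs.T @ rw
        M += np.outer(s_i, s_i)
    B_inv = np.linalg.inv(B)
    robust_cov = B_inv @ M @ B_inv

    if np.allclose(resid, 0.0):
        flags.append("separation: residuals identically zero, sandwich SE is 0")

    return GEEFit(
        beta=beta,
        robust_cov=robust_cov,
        rho=rho_hat if max_n > 1 else 0.0,
        scale=scale,
        n_clusters=int(n_clusters),
        n_obs=int(n_obs),
        converged=converged,
        n_iter=it,
        flags=flags,
    )


def wald_test(estimate: float, se: float) -> float:
    """Two-sided normal Wald p-value; degenerate SE=0 maps to p=1 when the
    estimate is also (numerically) 0 — no information — and p=0 otherwise."""
    if se == 0.0:
        return 1.0 if abs(estimate) < 1e-10 else 0.0
    z = estimate / se
    return float(2.0 * stats.norm.sf(abs(z)))
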