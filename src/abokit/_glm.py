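"""Newton/IRLS fits for logistic and multinomial log-linear models.

Both fits share a separation contract: maximum-likelihood estimation is
attempted unpenalized; if the iterates diverge (coefficients or linear
predictors running away, weights collapsing) or fail to converge, the model
is refit with a small fixed ridge (1e-6 by default) on the coefficients and
flagged ``converged=False``.  Near-perfect tag SNPs separate ABO phenotypes
routinely, so this path is ordinary, not exceptional.

Standard errors come from the inverse of the (penalized) observed Fisher
information; Wald tests are two-sided normal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

SEPARATION_RIDGE = 1e-6
_BETA_CAP = 30.0  # |linear predictor| beyond which we call it separation


@dataclass
class GLMFit:
    """Coefficients, covariance and convergence state of one fit."""

    beta: np.ndarray          # (p,) logistic, (K-1, p) multinomial
    cov: np.ndarray           # (p, p) or (K-1 * p, K-1 * p)
    converged: bool
    separated: bool
    n_iter: int
    ridge: float


def _clip_eta(eta: np.ndarray) -> np.ndarray:
    return np.clip(eta, -_BETA_CAP, _BETA_CAP)


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    ridge: float = 0.0,
    max_iter: int = 60,
    tol: float = 1e-10,
) -> GLMFit:
    """Binary logistic regression by Newton-Raphson.

    ``X`` must already include an intercept column.  On separation the fit
    is retried once with ``SEPARATION_RIDGE`` and flagged unconverged.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    beta = np.zeros(p)
    separated = False
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        if np.max(np.abs(eta)) > _BETA_CAP and ridge == 0.0:
            separated = True
            break
        mu = 1.0 / (1.0 + np.exp(-_clip_eta(eta)))
        w = mu * (1.0 - mu)
        grad = X.T @ (y - mu) - ridge * beta
        info = (X * w[:, None]).T @ X + ridge * np.eye(p)
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            separated = True
            break
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    if separated or (not converged and ridge == 0.0):
        fit = fit_logistic(X, y, ridge=SEPARATION_RIDGE, max_iter=200, tol=1e-8)
        return GLMFit(fit.beta, fit.cov, False, True, fit.n_iter,
                      SEPARATION_RIDGE)
    eta = _clip_eta(X @ beta)
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = np.maximum(mu * (1.0 - mu), 1e-12)
    info = (X * w[:, None]).T @ X + ridge * np.eye(p)
    cov = np.linalg.pinv(info)
    return GLMFit(beta, cov, converged, False, it, ridge)


def fit_multinomial(
    X: np.ndarray,
    y_index: np.ndarray,
    n_classes: int,
    ridge: float = 0.0,
    max_iter: int = 100,
    tol: float = 1e-9,
) -> GLMFit:
    """Multinomial log-linear model with class 0 as the reference level.

    ``y_index`` codes classes 0..K-1; class 0 (type O in our use) has linear
    predictor fixed at zero.  The joint Newton step uses the full
    (K-1)p x (K-1)p observed information.  Returns ``beta`` with shape
    (K-1, p).
    """
    X = np.asarray(X, dtype=float)
    y_index = np.asarray(y_index, dtype=int)
    n, p = X.shape
    K = n_classes
    if not np.any(y_index == 0):
        raise ValueError("reference class (index 0) absent from the data")
    Y = np.zeros((n, K - 1))
    for k in range(1, K):
        Y[:, k - 1] = y_index == k

    B = np.zeros((K - 1, p))
    separated = False
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ B.T  # (n, K-1)
        if np.max(np.abs(eta)) > _BETA_CAP and ridge == 0.0:
            separated = True
            break
        eta_c = np.clip(eta, -_BETA_CAP, _BETA_CAP)
        expeta = np.exp(eta_c)
        denom = 1.0 + expeta.sum(axis=1)
        P = expeta / denom[:, None]  # (n, K-1), probs of non-reference classes

        grad = (X.T @ (Y - P)).T.ravel() - ridge * B.ravel()
        info = np.empty(((K - 1) * p, (K - 1) * p))
        for a in range(K - 1):
            for b in range(K - 1):
                w = P[:, a] * ((a == b) - P[:, b])
                info[a * p:(a + 1) * p, b * p:(b + 1) * p] = \
                    (X * w[:, None]).T @ X
        info += ridge * np.eye((K - 1) * p)
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            separated = True
            break
        B = B + step.reshape(K - 1, p)
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    if separated or (not converged and ridge == 0.0):
        fit = fit_multinomial(
            X, y_index, n_classes, ridge=SEPARATION_RIDGE, max_iter=300,
            tol=1e-7,
        )
        return GLMFit(fit.beta, fit.cov, False, True, fit.n_iter,
                      SEPARATION_RIDGE)
    eta = np.clip(X @ B.T, -_BETA_CAP, _BETA_CAP)
    expeta = np.exp(eta)
    P = expeta / (1.0 + expeta.sum(axis=1))[:, None]
    info = np.empty(((K - 1) * p, (K - 1) * p))
    for a in range(K - 1):
        for b in range(K - 1):
            w = P[:, a] * ((a == b) - P[:, b])
            info[a * p:(a + 1) * p, b * p:(b + 1) * p] = \
                (X * w[:, None]).T @ X
    info += max(ridge, 1e-12) * np.eye((K - 1) * p)
    cov = np.linalg.pinv(info)
    return GLMFit(B, cov, converged, False, it, ridge)


def wald_p(beta: float, se: float) -> float:
    """Two-sided normal Wald p-value, floored away from exact 0."""
    if se <= 0 or not np.isfinite(se):
        return np.nan
    z = beta / se
    p = 2.0 * stats.norm.sf(abs(z))
    return max(p, np.nextafter(0, 1))
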