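"""Minimal dense least-squares and logistic solvers for tight simulation loops.

The instrumental-variable bootstrap and the coverage/power simulations refit
small (2--6 column) regressions tens of thousands of times; these routines do
exactly that and nothing else.  They are cross-checked against statsmodels in
the test suite, which remains the fitting engine for the user-facing
association layer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class OLSResult:
    beta: np.ndarray
    fitted: np.ndarray
    residuals: np.ndarray
    rss: float
    cov: np.ndarray  # sigma^2 (X'X)^-1
    df_resid: int


def ols(X: np.ndarray, y: np.ndarray) -> OLSResult:
    """OLS via normal equations; X must be full column rank."""
    XtX = X.T @ X
    Xty = X.T @ y
    beta = np.linalg.solve(XtX, Xty)
    fitted = X @ beta
    resid = y - fitted
    rss = float(resid @ resid)
    df = X.shape[0] - X.shape[1]
    if df <= 0:
        raise ValueError("more parameters than observations")
    cov = np.linalg.inv(XtX) * (rss / df)
    return OLSResult(beta, fitted, resid, rss, cov, df)


def _expit(z: np.ndarray) -> np.ndarray:
    # exp(-z) overflowing to inf still yields the correct limit 0.0
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-z))


class SeparationError(RuntimeError):
    """Raised when logistic ML estimates diverge (quasi-complete separation)."""


@dataclass
class LogitResult:
    beta: np.ndarray
    cov: np.ndarray  # inverse observed information
    loglik: float
    converged: bool
    n_iter: int

    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))


def logit(
    X: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray | None = None,
    offset: np.ndarray | None = None,
    beta0: np.ndarray | None = None,
    max_iter: int = 60,
    tol: float = 1e-10,
    divergence_bound: float = 60.0,
) -> LogitResult:
    """Newton–Raphson maximum likelihood for binary-response logistic regression.

    ``y`` may be 0/1 indicators or event proportions paired with frequency
    ``weights`` (grouped data).  Divergence is detected on the linear-predictor
    scale (scale-free, unlike a bound on raw coefficients): fitted log-odds
    beyond ``divergence_bound`` mean probabilities saturate at 0/1, the
    signature of quasi-complete separation; :class:`SeparationError` is raised.
    """
    n, p = X.shape
    w = np.ones(n) if weights is None else np.asarray(weights, float)
    off = np.zeros(n) if offset is None else offset
    beta = np.zeros(p) if beta0 is None else beta0.copy()
    ll_old = -np.inf
    for it in range(1, max_iter + 1):
        eta = X @ beta + off
        mu = _expit(eta)
        # penalize-free Newton step with tiny ridge for numerical safety
        wv = w * mu * (1.0 - mu)
        grad = X.T @ (w * (y - mu))
        H = (X * wv[:, None]).T @ X
        H[np.diag_indices_from(H)] += 1e-12
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError as exc:  # singular information
            raise SeparationError("singular information matrix") from exc
        beta_new = beta + step
        # step-halving if the log-likelihood decreases
        ll_new = _loglik(X, y, w, off, beta_new)
        halvings = 0
        while not np.isfinite(ll_new) or ll_new < ll_old - 1e-10:
            step *= 0.5
            beta_new = beta + step
            ll_new = _loglik(X, y, w, off, beta_new)
            halvings += 1
            if halvings > 30:
                raise SeparationError("logistic likelihood failed to increase")
        beta = beta_new
        if np.max(np.abs(X @ beta + off)) > divergence_bound:
            raise SeparationError(
                "fitted log-odds diverged beyond %.0f; data are separated"
                % divergence_bound
            )
        if abs(ll_new - ll_old) < tol * (abs(ll_old) + 1.0):
            eta = X @ beta + off
            mu = _expit(eta)
            wv = w * mu * (1.0 - mu)
            H = (X * wv[:, None]).T @ X
            return LogitResult(beta, np.linalg.inv(H), ll_new, True, it)
        ll_old = ll_new
    return LogitResult(beta, np.linalg.inv(H), ll_old, False, max_iter)


def _loglik(X, y, w, off, beta) -> float:
    eta = X @ beta + off
    # log(1+exp(eta)) = max(eta,0) + log1p(exp(-|eta|)), stable and fast
    log1pe = np.maximum(eta, 0.0) + np.log1p(np.exp(-np.abs(eta)))
    return float(np.sum(w * (y * eta - log1pe)))
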