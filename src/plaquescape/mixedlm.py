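"""Random-intercept linear mixed model via profiled REML.

The pseudobulk differential-expression models all share one structure:

    y = X beta + Z b + e,   b ~ N(0, sigma_b^2 I_q),   e ~ N(0, sigma^2 I_n)

with Z the indicator matrix of a single grouping factor (imaging batch). For
this model the likelihood profiles down to a one-dimensional optimization over
the variance ratio lambda = sigma_b^2 / sigma^2: with the eigendecomposition
Z Z' = Q D Q', the rotated problem is heteroscedastic least squares with
weights 1 / (1 + lambda d_i), so each candidate lambda costs one small
weighted regression. REML is used so the residual variance is unbiased at the
tiny replicate counts typical of pseudobulk designs, and Wald tests use a
t reference with n - p degrees of freedom. Designs where the grouping factor
cannot identify a variance (a single batch) fall back to ordinary least
squares, flagged in the result.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import t as t_dist

_LAMBDA_LOG_BOUNDS = (-10.0, 10.0)


@dataclass
class MixedFit:
    """Fitted fixed effects of a random-intercept model."""
    coef: np.ndarray
    se: np.ndarray
    tstat: np.ndarray
    pvalue: np.ndarray
    df: int
    sigma2: float           # residual variance
    lambda_: float          # variance ratio sigma_b^2 / sigma^2
    method: str             # "reml" or "ols"


def _reml_profile(y_t: np.ndarray, X_t: np.ndarray, d: np.ndarray, n: int, p: int):
    """REML criterion pieces in the rotated (eigen) basis, as a function of lambda."""

    def pieces(lam: float):
        w = 1.0 / (1.0 + lam * d)
        Xw = X_t * w[:, None]
        xtvx = X_t.T @ Xw
        xtvy = Xw.T @ y_t
        beta = np.linalg.solve(xtvx, xtvy)
        r = y_t - X_t @ beta
        rss = float(np.dot(r * w, r))
        sigma2 = rss / (n - p)
        sign, logdet_xtvx = np.linalg.slogdet(xtvx)
        logdet_v = float(np.sum(np.log1p(lam * d)))
        crit = (n - p) * np.log(max(sigma2, 1e-300)) + logdet_v + logdet_xtvx
        return crit, beta, sigma2, xtvx

    return pieces


def fit_random_intercept(y, X, groups) -> MixedFit:
    """Fit ``y = X beta + (1 | groups) + e`` by profiled REML.

    Parameters
    ----------
    y : (n,) response
    X : (n, p) fixed-effect design (include the intercept column)
    groups : (n,) grouping labels for the random intercept
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more observations ({n}) than fixed effects ({p})")
    codes = pd.factorize(np.asarray(groups))[0]
    q = codes.max() + 1
    if q < 2:
        return _ols(y, X)

    Z = np.zeros((n, q))
    Z[np.arange(n), codes] = 1.0
    # eigenbasis of ZZ' diagonalizes V(lambda) = I + lambda ZZ'
    dvals, Q = np.linalg.eigh(Z @ Z.T)
    dvals = np.clip(dvals, 0.0, None)
    y_t = Q.T @ y
    X_t = Q.T @ X
    pieces = _reml_profile(y_t, X_t, dvals, n, p)

    res = minimize_scalar(
        lambda u: pieces(np.exp(u))[0],
        bounds=_LAMBDA_LOG_BOUNDS, method="bounded",
        options={"xatol": 1e-6},
    )
    lam = float(np.exp(res.x))
    crit_hat = pieces(lam)[0]
    crit_zero = pieces(0.0)[0]
    if crit_zero <= crit_hat:        # boundary: no batch variance
        lam = 0.0
    crit, beta, sigma2, xtvx = pieces(lam)
    cov = sigma2 * np.linalg.inv(xtvx)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    # between-within degrees of freedom: once a batch variance is estimated,
    # the q - 1 batch contrasts no longer inform the residual variance
    df = n - p - (q - 1) if lam > 0 else n - p
    if df < 1:
        df = 1
    tstat, pval = _wald(beta, se, sigma2, df)
    return MixedFit(beta, se, tstat, pval, df, float(sigma2), lam, "reml")


def _wald(beta, se, sigma2, df):
    if sigma2 <= 1e-12:     # degenerate fit (identical responses): no evidence
        return np.zeros_like(beta), np.ones_like(beta)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, beta / se, 0.0)
    return tstat, 2.0 * t_dist.sf(np.abs(tstat), df)


def _ols(y: np.ndarray, X: np.ndarray) -> MixedFit:
    n, p = X.shape
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    df = n - p
    sigma2 = float(r @ r) / df
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    tstat, pval = _wald(beta, se, sigma2, df)
    return MixedFit(beta, se, tstat, pval, df, sigma2, 0.0, "ols")
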