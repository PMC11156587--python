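"""Vectorized ordinary least squares shared by the analysis stages.

All per-feature linear models in the package (differential expression,
eQTL mapping, DMR models, P_ST) reduce to OLS of a response matrix on a
common design; these helpers solve the whole matrix at once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class OlsFit:
    """OLS of Y (n x f) on X (n x p), solved jointly for all f columns."""

    coef: np.ndarray  # (p, f)
    se: np.ndarray  # (p, f)
    df: int
    resid: np.ndarray  # (n, f)
    sse: np.ndarray  # (f,)

    def tstat(self, term: int) -> np.ndarray:
        return self.coef[term] / self.se[term]

    def pvalue(self, term: int) -> np.ndarray:
        t = self.tstat(term)
        return 2.0 * stats.t.sf(np.abs(t), self.df)


def check_full_rank(X: np.ndarray, names=None) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        names = list(names) if names is not None else list(range(X.shape[1]))
        # identify columns involved in the collinearity by dropping one at a time
        bad = []
        for j in range(X.shape[1]):
            keep = [k for k in range(X.shape[1]) if k != j]
            if np.linalg.matrix_rank(X[:, keep]) == rank:
                bad.append(names[j])
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")


def ols(X: np.ndarray, Y: np.ndarray, names=None) -> OlsFit:
    """Fit Y ~ X by least squares; Y may hold many responses as columns.

    Raises if the design is rank deficient or has no residual degrees of
    freedom (n <= p).
    """
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, p = X.shape
    if n <= p:
        raise ValueError(f"n ({n}) must exceed number of predictors ({p})")
    check_full_rank(X, names)
    xtx = X.T @ X
    xtx_inv = np.linalg.inv(xtx)
    coef = xtx_inv @ (X.T @ Y)
    resid = Y - X @ coef
    df = n - p
    sse = np.einsum("ij,ij->j", resid, resid)
    sigma2 = sse / df
    se = np.sqrt(np.outer(np.diag(xtx_inv), sigma2))
    return OlsFit(coef=coef, se=se, df=df, resid=resid, sse=sse)


def residualize(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Residuals of each column of Y on the column space of X."""
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return Y - X @ beta


def add_intercept(*cols) -> np.ndarray:
    """Stack an intercept with the given columns/matrices into a design."""
    arrays = [np.ones((len(np.atleast_1d(cols[0])), 1))] if cols else []
    for c in cols:
        c = np.asarray(c, float)
        arrays.append(c[:, None] if c.ndim == 1 else c)
    return np.column_stack(arrays)


def zscore_rows(M: np.ndarray, drop_constant: bool = True):
    """Per-row z-scoring; returns (scaled, kept_mask).

    Rows with zero variance are dropped (mask False) when requested.
    """
    M = np.asarray(M, float)
    mu = M.mean(axis=1, keepdims=True)
    sd = M.std(axis=1, ddof=1, keepdims=True)
    keep = sd[:, 0] > 0
    if not drop_constant and not keep.all():
        raise ValueError("zero-variance rows present")
    Z = (M[keep] - mu[keep]) / sd[keep]
    return Z, keep
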