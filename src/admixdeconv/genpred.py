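"""Genotype-imputed expression and the genetic share of ancestry effects.

Expression is imputed from cis dosages either with the single top eQTL
(posterior effect x dosage) or with an elastic net over all cis variants
(coordinate descent over a lambda path, alpha tuned on a 0.05..1 grid,
weights averaged over cross-validation folds).  Regressing the imputed
expression on ancestry yields predicted ancestry effects; their squared
correlation with the observed (shrunken) ancestry effects across features is
the genetic share of ancestry-associated expression differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _regression as reg
from .genotypes import hwe_pvalues_from_dosage

DEFAULT_ALPHAS = np.round(np.arange(0.05, 1.0001, 0.05), 2)


@dataclass
class PredictionModel:
    feature_id: str
    variant_ids: list[str]
    weights: np.ndarray
    model_kind: str  # top_snp | elastic_net
    cv_r: float
    alpha: float | None = None
    lam: float | None = None
    flagged: bool = False
    converged: bool = True
    kept_idx: np.ndarray | None = None  # rows of the fitting dosage matrix used

    def __post_init__(self):
        self.weights = np.asarray(self.weights, float)
        if self.weights.size and not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")
        if np.isfinite(self.cv_r) and not -1.0 <= self.cv_r <= 1.0:
            raise ValueError("cv_r must lie in [-1, 1]")

    def predict(self, dosage: np.ndarray) -> np.ndarray:
        """Weighted dosage sum; accepts either the filtered matrix (rows ==
        weights) or the original fitting matrix (kept rows selected)."""
        dosage = np.asarray(dosage, float)
        if self.kept_idx is not None and dosage.shape[0] != self.weights.size:
            dosage = dosage[self.kept_idx]
        return self.weights @ dosage


@dataclass
class VarianceExplained:
    region: str
    r2: float
    slope: float
    n_features: int

    def __post_init__(self):
        if np.isfinite(self.r2) and not 0.0 <= self.r2 <= 1.0 + 1e-12:
            raise ValueError("r2 must lie in [0, 1]")


# ----------------------------------------------------- coordinate descent
def enet_objective(X, y, w, lam, l1_ratio):
    n = len(y)
    r = y - X @ w
    return (
        0.5 * (r @ r) / n
        + lam * (l1_ratio * np.abs(w).sum() + 0.5 * (1 - l1_ratio) * (w @ w))
    )


def _soft(x, t):
    return np.sign(x) * max(abs(x) - t, 0.0)


def _cd_gram_py(gram, xty, n, lam, l1_ratio, w, max_sweeps, tol):
    p = len(w)
    denom = np.diag(gram) / n + lam * (1.0 - l1_ratio)
    for sweep in range(max_sweeps):
        delta = 0.0
        for j in range(p):
            if denom[j] <= 0:
                w[j] = 0.0  # zero-variance predictor stays out
                continue
            rho = (xty[j] - gram[j] @ w + gram[j, j] * w[j]) / n
            new = _soft(rho, lam * l1_ratio) / denom[j]
            delta = max(delta, abs(new - w[j]))
            w[j] = new
        if delta < tol:
            return sweep + 1
    return max_sweeps


try:  # compiled kernel for the cross-validation grid; same update rule
    from numba import njit

    @njit(cache=True)
    def _cd_gram_nb(gram, xty, n, lam, l1_ratio, w, max_sweeps, tol):  # pragma: no cover
        p = len(w)
        thresh = lam * l1_ratio
        for sweep in range(max_sweeps):
            delta = 0.0
            for j in range(p):
                denom = gram[j, j] / n + lam * (1.0 - l1_ratio)
                if denom <= 0:
                    w[j] = 0.0
                    continue
                acc = 0.0
                for k in range(p):
                    acc += gram[j, k] * w[k]
                rho = (xty[j] - acc + gram[j, j] * w[j]) / n
                if rho > thresh:
                    new = (rho - thresh) / denom
                elif rho < -thresh:
                    new = (rho + thresh) / denom
                else:
                    new = 0.0
                d = abs(new - w[j])
                if d > delta:
                    delta = d
                w[j] = new
            if delta < tol:
                return sweep + 1
        return max_sweeps

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def _cd_gram(gram, xty, n, lam, l1_ratio, w, max_sweeps=1000, tol=1e-9):
    """Cyclic coordinate descent on the Gram formulation; updates w in place.

    Returns the number of sweeps taken (== max_sweeps when not converged).
    """
    if _HAVE_NUMBA:
        return _cd_gram_nb(
            np.ascontiguousarray(gram), np.ascontiguousarray(xty),
            float(n), float(lam), float(l1_ratio), w, int(max_sweeps), float(tol),
        )
    return _cd_gram_py(gram, xty, n, lam, l1_ratio, w, max_sweeps, tol)


def enet_coordinate_descent(
    X, y, lam, l1_ratio, w0=None, max_sweeps=1000, tol=1e-9, return_trace=False
):
    """Elastic net by cyclic coordinate descent.

    Minimizes ``(1/2n)||y - Xw||^2 + lam*(l1_ratio*||w||_1 +
    (1-l1_ratio)/2*||w||_2^2)``.  With ``return_trace`` the objective value
    after every sweep is returned; it is non-increasing.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, p = X.shape
    w = np.zeros(p) if w0 is None else np.asarray(w0, float).copy()
    gram = X.T @ X
    xty = X.T @ y
    if not return_trace:
        _cd_gram(gram, xty, n, lam, l1_ratio, w, max_sweeps, tol)
        return w
    trace = []
    denom = np.diag(gram) / n + lam * (1.0 - l1_ratio)
    for _ in range(max_sweeps):
        delta = 0.0
        for j in range(p):
            if denom[j] <= 0:
                w[j] = 0.0
                continue
            rho = (xty[j] - gram[j] @ w + gram[j, j] * w[j]) / n
            new = _soft(rho, lam * l1_ratio) / denom[j]
            delta = max(delta, abs(new - w[j]))
            w[j] = new
        trace.append(enet_objective(X, y, w, lam, l1_ratio))
        if delta < tol:
            break
    return w, np.asarray(trace)


def _lambda_path(X, y, l1_ratio, n_lambda, min_ratio):
    n = len(y)
    lam_max = np.max(np.abs(X.T @ y)) / (n * max(l1_ratio, 1e-3))
    lam_max = max(lam_max, 1e-10)
    return lam_max * np.exp(
        np.linspace(0.0, np.log(min_ratio), n_lambda)
    )


def _kfold_indices(n, k, rng):
    perm = rng.permutation(n)
    return [perm[i::k] for i in range(k)]


def fit_elastic_net(
    feature_id: str,
    dosage_matrix: np.ndarray,
    variant_ids,
    expr: np.ndarray,
    alphas=DEFAULT_ALPHAS,
    k_folds: int = 5,
    n_lambda: int = 30,
    lambda_min_ratio: float = 1e-3,
    maf_min: float = 0.01,
    hwe_min_p: float = 1e-5,
    seed: int = 0,
) -> PredictionModel:
    """Cross-validated elastic net over cis variants for one feature.

    Variants are prefiltered on MAF and exact HWE; predictors are
    standardized within training folds (weights back-transformed); the
    (alpha, lambda) pair minimizing cross-validated MSE is selected, final
    weights are the across-fold mean and cv_r the per-fold-averaged Pearson
    correlation of held-out predictions with the observed values.
    """
    G = np.asarray(dosage_matrix, float)  # variants x samples
    y = np.asarray(expr, float)
    n = y.shape[0]
    if n <= k_folds:
        raise ValueError("need more samples than folds")
    variant_ids = list(variant_ids)

    keep = np.isfinite(G).all(axis=1)
    f = G.mean(axis=1) / 2.0
    maf = np.minimum(f, 1 - f)
    keep &= maf >= maf_min
    keep &= G.std(axis=1) > 0
    if keep.any():
        keep_idx = np.where(keep)[0]
        hwe = hwe_pvalues_from_dosage(G[keep_idx])
        keep_idx = keep_idx[hwe >= hwe_min_p]
    else:
        keep_idx = np.array([], int)
    if keep_idx.size == 0:
        return PredictionModel(
            feature_id=feature_id, variant_ids=[], weights=np.array([]),
            model_kind="elastic_net", cv_r=np.nan, flagged=True,
        )
    X_all = G[keep_idx].T  # n x p
    kept_ids = [variant_ids[i] for i in keep_idx]
    p = X_all.shape[1]

    rng = np.random.default_rng(seed)
    folds = _kfold_indices(n, k_folds, rng)
    alphas = np.asarray(alphas, float)

    # shared lambda path per alpha from the full standardized data
    mu_all, sd_all = X_all.mean(0), X_all.std(0)
    sd_all[sd_all == 0] = 1.0
    Xs_all = (X_all - mu_all) / sd_all
    yc_all = y - y.mean()

    cv_sse = np.full((len(alphas), n_lambda), 0.0)
    paths = [_lambda_path(Xs_all, yc_all, a, n_lambda, lambda_min_ratio) for a in alphas]
    fold_cache = []
    for fold, test in enumerate(folds):
        train = np.setdiff1d(np.arange(n), test)
        Xtr = X_all[train]
        mu, sd = Xtr.mean(0), Xtr.std(0)
        sd[sd == 0] = 1.0
        Xtr = (Xtr - mu) / sd
        ytr = y[train] - y[train].mean()
        Xte = (X_all[test] - mu) / sd
        yte = y[test] - y[train].mean()
        gram, xty = Xtr.T @ Xtr, Xtr.T @ ytr
        fold_cache.append((train, test, mu, sd, Xte, yte))
        for a_i, a in enumerate(alphas):
            w = np.zeros(p)
            for l_i, lam in enumerate(paths[a_i]):
                _cd_gram(gram, xty, len(train), lam, a, w, max_sweeps=200, tol=1e-7)
                r = yte - Xte @ w
                cv_sse[a_i, l_i] += r @ r

    a_i, l_i = np.unravel_index(np.argmin(cv_sse), cv_sse.shape)
    alpha, lam = float(alphas[a_i]), float(paths[a_i][l_i])

    # refit per fold at the chosen pair for averaged weights and cv_r
    weights = np.zeros(p)
    rs, converged = [], True
    for train, test, mu, sd, Xte, yte in fold_cache:
        Xtr = (X_all[train] - mu) / sd
        ytr = y[train] - y[train].mean()
        gram, xty = Xtr.T @ Xtr, Xtr.T @ ytr
        w = np.zeros(p)
        sweeps = _cd_gram(gram, xty, len(train), lam, alpha, w, max_sweeps=2000, tol=1e-9)
        converged &= sweeps < 2000
        weights += (w / sd) / k_folds  # back-transform to dosage scale
        pred = Xte @ w
        if np.std(pred) > 0 and np.std(yte) > 0:
            rs.append(np.corrcoef(pred, yte)[0, 1])
    cv_r = float(np.mean(rs)) if rs else np.nan
    return PredictionModel(
        feature_id=feature_id, variant_ids=kept_ids, weights=weights,
        model_kind="elastic_net", cv_r=cv_r, alpha=alpha, lam=lam,
        flagged=False, converged=bool(converged), kept_idx=keep_idx,
    )


def predict_top_snp(posterior_effect: float, dosage: np.ndarray) -> np.ndarray:
    """Imputed expression from the top eQTL: effect size times dosage."""
    dosage = np.asarray(dosage, float)
    return posterior_effect * dosage


def ancestry_effect_variance_explained(
    predicted_expr: np.ndarray,
    ancestry,
    covariates,
    observed_effects: np.ndarray,
    region: str = "region",
    min_features: int = 10,
) -> VarianceExplained:
    """Share of observed ancestry-effect variance captured by imputation.

    Each feature's predicted expression is regressed on ancestry plus the
    same covariates as the observed differential expression model; r2 is the
    squared Pearson correlation between predicted and observed effects and
    the slope is from regressing predicted on observed.
    """
    P = np.asarray(predicted_expr, float)
    obs = np.asarray(observed_effects, float)
    if P.shape[0] != obs.shape[0]:
        raise ValueError("predicted_expr and observed_effects must align")
    if P.shape[0] < min_features:
        raise ValueError(f"need at least {min_features} features, got {P.shape[0]}")
    theta = np.asarray(ancestry, float)
    n = theta.shape[0]
    C = np.empty((n, 0)) if covariates is None else np.asarray(covariates, float)
    if C.ndim == 1:
        C = C[:, None]
    X = np.column_stack([np.ones(n), theta, C])
    fit = reg.ols(X, P.T)
    pred_eff = fit.coef[1]
    r = np.corrcoef(pred_eff, obs)[0, 1]
    slope = reg.ols(np.column_stack([np.ones(len(obs)), obs]), pred_eff).coef[1, 0]
    return VarianceExplained(
        region=region, r2=float(r**2), slope=float(slope), n_features=P.shape[0]
    )


def models_to_frame(models: list[PredictionModel]) -> pd.DataFrame:
    rows = []
    for m in models:
        for v, w in zip(m.variant_ids, m.weights):
            rows.append((m.feature_id, v, w, m.model_kind, m.cv_r, m.alpha))
    return pd.DataFrame(
        rows, columns=["feature_id", "variant_id", "weight", "model_kind", "cv_r", "alpha"]
    )
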