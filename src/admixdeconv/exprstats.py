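"""Expression normalization and per-region ancestry differential expression.

Produces per-feature ancestry effect sizes (log2 scale) with standard errors,
the input to the multivariate shrinkage stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _regression as reg

FEATURE_COLUMNS = ["feature_id", "chrom", "start", "end", "strand", "length_bp"]
JUNCTION_EFFECTIVE_LENGTH = 100.0


@dataclass
class ExpressionSet:
    """Integer count matrix (features x samples) with feature annotation."""

    counts: np.ndarray
    features: pd.DataFrame
    sample_ids: list[str]
    region: str = ""

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.counts.shape != (len(self.features), len(self.sample_ids)):
            raise ValueError("counts shape does not match features x samples")
        if self.features["feature_id"].duplicated().any():
            raise ValueError("feature ids must be unique")
        if (self.features["length_bp"] <= 0).any():
            raise ValueError("length_bp must be positive")

    @property
    def library_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def tmm_factors(self, trim_m: float = 0.3, trim_a: float = 0.05) -> np.ndarray:
        """Trimmed-mean-of-M-values normalization factors (edgeR-style).

        Column sums are a poor library measure when expression differences are
        concentrated in a subset of genes; TMM computes, per sample against a
        reference sample, a precision-weighted mean of per-gene log ratios
        after trimming the most extreme ratios (``trim_m``) and abundances
        (``trim_a``).  Factors are normalized to unit geometric mean.
        """
        counts = self.counts.astype(float)
        lib = counts.sum(axis=0)
        frac = counts / lib[None, :]
        # reference: sample whose upper-quartile fraction is closest to the mean
        uq = np.array([np.quantile(frac[:, j][counts[:, j] > 0], 0.75)
                       for j in range(counts.shape[1])])
        ref = int(np.argmin(np.abs(uq - uq.mean())))
        factors = np.ones(counts.shape[1])
        pr, lr = frac[:, ref], lib[ref]
        for j in range(counts.shape[1]):
            if j == ref:
                continue
            ok = (counts[:, j] > 0) & (counts[:, ref] > 0)
            if ok.sum() < 10:
                continue
            pj = frac[ok, j]
            m = np.log2(pj / pr[ok])
            a = 0.5 * np.log2(pj * pr[ok])
            # delta-method weights for the log ratio
            w = 1.0 / ((1 - pj) / (pj * lib[j]) + (1 - pr[ok]) / (pr[ok] * lr))
            lo_m, hi_m = np.quantile(m, [trim_m, 1 - trim_m])
            lo_a, hi_a = np.quantile(a, [trim_a, 1 - trim_a])
            keep = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
            if keep.sum() >= 5:
                factors[j] = 2.0 ** (np.sum(w[keep] * m[keep]) / np.sum(w[keep]))
        factors /= np.exp(np.mean(np.log(factors)))
        return factors

    def effective_library_sizes(self) -> np.ndarray:
        """TMM-scaled library sizes used for CPM normalization."""
        return self.library_sizes * self.tmm_factors()

    def subset(self, mask) -> "ExpressionSet":
        mask = np.asarray(mask)
        return ExpressionSet(
            counts=self.counts[mask],
            features=self.features.loc[mask].reset_index(drop=True),
            sample_ids=self.sample_ids,
            region=self.region,
        )

    def log2_cpm(self, offset: float = 0.5, tmm: bool = True) -> np.ndarray:
        lib = (self.effective_library_sizes() if tmm else self.library_sizes).astype(float)
        return np.log2((self.counts + offset) / (lib + 1.0)[None, :] * 1e6)

    def to_tsv(self, path: str) -> None:
        df = pd.DataFrame(self.counts, columns=self.sample_ids)
        df.insert(0, "feature_id", self.features["feature_id"].to_numpy())
        df.to_csv(path, sep="\t", index=False)


@dataclass
class EffectMatrix:
    """Per-feature effects and standard errors across regions (mash input)."""

    beta: pd.DataFrame  # features x regions, log2 scale
    se: pd.DataFrame
    df: dict = field(default_factory=dict)  # region -> residual dof

    def __post_init__(self):
        if not self.beta.index.equals(self.se.index) or list(self.beta.columns) != list(
            self.se.columns
        ):
            raise ValueError("beta and se must be aligned")
        bad = (self.se.to_numpy() <= 0) & np.isfinite(self.beta.to_numpy())
        if bad.any():
            raise ValueError("se must be positive wherever beta is defined")

    @property
    def regions(self) -> list[str]:
        return list(self.beta.columns)

    @classmethod
    def from_regions(cls, fits: dict[str, "EffectMatrix"]) -> "EffectMatrix":
        """Outer-join single-region fits on the feature index."""
        beta = pd.concat([f.beta.iloc[:, 0].rename(r) for r, f in fits.items()], axis=1)
        se = pd.concat([f.se.iloc[:, 0].rename(r) for r, f in fits.items()], axis=1)
        df = {r: f.df[list(f.df)[0]] for r, f in fits.items()}
        return cls(beta=beta, se=se, df=df)

    def complete_cases(self) -> "EffectMatrix":
        keep = np.isfinite(self.beta.to_numpy()).all(axis=1)
        return EffectMatrix(beta=self.beta.loc[keep], se=self.se.loc[keep], df=dict(self.df))

    def write(self, prefix: str) -> None:
        self.beta.to_csv(f"{prefix}.beta.tsv", sep="\t")
        self.se.to_csv(f"{prefix}.se.tsv", sep="\t")


def effective_length(length_bp, mean_insert_size: float, junction: bool = False):
    """length - mean insert size + 1 (fixed at 100 for junction features).

    Features with effective length <= 1 are to be dropped by the caller.
    """
    if junction:
        return np.full_like(np.asarray(length_bp, float), JUNCTION_EFFECTIVE_LENGTH)
    return np.asarray(length_bp, float) - float(mean_insert_size) + 1.0


def tpm_normalize(expr: ExpressionSet, efflen) -> np.ndarray:
    """Transcripts per million given per-feature effective lengths.

    Columns sum to 1e6; an all-zero sample yields a NaN column and a warning.
    """
    efflen = np.asarray(efflen, float)
    if efflen.shape[0] != expr.counts.shape[0]:
        raise ValueError("efflen must align with features")
    rate = expr.counts / efflen[:, None]
    denom = rate.sum(axis=0)
    if np.any(denom == 0):
        warnings.warn("all-zero sample column(s); TPM undefined there")
    with np.errstate(invalid="ignore", divide="ignore"):
        return 1e6 * rate / denom[None, :]


def filter_low_expression(
    expr: ExpressionSet,
    tpm: np.ndarray,
    min_tpm: float = 0.1,
    min_frac: float = 0.2,
    min_count: int = 6,
) -> ExpressionSet:
    """Keep features expressed above TPM and raw-count floors in enough samples."""
    n = expr.counts.shape[1]
    ok_tpm = (tpm > min_tpm).sum(axis=1) >= min_frac * n
    ok_count = (expr.counts >= min_count).sum(axis=1) >= min_frac * n
    keep = ok_tpm & ok_count
    if not keep.any():
        raise ValueError(
            f"no features pass the expression filter (TPM > {min_tpm} and count >= "
            f"{min_count} in >= {min_frac:.0%} of samples)"
        )
    return expr.subset(keep)


def _covariate_matrix(covariates: pd.DataFrame | np.ndarray | None, n: int):
    if covariates is None:
        return np.empty((n, 0)), []
    if isinstance(covariates, pd.DataFrame):
        cols = [c for c in covariates.columns if c != "sample_id"]
        return covariates[cols].to_numpy(float), cols
    arr = np.asarray(covariates, float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr, [f"cov{i}" for i in range(arr.shape[1])]


def fit_ancestry_de(
    expr: ExpressionSet,
    ancestry,
    covariates: pd.DataFrame | np.ndarray | None = None,
) -> EffectMatrix:
    """Per-feature OLS of log2-CPM on ancestry plus covariates (one region).

    ``ancestry`` is either a per-sample vector (global ancestry) or a
    per-feature x per-sample matrix (local-ancestry scores), in which case
    each feature is regressed on its own local score.  Samples with missing
    ancestry are dropped listwise.
    """
    y = expr.log2_cpm()
    n = len(expr.sample_ids)
    C, names = _covariate_matrix(covariates, n)
    anc = np.asarray(ancestry, float)

    if anc.ndim == 1:
        keep = np.isfinite(anc)
        X = np.column_stack([np.ones(keep.sum()), anc[keep], C[keep]])
        fit = reg.ols(X, y[:, keep].T, names=["intercept", "ancestry"] + names)
        beta, se, dof = fit.coef[1], fit.se[1], fit.df
    else:
        if anc.shape != y.shape:
            raise ValueError("local-ancestry matrix must be features x samples")
        beta = np.full(y.shape[0], np.nan)
        se = np.full(y.shape[0], np.nan)
        dof = n - (2 + C.shape[1])
        for i in range(y.shape[0]):
            keep = np.isfinite(anc[i])
            if keep.sum() <= 2 + C.shape[1] or np.std(anc[i, keep]) == 0:
                continue
            X = np.column_stack([np.ones(keep.sum()), anc[i, keep], C[keep]])
            f = reg.ols(X, y[i, keep], names=["intercept", "ancestry"] + names)
            beta[i], se[i] = f.coef[1, 0], f.se[1, 0]

    idx = pd.Index(expr.features["feature_id"], name="feature_id")
    region = expr.region or "region"
    return EffectMatrix(
        beta=pd.DataFrame({region: beta}, index=idx),
        se=pd.DataFrame({region: np.where(np.isfinite(beta), se, np.nan)}, index=idx),
        df={region: dof},
    )


def residualize(
    expr: ExpressionSet,
    covariates_null: pd.DataFrame | np.ndarray | None,
    scale: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Covariate-residualized log2-CPM, per-feature z-scored by default.

    The null model must exclude ancestry.  Returns ``(matrix, kept_mask)``;
    zero-variance features are dropped with a warning.  ``scale=False`` skips
    the z-scoring (used when imputing expression from genotypes, where the
    effect scale must be preserved).
    """
    y = expr.log2_cpm()
    C, _ = _covariate_matrix(covariates_null, len(expr.sample_ids))
    X = np.column_stack([np.ones(y.shape[1]), C])
    resid = reg.residualize(X, y.T).T
    if not scale:
        return resid, np.ones(resid.shape[0], bool)
    Z, keep = reg.zscore_rows(resid)
    if not keep.all():
        warnings.warn(f"{(~keep).sum()} zero-variance features dropped")
    return Z, keep
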