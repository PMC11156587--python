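"""Empirical-Bayes multivariate adaptive shrinkage across conditions.

Observed effects beta_j (one R-vector per feature, here R brain regions) with
standard errors se_j are modelled as

    beta_j | b_j ~ N(b_j, S_j),   S_j = diag(se_j) V diag(se_j)
    b_j ~ pi_0 delta_0 + sum_{k,l} pi_{kl} N(0, omega_l U_k)

where V is the correlation of measurement errors across conditions, the U_k
are canonical and data-driven covariance patterns and the omega_l a scale
grid.  Mixture weights are learned by EM (with a Dirichlet penalty on the
null), after which per-feature posterior means, standard deviations and the
local false sign rate (LFSR) follow from standard multivariate-normal
conjugacy.  The LFSR of effect r is min{P(b_r <= 0 | data), P(b_r >= 0 |
data)} with any point mass at zero counted in both tails.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp
from statsmodels.stats.multitest import multipletests

from .exprstats import EffectMatrix

logger = logging.getLogger(__name__)

_POINT_MASS_TOL = 1e-12


@dataclass
class CovarianceDictionary:
    """Labelled R x R PSD pattern matrices plus a positive scale grid."""

    labels: list[str]
    matrices: list[np.ndarray]
    grid: np.ndarray

    def __post_init__(self):
        self.grid = np.asarray(self.grid, float)
        if np.any(self.grid <= 0) or np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be positive and strictly increasing")
        for lab, U in zip(self.labels, self.matrices):
            U = np.asarray(U, float)
            if not np.allclose(U, U.T, atol=1e-10):
                raise ValueError(f"covariance '{lab}' is not symmetric")
            if np.linalg.eigvalsh(U).min() < -1e-8:
                raise ValueError(f"covariance '{lab}' is not PSD")

    @property
    def n_components(self) -> int:
        """Number of mixture components excluding the null."""
        return len(self.matrices) * len(self.grid)

    def component_labels(self) -> list[str]:
        return ["null"] + [
            f"{lab}@{w:.4g}" for lab in self.labels for w in self.grid
        ]

    def component_matrices(self):
        """Yield the scaled prior covariance of every non-null component."""
        for U in self.matrices:
            for w in self.grid:
                yield w * np.asarray(U, float)


@dataclass
class MashFit:
    pi: np.ndarray  # over [null] + dictionary components
    dictionary: CovarianceDictionary
    V: np.ndarray
    loglik_trace: np.ndarray
    converged: bool = True

    def __post_init__(self):
        if np.any(self.pi < -1e-12) or abs(self.pi.sum() - 1.0) > 1e-8:
            raise ValueError("pi must be a probability vector")


@dataclass
class MashPosterior:
    post_mean: pd.DataFrame
    post_sd: pd.DataFrame
    lfsr: pd.DataFrame

    def __post_init__(self):
        lf = self.lfsr.to_numpy()
        if np.any((lf < -1e-9) | (lf > 1 + 1e-9)):
            raise ValueError("lfsr must lie in [0, 1]")
        if np.any(self.post_sd.to_numpy() < -1e-12):
            raise ValueError("post_sd must be non-negative")

    def write(self, prefix: str) -> None:
        self.post_mean.to_csv(f"{prefix}.post_mean.tsv", sep="\t")
        self.post_sd.to_csv(f"{prefix}.post_sd.tsv", sep="\t")
        self.lfsr.to_csv(f"{prefix}.lfsr.tsv", sep="\t")


# ----------------------------------------------------------------- helpers
def _as_arrays(effects: EffectMatrix):
    eff = effects.complete_cases()
    return (
        eff.beta.to_numpy(float),
        eff.se.to_numpy(float),
        eff.beta.index,
        list(eff.beta.columns),
    )


def estimate_null_correlation(effects: EffectMatrix, z_thresh: float = 2.0) -> np.ndarray:
    """Error correlation across conditions from null-looking features.

    Correlation of z = beta/se over features whose max |z| < ``z_thresh``;
    identity (with a warning) when fewer than R+1 such features exist.
    """
    beta, se, _, regions = _as_arrays(effects)
    R = len(regions)
    z = beta / se
    nullish = np.max(np.abs(z), axis=1) < z_thresh
    if nullish.sum() < R + 1:
        warnings.warn("too few null-like features; returning identity null correlation")
        return np.eye(R)
    V = np.corrcoef(z[nullish].T)
    V = (V + V.T) / 2.0
    np.fill_diagonal(V, 1.0)
    return V


def strong_subset(effects: EffectMatrix, fdr: float = 0.05) -> np.ndarray:
    """Condition-by-condition strong set: BH FDR < ``fdr`` in >= 1 region.

    Per-region two-sided normal p-values from beta/se stand in for a
    condition-by-condition analysis; returns a boolean mask over the
    complete-case features.
    """
    beta, se, _, _ = _as_arrays(effects)
    p = 2.0 * stats.norm.sf(np.abs(beta / se))
    sig = np.zeros(beta.shape, bool)
    for r in range(p.shape[1]):
        sig[:, r] = multipletests(p[:, r], alpha=fdr, method="fdr_bh")[0]
    return sig.any(axis=1)


def build_covariances(
    effects_strong: EffectMatrix | np.ndarray,
    n_pcs: int = 4,
    se_all: np.ndarray | None = None,
    beta_all: np.ndarray | None = None,
) -> CovarianceDictionary:
    """Canonical plus data-driven covariance patterns and the scale grid.

    Canonical: identity, per-condition singletons, equal effects, and
    heterogeneous equicorrelated patterns at rho in {0.25, 0.5, 0.75}.
    Data-driven: rank-1 patterns from the top principal components of the
    strong-set z-scores plus their rank-``n_pcs`` reconstruction.  Every
    pattern is normalized to unit maximum diagonal.  The grid is geometric
    with ratio sqrt(2) spanning (min se)^2/100 to 4 max(beta^2).
    """
    if isinstance(effects_strong, EffectMatrix):
        beta_s, se_s, _, _ = _as_arrays(effects_strong)
        z = beta_s / se_s
        if se_all is None:
            se_all = se_s
        if beta_all is None:
            beta_all = beta_s
    else:
        z = np.asarray(effects_strong, float)
        if se_all is None or beta_all is None:
            raise ValueError("se_all and beta_all are required with a raw z matrix")
    R = z.shape[1]

    labels, mats = ["identity"], [np.eye(R)]
    if R > 1:
        for r in range(R):
            e = np.zeros((R, R))
            e[r, r] = 1.0
            labels.append(f"singleton_{r + 1}")
            mats.append(e)
        labels.append("equal_effects")
        mats.append(np.ones((R, R)))
        for rho in (0.25, 0.5, 0.75):
            labels.append(f"het_{rho}")
            mats.append(np.full((R, R), rho) + (1 - rho) * np.eye(R))

    n_strong = z.shape[0]
    if n_strong > 0:
        k = min(n_pcs, n_strong, R)
        if k < n_pcs:
            warnings.warn(f"strong set supports only {k} PCs (requested {n_pcs})")
        if k > 0:
            # uncentered PCA of the strong z-scores
            evals, evecs = np.linalg.eigh(z.T @ z / n_strong)
            order = np.argsort(evals)[::-1]
            evals, evecs = evals[order], evecs[:, order]
            recon = np.zeros((R, R))
            for p in range(k):
                U = evals[p] * np.outer(evecs[:, p], evecs[:, p])
                labels.append(f"pca_{p + 1}")
                mats.append(U)
                recon += U
            labels.append(f"rank_{k}")
            mats.append(recon)

    normed = []
    for U in mats:
        m = np.max(np.diag(U))
        normed.append(U / m if m > 0 else U)

    lo = float(np.min(se_all[np.isfinite(se_all)]) ** 2) / 100.0
    hi = 4.0 * float(np.max(beta_all[np.isfinite(beta_all)] ** 2))
    hi = max(hi, lo * 2.0)
    n_grid = int(np.ceil(np.log(hi / lo) / np.log(np.sqrt(2.0)))) + 1
    grid = lo * np.sqrt(2.0) ** np.arange(n_grid)
    return CovarianceDictionary(labels=labels, matrices=normed, grid=grid)


def _component_logliks(beta, se, V, dictionary: CovarianceDictionary) -> np.ndarray:
    """Log N(beta_j; 0, S_j + U_m) for every feature x component (null first)."""
    n, R = beta.shape
    S = se[:, :, None] * V[None, :, :] * se[:, None, :]
    comps = [np.zeros((R, R))] + list(dictionary.component_matrices())
    L = np.empty((n, len(comps)))
    for m, U in enumerate(comps):
        sigma = S + U[None, :, :]
        chol = np.linalg.cholesky(sigma)
        # solve L x = beta for each feature
        x = np.linalg.solve(chol, beta[:, :, None])[:, :, 0]
        quad = np.einsum("ij,ij->i", x, x)
        logdet = 2.0 * np.log(np.diagonal(chol, axis1=1, axis2=2)).sum(axis=1)
        L[:, m] = -0.5 * (quad + logdet + R * np.log(2.0 * np.pi))
    if not np.all(np.isfinite(L)):
        bad = np.where(~np.isfinite(L).all(axis=1))[0]
        raise FloatingPointError(f"non-finite likelihood for features {bad[:10].tolist()}")
    return L


def fit_mixture_em(
    effects: EffectMatrix,
    dictionary: CovarianceDictionary,
    V: np.ndarray,
    random_subset_frac: float | None = None,
    null_penalty: float = 10.0,
    max_iter: int = 500,
    tol: float = 1e-6,
    seed: int = 0,
) -> MashFit:
    """EM for the mixture weights pi over (pattern, scale) pairs plus null.

    The component likelihood matrix is fixed, so EM only re-estimates pi.
    ``null_penalty`` adds (penalty - 1) Dirichlet prior counts to the null
    weight; the penalized log-likelihood trace is non-decreasing.  With
    ``random_subset_frac`` set, the weights are learned on a random feature
    subset (the two-pass scheme for large effect tables).
    """
    beta, se, _, _ = _as_arrays(effects)
    if random_subset_frac is not None and random_subset_frac < 1.0:
        rng = np.random.default_rng(seed)
        take = max(int(np.ceil(random_subset_frac * beta.shape[0])), 2)
        idx = rng.choice(beta.shape[0], size=take, replace=False)
        beta, se = beta[idx], se[idx]

    L = _component_logliks(beta, se, V, dictionary)
    n, M = L.shape
    prior_extra = np.zeros(M)
    prior_extra[0] = max(null_penalty - 1.0, 0.0)

    # factor out the per-feature max log-likelihood once; EM then only needs
    # matrix-vector products with the exponentiated, rescaled matrix
    shift = L.max(axis=1)
    B = np.exp(L - shift[:, None])

    pi = np.full(M, 1.0 / M)
    trace = []
    converged = False
    for _ in range(max_iter):
        denom = B @ pi  # proportional to the per-feature marginal likelihood
        ll = np.log(denom).sum() + shift.sum() + prior_extra[0] * np.log(
            max(pi[0], 1e-300)
        )
        trace.append(ll)
        if len(trace) > 1 and trace[-1] - trace[-2] < tol:
            converged = True
            break
        # responsibilities summed over features: pi_m * sum_j B_jm / denom_j
        gamma_sum = pi * (B.T @ (1.0 / denom))
        pi = (gamma_sum + prior_extra) / (n + prior_extra.sum())
    if not converged:
        warnings.warn(f"EM did not converge in {max_iter} iterations")
    return MashFit(
        pi=pi, dictionary=dictionary, V=np.asarray(V, float),
        loglik_trace=np.asarray(trace), converged=converged,
    )


def posterior_summaries(
    effects: EffectMatrix, fit: MashFit, chunk_size: int = 2000
) -> MashPosterior:
    """Posterior means, SDs and LFSR for every feature under the fitted prior.

    Per component, the posterior of the true effect is
    N(U(U+S)^-1 beta, U - U(U+S)^-1 U); the null contributes a point mass at
    zero which is counted in both LFSR tails.
    """
    beta, se, index, regions = _as_arrays(effects)
    n, R = beta.shape
    comps = [None] + list(fit.dictionary.component_matrices())
    with np.errstate(divide="ignore"):
        logpi = np.where(fit.pi > 0, np.log(np.maximum(fit.pi, 1e-300)), -np.inf)

    post_mean = np.zeros((n, R))
    post_m2 = np.zeros((n, R))
    p_nonpos = np.zeros((n, R))  # P(b_r <= 0 | data)
    p_nonneg = np.zeros((n, R))

    for start in range(0, n, chunk_size):
        sl = slice(start, min(start + chunk_size, n))
        b, s = beta[sl], se[sl]
        L = _component_logliks(b, s, fit.V, fit.dictionary)
        joint = L + logpi[None, :]
        gamma = np.exp(joint - logsumexp(joint, axis=1)[:, None])
        S = s[:, :, None] * fit.V[None, :, :] * s[:, None, :]
        for m, U in enumerate(comps):
            g = gamma[:, m]
            if m == 0:
                p_nonpos[sl] += g[:, None]
                p_nonneg[sl] += g[:, None]
                continue
            sigma = S + U[None, :, :]
            try:
                solved = np.linalg.solve(sigma, np.broadcast_to(U, sigma.shape))
            except np.linalg.LinAlgError:
                logger.info("singular U + S encountered; adding 1e-10 ridge")
                sigma = sigma + 1e-10 * np.eye(R)[None, :, :]
                solved = np.linalg.solve(sigma, np.broadcast_to(U, sigma.shape))
            mu = np.einsum("nrk,nk->nr", np.swapaxes(solved, 1, 2), b)
            cov_diag = np.maximum(np.diag(U)[None, :] - np.einsum(
                "rk,nkr->nr", U, solved), 0.0)
            sd = np.sqrt(cov_diag)
            post_mean[sl] += g[:, None] * mu
            post_m2[sl] += g[:, None] * (cov_diag + mu**2)
            pointmass = sd <= _POINT_MASS_TOL
            with np.errstate(divide="ignore", invalid="ignore"):
                zneg = stats.norm.cdf(-mu / np.where(pointmass, 1.0, sd))
            cdf_le = np.where(pointmass, (mu <= _POINT_MASS_TOL).astype(float), zneg)
            cdf_ge = np.where(pointmass, (mu >= -_POINT_MASS_TOL).astype(float), 1.0 - zneg)
            p_nonpos[sl] += g[:, None] * cdf_le
            p_nonneg[sl] += g[:, None] * cdf_ge

    post_sd = np.sqrt(np.maximum(post_m2 - post_mean**2, 0.0))
    lfsr = np.clip(np.minimum(p_nonpos, p_nonneg), 0.0, 1.0)
    return MashPosterior(
        post_mean=pd.DataFrame(post_mean, index=index, columns=regions),
        post_sd=pd.DataFrame(post_sd, index=index, columns=regions),
        lfsr=pd.DataFrame(lfsr, index=index, columns=regions),
    )


def significant_features(posterior: MashPosterior, lfsr_cut: float = 0.05) -> dict:
    """Features with LFSR below the cut, per region plus their union."""
    out = {}
    union = set()
    for r in posterior.lfsr.columns:
        sig = set(posterior.lfsr.index[posterior.lfsr[r] < lfsr_cut])
        out[r] = sig
        union |= sig
    out["union"] = union
    return out


def run_mash(
    effects: EffectMatrix,
    n_pcs: int = 4,
    z_thresh: float = 2.0,
    strong_fdr: float = 0.05,
    random_subset_frac: float | None = None,
    null_penalty: float = 10.0,
    max_iter: int = 3000,
    seed: int = 0,
) -> tuple[MashFit, MashPosterior]:
    """Null correlation -> strong set -> dictionary -> EM -> posteriors."""
    eff = effects.complete_cases()
    V = estimate_null_correlation(eff, z_thresh=z_thresh)
    beta, se, _, _ = _as_arrays(eff)
    strong = strong_subset(eff, fdr=strong_fdr)
    if strong.sum() == 0:
        warnings.warn("empty strong set; dictionary uses canonical patterns only")
        z_strong = np.empty((0, beta.shape[1]))
    else:
        z_strong = (beta / se)[strong]
    dictionary = build_covariances(z_strong, se_all=se, beta_all=beta)
    fit = fit_mixture_em(
        eff, dictionary, V, random_subset_frac=random_subset_frac,
        null_penalty=null_penalty, max_iter=max_iter, seed=seed,
    )
    return fit, posterior_summaries(eff, fit)
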