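"""cis-eQTL mapping: nominal main-effect and ancestry-interaction scans,
fixed-count permutation top associations, Storey q-values and allele
frequency differences."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import _regression as reg
from .genotypes import GenotypeMatrix
from .simgen import AncestralPanel


def _tss(features: pd.DataFrame) -> np.ndarray:
    start = features["start"].to_numpy()
    end = features["end"].to_numpy()
    strand = features["strand"].to_numpy() if "strand" in features else np.repeat("+", len(start))
    return np.where(strand == "-", end, start)


def map_cis_nominal(
    expr_resid: np.ndarray,
    features: pd.DataFrame,
    genotypes: GenotypeMatrix,
    covariates=None,
    window_kb: float = 500.0,
    maf_min: float = 0.01,
    mode: str = "main",
    ancestry=None,
) -> pd.DataFrame:
    """Nominal association of every variant-feature pair within the window.

    main mode: expr ~ dosage + covariates (dosage term reported).
    interaction mode: expr ~ dosage + theta + dosage*theta + covariates
    (product term reported); requires ``ancestry`` and uses an MAF floor of
    0.05 by default per the interaction contract.
    """
    if mode not in ("main", "interaction"):
        raise ValueError("mode must be 'main' or 'interaction'")
    if mode == "interaction":
        if ancestry is None:
            raise ValueError("interaction mode requires ancestry")
        if maf_min < 0.05:
            maf_min = 0.05
    expr_resid = np.asarray(expr_resid, float)
    n = expr_resid.shape[1]
    C = np.empty((n, 0)) if covariates is None else np.asarray(covariates, float)
    if C.ndim == 1:
        C = C[:, None]
    w = int(window_kb * 1000)
    tss = _tss(features)
    maf = genotypes.maf()
    chroms = np.asarray(genotypes.chrom)

    rows = []
    for i, fid in enumerate(features["feature_id"]):
        idx = genotypes.window(features["chrom"].iloc[i], int(tss[i]) - w, int(tss[i]) + w)
        idx = idx[maf[idx] >= maf_min]
        y = expr_resid[i]
        for j in idx:
            g = genotypes.dosage[j]
            if np.std(g) == 0:
                continue  # monomorphic
            if mode == "main":
                X = np.column_stack([np.ones(n), g, C])
                term = 1
                names = ["intercept", "dosage"] + [f"c{k}" for k in range(C.shape[1])]
            else:
                th = np.asarray(ancestry, float)
                X = np.column_stack([np.ones(n), g, th, g * th, C])
                term = 3
                names = ["intercept", "dosage", "ancestry", "dosage:ancestry"] + [
                    f"c{k}" for k in range(C.shape[1])
                ]
            try:
                fit = reg.ols(X, y, names=names)
            except ValueError:
                continue  # degenerate design for this variant
            t = float(fit.tstat(term)[0])
            rows.append(
                (
                    fid,
                    str(genotypes.variant_id[j]),
                    int(genotypes.pos[j] - tss[i]),
                    float(fit.coef[term, 0]),
                    float(fit.se[term, 0]),
                    t,
                    float(2 * stats.t.sf(abs(t), fit.df)),
                    float(maf[j]),
                    mode,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "feature_id", "variant_id", "distance_to_tss",
            "beta", "se", "t", "p_nominal", "maf", "mode",
        ],
    )


def permute_top_association(
    feature_id: str,
    expr_resid: np.ndarray,
    genotypes_in_window: np.ndarray,
    covariates=None,
    n_perms: int = 1000,
    seed: int = 0,
) -> dict:
    """Permutation p-value for a feature's top cis association.

    The covariate-residualized phenotype is permuted; each permutation's
    strongest |correlation| over window variants is compared with the
    observed one.  empirical_p = (1 + #{perm >= obs}) / (n_perms + 1).
    """
    rng = np.random.default_rng(seed)
    y = np.asarray(expr_resid, float)
    G = np.asarray(genotypes_in_window, float)  # variants x samples
    if G.size == 0:
        return {
            "feature_id": feature_id, "variant_id": None,
            "empirical_p": np.nan, "n_perms": n_perms,
        }
    n = y.shape[0]
    C = np.ones((n, 1)) if covariates is None else np.column_stack(
        [np.ones(n), np.asarray(covariates, float)]
    )
    yr = reg.residualize(C, y[:, None])[:, 0]
    Gr = reg.residualize(C, G.T).T
    keep = Gr.std(axis=1) > 0
    G_norm = np.zeros_like(Gr)
    G_norm[keep] = (Gr[keep] - Gr[keep].mean(axis=1, keepdims=True))
    G_norm[keep] /= np.linalg.norm(G_norm[keep], axis=1, keepdims=True)
    yc = yr - yr.mean()
    yn = np.linalg.norm(yc)
    if yn == 0:
        return {
            "feature_id": feature_id, "variant_id": None,
            "empirical_p": np.nan, "n_perms": n_perms,
        }
    obs_corr = G_norm @ (yc / yn)
    obs = np.max(np.abs(obs_corr))
    top = int(np.argmax(np.abs(obs_corr)))

    perm_idx = np.argsort(rng.random((n_perms, n)), axis=1)
    Yp = yc[perm_idx]  # n_perms x n
    Yp /= np.linalg.norm(Yp, axis=1, keepdims=True)
    perm_max = np.max(np.abs(G_norm @ Yp.T), axis=0)
    emp = (1.0 + np.sum(perm_max >= obs - 1e-12)) / (n_perms + 1.0)
    return {
        "feature_id": feature_id,
        "variant_id": top,
        "empirical_p": float(emp),
        "n_perms": n_perms,
    }


def qvalues(pvals, lam: float = 0.5, pi0: float | None = None) -> np.ndarray:
    """Storey q-values; pi0 estimated at a single lambda (clipped to 1)
    unless supplied explicitly."""
    p = np.asarray(pvals, float)
    if p.size == 0:
        return np.array([])
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    if pi0 is None:
        pi0 = min(np.mean(p > lam) / (1.0 - lam), 1.0)
        if pi0 <= 0:
            pi0 = 1.0 / m
    order = np.argsort(p)
    ranked = p[order]
    q = pi0 * m * ranked / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(q, 1.0)
    return out


def afd(freq_afr, freq_eur) -> np.ndarray:
    """Absolute allele frequency difference |AFR - EUR|."""
    return np.abs(np.asarray(freq_afr, float) - np.asarray(freq_eur, float))


def match_alleles(ref1, alt1, f1, ref2, alt2, f2):
    """Align population-2 frequencies to population-1 allele orientation.

    Returns (f2_aligned, matched_mask); a swapped ref/alt orientation flips
    the frequency to 1 - f2, anything else is unmatched.
    """
    ref1, alt1 = np.asarray(ref1), np.asarray(alt1)
    ref2, alt2 = np.asarray(ref2), np.asarray(alt2)
    f2 = np.asarray(f2, float)
    same = (ref1 == ref2) & (alt1 == alt2)
    flipped = (ref1 == alt2) & (alt1 == ref2) & ~same
    aligned = np.where(flipped, 1.0 - f2, f2)
    matched = same | flipped
    return aligned, matched


def gene_afd(
    gene_id: str, significant_eqtls: pd.DataFrame, panel: AncestralPanel
) -> tuple[float, int]:
    """Mean AFD over a gene's significant eQTL variants.

    Returns (mean_afd, n_skipped) where skipped counts eQTL variants absent
    from the panel.
    """
    vids = significant_eqtls.loc[
        significant_eqtls["feature_id"] == gene_id, "variant_id"
    ].unique()
    lookup = {v: i for i, v in enumerate(panel.variant_id)}
    idx = [lookup[v] for v in vids if v in lookup]
    skipped = len(vids) - len(idx)
    if not idx:
        return np.nan, skipped
    return float(np.mean(afd(panel.freq_afr[idx], panel.freq_eur[idx]))), skipped
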