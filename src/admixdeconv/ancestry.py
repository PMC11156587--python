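"""Ancestry-informative marker selection, global-ancestry MLE, local scores.

Global ancestry is estimated by supervised maximum likelihood: given ancestral
alt-allele frequencies p_AFR and p_EUR at unlinked markers, the dosage at each
site is modelled Binomial(2, theta*p_AFR + (1-theta)*p_EUR) and theta is
maximized over [0, 1] by golden-section search.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, hwe_pvalues_from_dosage
from .simgen import AncestralPanel

INVPHI = (np.sqrt(5.0) - 1.0) / 2.0


@dataclass
class AimThresholds:
    min_afd: float = 0.5  # |p_AFR - p_EUR| floor
    max_r2: float = 0.1  # pairwise LD ceiling within each population
    min_hwe_p: float = 0.01
    ld_window_bp: int = 1_000_000


def select_aims(
    panel: AncestralPanel,
    genotypes_ref: dict[str, GenotypeMatrix],
    thresholds: AimThresholds | None = None,
) -> list[str]:
    """Ancestry-informative markers passing divergence, LD and HWE filters.

    ``genotypes_ref`` maps population labels ('afr', 'eur') to reference
    cohorts used for the r^2 pruning (greedy, in genomic order, within a
    sliding window) and the exact Hardy-Weinberg test.
    """
    thr = thresholds or AimThresholds()
    freqs = np.column_stack([panel.freq_afr, panel.freq_eur])
    usable = np.all(np.isfinite(freqs), axis=1)
    if not usable.all():
        warnings.warn(f"{(~usable).sum()} variants skipped for missing frequencies")
    delta = np.abs(panel.freq_afr - panel.freq_eur)
    cand = usable & (delta > thr.min_afd)

    for pop, ref in genotypes_ref.items():
        if not np.array_equal(ref.variant_id, panel.variant_id):
            raise ValueError(f"reference cohort '{pop}' does not cover the panel")
        hwe = hwe_pvalues_from_dosage(ref.dosage)
        cand &= hwe > thr.min_hwe_p

    idx = np.where(cand)[0]  # panel positions are sorted within chrom
    kept: list[int] = []
    for i in idx:
        ok = True
        for j in reversed(kept):
            if (np.asarray(panel.chrom)[j] != np.asarray(panel.chrom)[i]
                    or panel.pos[i] - panel.pos[j] > thr.ld_window_bp):
                break
            for ref in genotypes_ref.values():
                gi, gj = ref.dosage[i], ref.dosage[j]
                if gi.std() == 0 or gj.std() == 0:
                    continue
                r = np.corrcoef(gi, gj)[0, 1]
                if r * r >= thr.max_r2:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            kept.append(i)
    if not kept:
        warnings.warn("no variants passed the AIM filters")
    return [str(v) for v in panel.variant_id[kept]]


def _loglik_theta(theta, dosage, p_afr, p_eur):
    q = np.clip(theta * p_afr + (1 - theta) * p_eur, 1e-12, 1 - 1e-12)
    return float(np.sum(dosage * np.log(q) + (2 - dosage) * np.log1p(-q)))


def _golden_max(fun, lo=0.0, hi=1.0, tol=1e-6):
    a, b = lo, hi
    c, d = b - INVPHI * (b - a), a + INVPHI * (b - a)
    fc, fd = fun(c), fun(d)
    while b - a > tol:
        if fc >= fd:
            b, d, fd = d, c, fc
            c = b - INVPHI * (b - a)
            fc = fun(c)
        else:
            a, c, fc = c, d, fd
            d = a + INVPHI * (b - a)
            fd = fun(d)
    x = (a + b) / 2
    return x, fun(x)


def estimate_global_ancestry(
    genotypes: GenotypeMatrix, panel: AncestralPanel, aims: list[str]
) -> pd.DataFrame:
    """Per-sample African-ancestry MLE over the supplied AIMs.

    Returns a table with columns ``sample_id, theta_hat, loglik,
    n_markers_used, unidentifiable``.  When p_AFR == p_EUR at every marker
    the likelihood is flat; theta_hat is reported as 0.5 and flagged.
    """
    if len(aims) == 0:
        raise ValueError("aims must be non-empty")
    panel_idx = {v: i for i, v in enumerate(panel.variant_id)}
    geno_idx = {v: i for i, v in enumerate(genotypes.variant_id)}
    pairs = [(geno_idx[a], panel_idx[a]) for a in aims if a in geno_idx and a in panel_idx]
    gi = np.array([p[0] for p in pairs])
    pi = np.array([p[1] for p in pairs])
    p_afr, p_eur = panel.freq_afr[pi], panel.freq_eur[pi]
    informative = np.abs(p_afr - p_eur) > 1e-12
    flat = not informative.any()

    rows = []
    for s, sid in enumerate(genotypes.sample_ids):
        dos = genotypes.dosage[gi, s]
        if flat:
            rows.append((sid, 0.5, _loglik_theta(0.5, dos, p_afr, p_eur), len(gi), True))
            continue
        theta, ll = _golden_max(lambda t: _loglik_theta(t, dos, p_afr, p_eur))
        # the likelihood is unimodal in theta; snap to a boundary if better
        for edge in (0.0, 1.0):
            lle = _loglik_theta(edge, dos, p_afr, p_eur)
            if lle > ll:
                theta, ll = edge, lle
        rows.append((sid, theta, ll, len(gi), False))
    return pd.DataFrame(
        rows, columns=["sample_id", "theta_hat", "loglik", "n_markers_used", "unidentifiable"]
    )


def local_ancestry_feature_score(
    tract_posteriors: np.ndarray,
    snp_chrom: np.ndarray,
    snp_pos: np.ndarray,
    features: pd.DataFrame,
    sample_ids: list[str],
    window_kb: float = 200.0,
) -> pd.DataFrame:
    """Mean African posterior over all SNPs and haplotypes near each feature.

    ``tract_posteriors`` is (n_snps x 2*n_samples); the window is the feature
    span padded by ``window_kb`` on both sides.  Features with no SNP in the
    window get NaN scores and ``flagged=True``.
    """
    w = int(window_kb * 1000)
    n = len(sample_ids)
    snp_pos = np.asarray(snp_pos)
    snp_chrom = np.asarray(snp_chrom)
    scores = np.full((len(features), n), np.nan)
    flagged = np.zeros(len(features), bool)
    per_sample = 0.5 * (tract_posteriors[:, 0::2] + tract_posteriors[:, 1::2])
    for i, row in enumerate(features.itertuples(index=False)):
        in_win = (snp_chrom == row.chrom) & (snp_pos >= row.start - w) & (snp_pos <= row.end + w)
        if not in_win.any():
            flagged[i] = True
            continue
        scores[i] = per_sample[in_win].mean(axis=0)
    out = pd.DataFrame(scores, columns=sample_ids)
    out.insert(0, "feature_id", features["feature_id"].to_numpy())
    out["flagged"] = flagged
    return out
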