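"""Variably methylated regions and the P_ST / delta-P_ST statistics.

WGBS CpG counts are coverage-filtered and locally smoothed; CpGs whose
methylation stays variable after removing global ancestry and the top
principal components are grouped into variably methylated regions (VMRs).
P_ST is the partial coefficient of determination of ancestry in a gene's
expression model; recomputing it with residualized VMR methylation in the
model and taking the relative drop (delta-P_ST) quantifies the share of the
ancestry association attributable to the methylation-tracked environment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _regression as reg


@dataclass
class CpGTable:
    """Per-CpG methylated/total read counts (CpGs x samples), 0-based pos."""

    chrom: np.ndarray
    pos: np.ndarray
    meth: np.ndarray
    total: np.ndarray
    sample_ids: list[str]
    smoothed: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.pos = np.asarray(self.pos, int)
        self.meth = np.asarray(self.meth)
        self.total = np.asarray(self.total)
        if np.any(self.meth > self.total) or np.any(self.meth < 0):
            raise ValueError("need 0 <= meth <= total")

    @property
    def n_cpgs(self) -> int:
        return len(self.pos)

    def subset(self, mask) -> "CpGTable":
        mask = np.asarray(mask)
        return CpGTable(
            chrom=np.asarray(self.chrom)[mask],
            pos=self.pos[mask],
            meth=self.meth[mask],
            total=self.total[mask],
            sample_ids=self.sample_ids,
            smoothed=None if self.smoothed is None else self.smoothed[mask],
        )

    def raw_proportion(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.total > 0, self.meth / self.total, np.nan)

    def to_tsv(self, path: str) -> None:
        df = pd.DataFrame({"chrom": self.chrom, "start": self.pos, "end": self.pos + 1})
        prop = [
            [f"{m},{t}" for m, t in zip(self.meth[:, s], self.total[:, s])]
            for s in range(len(self.sample_ids))
        ]
        for s, sid in enumerate(self.sample_ids):
            df[sid] = prop[s]
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str) -> "CpGTable":
        df = pd.read_csv(path, sep="\t")
        samples = [c for c in df.columns if c not in ("chrom", "start", "end")]
        meth = np.empty((len(df), len(samples)), int)
        total = np.empty_like(meth)
        for s, sid in enumerate(samples):
            parts = df[sid].str.split(",", expand=True).astype(int)
            meth[:, s] = parts[0]
            total[:, s] = parts[1]
        return cls(
            chrom=df["chrom"].to_numpy(), pos=df["start"].to_numpy(),
            meth=meth, total=total, sample_ids=samples,
        )


@dataclass
class VmrSet:
    """Non-overlapping variable regions with per-sample methylation levels."""

    regions: pd.DataFrame  # chrom, start, end (0-based half-open), n_cpgs
    levels: np.ndarray  # regions x samples, sum(meth)/sum(total)
    sample_ids: list[str]
    residual_sd: np.ndarray | None = None

    def __post_init__(self):
        if (self.regions["n_cpgs"] <= 5).any():
            raise ValueError("retained VMRs must have more than five CpGs")
        starts = self.regions["start"].to_numpy()
        ends = self.regions["end"].to_numpy()
        if np.any(np.diff(starts) < 0) or np.any(starts[1:] < ends[:-1]):
            raise ValueError("regions must be sorted and non-overlapping")

    def __len__(self):
        return len(self.regions)


def coverage_filter(table: CpGTable, min_reads: int = 5, min_frac: float = 0.8) -> CpGTable:
    """Keep CpGs covered by more than ``min_reads`` reads in more than
    ``min_frac`` of samples."""
    frac = (table.total > min_reads).mean(axis=1)
    return table.subset(frac > min_frac)


def smooth_methylation(table: CpGTable, window_bp: int = 1000) -> CpGTable:
    """Triangular-weighted rolling mean of raw proportions within a window.

    A light local smoother standing in for a local-likelihood fit: each CpG's
    smoothed level is the distance-weighted mean of proportions of CpGs
    within ``window_bp``/2 on the same chromosome.
    """
    prop = table.raw_proportion()
    sm = np.empty_like(prop, dtype=float)
    half = window_bp / 2.0
    chroms = np.asarray(table.chrom)
    for c in pd.unique(chroms):
        idx = np.where(chroms == c)[0]
        pos = table.pos[idx].astype(float)
        if np.any(np.diff(pos) < 0):
            order = np.argsort(pos, kind="stable")
            idx, pos = idx[order], pos[order]
        lo = np.searchsorted(pos, pos - half, side="left")
        hi = np.searchsorted(pos, pos + half, side="right")
        P = prop[idx]
        finite = np.isfinite(P)
        P0 = np.where(finite, P, 0.0)
        for k in range(len(idx)):
            sl = slice(lo[k], hi[k])
            w = 1.0 - np.abs(pos[sl] - pos[k]) / (half + 1.0)
            denom = w @ finite[sl]
            with np.errstate(invalid="ignore"):
                sm[idx[k]] = np.where(denom > 0, (w @ P0[sl]) / denom, np.nan)
    out = table.subset(np.ones(table.n_cpgs, bool))
    out.smoothed = sm
    return out


def methylation_pcs(levels: np.ndarray, n_pcs: int = 5) -> np.ndarray:
    """Top sample-space principal components of a levels matrix (rows x samples)."""
    M = np.asarray(levels, float)
    M = M[np.isfinite(M).all(axis=1)]
    Mc = M - M.mean(axis=1, keepdims=True)
    _, _, vt = np.linalg.svd(Mc, full_matrices=False)
    return vt[: min(n_pcs, vt.shape[0])].T  # samples x k


def select_variable_cpgs(
    table: CpGTable,
    theta,
    n_pcs: int = 5,
    top_frac: float = 0.01,
    pca_frac: float = 0.05,
) -> np.ndarray:
    """Indices of the most variable CpGs after removing ancestry and PCs.

    Smoothed levels are residualized on global ancestry; PCs are computed
    from the most variable residualized CpGs (``pca_frac`` of them); all CpGs
    are then re-residualized on the top ``n_pcs`` PCs and ranked by residual
    standard deviation; the top ``top_frac`` are returned in ranked order.
    """
    if table.smoothed is None:
        raise ValueError("smooth_methylation must run first")
    theta = np.asarray(theta, float)
    X = np.column_stack([np.ones(len(theta)), theta])
    resid = reg.residualize(X, table.smoothed.T).T
    sd0 = resid.std(axis=1, ddof=1)
    n_pca = max(int(np.ceil(pca_frac * len(sd0))), min(len(sd0), 10))
    top_for_pca = np.argsort(sd0)[::-1][:n_pca]
    k = min(n_pcs, n_pca - 1, len(theta) - 2)
    if k < n_pcs:
        warnings.warn(f"reducing methylation PCs to {k}")
    if k > 0:
        pcs = methylation_pcs(resid[top_for_pca], n_pcs=k)
        X2 = np.column_stack([np.ones(len(theta)), pcs])
        resid = reg.residualize(X2, resid.T).T
    sd = resid.std(axis=1, ddof=1)
    n_top = int(np.ceil(top_frac * len(sd)))
    ranked = np.argsort(sd, kind="stable")[::-1]
    ranked = ranked[sd[ranked] > 1e-12]
    return ranked[:n_top]


def call_vmrs(
    table: CpGTable,
    selected_idx: np.ndarray,
    max_gap_bp: int = 1000,
    min_cpgs: int = 6,
) -> VmrSet:
    """Merge selected CpGs within ``max_gap_bp`` into regions; keep regions
    with at least ``min_cpgs`` CpGs.  Region level per sample is
    sum(meth)/sum(total) over the region's selected CpGs."""
    sel = np.sort(np.asarray(selected_idx, int))
    rows, levels, sds = [], [], []
    if sel.size:
        chroms = np.asarray(table.chrom)[sel]
        pos = table.pos[sel]
        group_start = 0
        boundaries = list(
            np.where((chroms[1:] != chroms[:-1]) | (np.diff(pos) > max_gap_bp))[0] + 1
        ) + [len(sel)]
        for b in boundaries:
            grp = sel[group_start:b]
            group_start = b
            if len(grp) < min_cpgs:
                continue
            meth = table.meth[grp].sum(axis=0)
            total = table.total[grp].sum(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                lev = np.where(total > 0, meth / total, np.nan)
            rows.append(
                (
                    str(np.asarray(table.chrom)[grp[0]]),
                    int(table.pos[grp[0]]),
                    int(table.pos[grp[-1]]) + 1,
                    len(grp),
                )
            )
            levels.append(lev)
            sds.append(np.nanstd(lev, ddof=1))
    regions = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_cpgs"])
    lev = (np.asarray(levels, float) if rows
           else np.zeros((0, len(table.sample_ids))))
    return VmrSet(
        regions=regions,
        levels=lev,
        sample_ids=list(table.sample_ids),
        residual_sd=np.asarray(sds),
    )


def fit_dmr(
    vmrs: VmrSet, ancestry, age, sex, meth_pcs=None
) -> pd.DataFrame:
    """Ancestry association per VMR: OLS with age, sex, methylation PCs; BH FDR."""
    from statsmodels.stats.multitest import multipletests

    n = len(vmrs.sample_ids)
    cols = [np.ones(n), np.asarray(ancestry, float), np.asarray(age, float),
            np.asarray(sex, float)]
    names = ["intercept", "ancestry", "age", "sex"]
    if meth_pcs is not None:
        pcs = np.asarray(meth_pcs, float)
        cols.append(pcs)
        names += [f"pc{i + 1}" for i in range(pcs.shape[1])]
    X = np.column_stack(cols)
    fit = reg.ols(X, vmrs.levels.T, names=names)
    p = fit.pvalue(1)
    out = vmrs.regions.copy()
    out["beta"] = fit.coef[1]
    out["se"] = fit.se[1]
    out["p"] = p
    out["fdr"] = multipletests(p, method="fdr_bh")[1] if len(p) else p
    return out


def annotate_vmrs_to_genes(
    vmrs: VmrSet, features: pd.DataFrame, promoter_pad_bp: int = 5000
) -> dict[str, list[int]]:
    """Map feature_id -> indices of VMRs overlapping the gene body +/- pad."""
    out: dict[str, list[int]] = {}
    vchrom = vmrs.regions["chrom"].to_numpy()
    vstart = vmrs.regions["start"].to_numpy()
    vend = vmrs.regions["end"].to_numpy()
    for row in features.itertuples(index=False):
        lo, hi = row.start - promoter_pad_bp, row.end + promoter_pad_bp
        hit = np.where((vchrom == row.chrom) & (vend > lo) & (vstart < hi))[0]
        if hit.size:
            out[row.feature_id] = hit.tolist()
    return out


def residualize_vmr_levels(
    vmrs: VmrSet, local_ancestry, age, sex, meth_pcs=None
) -> np.ndarray:
    """VMR levels with known biology (local ancestry, age, sex) and the top
    methylation PCs regressed out; rows align with vmrs.regions."""
    n = len(vmrs.sample_ids)
    la = np.asarray(local_ancestry, float)
    cols = [np.ones(n), np.asarray(age, float), np.asarray(sex, float)]
    if meth_pcs is not None:
        cols.append(np.asarray(meth_pcs, float))
    base = np.column_stack(cols)
    out = np.empty_like(vmrs.levels, dtype=float)
    for i in range(len(vmrs)):
        la_i = la[i] if la.ndim == 2 else la
        if np.all(np.isfinite(la_i)):
            X = np.column_stack([base, la_i])
        else:  # no local-ancestry call for this region
            X = base
        out[i] = reg.residualize(X, vmrs.levels[i][:, None])[:, 0]
    return out


def partial_r2_from_sse(sse_reduced: float, sse_full: float) -> float:
    """Partial coefficient of determination from the two model SSEs."""
    if sse_reduced <= 0:
        raise ValueError("SSE(reduced) must be positive")
    return (sse_reduced - sse_full) / sse_reduced


def pst(gene_expr, theta, covariates=None, vmr_covariates=None) -> float:
    """Partial R^2 of ancestry: (SSE(reduced) - SSE(full)) / SSE(reduced).

    The reduced model drops ancestry; with ``vmr_covariates`` (residualized
    VMR levels, one column per VMR) both models include them.
    """
    y = np.asarray(gene_expr, float)
    theta = np.asarray(theta, float)
    n = y.shape[0]
    cols = [np.ones(n)]
    if covariates is not None:
        C = np.asarray(covariates, float)
        cols.append(C[:, None] if C.ndim == 1 else C)
    if vmr_covariates is not None:
        M = np.asarray(vmr_covariates, float)
        cols.append(M[:, None] if M.ndim == 1 else M)
    base = np.column_stack(cols)
    full = np.column_stack([base, theta])
    sse_reduced = float(np.sum(reg.residualize(base, y[:, None]) ** 2))
    sse_full = float(np.sum(reg.residualize(full, y[:, None]) ** 2))
    if sse_reduced <= 0:
        raise ValueError("SSE(reduced) is zero; partial R^2 undefined")
    return max(partial_r2_from_sse(sse_reduced, sse_full), 0.0)


def delta_pst(pst_value: float, pst_vmr: float) -> float:
    """(P_ST - P_ST_VMR) / P_ST; negative when VMR adjustment increases the
    ancestry share (reported as-is)."""
    if pst_value <= 0:
        raise ValueError("pst must be positive for delta_pst")
    return (pst_value - pst_vmr) / pst_value
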