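"""Cross-region sharing, enrichment, Monte-Carlo overlap, cell-type
specificity markers and AFD distribution comparisons."""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .mashlite import MashPosterior, significant_features


@dataclass
class SharingSummary:
    sign_match: pd.DataFrame  # region-pair proportions, unit diagonal
    magnitude_share: pd.DataFrame
    overlap_counts: dict  # k-way counts: {1: unique, 2: ..., R: shared in all}


def pairwise_sharing(
    posterior: MashPosterior, lfsr_cut: float = 0.05, factor: float = 0.5
) -> SharingSummary:
    """Sharing proportions among features significant in either region of a pair.

    sign_match: same effect sign; magnitude_share: same sign AND effect ratio
    within [factor, 1/factor].
    """
    regions = list(posterior.lfsr.columns)
    if len(regions) < 2:
        raise ValueError("need at least two regions")
    lfsr = posterior.lfsr.to_numpy()
    pm = posterior.post_mean.to_numpy()
    R = len(regions)
    sign = np.full((R, R), 1.0)
    mag = np.full((R, R), 1.0)
    for i, j in itertools.combinations(range(R), 2):
        either = (lfsr[:, i] < lfsr_cut) | (lfsr[:, j] < lfsr_cut)
        if not either.any():
            warnings.warn(f"no significant features for pair {regions[i]}/{regions[j]}")
            sign[i, j] = sign[j, i] = np.nan
            mag[i, j] = mag[j, i] = np.nan
            continue
        a, b = pm[either, i], pm[either, j]
        same = np.sign(a) == np.sign(b)
        sign[i, j] = sign[j, i] = same.mean()
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.abs(a) / np.abs(b)
        within = same & (ratio >= factor) & (ratio <= 1.0 / factor)
        mag[i, j] = mag[j, i] = within.mean()

    sig = significant_features(posterior, lfsr_cut)
    per_region = [sig[r] for r in regions]
    union = sig["union"]
    counts = {}
    n_regions_of = {f: sum(f in s for s in per_region) for f in union}
    for k in range(1, R + 1):
        counts[k] = sum(1 for v in n_regions_of.values() if v == k)
    return SharingSummary(
        sign_match=pd.DataFrame(sign, index=regions, columns=regions),
        magnitude_share=pd.DataFrame(mag, index=regions, columns=regions),
        overlap_counts=counts,
    )


def fisher_bh(gene_lists: dict[str, set], target: set, universe: set) -> pd.DataFrame:
    """Two-sided Fisher's exact enrichment of ``target`` in each list, BH FDR.

    Odds ratios get a Haldane 0.5 correction only when a zero cell exists
    (flagged in the output).
    """
    universe = set(universe)
    target = set(target)
    if not target <= universe:
        raise ValueError("target set must be a subset of the universe")
    rows = []
    for name, lst in gene_lists.items():
        lst = set(lst)
        if not lst <= universe:
            raise ValueError(f"list '{name}' is not a subset of the universe")
        a = len(lst & target)
        b = len(lst - target)
        c = len(target - lst)
        d = len(universe) - a - b - c
        table = np.array([[a, b], [c, d]])
        _, p = stats.fisher_exact(table, alternative="two-sided")
        zero = (table == 0).any()
        if zero:
            odds = (a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5))
        else:
            odds = a * d / (b * c)
        rows.append((name, len(universe), a, b, c, d, float(odds), float(p), bool(zero)))
    out = pd.DataFrame(
        rows,
        columns=["list_name", "universe", "a", "b", "c", "d", "odds_ratio", "p", "haldane"],
    )
    out["fdr"] = multipletests(out["p"], method="fdr_bh")[1] if len(out) else []
    return out


def monte_carlo_overlap(
    sig_sets: list[set], universe: set, n_draws: int = 100_000, seed: int = 0
) -> dict:
    """Empirical p for the observed k-way overlap of significant sets.

    Random sets of the same sizes are drawn from the universe; the k-way
    intersection size of independent uniform sets is simulated by chaining
    hypergeometric draws (|A∩B| ~ Hypergeom, then intersecting with each
    further random set), which is distributionally identical to materializing
    the sets.  empirical_p = (1 + #{draws with overlap >= observed}) /
    (n_draws + 1).
    """
    N = len(universe)
    sizes = [len(s) for s in sig_sets]
    if any(sz > N for sz in sizes):
        raise ValueError("set sizes must not exceed the universe")
    observed = len(set.intersection(*[set(s) for s in sig_sets]))
    rng = np.random.default_rng(seed)
    inter = np.full(n_draws, sizes[0], dtype=np.int64)
    for sz in sizes[1:]:
        # overlap of a uniform random size-sz set with a fixed set of size `inter`
        inter = rng.hypergeometric(inter, N - inter, sz)
    p = (1.0 + np.sum(inter >= observed)) / (n_draws + 1.0)
    return {"observed_overlap": int(observed), "empirical_p": float(p), "n_draws": n_draws}


def exact_overlap_pvalue(sizes: list[int], universe_size: int, observed: int) -> float:
    """Exact P(k-way overlap >= observed) by chained hypergeometric PMFs.

    Enumeration oracle for small universes.
    """
    N = universe_size
    dist = {sizes[0]: 1.0}
    for sz in sizes[1:]:
        new: dict[int, float] = {}
        for m, pr in dist.items():
            ks = np.arange(max(0, m + sz - N), min(m, sz) + 1)
            pk = stats.hypergeom.pmf(ks, N, m, sz)
            for k, q in zip(ks, pk):
                new[int(k)] = new.get(int(k), 0.0) + pr * float(q)
        dist = new
    return float(sum(pr for m, pr in dist.items() if m >= observed))


def specificity_markers(
    mean_expr_by_celltype: pd.DataFrame, min_tpm: float = 1.0, top_frac: float = 0.10
) -> dict[str, set]:
    """Top-decile specificity markers per cell type.

    ``mean_expr_by_celltype`` is genes x cell types (mean TPM).  Genes with
    zero expression everywhere are removed; the specificity score is each
    gene's share of its total expression; markers are the top ``top_frac`` by
    score among genes with at least ``min_tpm`` in that cell type.
    """
    M = mean_expr_by_celltype
    M = M.loc[M.sum(axis=1) > 0]
    score = M.div(M.sum(axis=1), axis=0)
    out = {}
    for ct in M.columns:
        ok = M.index[M[ct] >= min_tpm]
        ranked = score.loc[ok, ct].sort_values(ascending=False, kind="stable")
        k = int(np.ceil(top_frac * len(ranked)))
        out[ct] = set(ranked.index[:k])
    return out


def compare_afd(deg_afd, nondeg_afd, exact_max_n: int = 20) -> dict:
    """One-sided Mann-Whitney U: are DEG AFDs stochastically greater?

    Exact rank-sum for small samples, normal approximation with tie
    correction otherwise; all-tied input yields p = 0.5 flagged degenerate.
    """
    x = np.asarray(deg_afd, float)
    y = np.asarray(nondeg_afd, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    if np.all(np.concatenate([x, y]) == np.concatenate([x, y])[0]):
        return {"p": 0.5, "statistic": np.nan, "degenerate": True}
    method = "exact" if (x.size + y.size <= exact_max_n and
                         len(np.unique(np.concatenate([x, y]))) == x.size + y.size) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="greater", method=method)
    return {"p": float(res.pvalue), "statistic": float(res.statistic), "degenerate": False}
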