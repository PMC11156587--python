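"""Self-contained recovery benchmarks exercising the pipeline end to end.

Each function simulates its own inputs at documented study conditions, runs
the relevant stages, and returns the measured quantities.  They power the
reproducibility script (``scripts/acceptance.py``) and the corresponding
tests; problem sizes are chosen so the full set runs in a few minutes on one
CPU (the methods note states every size).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from . import ancestry, cis_qtl, genpred, mashlite, popshare, simgen
from . import exprstats as es
from . import methylvar as mv
from ._regression import residualize as rz


def _quiet(fn, *args, **kw):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fn(*args, **kw)


# ------------------------------------------------------------ 1: ancestry
def global_ancestry_benchmark(seed: int, n_aims: int = 1634, n_per_level: int = 200):
    """MLE accuracy on simulated AIMs at five true ancestry levels.

    AIM-like divergence (|p_AFR - p_EUR| > 0.5 at every site); genotypes are
    site-independent binomial mixtures, the estimator's own model, so the
    error measures the estimator rather than tract noise.
    """
    rng = np.random.default_rng(seed)
    panel = simgen.AncestralPanel(
        variant_id=np.array([f"aim{i:05d}" for i in range(n_aims)]),
        chrom=np.repeat("chr1", n_aims),
        pos=(np.arange(n_aims) + 1) * 1_000,
        ref=np.repeat("A", n_aims), alt=np.repeat("G", n_aims),
        freq_afr=rng.uniform(0.75, 1.0, n_aims),
        freq_eur=rng.uniform(0.0, 0.25, n_aims),
    )
    theta = np.repeat([0.0, 0.2, 0.5, 0.8, 1.0], n_per_level)
    geno = simgen.simulate_aim_genotypes(panel, theta, seed=seed + 1)
    tab = ancestry.estimate_global_ancestry(geno, panel, list(panel.variant_id))
    est = tab["theta_hat"].to_numpy()

    # independent oracle: exhaustive grid over theta at step 1e-4
    grid = np.linspace(0.0, 1.0, 10_001)
    q = np.clip(
        grid[:, None] * panel.freq_afr[None, :]
        + (1 - grid[:, None]) * panel.freq_eur[None, :],
        1e-12, 1 - 1e-12,
    )
    ll = np.log(q) @ geno.dosage + np.log1p(-q) @ (2 - geno.dosage)
    grid_best = grid[np.argmax(ll, axis=0)]
    return {
        "mae": float(np.mean(np.abs(est - theta))),
        "max_diff_vs_grid": float(np.max(np.abs(est - grid_best))),
        "n": len(theta),
    }


# ----------------------------------------------------------- 2: shrinkage
def mash_engine_benchmark(seed: int, n_features: int = 5000):
    """Posterior quadrature oracle (R=2 toy) and EM mixture-weight recovery."""
    # quadrature oracle on a two-component, hand-set-error toy
    beta = np.array([[1.3, -0.4]])
    se = np.array([[1.0, 0.7]])
    V = np.array([[1.0, 0.3], [0.3, 1.0]])
    d = mashlite.CovarianceDictionary(
        labels=["a", "b"],
        matrices=[np.array([[1.0, 0.8], [0.8, 1.0]]),
                  np.array([[0.5, 0.0], [0.0, 0.1]])],
        grid=np.array([0.5, 2.0]),
    )
    pi = np.array([0.3, 0.25, 0.15, 0.2, 0.1])
    eff = es.EffectMatrix(
        beta=pd.DataFrame(beta, index=["g"], columns=["x", "y"]),
        se=pd.DataFrame(se, index=["g"], columns=["x", "y"]),
    )
    fit = mashlite.MashFit(pi=pi, dictionary=d, V=V, loglik_trace=np.zeros(1))
    post = mashlite.posterior_summaries(eff, fit)

    gx = np.linspace(-8, 8, 401)
    B1, B2 = np.meshgrid(gx, gx, indexing="ij")
    S = np.diag(se[0]) @ V @ np.diag(se[0])
    lik = stats.multivariate_normal(mean=beta[0], cov=S)
    dens = lik.pdf([0.0, 0.0]) * pi[0]
    num = np.zeros(2)
    for w, U in zip(pi[1:], d.component_matrices()):
        pb = stats.multivariate_normal(mean=[0, 0], cov=U, allow_singular=True)
        joint = w * pb.pdf(np.dstack([B1, B2])) * lik.pdf(np.dstack([B1, B2]))
        dens += np.trapezoid(np.trapezoid(joint, gx, axis=1), gx)
        num[0] += np.trapezoid(np.trapezoid(joint * B1, gx, axis=1), gx)
        num[1] += np.trapezoid(np.trapezoid(joint * B2, gx, axis=1), gx)
    quad_err = float(np.max(np.abs(post.post_mean.to_numpy()[0] - num / dens)))

    # EM weight recovery against a 1-D grid-search oracle
    rng = np.random.default_rng(seed)
    R = 4
    U = np.full((R, R), 0.5) + 0.5 * np.eye(R)
    sig = rng.random(n_features) < 0.5
    b = np.zeros((n_features, R))
    b[sig] = rng.multivariate_normal(np.zeros(R), U, int(sig.sum()))
    beta2 = b + rng.standard_normal((n_features, R))
    eff2 = es.EffectMatrix(
        beta=pd.DataFrame(beta2, columns=list("abcd")),
        se=pd.DataFrame(np.ones_like(beta2), columns=list("abcd")),
    )
    d2 = mashlite.CovarianceDictionary(labels=["sig"], matrices=[U],
                                       grid=np.array([1.0]))
    fit2 = mashlite.fit_mixture_em(eff2, d2, np.eye(R), null_penalty=1.0,
                                   max_iter=2000)
    L = mashlite._component_logliks(beta2, np.ones_like(beta2), np.eye(R), d2)
    grid = np.linspace(0.005, 0.995, 199)
    lls = [logsumexp(L + np.log([p0, 1 - p0]), axis=1).sum() for p0 in grid]
    oracle = float(grid[int(np.argmax(lls))])
    return {
        "quadrature_max_abs_err": quad_err,
        "pi_null_vs_oracle_abs_err": float(abs(fit2.pi[0] - oracle)),
        "pi_null_vs_truth_abs_err": float(abs(fit2.pi[0] - 0.5)),
        "loglik_min_increment": float(np.min(np.diff(fit2.loglik_trace))),
        "n": n_features,
    }


# ------------------------------------------------------ 3: LFSR under null
def lfsr_null_benchmark(seed: int, n_features: int = 5000, n_regions: int = 4):
    """Fraction of LFSR < 0.05 calls when every true effect is zero."""
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_features, n_regions))
    eff = es.EffectMatrix(
        beta=pd.DataFrame(z, columns=[f"r{j}" for j in range(n_regions)]),
        se=pd.DataFrame(np.ones_like(z), columns=[f"r{j}" for j in range(n_regions)]),
    )
    _, post = _quiet(mashlite.run_mash, eff, max_iter=1500, seed=seed)
    return {
        "significant_fraction": float((post.lfsr.to_numpy() < 0.05).mean()),
        "n": n_features * n_regions,
    }


# ----------------------------------------------- 4: genetic share recovery
def genetic_fraction_benchmark(seed: int, n_features: int = 200, n_samples: int = 150):
    """Recover genetic_fraction=0.6 via elastic-net imputation + shrinkage."""
    cfg = simgen.SimConfig(n_samples=n_samples, n_features=n_features)
    panel = simgen.simulate_panel(cfg, seed)
    geno, truth = simgen.simulate_genotypes(panel, cfg, seed + 1)
    sets, covs = _quiet(simgen.simulate_expression, geno, truth, cfg)
    cmat = covs[[c for c in covs.columns if c != "sample_id"]].to_numpy(float)
    theta = truth.theta
    fits = {s.region: es.fit_ancestry_de(s, theta, cmat) for s in sets}
    eff = es.EffectMatrix.from_regions(fits)
    _, post = _quiet(mashlite.run_mash, eff, seed=seed)

    s = sets[0]
    resid, _ = es.residualize(s, cmat, scale=False)
    focal = truth.focal_idx
    w = cfg.cis_window_bp
    preds = []
    for i in focal:
        row = s.features.iloc[i]
        idx = geno.window(row["chrom"], row["start"] - w, row["end"] + w)
        model = genpred.fit_elastic_net(
            row["feature_id"], geno.dosage[idx], geno.variant_id[idx], resid[i],
            seed=seed + 100 + int(i),
        )
        preds.append(model.predict(geno.dosage[idx]) if model.weights.size
                     else np.zeros(resid.shape[1]))
    observed = post.post_mean.iloc[:, 0].to_numpy()[focal]
    ve = genpred.ancestry_effect_variance_explained(
        np.asarray(preds), theta, cmat, observed, region=s.region
    )

    # solver sanity at the same run: objective trace and ridge limit
    rng = np.random.default_rng(seed + 7)
    X = rng.standard_normal((60, 10))
    y = X @ rng.standard_normal(10) + rng.standard_normal(60)
    _, trace = genpred.enet_coordinate_descent(X, y, lam=0.05, l1_ratio=0.5,
                                               return_trace=True)
    Xr = rng.standard_normal((30, 3))
    yr = Xr @ np.array([1.0, -0.5, 0.2]) + 0.1 * rng.standard_normal(30)
    w_cd = genpred.enet_coordinate_descent(Xr, yr, lam=0.3, l1_ratio=0.0,
                                           max_sweeps=50_000, tol=1e-14)
    w_closed = np.linalg.solve(Xr.T @ Xr / 30 + 0.3 * np.eye(3), Xr.T @ yr / 30)
    return {
        "r2": float(ve.r2),
        "objective_max_increase": float(np.max(np.diff(trace))),
        "ridge_limit_max_abs_err": float(np.max(np.abs(w_cd - w_closed))),
        "n": int(ve.n_features),
    }


# ------------------------------------------- 5: environmental share recovery
def env_fraction_benchmark(seed: int, n_features: int = 150, n_samples: int = 150,
                           min_pst: float = 0.05):
    """Recover env_fraction=0.15 as the mean delta-P_ST over analyzable genes.

    Analyzable: an annotated VMR and an ancestry partial R^2 of at least
    ``min_pst`` (a ratio statistic needs its denominator away from zero).
    """
    cfg = simgen.SimConfig(n_samples=n_samples, n_features=n_features)
    panel = simgen.simulate_panel(cfg, seed)
    geno, truth = simgen.simulate_genotypes(panel, cfg, seed + 1)
    sets, covs = _quiet(simgen.simulate_expression, geno, truth, cfg)
    cpgs = _quiet(simgen.simulate_methylation, truth, cfg)
    theta = truth.theta
    cmat = covs[[c for c in covs.columns if c != "sample_id"]].to_numpy(float)
    s = sets[0]
    y = s.log2_cpm()

    table = mv.smooth_methylation(mv.coverage_filter(cpgs))
    sel = mv.select_variable_cpgs(table, theta)
    vmrs = mv.call_vmrs(table, sel)
    pcs = mv.methylation_pcs(table.smoothed)
    post = simgen.tract_posteriors(geno, truth)
    vmr_feats = pd.DataFrame(
        {
            "feature_id": [f"vmr{i}" for i in range(len(vmrs))],
            "chrom": vmrs.regions["chrom"], "start": vmrs.regions["start"],
            "end": vmrs.regions["end"],
        }
    )
    la = ancestry.local_ancestry_feature_score(
        post, geno.chrom, geno.pos, vmr_feats, geno.sample_ids
    )[geno.sample_ids].to_numpy()
    resid_vmr = mv.residualize_vmr_levels(vmrs, la, covs["age"], covs["sex"], pcs)
    gene_vmrs = mv.annotate_vmrs_to_genes(vmrs, truth.features)
    fid_to_row = {f: i for i, f in enumerate(s.features["feature_id"])}
    deltas, psts = [], []
    for fid, vidx in gene_vmrs.items():
        i = fid_to_row[fid]
        p0 = mv.pst(y[i], theta, cmat)
        if p0 <= min_pst:
            continue
        p1 = mv.pst(y[i], theta, cmat, vmr_covariates=resid_vmr[vidx].T)
        deltas.append(mv.delta_pst(p0, p1))
        psts.append(p0)

    # exact partial-R^2 arithmetic on the printed SSE pair
    arithmetic = mv.partial_r2_from_sse(10.0, 4.0)
    return {
        "mean_delta_pst": float(np.mean(deltas)),
        "pst_sse_pair_value": float(arithmetic),
        "n": len(deltas),
    }


# ----------------------------------------------------------------- 6: eQTL
def eqtl_benchmark(seed: int, n_features: int = 200, n_samples: int = 150,
                   n_null_features_perm: int = 500):
    """Closed-form OLS toy, permutation uniformity and causal-variant recovery."""
    # closed form on the printed 8-sample toy
    g = np.array([0, 1, 2, 0, 1, 2, 1, 0], float)
    yv = np.array([0.3, 1.1, 2.2, -0.2, 0.9, 2.5, 1.3, 0.1])
    feats = pd.DataFrame({"feature_id": ["g1"], "chrom": ["chr1"],
                          "start": [5000], "end": [5100], "strand": ["+"]})
    from .genotypes import GenotypeMatrix

    geno_toy = GenotypeMatrix(
        variant_id=np.array(["v0"]), chrom=np.array(["chr1"]),
        pos=np.array([5000]), ref=np.array(["A"]), alt=np.array(["G"]),
        dosage=g[None, :], sample_ids=[f"s{j}" for j in range(8)],
    )
    res = cis_qtl.map_cis_nominal(yv[None, :], feats, geno_toy)
    X = np.column_stack([np.ones(8), g])
    xtx_inv = np.linalg.inv(X.T @ X)
    bhat = xtx_inv @ X.T @ yv
    se_hat = np.sqrt((yv - X @ bhat) @ (yv - X @ bhat) / 6 * xtx_inv[1, 1])
    closed_form_err = max(
        abs(res["beta"].iloc[0] - bhat[1]), abs(res["se"].iloc[0] - se_hat)
    )

    # permutation empirical p uniform under the null
    rng = np.random.default_rng(seed)
    emp = []
    for i in range(n_null_features_perm):
        yy = rng.standard_normal(60)
        G = rng.binomial(2, rng.uniform(0.1, 0.5, 15)[:, None], (15, 60)).astype(float)
        rec = cis_qtl.permute_top_association(f"f{i}", yy, G, n_perms=300,
                                              seed=seed + i)
        emp.append(rec["empirical_p"])
    ks = stats.kstest(emp, "uniform")

    # causal variant tops the scan at h^2 = 0.3
    cfg = simgen.SimConfig(cis_h2=0.3, n_features=n_features, n_samples=n_samples)
    panel = simgen.simulate_panel(cfg, seed + 2)
    geno, truth = simgen.simulate_genotypes(panel, cfg, seed + 3)
    sets, covs = _quiet(simgen.simulate_expression, geno, truth, cfg)
    cmat = covs[[c for c in covs.columns if c != "sample_id"]].to_numpy(float)
    s = sets[0]
    resid = rz(np.column_stack([np.ones(n_samples), cmat]), s.log2_cpm().T).T
    focal = truth.focal_idx
    nominal = cis_qtl.map_cis_nominal(
        resid[focal], s.features.iloc[focal].reset_index(drop=True), geno
    )
    top = nominal.sort_values("p_nominal", kind="stable").groupby(
        "feature_id", as_index=False).first()
    causal = {s.features["feature_id"].iloc[i]: truth.causal_variant[i]
              for i in focal}
    hit_rate = float(np.mean(
        [causal[f] == v for f, v in zip(top["feature_id"], top["variant_id"])]
    ))
    return {
        "closed_form_max_abs_err": float(closed_form_err),
        "perm_uniformity_ks_p": float(ks.pvalue),
        "causal_top_hit_rate": hit_rate,
        "n": n_features,
    }


# ----------------------------------------------------------- 7: enrichment
def enrichment_benchmark(seed: int, n_tables: int = 2000):
    """Exactness of Fisher/BH and the Monte-Carlo overlap test."""
    rng = np.random.default_rng(seed)
    max_err = 0.0
    for _ in range(n_tables):
        N = int(rng.integers(8, 61))
        K = int(rng.integers(1, N))
        T = int(rng.integers(1, N))
        a = int(rng.integers(max(0, K + T - N), min(K, T) + 1))
        table = np.array([[a, K - a], [T - a, N - K - T + a]])
        _, p = stats.fisher_exact(table)
        ks = np.arange(max(0, K + T - N), min(K, T) + 1)
        pmf = stats.hypergeom.pmf(ks, N, T, K)
        exact = pmf[pmf <= pmf[ks == a][0] * (1 + 1e-9)].sum()
        max_err = max(max_err, abs(p - exact))

    from statsmodels.stats.multitest import multipletests

    bh = multipletests(np.array([0.01, 0.02, 0.03, 0.04]), method="fdr_bh")[1]
    bh_err = float(np.max(np.abs(bh - 0.04)))

    universe = set(range(20))
    sets = [set(range(8)), set(range(4, 14)), set(range(2, 9))]
    obs = len(set.intersection(*sets))
    mc = popshare.monte_carlo_overlap(sets, universe, n_draws=100_000, seed=seed)
    exact_p = popshare.exact_overlap_pvalue([8, 10, 7], 20, obs)
    return {
        "fisher_enumeration_max_abs_err": float(max_err),
        "bh_toy_max_abs_err": bh_err,
        "mc_overlap_vs_exact_abs_err": float(abs(mc["empirical_p"] - exact_p)),
        "n": n_tables,
    }


# -------------------------------------------------- 8: filters and callers
def filter_exactness_benchmark(seed: int):
    """Brute-force equality of the filters/callers plus TPM column sums."""
    rng = np.random.default_rng(seed)

    # expression filter vs enumeration
    counts = rng.integers(0, 40, (60, 25))
    lens = rng.uniform(50, 4000, 60)
    feats = pd.DataFrame(
        {"feature_id": [f"g{i}" for i in range(60)], "chrom": "chr1",
         "start": np.arange(60) * 10_000 + 1, "end": np.arange(60) * 10_000 + 900,
         "strand": "+", "length_bp": 900}
    )
    expr = es.ExpressionSet(counts=counts, features=feats,
                            sample_ids=[f"s{j}" for j in range(25)])
    tpm = es.tpm_normalize(expr, lens)
    kept = es.filter_low_expression(expr, tpm)
    n = counts.shape[1]
    brute = {
        f"g{i}" for i in range(60)
        if (tpm[i] > 0.1).sum() >= 0.2 * n and (counts[i] >= 6).sum() >= 0.2 * n
    }
    filter_mismatch = len(brute.symmetric_difference(set(kept.features["feature_id"])))
    colsum_err = float(np.max(np.abs(tpm.sum(axis=0) - 1e6) / 1e6))

    # AIM selection vs enumeration
    cfg = simgen.SimConfig(n_variants=60, chrom_length_bp=2_000_000,
                           divergence_fst=0.4)
    panel = simgen.simulate_panel(cfg, seed + 1)
    refs = {p: simgen.simulate_reference_genotypes(panel, 120, p, seed + 2 + k)
            for k, p in enumerate(("afr", "eur"))}
    got = _quiet(ancestry.select_aims, panel, refs)
    from .genotypes import hwe_pvalues_from_dosage

    ok = np.abs(panel.freq_afr - panel.freq_eur) > 0.5
    for ref in refs.values():
        ok &= hwe_pvalues_from_dosage(ref.dosage) > 0.01
    kept_idx: list[int] = []
    for i in np.where(ok)[0]:
        keep = True
        for j in kept_idx:
            if panel.pos[i] - panel.pos[j] > 1_000_000:
                continue
            for ref in refs.values():
                gi, gj = ref.dosage[i], ref.dosage[j]
                if gi.std() and gj.std() and np.corrcoef(gi, gj)[0, 1] ** 2 >= 0.1:
                    keep = False
        if keep:
            kept_idx.append(i)
    aims_mismatch = len(set(got).symmetric_difference(
        {str(panel.variant_id[i]) for i in kept_idx}))

    # VMR caller vs a hand-rolled merge
    pos = np.sort(rng.choice(300_000, 120, replace=False))
    meth = rng.integers(0, 9, (120, 6))
    total = meth + rng.integers(1, 9, (120, 6))
    table = mv.CpGTable(chrom=np.repeat("chr1", 120), pos=pos, meth=meth,
                        total=total, sample_ids=[f"s{j}" for j in range(6)])
    sel = np.sort(rng.choice(120, 70, replace=False))
    vmrs = mv.call_vmrs(table, sel)
    groups, cur = [], [sel[0]]
    for i in sel[1:]:
        if pos[i] - pos[cur[-1]] <= 1000:
            cur.append(i)
        else:
            groups.append(cur)
            cur = [i]
    groups.append(cur)
    brute_regions = [(int(pos[g[0]]), int(pos[g[-1]]) + 1, len(g))
                     for g in groups if len(g) >= 6]
    got_regions = list(zip(vmrs.regions["start"], vmrs.regions["end"],
                           vmrs.regions["n_cpgs"]))
    vmr_mismatch = len(set(brute_regions).symmetric_difference(set(got_regions)))

    return {
        "filter_enumeration_mismatches": filter_mismatch,
        "aims_enumeration_mismatches": aims_mismatch,
        "vmr_enumeration_mismatches": vmr_mismatch,
        "tpm_colsum_max_rel_err": colsum_err,
        "n": 60,
    }
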