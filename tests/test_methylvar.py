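"""Variable-CpG selection, VMR calling, DMR models and P_ST statistics."""

import numpy as np
import pandas as pd
import pytest

from admixdeconv import methylvar as mv


def _table(pos, meth, total, chrom=None):
    meth = np.asarray(meth)
    return mv.CpGTable(
        chrom=np.asarray(chrom) if chrom is not None else np.repeat("chr1", len(pos)),
        pos=np.asarray(pos),
        meth=meth,
        total=np.asarray(total),
        sample_ids=[f"s{j}" for j in range(meth.shape[1])],
    )


# --------------------------------------------------------------- coverage
def test_coverage_filter_rule():
    # keep CpGs with > 5 reads in > 80% of samples
    total = np.array([[10, 10, 10, 10, 10],   # pass
                      [10, 10, 10, 10, 5],    # 80% exactly -> fail (strict >)
                      [6, 6, 6, 6, 6]])       # 6 > 5 everywhere -> pass
    meth = np.zeros_like(total)
    kept = mv.coverage_filter(_table([1, 2, 3], meth, total))
    assert list(kept.pos) == [1, 3]


# -------------------------------------------------------------- smoothing
def test_smoothing_weighted_mean_oracle():
    pos = np.array([0, 100, 400, 5000])
    meth = np.array([[10], [0], [5], [8]])
    total = np.full((4, 1), 10)
    table = mv.smooth_methylation(_table(pos, meth, total), window_bp=1000)
    prop = meth[:, 0] / 10
    half = 500.0
    for i in range(4):
        near = np.abs(pos - pos[i]) <= half
        w = 1 - np.abs(pos[near] - pos[i]) / (half + 1)
        assert table.smoothed[i, 0] == pytest.approx((w @ prop[near]) / w.sum())
    # the isolated CpG smooths to itself
    assert table.smoothed[3, 0] == pytest.approx(0.8)


# ---------------------------------------------------------- variable CpGs
def test_select_variable_cpgs_finds_high_variance(rng):
    # shared batch structure (captured by the PCs) plus two CpGs with strong
    # idiosyncratic variability that must survive the projections
    n = 40
    theta = rng.uniform(0, 1, n)
    batch = rng.standard_normal((5, n))
    loads = rng.normal(0, 0.15, (200, 5))
    base = (rng.uniform(0.3, 0.7, (200, 1))
            + loads @ batch
            + 0.01 * rng.standard_normal((200, n)))
    base[50] += 0.3 * np.sign(rng.standard_normal(n))  # two clearly variable CpGs
    base[120] += 0.3 * np.sign(rng.standard_normal(n))
    prob = np.clip(base, 0.01, 0.99)
    total = np.full(prob.shape, 200)
    meth = np.rint(prob * 200).astype(int)
    table = _table(np.arange(200) * 2000, meth, total)
    table = mv.smooth_methylation(table)
    sel = mv.select_variable_cpgs(table, theta, top_frac=0.01)
    assert set(sel) == {50, 120}


def test_select_variable_cpgs_empty_when_constant():
    meth = np.full((50, 10), 5)
    total = np.full((50, 10), 10)
    table = mv.smooth_methylation(_table(np.arange(50) * 5000, meth, total))
    sel = mv.select_variable_cpgs(table, np.linspace(0, 1, 10))
    assert len(sel) == 0


# ------------------------------------------------------------ VMR calling
def test_isolated_cpg_yields_no_vmr():
    meth = np.ones((1, 4), int)
    total = np.full((1, 4), 10)
    vmrs = mv.call_vmrs(_table([100], meth, total), np.array([0]))
    assert len(vmrs) == 0


def test_call_vmrs_hand_traced_merge(rng):
    # 7 CpGs spaced 100 bp apart merge into one region (half-open bounds)
    pos = np.array([1000 + 100 * i for i in range(7)] + [50_000])
    meth = rng.integers(0, 5, (8, 3))
    total = meth + rng.integers(1, 5, (8, 3))
    vmrs = mv.call_vmrs(_table(pos, meth, total), np.arange(8))
    assert len(vmrs) == 1
    assert vmrs.regions.iloc[0]["start"] == 1000
    assert vmrs.regions.iloc[0]["end"] == 1601
    assert vmrs.regions.iloc[0]["n_cpgs"] == 7


def test_vmr_level_is_read_weighted():
    pos = np.arange(7) * 100 + 1
    meth = np.zeros((7, 1), int)
    total = np.full((7, 1), 10)
    meth[0, 0], meth[1, 0] = 3, 5
    total[2:, 0] = 0
    vmrs = mv.call_vmrs(_table(pos, meth, total), np.arange(7))
    assert vmrs.levels[0, 0] == pytest.approx(8 / 20)


def test_call_vmrs_idempotent_under_resorting(rng):
    pos = np.sort(rng.choice(100_000, 60, replace=False))
    meth = rng.integers(0, 8, (60, 4))
    total = meth + rng.integers(1, 8, (60, 4))
    sel = rng.choice(60, 30, replace=False)
    a = mv.call_vmrs(_table(pos, meth, total), sel)
    b = mv.call_vmrs(_table(pos, meth, total), np.sort(sel))
    assert a.regions.equals(b.regions)
    assert np.allclose(a.levels, b.levels, equal_nan=True)


def test_vmr_min_cpgs_enforced():
    with pytest.raises(ValueError, match="five"):
        mv.VmrSet(
            regions=pd.DataFrame(
                {"chrom": ["chr1"], "start": [0], "end": [100], "n_cpgs": [3]}
            ),
            levels=np.zeros((1, 2)),
            sample_ids=["a", "b"],
        )


# ------------------------------------------------------------------- DMRs
def test_fit_dmr_exact_slope(rng):
    n = 30
    local = rng.uniform(0, 1, n)
    levels = (0.3 * local)[None, :]
    regions = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [800],
                            "n_cpgs": [8]})
    vmrs = mv.VmrSet(regions=regions, levels=levels,
                     sample_ids=[f"s{j}" for j in range(n)])
    out = mv.fit_dmr(vmrs, local, age=rng.normal(50, 10, n), sex=rng.integers(0, 2, n))
    assert out["beta"].iloc[0] == pytest.approx(0.3, abs=1e-8)
    assert out["p"].iloc[0] < 1e-20


def test_fit_dmr_matches_closed_form(rng):
    n = 6
    anc = np.array([0.1, 0.4, 0.6, 0.8, 0.2, 0.9])
    age = np.array([40.0, 55, 62, 48, 51, 70])
    sex = np.array([0.0, 1, 0, 1, 1, 0])
    levels = rng.uniform(0.2, 0.8, (2, n))
    regions = pd.DataFrame({"chrom": ["chr1"] * 2, "start": [0, 2000],
                            "end": [800, 2800], "n_cpgs": [8, 8]})
    vmrs = mv.VmrSet(regions=regions, levels=levels,
                     sample_ids=[f"s{j}" for j in range(n)])
    out = mv.fit_dmr(vmrs, anc, age, sex)
    X = np.column_stack([np.ones(n), anc, age, sex])
    xtx_inv = np.linalg.inv(X.T @ X)
    for i in range(2):
        bhat = xtx_inv @ X.T @ levels[i]
        resid = levels[i] - X @ bhat
        se = np.sqrt(resid @ resid / (n - 4) * xtx_inv[1, 1])
        assert out["beta"].iloc[i] == pytest.approx(bhat[1], abs=1e-12)
        assert out["se"].iloc[i] == pytest.approx(se, abs=1e-12)


def test_fit_dmr_bh_fdr_controlled(rng):
    # pure-null VMR levels: expected share of FDR<0.05 calls stays at the level
    n, m, reps = 40, 120, 10
    hits = []
    for rep in range(reps):
        levels = rng.uniform(0.2, 0.8, (m, n))
        regions = pd.DataFrame(
            {"chrom": ["chr1"] * m, "start": np.arange(m) * 2000,
             "end": np.arange(m) * 2000 + 800, "n_cpgs": [8] * m}
        )
        vmrs = mv.VmrSet(regions=regions, levels=levels,
                         sample_ids=[f"s{j}" for j in range(n)])
        out = mv.fit_dmr(vmrs, rng.uniform(0, 1, n), rng.normal(50, 10, n),
                         rng.integers(0, 2, n))
        hits.append((out["fdr"] < 0.05).mean())
    assert np.mean(hits) <= 0.05


# ------------------------------------------------------------------- P_ST
def test_partial_r2_from_sse_arithmetic():
    assert mv.partial_r2_from_sse(10.0, 4.0) == pytest.approx(0.6)
    with pytest.raises(ValueError):
        mv.partial_r2_from_sse(0.0, 0.0)


def test_pst_equals_explicit_two_model_fit(rng):
    n = 50
    theta = rng.uniform(0, 1, n)
    C = rng.standard_normal((n, 2))
    y = 1.2 * theta + C @ [0.5, -0.3] + rng.standard_normal(n)
    got = mv.pst(y, theta, C)
    base = np.column_stack([np.ones(n), C])
    full = np.column_stack([base, theta])
    sse_r = np.sum((y - base @ np.linalg.lstsq(base, y, rcond=None)[0]) ** 2)
    sse_f = np.sum((y - full @ np.linalg.lstsq(full, y, rcond=None)[0]) ** 2)
    assert got == pytest.approx((sse_r - sse_f) / sse_r, abs=1e-12)


def test_pst_deterministic_expression_gives_one(rng):
    theta = rng.uniform(0, 1, 30)
    assert mv.pst(3.0 * theta + 1.0, theta) == pytest.approx(1.0, abs=1e-9)


def test_pst_independent_theta_near_zero(rng):
    theta = rng.uniform(0, 1, 2000)
    y = rng.standard_normal(2000)
    assert mv.pst(y, theta) < 0.01


def test_pst_affine_invariance(rng):
    theta = rng.uniform(0, 1, 40)
    C = rng.standard_normal((40, 2))
    y = theta + C @ [1.0, 2.0] + rng.standard_normal(40)
    assert mv.pst(y, theta, C) == pytest.approx(mv.pst(-3.0 * y + 11.0, theta, C),
                                                abs=1e-12)


def test_pst_orthogonal_covariate_no_change(rng):
    n = 60
    theta = rng.uniform(0, 1, n)
    y = 2 * theta + rng.standard_normal(n)
    extra = rng.standard_normal(n)
    A = np.column_stack([np.ones(n), theta, y])
    extra -= A @ np.linalg.lstsq(A, extra, rcond=None)[0]
    assert abs(mv.pst(y, theta) - mv.pst(y, theta, extra)) < 1e-10


def test_delta_pst_values():
    assert mv.delta_pst(0.5, 0.5) == 0.0
    assert mv.delta_pst(0.5, 0.4) == pytest.approx(0.2)
    assert mv.delta_pst(0.3, 0.4) < 0  # reported as-is
    with pytest.raises(ValueError):
        mv.delta_pst(0.0, 0.1)


# ------------------------------------------------------------- annotation
def test_annotate_vmrs_to_genes_overlap_rule():
    regions = pd.DataFrame(
        {"chrom": ["chr1", "chr1"], "start": [1000, 50_000],
         "end": [1800, 50_800], "n_cpgs": [8, 8]}
    )
    vmrs = mv.VmrSet(regions=regions, levels=np.zeros((2, 3)),
                     sample_ids=["a", "b", "c"])
    feats = pd.DataFrame(
        {"feature_id": ["near", "far"], "chrom": ["chr1", "chr1"],
         "start": [3000, 300_000], "end": [9000, 310_000]}
    )
    out = mv.annotate_vmrs_to_genes(vmrs, feats, promoter_pad_bp=5000)
    assert out == {"near": [0]}


def test_cpg_table_tsv_round_trip(tmp_path, rng):
    meth = rng.integers(0, 10, (6, 3))
    total = meth + rng.integers(0, 10, (6, 3))
    table = _table(np.arange(6) * 100, meth, total)
    path = str(tmp_path / "cpg.tsv")
    table.to_tsv(path)
    back = mv.CpGTable.read_tsv(path)
    assert np.array_equal(back.meth, table.meth)
    assert np.array_equal(back.total, table.total)
    assert np.array_equal(back.pos, table.pos)
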