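"""Normalization arithmetic, expression filters and the per-region DE model."""

import numpy as np
import pandas as pd
import pytest

from admixdeconv import exprstats as es
from admixdeconv._regression import ols


def _expr(counts, lengths=None, region="r1"):
    counts = np.asarray(counts)
    f = counts.shape[0]
    lengths = np.asarray(lengths) if lengths is not None else np.full(f, 1000)
    feats = pd.DataFrame(
        {
            "feature_id": [f"g{i}" for i in range(f)],
            "chrom": "chr1",
            "start": np.arange(f) * 10_000 + 1,
            "end": np.arange(f) * 10_000 + 1 + lengths,
            "strand": "+",
            "length_bp": lengths,
        }
    )
    return es.ExpressionSet(
        counts=counts, features=feats,
        sample_ids=[f"s{j}" for j in range(counts.shape[1])], region=region,
    )


# ------------------------------------------------------- effective length
@pytest.mark.parametrize(
    "length,insert,junction,expected",
    [(300, 250, False, 51.0), (100, 100, False, 1.0), (987, 250, True, 100.0)],
)
def test_effective_length_arithmetic(length, insert, junction, expected):
    out = es.effective_length(np.array([length]), insert, junction=junction)
    assert out[0] == expected


# -------------------------------------------------------------------- TPM
def test_tpm_equal_counts_equal_lengths():
    expr = _expr([[100], [100]])
    tpm = es.tpm_normalize(expr, np.array([10.0, 10.0]))
    assert np.allclose(tpm[:, 0], 5e5)


def test_tpm_worked_example():
    expr = _expr([[10], [10]])
    tpm = es.tpm_normalize(expr, np.array([1.0, 10.0]))
    assert tpm[0, 0] == pytest.approx(1e6 * 10 / 11, rel=1e-9)
    assert tpm[1, 0] == pytest.approx(1e6 * 1 / 11, rel=1e-9)


def test_tpm_scale_invariance_and_column_sums(rng):
    counts = rng.integers(0, 500, (30, 8))
    counts[0] += 1  # avoid an all-zero column
    lens = rng.uniform(100, 5000, 30)
    a = es.tpm_normalize(_expr(counts), lens)
    b = es.tpm_normalize(_expr(counts * 7), lens)
    assert np.allclose(a, b)
    assert np.allclose(a.sum(axis=0), 1e6, rtol=1e-6)


def test_tpm_all_zero_sample_flagged():
    counts = np.array([[5, 0], [3, 0]])
    with pytest.warns(UserWarning, match="all-zero"):
        tpm = es.tpm_normalize(_expr(counts), np.array([1.0, 1.0]))
    assert np.isnan(tpm[:, 1]).all()


# ----------------------------------------------------------------- filter
def test_filter_low_expression_matches_enumeration(rng):
    counts = np.array(
        [
            [0, 0, 1, 0, 0],        # fails everything
            [50, 60, 70, 80, 90],   # passes
            [7, 7, 0, 0, 0],        # count floor in 40% of samples, TPM varies
            [2, 3, 2, 3, 2],        # TPM may pass, counts below 6 everywhere
            [600, 0, 0, 0, 0],      # high in one sample only (20%)
        ]
    )
    lens = np.array([100.0, 100.0, 100.0, 1.0, 100.0])
    expr = _expr(counts, lengths=np.maximum(lens, 1))
    tpm = es.tpm_normalize(expr, lens)
    kept = es.filter_low_expression(expr, tpm)
    n = counts.shape[1]
    expected = [
        i for i in range(5)
        if (tpm[i] > 0.1).sum() >= 0.2 * n and (counts[i] >= 6).sum() >= 0.2 * n
    ]
    assert list(kept.features["feature_id"]) == [f"g{i}" for i in expected]


def test_filter_removes_uniformly_low_feature():
    # TPM ~0.05 everywhere -> removed regardless of counts
    counts = np.vstack([np.full(5, 1), np.full(5, 20_000_000)])
    expr = _expr(counts, lengths=[1000, 1000])
    tpm = es.tpm_normalize(expr, np.array([1000.0, 1000.0]))
    assert tpm[0].max() < 0.1
    kept = es.filter_low_expression(expr, tpm)
    assert list(kept.features["feature_id"]) == ["g1"]


def test_filter_empty_result_raises():
    counts = np.zeros((2, 5), int)
    counts[:, 0] = 1
    expr = _expr(counts)
    tpm = np.zeros((2, 5))
    with pytest.raises(ValueError, match="filter"):
        es.filter_low_expression(expr, tpm)


# --------------------------------------------------------------------- DE
def test_fit_ancestry_de_noiseless_slope(rng):
    theta = rng.uniform(0, 1, 50)
    # counts whose log2 is 2*theta + const, plus a large constant feature so
    # the library term is itself (nearly) constant across samples
    signal = 2.0 ** (2 * theta + 12)
    counts = np.rint(np.vstack([signal, signal * 4, np.full(50, 1e8)])).astype(np.int64)
    expr = _expr(counts)
    eff = es.fit_ancestry_de(expr, theta, covariates=None)
    assert np.allclose(eff.beta.iloc[:2, 0], 2.0, atol=0.01)


def test_fit_ancestry_de_matches_closed_form(rng):
    theta = np.array([0.1, 0.3, 0.5, 0.7, 0.9])
    counts = rng.integers(50, 500, (3, 5))
    expr = _expr(counts)
    eff = es.fit_ancestry_de(expr, theta, covariates=None)
    y = expr.log2_cpm()
    X = np.column_stack([np.ones(5), theta])
    xtx_inv = np.linalg.inv(X.T @ X)
    for i in range(3):
        bhat = xtx_inv @ X.T @ y[i]
        resid = y[i] - X @ bhat
        se = np.sqrt(resid @ resid / (5 - 2) * xtx_inv[1, 1])
        assert eff.beta.iloc[i, 0] == pytest.approx(bhat[1], abs=1e-10)
        assert eff.se.iloc[i, 0] == pytest.approx(se, abs=1e-10)
    assert eff.df[expr.region] == 3


def test_fit_ancestry_de_null_type_one(rng):
    n, f = 60, 1000
    theta = rng.uniform(0, 1, n)
    counts = rng.negative_binomial(20, 20 / (20 + 300.0), (f, n))
    expr = _expr(counts)
    perm = rng.permutation(n)
    eff = es.fit_ancestry_de(expr, theta[perm], covariates=None)
    z = eff.beta.iloc[:, 0] / eff.se.iloc[:, 0]
    from scipy import stats

    p = 2 * stats.t.sf(np.abs(z), n - 2)
    assert abs(np.mean(eff.beta.iloc[:, 0])) < 0.05
    assert abs(np.mean(p < 0.05) - 0.05) < 0.025


def test_fit_ancestry_de_covariate_affine_invariance(cohort, covariate_matrix):
    expr = cohort["sets"][0]
    theta = cohort["truth"].theta
    a = es.fit_ancestry_de(expr, theta, covariate_matrix)
    scaled = covariate_matrix * np.array([2.0, -3.0, 0.5, 10.0]) + 7.0
    b = es.fit_ancestry_de(expr, theta, scaled)
    assert np.allclose(a.beta.to_numpy(), b.beta.to_numpy(), atol=1e-8)
    assert np.allclose(a.se.to_numpy(), b.se.to_numpy(), atol=1e-8)


def test_fit_ancestry_de_local_matrix(cohort, covariate_matrix):
    expr = cohort["sets"][0]
    n = len(expr.sample_ids)
    rng = np.random.default_rng(4)
    local = np.clip(
        cohort["truth"].theta[None, :] + 0.1 * rng.standard_normal((expr.counts.shape[0], n)),
        0, 1,
    )
    eff = es.fit_ancestry_de(expr, local, covariate_matrix)
    assert np.isfinite(eff.beta.to_numpy()).all()


def test_global_and_local_effects_correlate(cohort, covariate_matrix):
    """Ancestry effects from global theta and from local scores agree in rank."""
    from scipy.stats import spearmanr

    from admixdeconv import simgen
    from admixdeconv.ancestry import local_ancestry_feature_score

    expr = cohort["sets"][0]
    truth, geno = cohort["truth"], cohort["geno"]
    glob = es.fit_ancestry_de(expr, truth.theta, covariate_matrix)
    post = simgen.tract_posteriors(geno, truth)
    local = local_ancestry_feature_score(
        post, geno.chrom, geno.pos, expr.features, geno.sample_ids
    )
    loc = es.fit_ancestry_de(expr, local[geno.sample_ids].to_numpy(), covariate_matrix)
    focal = truth.focal_idx
    ok = np.isfinite(loc.beta.to_numpy()[focal, 0])
    rho = spearmanr(
        glob.beta.to_numpy()[focal, 0][ok], loc.beta.to_numpy()[focal, 0][ok]
    ).statistic
    assert rho > 0.5


def test_rank_deficient_design_names_columns(cohort):
    expr = cohort["sets"][0]
    theta = cohort["truth"].theta
    C = np.column_stack([theta, theta])  # collinear with ancestry
    with pytest.raises(ValueError, match="collinear"):
        es.fit_ancestry_de(expr, theta, C)


# ----------------------------------------------------------- residualize
def test_residualize_orthogonal_covariates_center_scale(rng):
    counts = rng.integers(100, 1000, (10, 40))
    expr = _expr(counts)
    C = rng.standard_normal((40, 2))
    y = expr.log2_cpm()
    A = np.column_stack([np.ones(40), y.T])
    C -= A @ np.linalg.lstsq(A, C, rcond=None)[0]  # orthogonal to 1 and expression
    Z, keep = es.residualize(expr, C)
    ref = (y - y.mean(axis=1, keepdims=True)) / y.std(axis=1, ddof=1, keepdims=True)
    assert np.allclose(Z, ref[keep], atol=1e-6)


def test_residualize_zscore_contract(cohort, covariate_matrix):
    Z, _ = es.residualize(cohort["sets"][0], covariate_matrix)
    assert np.max(np.abs(Z.mean(axis=1))) < 1e-10
    assert np.allclose(Z.std(axis=1, ddof=1), 1.0, atol=1e-10)


def test_residualize_matches_projection_oracle(rng):
    counts = rng.integers(100, 1000, (4, 6))
    expr = _expr(counts)
    C = rng.standard_normal((6, 2))
    Z, keep = es.residualize(expr, C)
    X = np.column_stack([np.ones(6), C])
    P = np.eye(6) - X @ np.linalg.inv(X.T @ X) @ X.T
    y = expr.log2_cpm()
    resid = (P @ y.T).T
    ref = (resid - resid.mean(axis=1, keepdims=True)) / resid.std(axis=1, ddof=1, keepdims=True)
    assert np.allclose(Z, ref[keep], atol=1e-8)


def test_tmm_factors_remove_composition_bias(rng):
    # two samples identical except one gene hugely up in sample 2: TMM factors
    # should keep the log ratios of unchanged genes near zero
    counts = rng.integers(100, 1000, (200, 2))
    counts[:, 1] = counts[:, 0]
    counts[0, 1] = 200_000
    expr = _expr(counts)
    eff_lib = expr.effective_library_sizes()
    cpm = counts / eff_lib[None, :] * 1e6
    ratios = np.log2(cpm[1:, 1] / cpm[1:, 0])
    assert abs(np.median(ratios)) < 0.05


def test_effect_matrix_validation():
    beta = pd.DataFrame({"a": [1.0]}, index=["g1"])
    with pytest.raises(ValueError, match="positive"):
        es.EffectMatrix(beta=beta, se=pd.DataFrame({"a": [0.0]}, index=["g1"]))
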