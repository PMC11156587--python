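"""Shrinkage engine: null correlation, dictionary, EM, posteriors, LFSR."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import logsumexp

from admixdeconv import exprstats as es
from admixdeconv import mashlite as M


def _effects(beta, se, regions=None):
    beta = np.atleast_2d(np.asarray(beta, float))
    se = np.broadcast_to(np.asarray(se, float), beta.shape)
    regions = regions or [f"r{j}" for j in range(beta.shape[1])]
    idx = [f"g{i}" for i in range(beta.shape[0])]
    return es.EffectMatrix(
        beta=pd.DataFrame(beta, index=idx, columns=regions),
        se=pd.DataFrame(se.copy(), index=idx, columns=regions),
    )


# -------------------------------------------------------- null correlation
def test_null_correlation_recovers_identity(rng):
    z = rng.standard_normal((5000, 4))
    eff = _effects(z, 1.0)
    V = M.estimate_null_correlation(eff)
    assert np.max(np.abs(V - np.eye(4))) < 0.05


def test_null_correlation_duplicated_columns(rng):
    z = rng.standard_normal(2000)
    eff = _effects(np.column_stack([z, z]), 1.0)
    V = M.estimate_null_correlation(eff)
    assert V[0, 1] == pytest.approx(1.0, abs=1e-12)
    assert np.allclose(np.diag(V), 1.0)
    assert np.allclose(V, V.T)


def test_null_correlation_too_few_features_warns(rng):
    eff = _effects(rng.standard_normal((3, 4)) * 10, 1.0)
    with pytest.warns(UserWarning, match="null-like"):
        V = M.estimate_null_correlation(eff)
    assert np.array_equal(V, np.eye(4))


# -------------------------------------------------------------- dictionary
def test_covariance_pca_matches_eigendecomposition(rng):
    z = rng.standard_normal((300, 3)) @ np.array(
        [[1.0, 0.5, 0.0], [0.0, 1.0, 0.3], [0.0, 0.0, 0.7]]
    )
    d = M.build_covariances(z, n_pcs=2, se_all=np.ones((300, 3)), beta_all=z)
    evals, evecs = np.linalg.eigh(z.T @ z / len(z))
    order = np.argsort(evals)[::-1]
    for p in range(2):
        U = evals[order[p]] * np.outer(evecs[:, order[p]], evecs[:, order[p]])
        U = U / np.max(np.diag(U))
        got = d.matrices[d.labels.index(f"pca_{p + 1}")]
        assert np.allclose(got, U, atol=1e-10)
    assert np.all(np.diff(d.grid) > 0)
    ratios = d.grid[1:] / d.grid[:-1]
    assert np.allclose(ratios, np.sqrt(2.0))


def test_equal_strong_zscores_make_pc1_equal_effects(rng):
    z = np.repeat(rng.standard_normal((200, 1)), 3, axis=1)
    d = M.build_covariances(z, se_all=np.ones((200, 3)), beta_all=z)
    pc1 = d.matrices[d.labels.index("pca_1")]
    eq = d.matrices[d.labels.index("equal_effects")]
    assert np.allclose(pc1, eq, atol=1e-10)


def test_dictionary_validation():
    with pytest.raises(ValueError, match="PSD"):
        M.CovarianceDictionary(labels=["bad"], matrices=[np.array([[-1.0]])],
                               grid=np.array([1.0]))
    with pytest.raises(ValueError, match="grid"):
        M.CovarianceDictionary(labels=["i"], matrices=[np.eye(2)],
                               grid=np.array([2.0, 1.0]))


# --------------------------------------------------------------------- EM
def test_null_only_dictionary_gives_pi_one(rng):
    eff = _effects(rng.standard_normal((100, 2)), 1.0)
    d = M.CovarianceDictionary(labels=[], matrices=[], grid=np.array([1.0]))
    fit = M.fit_mixture_em(eff, d, np.eye(2), null_penalty=1.0, max_iter=5)
    assert fit.pi[0] == pytest.approx(1.0)


def test_em_loglik_trace_non_decreasing(cohort, covariate_matrix):
    fits = {s.region: es.fit_ancestry_de(s, cohort["truth"].theta, covariate_matrix)
            for s in cohort["sets"]}
    eff = es.EffectMatrix.from_regions(fits)
    with pytest.warns(UserWarning):
        fit, _ = M.run_mash(eff, max_iter=300)
    assert np.all(np.diff(fit.loglik_trace) >= -1e-9)


def test_em_recovers_binary_mixture_weight(rng):
    n, R = 5000, 4
    U = np.full((R, R), 0.5) + 0.5 * np.eye(R)
    sig = rng.random(n) < 0.5
    b = np.zeros((n, R))
    b[sig] = rng.multivariate_normal(np.zeros(R), U, sig.sum())
    beta = b + rng.standard_normal((n, R))
    eff = _effects(beta, 1.0)
    d = M.CovarianceDictionary(labels=["sig"], matrices=[U], grid=np.array([1.0]))
    fit = M.fit_mixture_em(eff, d, np.eye(R), null_penalty=1.0, max_iter=2000)
    # 1-D grid-search oracle over the binary weight
    L = M._component_logliks(beta, np.ones((n, R)), np.eye(R), d)
    grid = np.linspace(0.005, 0.995, 199)
    lls = [logsumexp(L + np.log([p0, 1 - p0]), axis=1).sum() for p0 in grid]
    oracle = grid[int(np.argmax(lls))]
    assert abs(fit.pi[0] - oracle) < 0.01
    assert abs(fit.pi[0] - 0.5) < 0.05


def test_em_random_subset_reproducible(rng):
    eff = _effects(rng.standard_normal((500, 2)) * 2, 1.0)
    d = M.CovarianceDictionary(labels=["i"], matrices=[np.eye(2)],
                               grid=np.array([0.5, 1.0, 2.0]))
    a = M.fit_mixture_em(eff, d, np.eye(2), random_subset_frac=0.2, seed=3)
    b = M.fit_mixture_em(eff, d, np.eye(2), random_subset_frac=0.2, seed=3)
    assert np.array_equal(a.pi, b.pi)


# -------------------------------------------------------------- posterior
def test_pi_null_one_gives_zero_posterior_and_lfsr_one(rng):
    eff = _effects(rng.standard_normal((20, 3)), 1.0)
    d = M.CovarianceDictionary(labels=["i"], matrices=[np.eye(3)],
                               grid=np.array([1.0]))
    fit = M.MashFit(pi=np.array([1.0, 0.0]), dictionary=d, V=np.eye(3),
                    loglik_trace=np.zeros(1))
    post = M.posterior_summaries(eff, fit)
    assert np.allclose(post.post_mean.to_numpy(), 0.0)
    assert np.allclose(post.lfsr.to_numpy(), 1.0)


def test_lfsr_symmetry_at_zero_observation():
    eff = _effects(np.zeros((1, 1)), 1.0)
    d = M.CovarianceDictionary(labels=["i"], matrices=[np.eye(1)],
                               grid=np.array([1.0]))
    fit = M.MashFit(pi=np.array([0.0, 1.0]), dictionary=d, V=np.eye(1),
                    loglik_trace=np.zeros(1))
    post = M.posterior_summaries(eff, fit)
    assert post.lfsr.iloc[0, 0] == pytest.approx(0.5, abs=1e-12)


def test_posterior_matches_quadrature_oracle():
    """R=2, two components, hand-set errors: dense Bayes-rule integration."""
    beta = np.array([[1.3, -0.4]])
    se = np.array([[1.0, 0.7]])
    V = np.array([[1.0, 0.3], [0.3, 1.0]])
    U1 = np.array([[1.0, 0.8], [0.8, 1.0]])
    U2 = np.array([[0.5, 0.0], [0.0, 0.1]])
    d = M.CovarianceDictionary(labels=["a", "b"], matrices=[U1, U2],
                               grid=np.array([0.5, 2.0]))
    pi = np.array([0.3, 0.25, 0.15, 0.2, 0.1])
    eff = _effects(beta, se)
    fit = M.MashFit(pi=pi, dictionary=d, V=V, loglik_trace=np.zeros(1))
    post = M.posterior_summaries(eff, fit)

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
    assert np.max(np.abs(post.post_mean.to_numpy()[0] - num / dens)) < 1e-4


def test_shrinkage_bounds_posterior_mean(rng):
    # diagonal dictionary with scales below the observation variance
    beta = rng.standard_normal((200, 1)) * 2
    eff = _effects(beta, 1.0)
    d = M.CovarianceDictionary(labels=["i"], matrices=[np.eye(1)],
                               grid=np.array([0.25, 0.5, 1.0]))
    fit = M.fit_mixture_em(eff, d, np.eye(1), max_iter=1000)
    post = M.posterior_summaries(eff, fit)
    assert np.all(np.abs(post.post_mean.to_numpy()[:, 0]) <= np.abs(beta[:, 0]) + 1e-12)


def test_posterior_limits_in_se(rng):
    d = M.CovarianceDictionary(labels=["i"], matrices=[np.eye(1)],
                               grid=np.array([1.0]))
    fit = M.MashFit(pi=np.array([0.2, 0.8]), dictionary=d, V=np.eye(1),
                    loglik_trace=np.zeros(1))
    tiny = M.posterior_summaries(_effects([[1.7]], 1e-6), fit)
    assert tiny.post_mean.iloc[0, 0] == pytest.approx(1.7, abs=1e-3)
    huge = M.posterior_summaries(_effects([[1.7]], 1e5), fit)
    assert abs(huge.post_mean.iloc[0, 0]) < 1e-3


def test_r1_dictionary_matches_univariate_shrinkage(rng):
    # R=1: posterior mean must equal the scalar normal-normal formula
    beta = np.array([[0.9]])
    se = np.array([[0.5]])
    omega = 2.0
    d = M.CovarianceDictionary(labels=["i"], matrices=[np.eye(1)],
                               grid=np.array([omega]))
    fit = M.MashFit(pi=np.array([0.0, 1.0]), dictionary=d, V=np.eye(1),
                    loglik_trace=np.zeros(1))
    post = M.posterior_summaries(_effects(beta, se), fit)
    expected = omega / (omega + se[0, 0] ** 2) * beta[0, 0]
    assert post.post_mean.iloc[0, 0] == pytest.approx(expected, abs=1e-12)


def test_no_underflow_at_extreme_z():
    beta = np.array([[40.0, -40.0]])
    se = np.array([[1.0, 1.0]])
    d = M.CovarianceDictionary(labels=["i"], matrices=[np.eye(2)],
                               grid=np.array([1.0, 1000.0]))
    L = M._component_logliks(beta, se, np.eye(2), d)
    assert np.all(np.isfinite(L))


# ----------------------------------------------------------- significance
def test_significant_features_thresholding():
    lfsr = pd.DataFrame(
        {"r1": [0.01, 0.2, 1.0], "r2": [0.06, 0.04, 1.0]},
        index=["g1", "g2", "g3"],
    )
    zeros = pd.DataFrame(np.zeros((3, 2)), index=lfsr.index, columns=lfsr.columns)
    post = M.MashPosterior(post_mean=zeros, post_sd=zeros, lfsr=lfsr)
    sig = M.significant_features(post)
    assert sig["r1"] == {"g1"} and sig["r2"] == {"g2"}
    assert sig["union"] == {"g1", "g2"}
    all_one = M.MashPosterior(post_mean=zeros, post_sd=zeros,
                              lfsr=zeros + 1.0)
    assert M.significant_features(all_one)["union"] == set()


def test_lfsr_conservative_under_complete_null(rng):
    z = rng.standard_normal((3000, 4))
    eff = _effects(z, 1.0)
    _, post = M.run_mash(eff, max_iter=1000)
    assert (post.lfsr.to_numpy() < 0.05).mean() <= 0.05
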