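"""Shared synthetic cohorts, generated once per session."""

import warnings

import numpy as np
import pytest

from admixdeconv import simgen


@pytest.fixture(scope="session")
def small_config():
    return simgen.SimConfig(
        n_samples=80,
        n_features=40,
        n_variants=800,
        chrom_length_bp=40_000_000,
    )


@pytest.fixture(scope="session")
def cohort(small_config):
    """Panel, genotypes, truth, per-region expression and covariates."""
    panel = simgen.simulate_panel(small_config, seed=7)
    geno, truth = simgen.simulate_genotypes(panel, small_config, seed=8)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sets, covariates = simgen.simulate_expression(geno, truth, small_config)
    return {
        "config": small_config,
        "panel": panel,
        "geno": geno,
        "truth": truth,
        "sets": sets,
        "covariates": covariates,
    }


@pytest.fixture(scope="session")
def covariate_matrix(cohort):
    covs = cohort["covariates"]
    return covs[[c for c in covs.columns if c != "sample_id"]].to_numpy(float)


@pytest.fixture(scope="session")
def methylation(cohort, small_config):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simgen.simulate_methylation(cohort["truth"], small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
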