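# admixdeconv

Decomposing ancestry-associated gene expression into genetic and
environmental components, on synthetic admixed cohorts with known ground
truth.

## The problem

In admixed populations (here a two-way African/European model), gene
expression differences that track global genetic ancestry θ can arise from
three routes: *cis*-genetic variation (a causal variant whose allele
frequency diverges between the ancestral populations), ancestry-correlated
environmental exposures, and everything else. Disentangling these routes
requires a chain of analyses — ancestry estimation, multi-region
differential expression with empirical-Bayes shrinkage, *cis*-eQTL mapping,
genotype-based expression imputation, and a methylation-derived
environmental statistic — whose real inputs are usually access-restricted.
This package implements that chain end to end and pairs it with a synthetic
cohort generator so every stage is testable against known truth.

It is aimed at statistical geneticists who want a desk-scale, fully
inspectable reimplementation of this analysis style: each stage is an
ordinary Python function over explicit containers (dosage matrices, count
matrices, CpG tables), with TSV/VCF input-output and a thin `admixdeconv`
command-line wrapper.

## Models at the core

**Global ancestry.** For dosage `g_s` at unlinked markers with ancestral
alt-allele frequencies `p_AFR`, `p_EUR`, per-sample ancestry maximizes

```
L(θ) = Σ_sites log Binom(g_s | 2, θ·p_AFR + (1−θ)·p_EUR),  θ ∈ [0, 1]
```

**Differential expression and shrinkage.** Per region, log₂-CPM
(TMM-normalized) is regressed on ancestry plus covariates (sex, age,
qSV-like columns), yielding effects β̂ⱼ and standard errors across R regions.
These enter a multivariate adaptive-shrinkage model

```
β̂ⱼ | bⱼ ~ N(bⱼ, Sⱼ),   bⱼ ~ π₀δ₀ + Σ_{k,l} π_{kl} N(0, ω_l U_k)
```

with canonical and data-driven covariance patterns U_k; mixture weights are
learned by EM and significance is reported as the local false sign rate
(LFSR), the posterior probability that an effect's sign is wrong or null.

**Genetic share.** Expression is imputed from *cis* dosages (top-eQTL or a
cross-validated elastic net); regressing imputed expression on ancestry
gives predicted ancestry effects, and their squared correlation with the
observed (shrunken) effects across genes is the genetic share of
ancestry-associated expression.

**Environmental share.** Variably methylated regions (VMRs) are called from
WGBS-like CpG counts; per gene, the ancestry partial R² of expression
(P_ST = (SSE_reduced − SSE_full)/SSE_reduced) is computed before and after
conditioning on residualized VMR methylation, and
ΔP_ST = (P_ST − P_ST,VMR)/P_ST is the methylation-tracked environmental
share.

## Worked example

```python
import numpy as np
from admixdeconv import simgen, ancestry, exprstats, mashlite

cfg = simgen.SimConfig(n_samples=100, n_features=50, n_variants=1500,
                       chrom_length_bp=50_000_000)
panel = simgen.simulate_panel(cfg, seed=1)
geno, truth = simgen.simulate_genotypes(panel, cfg, seed=2)
sets, covariates = simgen.simulate_expression(geno, truth, cfg)

refs = {pop: simgen.simulate_reference_genotypes(panel, 100, pop, seed=3)
        for pop in ("afr", "eur")}
aims = ancestry.select_aims(panel, refs)
table = ancestry.estimate_global_ancestry(geno, panel, aims)

covs = covariates[[c for c in covariates.columns if c != "sample_id"]].to_numpy()
fits = {s.region: exprstats.fit_ancestry_de(s, table.theta_hat.to_numpy(), covs)
        for s in sets}
fit, posterior = mashlite.run_mash(exprstats.EffectMatrix.from_regions(fits), seed=4)
sig = mashlite.significant_features(posterior)
```

This prints (via the accompanying summaries):

```
AIMs selected: 54
mean ancestry estimate: 0.747 (true mean 0.758)
MAE vs truth: 0.0449
features tested: 250
ancestry-DE features (LFSR < 0.05, any region): 47
of which truly ancestry-associated: 47
```

So with 54 ancestry-informative markers the likelihood estimator recovers
per-sample ancestry to ~0.045 on average; of 250 simulated features (50 with
true ancestry effects, 200 neutral background genes) the shrinkage model
calls 47 significant — all of them truly ancestry-associated, with no false
positives among the 200 nulls.

The same stages run from the shell:

```
admixdeconv all --config cfg.toml        # end-to-end with a manifest
admixdeconv simulate --seed 7 --out DIR  # cohort only
admixdeconv ancestry --vcf g.vcf --panel panel.tsv --out DIR
admixdeconv mash --betas b.tsv --ses s.tsv --out PREFIX
```

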