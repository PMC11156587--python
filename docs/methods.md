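# Methods

This note documents the models implemented in `admixdeconv`, the design of
the synthetic cohort generator, the calibration behind its two ground-truth
fractions, and the numerical choices made where the design was genuinely
open. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. Synthetic admixed cohorts (`simgen`)

**Ancestral panel.** Variants are placed uniformly on one chromosome
(default 2,000 variants over 100 Mb). Allele frequencies in the two
ancestral populations follow a Balding–Nichols model: for an ancestral
frequency p ~ U(0.05, 0.95), each population's frequency is drawn
Beta(p(1−F)/F, (1−p)(1−F)/F) with divergence F = 0.15, giving
AFR/EUR-like site-frequency divergence.

**Ancestry and tracts.** Each individual draws a mixing parameter
θ* ~ Beta(3.95, 1.05) (mean 0.79, matching a predominantly-African admixed
cohort with substantial spread; fixed θ is available for benchmarking). Each
haplotype is tiled by tracts: switch points form a Poisson process with rate
`recomb_rate_per_bp` (default 8×10⁻⁸, i.e. roughly eight generations of
admixture at human crossover rates — about eight 12.5-Mb tracts per
haplotype on the default chromosome), and every inter-switch segment draws
its origin Bernoulli(θ*). The recorded truth `theta` is the realized,
length-weighted African tract fraction — the quantity a genome-wide
estimator actually estimates — and equals the tract table's AFR share to
1e-9 by construction; θ* is kept separately as `theta_param`. Alleles are
drawn per haplotype from the tract-of-origin's frequency, and dosage is the
haplotype sum.

**Expression.** Each of R = 4 "brain regions" gets a negative-binomial count
matrix. A feature's latent log₂ expression is

```
baseline + b_dir·θ + b_gen·G + b_env·E + covariate effects + N(0, noise_sd)
```

where G is the dosage of the feature's causal variant (the most
ancestry-divergent variant within ±500 kb of the TSS — mirroring the
observation that ancestry-associated genes are driven by high-divergence
eQTLs, and avoiding the pathological regime where a low-divergence causal
variant needs an enormous allele effect to carry an ancestry signal), and E
is a per-feature environmental exposure E_i = θ + ε_i with
corr(E, θ)² = 0.2 by default. Exposures are idiosyncratic per gene: a single
shared exposure would dominate the methylation covariance and be removed by
the variable-CpG recipe's own principal-component step, which is neither
realistic nor measurable. Counts are NB with per-feature log-normal
dispersion around 0.05 and log-normal library factors.

**Ancestry-neutral background.** Besides the `n_features` focal features the
matrices include 4× as many background features with no ancestry, genotype
or exposure terms. Without them every gene in the library would carry an
ancestry effect and the column sums themselves would acquire a large
ancestry slope (≈2.4 on the log₂ scale in early experiments) that CPM
normalization then subtracts from every feature, destroying all calibrated
effects. Real libraries are dominated by non-associated genes; the
background restores that.

**Effect decomposition and the two target fractions.** Focal ancestry
effects are built from independent genotype-path and direct-path components
g, d drawn with equicorrelation 0.8 across regions (the across-region
sharing of true effects is deliberately a parameter, not a fixed constant)
and variance ratio `genetic_fraction : 1−genetic_fraction`. A
DEG-ascertainment floor rescales features whose mean |effect| falls below
1.0 log₂-per-unit-ancestry: focal features emulate *ascertained* DEGs, and
genes with tiny ancestry effects could neither be detected nor express a
meaningful relative reduction in their ancestry variance.

*genetic_fraction* is the share of cross-feature variance of the total
ancestry effect carried by the genotype path. Because g and d are
independent, the squared correlation between genotype-predicted and observed
ancestry effects — exactly what the downstream imputation analysis measures
— equals this share.

*env_fraction* is defined as the expected per-gene ΔP_ST: the relative drop
in the ancestry partial R² of expression when the model is conditioned on
the gene's measured exposure proxy (VMR methylation residualized on local
ancestry, age and sex). A naive "slope share" loading is *not* recovered by
ΔP_ST; four structural effects intervene, all verified step by step during
development:

1. residualizing the proxy on local ancestry projects out the fraction
   ρ = var(θ)/(var(θ) + E[θ(1−θ)]/2) of its ancestry coupling (the squared
   correlation between global ancestry and the diploid one-locus ancestry
   fraction);
2. conditioning removes the exposure's non-ancestry variance from the
   model residual, which *inflates* the adjusted partial R² and can push
   ΔP_ST negative;
3. the proxy's leftover ancestry correlation shrinks var(θ | proxy),
   pushing ΔP_ST up;
4. the causal variant and the VMR share the same tract deviation
   h = l − θ, so the genetic component g·h covaries negatively with the
   partialled proxy and attenuates the measured absorption.

All four are exact functions of inner products among θ, ε, G and the
residualized proxy — all held by the generator — so the environmental
loading e is solved per feature and region from the closed-form expectation
of ΔP_ST (projection algebra over a per-gene 4×4 Gram matrix plus the
independent-noise variance; the formula reproduces simulated ΔP_ST to
within Monte-Carlo error at n = 20,000 under its own model). The default
corr(E, θ)² = 0.2 comes from a reachability analysis: at weaker
exposure–ancestry coupling, effect (2) caps the achievable ΔP_ST below
typical targets for most genes. Where the solver cannot reach the target
(small effects with strong coupling) the loading falls back to the plain
slope share and a warning counts the fallbacks.

**Methylation.** Each focal gene gets one CpG cluster at its TSS (8 CpGs,
120-bp spacing) loading on the gene's standardized exposure with strength
1.2 on the logit scale; 99× as many background clusters carry no exposure.
The 100:1 cluster ratio makes a top-1% variable-CpG cut match the scale
geometry of a genome-wide WGBS screen. All clusters load on 5 shared batch
factors (loading sd 0.25) and a local-ancestry effect (sd 0.3); CpG-level
logits add cluster and site noise. Read depth is Poisson (mean 30×),
methylated reads Binomial around the logistic latent level.

**What the generator does not emulate.** Linkage disequilibrium beyond
ancestry-induced correlation (panel sites are exchangeable given the
tracts); multi-chromosome genomes; RNA-degradation structure behind qSVs
(they are plain standard normals with real effects on expression);
bimodal CpG methylation landscapes; isoform-level features. Passing tests
therefore demonstrate correctness of the statistical machinery under the
stated model, not robustness to those phenomena.

## 2. Ancestry (`ancestry`)

AIM selection applies three filters: |p_AFR − p_EUR| > 0.5; exact
conditional Hardy–Weinberg P > 0.01 within each reference population
(a hand-coded exact test — the standard heterozygote-count enumeration —
since none is available in the installed stack); and greedy LD pruning in
genomic order, dropping a variant whose r² with any kept variant within
1 Mb reaches 0.1 in either population.

Global ancestry maximizes the binomial mixture likelihood by golden-section
search on [0, 1] to tolerance 1e-6, with a boundary check (the likelihood is
unimodal in θ). If every marker is uninformative the sample is flagged
`unidentifiable` and reported at 0.5. Local-ancestry feature scores average
the per-SNP African posteriors over both haplotypes within the feature span
padded by 200 kb; features with no SNP in the window are flagged and left
missing rather than imputed.

## 3. Differential expression (`exprstats`)

Counts are normalized to log₂-CPM with a 0.5 pseudo-count and
TMM-rescaled library sizes (an edgeR-style trimmed mean of M-values against
a reference sample, 30%/5% trims, precision weights by the delta method).
Plain column sums are available (`tmm=False`) but are a poor library measure
whenever expression differences concentrate in a subset of genes. TPM uses
effective lengths (length − mean insert + 1; fixed at 100 for junction
features; features with effective length ≤ 1 are dropped by the caller), and
the expression filter keeps features with TPM > 0.1 and count ≥ 6 in at
least 20% of samples.

The ancestry model is unweighted OLS of log₂-CPM on ancestry plus covariates
— the precision-weighting and empirical-Bayes moderation of count-aware DE
fitters are deliberately out of scope, since the multivariate shrinkage
stage is the inferential engine and only needs an effect and a standard
error per feature and region. Local-ancestry DE uses each feature's own
local score as the regressor. Residualization for eQTL input regresses
log₂-CPM on the null covariate model and z-scores per feature; for
genotype-based imputation the z-scoring is skipped so the effect scale is
preserved.

## 4. Multivariate shrinkage (`mashlite`)

The error correlation V across regions is the correlation of z-scores over
features with max |z| < 2 (identity, with a warning, when fewer than R+1
such features exist). The covariance dictionary holds the canonical patterns
(identity, per-region singletons, equal effects, equicorrelated at ρ ∈
{0.25, 0.5, 0.75}) plus data-driven rank-1 patterns from the top principal
components (uncentered) of the strong-set z-scores and their rank-k
reconstruction, all normalized to unit maximum diagonal. The "strong set" is
operationalized as features passing per-region BH FDR < 0.05 on normal
p-values from β/se in at least one region. The scale grid is geometric with
ratio √2 from (min se)²/100 to 4·max β².

EM re-estimates only the mixture weights: the component log-likelihood
matrix is computed once (batched Cholesky per component; everything in log
space, so |z| up to 40 is exact) and each iteration is two matrix–vector
products with the exponentiated, per-feature-rescaled matrix. A Dirichlet
penalty of 10 prior counts regularizes the null weight. The convenience
driver allows 3,000 iterations (the low-level function keeps a 500 default
and returns flagged when not converged — the penalized log-likelihood trace
is non-decreasing either way). Posteriors follow multivariate-normal
conjugacy per component; the LFSR of effect r is
min{P(b_r ≤ 0 | data), P(b_r ≥ 0 | data)} with point masses (the null, and
degenerate pattern components) counted in both tails. The engine is checked
against dense two-dimensional quadrature and, at R = 1, the scalar
normal–normal formula. Effects enter on their own scale (EE form);
z-score-scaled shrinkage is not implemented.

## 5. cis-eQTL mapping (`cis_qtl`)

Nominal main-effect scans regress residualized expression on dosage plus
covariates within ±500 kb of the TSS at MAF ≥ 0.01; interaction scans add
ancestry and dosage×ancestry (the product term is reported) at MAF ≥ 0.05
and drop genotype-PC-style covariates. Permutation top-association p-values
use a fixed permutation count (default 1,000) of the covariate-residualized
phenotype against the window's maximum |correlation| — exactly testable,
unlike adaptive schemes — with empirical_p = (1 + #{perm ≥ obs})/(perms+1).
Storey q-values estimate π₀ at λ = 0.5 (clipped to 1; an explicit π₀
override exists for testing). Allele-frequency differences match alleles
between panels, flipping to 1−f for swapped ref/alt orientations and
skipping (with a count) anything else; gene-level AFD averages over the
gene's significant eQTL variants.

## 6. Genotype-based imputation (`genpred`)

The elastic net is solved by cyclic coordinate descent on the Gram
formulation, minimizing (1/2n)‖y − Xw‖² + λ(α‖w‖₁ + (1−α)/2‖w‖₂²). The
kernel is numba-compiled with an identical pure-Python fallback; the
traced variant exposes the per-sweep objective, which is non-increasing (a
tested property). α is tuned over 0.05–1.00 in steps of 0.05; the λ path is
geometric with 30 values spanning three orders of magnitude below λ_max
(the smallest λ with an all-zero solution) — enough resolution at the
few-dozen-predictor scale of cis windows while keeping the 20-alpha ×
k-fold cross-validation grid cheap. Variants are prefiltered at MAF ≥ 0.01
and exact-test HWE P ≥ 1e-5; predictors are standardized within training
folds and weights back-transformed; the (α, λ) pair minimizes
cross-validated MSE, final weights are the across-fold mean, and cv_r is
the per-fold-averaged Pearson correlation of held-out predictions.
Top-eQTL imputation is simply effect × dosage.

The genetic share regresses each feature's imputed expression on ancestry
plus the DE covariates and reports the squared Pearson correlation between
predicted and observed (posterior-mean) effects, with the slope from
regressing predicted on observed; fewer than 10 features is refused.

## 7. Methylation and P_ST (`methylvar`)

CpGs need more than 5 reads in more than 80% of samples. Smoothing is a
triangular-weighted rolling mean of raw proportions over a 1,000-bp window —
a light local smoother preserving the "locally smoothed" contract at desk
scale. Variable-CpG selection residualizes smoothed levels on global
ancestry, computes 5 sample-space principal components from the most
variable 5% of residualized CpGs, re-residualizes everything on those PCs,
ranks by residual SD and keeps the top 1%. One SD definition serves both the
PCA subset and the final ranking. VMRs merge consecutive selected CpGs
within 1,000 bp and keep regions with at least 6 CpGs; the region level is
Σmeth/Σtotal over the region's CpGs (read-weighted, from raw counts). DMR
models are OLS of region levels on ancestry, age, sex and the top
methylation PCs with BH correction.

P_ST is the ancestry partial R², (SSE_reduced − SSE_full)/SSE_reduced, with
the reduced model dropping only ancestry; the VMR-adjusted variant adds the
gene's residualized VMR levels (residualized on local ancestry at the VMR,
age, sex and the methylation PCs; regions without a local-ancestry call
fall back to the remaining covariates) to both models. VMRs annotate to
genes by overlap with the gene body ± 5 kb. ΔP_ST = (P_ST − P_ST,VMR)/P_ST
may be negative and is reported as-is; it is undefined at P_ST = 0 and the
benchmark summaries additionally require P_ST ≥ 0.05 ("analyzable" genes) —
a ratio statistic needs its denominator a sensible distance from zero
(≈1.5 standard errors at n = 150).

## 8. Sharing and enrichment (`popshare`)

Pairwise sharing among features significant in either region of a pair
reports the sign-match fraction and the fraction with concordant sign and
effect ratio within [0.5, 2] (the usual magnitude-sharing convention).
Fisher tests are two-sided exact (summing hypergeometric terms no more
likely than observed) with BH adjustment across lists; odds ratios get a
Haldane 0.5 correction only when a zero cell exists, and that is flagged.
The Monte-Carlo overlap test draws random same-size sets from the universe;
the k-way intersection of independent uniform sets is simulated by chained
hypergeometric draws (|A∩B| is hypergeometric; intersecting with each
further uniform set is again hypergeometric), which is distributionally
identical to materializing the sets and fully vectorized; an exact
enumeration by PMF convolution serves as the oracle on small universes.
Cell-type specificity scores are each gene's share of its total mean TPM
across cell types, with markers the top decile among genes at ≥ 1 TPM in
that type. The AFD comparison is a one-sided Mann–Whitney U (exact for ≤ 20
untied values, tie-corrected normal approximation otherwise); all-tied
input returns 0.5, flagged degenerate.

## 9. Orchestration and reproducibility

`pipeline.run_all` executes simulate → ancestry → DE per region → shrinkage
→ eQTL (+ shrinkage of per-feature top associations) → imputation →
methylation/P_ST → sharing from a flat TOML config, writes every stage as
TSV/VCF/JSON and a manifest with SHA-256 digests, parameters and row counts,
and aborts with the stage name on failure. All randomness flows through
explicitly seeded `numpy.random.Generator` instances; identical configs
produce byte-identical outputs (tested on digests).

Benchmark problem sizes (also the acceptance-script sizes): ancestry — 1,634
AIMs × 1,000 samples at five true levels, grid oracle at step 1e-4;
shrinkage — R = 2 quadrature toy plus 5,000 × 4 mixture recovery; LFSR null
— 5,000 × 4; genetic share — 200 focal features × 150 samples (plus 800
background genes); environmental share — 150 focal features × 150 samples,
~120,000 CpGs; eQTL — 200 features at h² = 0.3, 500 null features × 300
permutations for uniformity; enrichment — 2,000 random tables with universe
≤ 60 and a 20-gene exact-enumeration universe. The full set runs in about a
minute on one CPU.

## Known limitations

- The ΔP_ST estimator is intrinsically noisy at realistic per-gene P_ST;
  its per-gene values are meaningful only in aggregate, and the mean over
  analyzable genes varies by a few percentage points across seeds.
- The environmental-loading solve conditions on the generator's own
  idealized proxy; measurement losses in the VMR chain (logistic
  compression, finite depth, PC leakage) attenuate recovery mildly below
  the target.
- The supervised ancestry MLE assumes known ancestral frequencies and
  unlinked markers; it is not an unsupervised admixture method.
- Unweighted OLS standard errors ignore the count mean–variance
  relationship; with moderate expression and the shrinkage stage downstream
  this is immaterial here, but very low counts would violate it.
- Single chromosome, two ancestries, hard tract posteriors (with an
  optional blur); no phasing or haplotype-inference error model.
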