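"""Synthetic admixed cohorts with known genetic/environmental ground truth.

The generator emulates a two-way admixed population (African/European): each
individual draws a global African-ancestry proportion ``theta`` from a Beta
prior, each haplotype is tiled by Markovian ancestry tracts, alleles are
drawn from the tract-of-origin's ancestral allele frequency, and gene
expression in several correlated "brain regions" carries an ancestry effect
that is split between a cis-genetic path (a causal variant whose frequency
diverges between the ancestral populations), an environmental factor E that
is itself correlated with ancestry, and a residual direct path.  A WGBS-like
methylation layer wires the same E into CpG clusters so that the
methylation-proxy statistics downstream can recover the environmental share.

Calibration of the two target fractions
---------------------------------------
``genetic_fraction`` is the share of the *cross-feature variance* of the
total ancestry effect carried by the cis-genotype path: the genotype-path and
direct-path slopes are drawn independently per feature with variances in the
ratio ``genetic_fraction : 1 - genetic_fraction``, which is exactly what the
squared correlation between genotype-predicted and observed ancestry effects
estimates.

``env_fraction`` is the expected value, per feature, of the delta-P_ST
statistic the pipeline measures: the relative drop in the ancestry partial
R^2 of expression when the model is conditioned on the feature's exposure
proxy (VMR methylation residualized on local ancestry, age and sex).  This
conditioning has several interacting consequences that a naive "slope share"
loading would miss:

* the residualization on local ancestry projects out part of the exposure's
  ancestry coupling (only the remainder can displace the ancestry slope);
* absorbing the exposure's non-ancestry variance from the residual inflates
  the adjusted partial R^2 (pushing delta-P_ST down, even negative);
* the proxy's leftover ancestry correlation shrinks var(theta | proxy)
  (pushing delta-P_ST up);
* the causal cis variant and the proxy's local-ancestry regressor share the
  same tract deviation, so the genetic component covaries negatively with
  the partialled proxy and attenuates the measured environmental absorption.

All of these are exact functions of inner products among theta, the
exposure noise, the causal dosage and the residualized proxy — quantities
the generator holds — so the environmental loading ``e`` is solved per
feature (and region) from the closed-form expectation of delta-P_ST so that
it equals ``env_fraction``.  The derivation is reproduced in the methods
note.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit

from .genotypes import GenotypeMatrix

AFR, EUR = 1, 0  # tract origin codes


# --------------------------------------------------------------------- types
@dataclass
class AncestralPanel:
    """Reference-panel variants with allele frequencies in both ancestries."""

    variant_id: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray  # 1-based
    ref: np.ndarray
    alt: np.ndarray
    freq_afr: np.ndarray
    freq_eur: np.ndarray

    def __post_init__(self):
        self.pos = np.asarray(self.pos, int)
        self.freq_afr = np.asarray(self.freq_afr, float)
        self.freq_eur = np.asarray(self.freq_eur, float)
        for f in (self.freq_afr, self.freq_eur):
            if np.any((f < 0) | (f > 1)):
                raise ValueError("allele frequencies must lie in [0, 1]")
        if len(np.unique(self.variant_id)) != len(self.variant_id):
            raise ValueError("variant ids must be unique")
        for c in np.unique(np.asarray(self.chrom)):
            p = self.pos[np.asarray(self.chrom) == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError("positions must be strictly increasing within chrom")

    def __len__(self):
        return len(self.variant_id)

    def to_tsv(self, path: str) -> None:
        pd.DataFrame(asdict(self)).to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str) -> "AncestralPanel":
        df = pd.read_csv(path, sep="\t")
        return cls(**{k: df[k].to_numpy() for k in df.columns})


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults emulate the admixed cohort the pipeline targets: mean African
    ancestry ~0.79 with substantial spread, four correlated brain regions,
    a cis-genetic share of ~0.6 and an environmental share of ~0.15 of the
    ancestry effect, ~8 ancestry tracts per haplotype (a few generations of
    admixture on a 100-Mb chromosome), moderate bulk RNA-seq noise and 30x
    mean WGBS depth.
    """

    n_samples: int = 150
    n_regions: int = 4
    n_features: int = 200
    # ancestry-neutral background features co-simulated so that library sizes
    # are dominated by non-associated genes, as in a real transcriptome
    # (default 4x the focal features)
    n_null_features: int | None = None
    n_variants: int = 2000
    chrom_length_bp: int = 100_000_000
    chrom: str = "chr1"
    theta_beta_params: tuple[float, float] = (3.95, 1.05)
    theta_fixed: object = None  # scalar or per-sample array; overrides the Beta draw
    recomb_rate_per_bp: float = 8e-8
    effect_sharing_correlation: float = 0.8
    noise_sd: float = 0.5
    effect_sd: float = 2.0
    # focal features emulate ascertained ancestry-DEGs, so their shared
    # ancestry effect is drawn from the detectable tail (per-feature mean
    # |log2FC per unit ancestry| at least this floor)
    min_ancestry_effect: float = 1.0
    genetic_fraction: float = 0.6
    env_fraction: float = 0.15
    env_ancestry_r2: float = 0.20
    cis_window_bp: int = 500_000
    cis_h2: object = None  # if set, pure eQTL mode: per-feature causal h^2
    n_qsvs: int = 2
    baseline_log2_mean: float = 7.0
    baseline_log2_sd: float = 1.5
    dispersion_log_mean: float = -3.0
    dispersion_log_sd: float = 0.5
    library_size_log_sd: float = 0.3
    divergence_fst: float = 0.15
    min_causal_afd: float = 0.1
    # methylation layer; background clusters default to 99x the gene clusters
    # so that a top-1% variable-CpG cut matches the scale ratio of a
    # genome-wide WGBS screen
    mean_depth: float = 30.0
    cpgs_per_cluster: int = 8
    cpg_spacing_bp: int = 120
    n_background_clusters: int | None = None
    meth_env_loading: float = 1.2
    meth_local_ancestry_sd: float = 0.3
    n_meth_batch_factors: int = 5
    meth_batch_loading_sd: float = 0.25
    meth_cpg_noise_sd: float = 0.15

    def validate(self) -> None:
        counts = [
            self.n_samples, self.n_regions, self.n_features,
            self.n_variants, self.chrom_length_bp,
        ]
        if any(c <= 0 for c in counts):
            raise ValueError("all counts must be positive")
        if not 0.0 <= self.effect_sharing_correlation <= 1.0:
            raise ValueError("effect_sharing_correlation must lie in [0, 1]")
        if not (0 <= self.genetic_fraction <= 1 and 0 <= self.env_fraction <= 1):
            raise ValueError("fractions must lie in [0, 1]")
        if self.genetic_fraction + self.env_fraction > 1:
            raise ValueError("genetic_fraction + env_fraction must be <= 1")
        a, b = self.theta_beta_params
        if a <= 0 or b <= 0:
            raise ValueError("Beta parameters must be positive")


@dataclass
class SimTruth:
    """Ground truth recorded while simulating.

    ``theta`` is the realized, length-weighted African tract fraction per
    sample (the genome-wide truth an estimator should recover);
    ``theta_param`` is the Beta-distributed mixing parameter the tracts were
    generated from.
    """

    seed: int
    theta: np.ndarray
    theta_param: np.ndarray
    tracts: pd.DataFrame  # sample, hap, chrom, start, end (0-based half-open), origin
    genetic_fraction: float
    env_fraction: float
    # filled by simulate_expression
    features: pd.DataFrame | None = None
    beta_true: np.ndarray | None = None  # (features, regions) total ancestry slope
    b_gen: np.ndarray | None = None
    b_env: np.ndarray | None = None
    b_dir: np.ndarray | None = None
    causal_variant: np.ndarray | None = None
    env_factor: np.ndarray | None = None  # (focal features x samples)
    focal_idx: np.ndarray | None = None  # rows of `features` that carry effects
    is_null: np.ndarray | None = None
    covariates: pd.DataFrame | None = field(default=None, repr=False)
    # filled by simulate_methylation
    vmr_truth: pd.DataFrame | None = None

    def __post_init__(self):
        if self.genetic_fraction + self.env_fraction > 1 + 1e-12:
            raise ValueError("genetic_fraction + env_fraction must be <= 1")
        frac = afr_tract_fraction(self.tracts)
        if np.max(np.abs(frac - self.theta)) > 1e-9:
            raise ValueError("theta must equal the length-weighted AFR tract fraction")

    def to_json(self, path: str) -> None:
        payload = {
            "seed": int(self.seed),
            "theta": self.theta.tolist(),
            "theta_param": self.theta_param.tolist(),
            "genetic_fraction": self.genetic_fraction,
            "env_fraction": self.env_fraction,
        }
        if self.beta_true is not None:
            payload["beta_true"] = self.beta_true.tolist()
            payload["causal_variant"] = list(map(str, self.causal_variant))
            payload["env_factor"] = self.env_factor.tolist()
        with open(path, "w") as fh:
            json.dump(payload, fh)


def afr_tract_fraction(tracts: pd.DataFrame) -> np.ndarray:
    """Length-weighted AFR fraction per sample from a tract table."""
    length = (tracts["end"] - tracts["start"]).to_numpy(float)
    afr_len = np.where(tracts["origin"].to_numpy() == AFR, length, 0.0)
    tot = pd.Series(length).groupby(tracts["sample"].to_numpy()).sum()
    afr = pd.Series(afr_len).groupby(tracts["sample"].to_numpy()).sum()
    return (afr / tot).to_numpy()


def _distinct_positions(rng, n: int, lo: int, hi: int) -> np.ndarray:
    """n sorted distinct integer positions in [lo, hi) without materializing the range."""
    draw = rng.integers(lo, hi, size=int(n * 1.2) + 16)
    uniq = np.unique(draw)
    while len(uniq) < n:
        uniq = np.unique(np.concatenate([uniq, rng.integers(lo, hi, size=n)]))
    return np.sort(rng.choice(uniq, size=n, replace=False))


# ------------------------------------------------------------------- panels
def simulate_panel(config: SimConfig, seed: int) -> AncestralPanel:
    """Balding-Nichols two-population panel at the configured divergence."""
    config.validate()
    rng = np.random.default_rng(seed)
    pos = _distinct_positions(rng, config.n_variants, 1, config.chrom_length_bp)
    p_anc = rng.uniform(0.05, 0.95, config.n_variants)
    fst = config.divergence_fst
    shape = (1 - fst) / fst
    freq_afr = rng.beta(p_anc * shape, (1 - p_anc) * shape)
    freq_eur = rng.beta(p_anc * shape, (1 - p_anc) * shape)
    bases = np.array(list("ACGT"))
    ref = bases[rng.integers(0, 4, config.n_variants)]
    alt = np.array([bases[(list(bases).index(r) + rng.integers(1, 4)) % 4] for r in ref])
    return AncestralPanel(
        variant_id=np.array([f"rs{i:06d}" for i in range(config.n_variants)]),
        chrom=np.repeat(config.chrom, config.n_variants),
        pos=pos,
        ref=ref,
        alt=alt,
        freq_afr=freq_afr,
        freq_eur=freq_eur,
    )


# ---------------------------------------------------------------- genotypes
def simulate_genotypes(
    panel: AncestralPanel, config: SimConfig, seed: int
) -> tuple[GenotypeMatrix, SimTruth]:
    """Draw theta, tile haplotypes with ancestry tracts, emit dosages.

    Tracts are the segments between the switch points of a Poisson process
    with rate ``recomb_rate_per_bp``; each segment's origin is an independent
    Bernoulli(theta) draw, so consecutive segments may share an origin while
    inter-switch distances stay exponential.
    """
    if seed is None:
        raise ValueError("a seed is required (reproducibility contract)")
    if len(panel) == 0:
        raise ValueError("panel must be non-empty")
    config.validate()
    rng = np.random.default_rng(seed)
    n = config.n_samples
    L = int(config.chrom_length_bp)

    a, b = config.theta_beta_params
    if config.theta_fixed is not None:
        theta_param = np.broadcast_to(np.asarray(config.theta_fixed, float), (n,)).copy()
    else:
        theta_param = rng.beta(a, b, n)

    rows = []
    origins = np.empty((2 * n, len(panel)), np.int8)
    for s in range(n):
        for h in range(2):
            n_breaks = rng.poisson(config.recomb_rate_per_bp * L)
            breaks = np.sort(rng.integers(1, L, n_breaks))
            starts = np.concatenate([[0], breaks])
            ends = np.concatenate([breaks, [L]])
            orig = (rng.random(len(starts)) < theta_param[s]).astype(np.int8)
            for st, en, og in zip(starts, ends, orig):
                rows.append((s, h, config.chrom, int(st), int(en), int(og)))
            # tract of each panel position: pos is 1-based, tracts half-open 0-based
            origins[2 * s + h] = orig[np.searchsorted(breaks, panel.pos - 1, side="right")]
    tracts = pd.DataFrame(rows, columns=["sample", "hap", "chrom", "start", "end", "origin"])

    freq = np.where(origins == AFR, panel.freq_afr[None, :], panel.freq_eur[None, :])
    haps = (rng.random(freq.shape) < freq).astype(np.int8).T  # variants x 2n
    dosage = haps[:, 0::2] + haps[:, 1::2]

    theta = afr_tract_fraction(tracts)
    truth = SimTruth(
        seed=int(seed),
        theta=theta,
        theta_param=theta_param,
        tracts=tracts,
        genetic_fraction=float(config.genetic_fraction),
        env_fraction=float(config.env_fraction),
    )
    geno = GenotypeMatrix(
        variant_id=panel.variant_id.copy(),
        chrom=np.asarray(panel.chrom).copy(),
        pos=panel.pos.copy(),
        ref=np.asarray(panel.ref).copy(),
        alt=np.asarray(panel.alt).copy(),
        dosage=dosage.astype(float),
        sample_ids=[f"S{i:04d}" for i in range(n)],
        freq_afr=panel.freq_afr.copy(),
        freq_eur=panel.freq_eur.copy(),
        haplotypes=haps,
    )
    return geno, truth


def simulate_reference_genotypes(
    panel: AncestralPanel, n_samples: int, population: str, seed: int
) -> GenotypeMatrix:
    """Pure-ancestry reference cohort drawn site-independently under HWE."""
    rng = np.random.default_rng(seed)
    freq = panel.freq_afr if population.lower() == "afr" else panel.freq_eur
    dosage = rng.binomial(2, freq[:, None], (len(panel), n_samples)).astype(float)
    return GenotypeMatrix(
        variant_id=panel.variant_id.copy(),
        chrom=np.asarray(panel.chrom).copy(),
        pos=panel.pos.copy(),
        ref=np.asarray(panel.ref).copy(),
        alt=np.asarray(panel.alt).copy(),
        dosage=dosage,
        sample_ids=[f"{population.upper()}{i:04d}" for i in range(n_samples)],
        freq_afr=panel.freq_afr.copy(),
        freq_eur=panel.freq_eur.copy(),
    )


def simulate_aim_genotypes(panel: AncestralPanel, theta, seed: int) -> GenotypeMatrix:
    """Admixed genotypes at unlinked sites: dosage ~ Bin(2, theta*pA + (1-theta)*pE).

    Matches the global-ancestry estimator's model exactly; used to benchmark
    the estimator itself without tract noise.
    """
    rng = np.random.default_rng(seed)
    theta = np.atleast_1d(np.asarray(theta, float))
    q = theta[None, :] * panel.freq_afr[:, None] + (1 - theta[None, :]) * panel.freq_eur[:, None]
    dosage = rng.binomial(2, q).astype(float)
    return GenotypeMatrix(
        variant_id=panel.variant_id.copy(),
        chrom=np.asarray(panel.chrom).copy(),
        pos=panel.pos.copy(),
        ref=np.asarray(panel.ref).copy(),
        alt=np.asarray(panel.alt).copy(),
        dosage=dosage,
        sample_ids=[f"S{i:04d}" for i in range(len(theta))],
        freq_afr=panel.freq_afr.copy(),
        freq_eur=panel.freq_eur.copy(),
    )


def tract_posteriors(
    geno: GenotypeMatrix, truth: SimTruth, blur: float = 0.0, seed: int = 0
) -> np.ndarray:
    """Per-SNP per-haplotype African-ancestry 'posteriors' (variants x 2n).

    Hard 0/1 origins, optionally blurred toward the interior with Beta noise
    to emulate the soft posteriors a local-ancestry caller emits.
    """
    n = truth.theta.shape[0]
    post = np.empty((geno.n_variants, 2 * n))
    by_hap = truth.tracts.groupby(["sample", "hap"])
    for (s, h), tr in by_hap:
        breaks = tr["end"].to_numpy()[:-1]
        orig = tr["origin"].to_numpy()
        post[:, 2 * s + h] = orig[np.searchsorted(breaks, geno.pos - 1, side="right")]
    if blur > 0:
        rng = np.random.default_rng(seed)
        eps = rng.beta(1.0, max(1.0 / blur, 1.0), post.shape)
        post = np.abs(post - eps)
    return post


# --------------------------------------------------------------- expression
def _equicorrelated(rng, n_features, n_regions, rho):
    z0 = rng.standard_normal((n_features, 1))
    zr = rng.standard_normal((n_features, n_regions))
    return np.sqrt(rho) * z0 + np.sqrt(1.0 - rho) * zr


def _expected_delta_pst(e, u, b_gen, gram, sigma_n2, n_eff):
    """Closed-form expectation of delta-P_ST for a candidate env loading.

    ``gram`` is the 4x4 matrix of inner products of (theta, eps, G, M), each
    already residualized on the expression-model covariates; M is the
    exposure proxy residualized on (intercept, age, sex, local ancestry).
    The expression mean structure is (u+e)*theta + e*eps + b_gen*G plus iid
    noise of variance ``sigma_n2``; expected SSEs follow from projecting the
    mean structure onto the candidate regressors.
    """
    c = np.array([u + e, e, b_gen])
    A = gram[:3, :3]
    mu2 = c @ A @ c
    mu_th = c @ gram[:3, 0]
    mu_m = c @ gram[:3, 3]
    s_th, s_m, s_thm = gram[0, 0], gram[3, 3], gram[0, 3]
    sse0 = mu2 + n_eff * sigma_n2
    sse_th = mu2 - mu_th**2 / s_th + (n_eff - 1) * sigma_n2
    sse_m = mu2 - mu_m**2 / s_m + (n_eff - 1) * sigma_n2
    det = s_th * s_m - s_thm**2
    if det <= 1e-12 * s_th * s_m:
        return 0.0
    quad = (s_m * mu_th**2 - 2 * s_thm * mu_th * mu_m + s_th * mu_m**2) / det
    sse_thm = mu2 - quad + (n_eff - 2) * sigma_n2
    p0 = (sse0 - sse_th) / sse0
    p1 = (sse_m - sse_thm) / sse_m
    if p0 <= 0:
        return 0.0
    return 1.0 - p1 / p0


def _solve_env_loading(u, b_gen, gram, sigma_n2, n_eff, target):
    """Smallest non-negative e (signed with u) with expected delta-P_ST == target.

    Returns (e, fallback_flag); when the target is unreachable the loading
    falls back to the plain slope share target/(1-target)*u.
    """
    sign = 1.0 if u >= 0 else -1.0
    hi = 4.0 * (abs(u) + 1.0)
    xs = np.linspace(0.0, hi, 81)
    vals = np.array([
        _expected_delta_pst(sign * x, u, b_gen, gram, sigma_n2, n_eff) for x in xs
    ])
    above = np.where(vals >= target)[0]
    if above.size == 0:
        return sign * abs(u) * target / (1.0 - target), True
    j = above[0]
    if j == 0:
        return 0.0, False
    lo_x, hi_x = xs[j - 1], xs[j]
    for _ in range(40):  # bisection on the bracketing interval
        mid = 0.5 * (lo_x + hi_x)
        if _expected_delta_pst(sign * mid, u, b_gen, gram, sigma_n2, n_eff) < target:
            lo_x = mid
        else:
            hi_x = mid
    return sign * 0.5 * (lo_x + hi_x), False


def simulate_expression(geno: GenotypeMatrix, truth: SimTruth, config: SimConfig):
    """Simulate per-region negative-binomial counts with calibrated effects.

    Returns ``(expression_sets, covariates)`` — one
    :class:`~admixdeconv.exprstats.ExpressionSet` per region plus the sample
    covariate table (sex, age, qSV-like columns).  Ground-truth effects are
    written into ``truth``.

    Besides the ``n_features`` focal (ancestry-associated) features, the count
    matrices include ancestry-neutral background features so that library
    sizes are dominated by non-associated genes as in a real transcriptome;
    without them, the column sums would themselves carry a large ancestry
    slope and distort every CPM-normalized effect.
    """
    from .exprstats import ExpressionSet  # local import to avoid a cycle

    config.validate()
    rng = np.random.default_rng(truth.seed + 1)
    n, F, R = config.n_samples, config.n_features, config.n_regions
    Fn = config.n_null_features if config.n_null_features is not None else 4 * F
    F_tot = F + Fn
    theta = truth.theta

    # feature annotation: random TSSs, gene bodies on the + strand; focal
    # features are a random subset, the rest are ancestry-neutral background
    tss = _distinct_positions(rng, F_tot, 1, config.chrom_length_bp - 100_000)
    length = rng.integers(1_000, 50_000, F_tot)
    features = pd.DataFrame(
        {
            "feature_id": [f"gene{i:05d}" for i in range(F_tot)],
            "chrom": config.chrom,
            "start": tss,
            "end": tss + length,
            "strand": "+",
            "length_bp": length,
        }
    )
    focal_idx = np.sort(rng.choice(F_tot, size=F, replace=False))
    is_null = np.ones(F_tot, bool)
    is_null[focal_idx] = False
    tss_f = tss[focal_idx]

    # causal variant: the most ancestry-divergent variant in the cis window,
    # mirroring the elevated allele-frequency divergence of ancestry-DEG eQTLs
    afd = np.abs(np.asarray(geno.freq_afr) - np.asarray(geno.freq_eur))
    causal_idx = np.empty(F, int)
    for i in range(F):
        win = geno.window(config.chrom, int(tss_f[i]) - config.cis_window_bp,
                          int(tss_f[i]) + config.cis_window_bp)
        if win.size == 0 or afd[win].max() < config.min_causal_afd:
            raise ValueError(
                f"no usable causal variant within ±{config.cis_window_bp} bp of feature {i}"
            )
        causal_idx[i] = win[np.argmax(afd[win])]
    G = geno.dosage[causal_idx]  # F x n
    delta_p = (np.asarray(geno.freq_afr) - np.asarray(geno.freq_eur))[causal_idx]

    # per-feature environmental exposures, each correlated with ancestry;
    # exposures are idiosyncratic per gene so that no single environmental
    # direction dominates the methylation covariance (as with real exposures)
    v_t = max(np.var(theta), 1e-12)
    r2e = config.env_ancestry_r2
    sigma_eps = np.sqrt(v_t * (1 - r2e) / r2e) if r2e > 0 else np.inf
    E = theta[None, :] + (
        rng.standard_normal((F, n)) * sigma_eps if np.isfinite(sigma_eps) else 0.0
    )

    # nuisance covariates
    sex = rng.integers(0, 2, n).astype(float)
    age = rng.normal(50, 15, n)
    qsv = rng.standard_normal((n, config.n_qsvs))
    covariates = pd.DataFrame({"sample_id": geno.sample_ids, "sex": sex, "age": age})
    for k in range(config.n_qsvs):
        covariates[f"qsv{k + 1}"] = qsv[:, k]
    sex_eff = rng.normal(0, 0.3, F_tot)
    age_eff = rng.normal(0, 0.01, F_tot)
    qsv_eff = rng.normal(0, 0.3, (F_tot, config.n_qsvs))

    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, F_tot)
    dispersion = np.exp(
        rng.normal(config.dispersion_log_mean, config.dispersion_log_sd, F_tot)
    )

    gf, ef, tau = config.genetic_fraction, config.env_fraction, config.effect_sd
    rho = config.effect_sharing_correlation
    fallbacks = 0
    if config.cis_h2 is not None:
        # pure eQTL benchmarking mode: only the causal cis effect, sized to h2
        h2 = float(config.cis_h2)
        g_sd = np.std(G, axis=1, ddof=1)
        g_sd[g_sd == 0] = 1.0
        b_gen = (np.sign(rng.standard_normal((F, 1))) *
                 config.noise_sd * np.sqrt(h2 / (1 - h2)) / g_sd[:, None])
        b_gen = np.repeat(b_gen, R, axis=1)
        b_dir = np.zeros((F, R)); b_env = np.zeros((F, R))
        beta_f = b_gen * (2 * delta_p[:, None])
    else:
        # ancestry-effect decomposition (see module docstring)
        sd_u = tau * (1.0 - ef)
        g = _equicorrelated(rng, F, R, rho) * sd_u * np.sqrt(gf)
        d = _equicorrelated(rng, F, R, rho) * sd_u * np.sqrt(1.0 - gf)
        u = g + d
        # DEG-ascertainment floor: rescale features whose mean |effect| falls
        # below the detectable tail (preserves signs and the g/d split)
        mean_abs = np.abs(u).mean(axis=1, keepdims=True)
        scale = np.maximum(1.0, config.min_ancestry_effect / np.maximum(mean_abs, 1e-9))
        g, d, u = g * scale, d * scale, u * scale
        b_dir = d
        dp = np.where(np.abs(delta_p) < 1e-9, np.nan, 2 * delta_p)
        b_gen = g / dp[:, None]

        # solve the env loading per feature x region against the closed-form
        # delta-P_ST expectation (see module docstring)
        Xc = np.column_stack([np.ones(n), sex, age, qsv])
        beta_c, *_ = np.linalg.lstsq(Xc, np.column_stack([theta]), rcond=None)
        th_p = theta - (Xc @ beta_c)[:, 0]
        # local ancestry (diploid AFR fraction) at each focal TSS from the tracts
        la_tss = np.zeros((F, n))
        for (smp, hap), tr in truth.tracts.groupby(["sample", "hap"]):
            breaks = tr["end"].to_numpy()[:-1]
            orig = tr["origin"].to_numpy()
            la_tss[:, smp] += orig[np.searchsorted(breaks, tss_f - 1, side="right")] / 2.0
        eps = E - theta[None, :]
        mu_count = np.exp2(baseline[focal_idx])
        sigma_n2 = config.noise_sd**2 + (1.0 / np.log(2.0)) ** 2 * (
            dispersion[focal_idx] + 1.0 / np.maximum(mu_count, 1.0)
        )
        n_eff = n - Xc.shape[1]
        b_env = np.zeros((F, R))
        for i in range(F):
            D = np.column_stack([np.ones(n), age, sex, la_tss[i]])
            exposure = theta + eps[i]
            bD, *_ = np.linalg.lstsq(D, exposure[:, None], rcond=None)
            M = exposure - (D @ bD)[:, 0]
            vecs = np.column_stack([
                th_p,
                eps[i] - Xc @ np.linalg.lstsq(Xc, eps[i], rcond=None)[0],
                G[i] - Xc @ np.linalg.lstsq(Xc, G[i], rcond=None)[0],
                M - Xc @ np.linalg.lstsq(Xc, M, rcond=None)[0],
            ])
            gram = vecs.T @ vecs
            for r in range(R):
                e_ir, fb = _solve_env_loading(
                    u[i, r], b_gen[i, r], gram, sigma_n2[i], n_eff, ef
                ) if ef > 0 else (0.0, False)
                b_env[i, r] = e_ir
                fallbacks += fb
        beta_f = u + b_env
        if fallbacks:
            warnings.warn(
                f"env loading fell back to the slope-share value for {fallbacks} "
                "feature-region pairs (target delta-P_ST unreachable)"
            )

    sets = []
    for r in range(R):
        latent = (
            baseline[:, None]
            + sex_eff[:, None] * sex[None, :]
            + age_eff[:, None] * (age - 50)[None, :]
            + qsv_eff @ qsv.T
            + (rng.standard_normal((F_tot, n)) * config.noise_sd
               if config.noise_sd > 0 else 0.0)
        )
        latent[focal_idx] += (
            b_dir[:, r][:, None] * theta[None, :]
            + b_gen[:, r][:, None] * G
            + b_env[:, r][:, None] * E
        )
        libfac = np.exp(rng.normal(0, config.library_size_log_sd, n))
        mu = np.exp2(np.clip(latent, -5, 26)) * libfac[None, :]
        if config.noise_sd == 0 and config.cis_h2 is None:
            counts = np.rint(mu).astype(np.int64)  # deterministic limit
        else:
            size = 1.0 / dispersion[:, None]
            p = size / (size + mu)
            counts = rng.negative_binomial(size, p).astype(np.int64)
        sets.append(
            ExpressionSet(
                counts=counts,
                features=features.copy(),
                sample_ids=list(geno.sample_ids),
                region=f"region{r + 1}",
            )
        )

    def expand(arr):
        full = np.zeros((F_tot, R))
        full[focal_idx] = arr
        return full

    causal_full = np.full(F_tot, "", dtype=object)
    causal_full[focal_idx] = geno.variant_id[causal_idx]
    truth.features = features
    truth.beta_true = expand(beta_f)
    truth.b_gen = expand(b_gen)
    truth.b_env = expand(b_env)
    truth.b_dir = expand(b_dir)
    truth.causal_variant = causal_full
    truth.env_factor = E
    truth.focal_idx = focal_idx
    truth.is_null = is_null
    truth.covariates = covariates
    return sets, covariates


# -------------------------------------------------------------- methylation
def simulate_methylation(truth: SimTruth, config: SimConfig, return_latent: bool = False):
    """WGBS-like CpG counts: clusters near gene TSSs carry the E factor.

    One CpG cluster per simulated gene loads on the environmental factor E
    (these are the ground-truth VMRs) on top of a local-ancestry effect and
    shared batch factors; background clusters carry batch and local-ancestry
    signal only.  Read depth is Poisson, methylated reads Binomial around a
    logistic latent level.
    """
    from .methylvar import CpGTable

    if config.mean_depth < 1:
        raise ValueError("mean methylation depth must be at least 1")
    if truth.features is None:
        raise ValueError("simulate_expression must run before simulate_methylation")
    rng = np.random.default_rng(truth.seed + 2)
    n = len(truth.theta)
    focal = truth.focal_idx if truth.focal_idx is not None else np.arange(len(truth.features))
    F = len(focal)
    spacing, k = config.cpg_spacing_bp, config.cpgs_per_cluster
    n_bg = (
        config.n_background_clusters
        if config.n_background_clusters is not None
        else 99 * F
    )

    starts = truth.features["start"].to_numpy()[focal]
    bg_starts = _distinct_positions(rng, n_bg, 1, config.chrom_length_bp - k * spacing)
    cluster_start = np.concatenate([starts, bg_starts])
    is_env = np.concatenate([np.ones(F, bool), np.zeros(n_bg, bool)])
    gene_of = np.concatenate([np.arange(F), np.full(n_bg, -1)])  # focal order
    order = np.argsort(cluster_start, kind="stable")
    cluster_start, is_env, gene_of = cluster_start[order], is_env[order], gene_of[order]
    n_clusters = len(cluster_start)

    # per-sample local African dosage fraction at each cluster midpoint
    mid = cluster_start + (k // 2) * spacing
    local = np.zeros((n_clusters, n))
    by_hap = truth.tracts.groupby(["sample", "hap"])
    for (s, h), tr in by_hap:
        breaks = tr["end"].to_numpy()[:-1]
        orig = tr["origin"].to_numpy()
        local[:, s] += orig[np.searchsorted(breaks, mid, side="right")] / 2.0

    # each gene cluster tracks its gene's own exposure (standardized)
    E = np.atleast_2d(truth.env_factor)
    Ec = (E - E.mean(axis=1, keepdims=True)) / np.maximum(
        E.std(axis=1, keepdims=True), 1e-12
    )
    exposure = np.zeros((n_clusters, n))
    exposure[is_env] = Ec[gene_of[is_env]]
    env_load = np.where(
        is_env,
        rng.choice([-1.0, 1.0], n_clusters) * np.abs(rng.normal(config.meth_env_loading, 0.3, n_clusters)),
        0.0,
    )
    la_eff = rng.normal(0, config.meth_local_ancestry_sd, n_clusters)
    batch = rng.standard_normal((config.n_meth_batch_factors, n))
    batch_load = rng.normal(0, config.meth_batch_loading_sd,
                            (n_clusters, config.n_meth_batch_factors))
    base_cluster = rng.normal(0, 0.8, n_clusters)

    cluster_logit = (
        base_cluster[:, None]
        + la_eff[:, None] * (local - local.mean(axis=1, keepdims=True))
        + env_load[:, None] * exposure
        + batch_load @ batch
    ).astype(np.float32)

    n_cpgs = n_clusters * k
    pos_all = (cluster_start[:, None] + np.arange(k)[None, :] * spacing).reshape(-1)
    cpg_base = rng.normal(0, 0.3, n_cpgs).astype(np.float32)
    logit = np.repeat(cluster_logit, k, axis=0)
    logit += cpg_base[:, None]
    logit += rng.normal(0, config.meth_cpg_noise_sd, (n_cpgs, n)).astype(np.float32)
    prob = expit(logit)
    depth = rng.poisson(config.mean_depth, (n_cpgs, n)).astype(np.int32)
    meth = rng.binomial(depth, prob).astype(np.int32)

    order = np.argsort(pos_all, kind="stable")
    table = CpGTable(
        chrom=np.repeat(config.chrom, n_cpgs),
        pos=pos_all[order],
        meth=meth[order],
        total=depth[order],
        sample_ids=[f"S{i:04d}" for i in range(n)],
    )
    truth.vmr_truth = pd.DataFrame(
        {
            "chrom": config.chrom,
            "start": cluster_start,
            "end": cluster_start + (k - 1) * spacing + 1,
            "env_loading": env_load,
            "is_env": is_env,
            "gene_index": gene_of,
        }
    )
    if return_latent:
        return table, prob[order]
    return table
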