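"""Configuration-driven end-to-end orchestration with a provenance manifest.

Runs simulate -> ancestry -> per-region differential expression -> shrinkage
-> cis-eQTL (+ shrinkage) -> genotype prediction -> methylation/P_ST ->
sharing, writing every stage's tables under the output directory and a JSON
manifest recording parameters, input digests and per-stage row counts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import ancestry as anc
from . import cis_qtl, genpred, mashlite, methylvar, popshare, simgen
from . import exprstats as es

logger = logging.getLogger("admixdeconv")

STAGES = ["simulate", "ancestry", "de", "mash", "eqtl", "predict", "methyl", "share"]


@dataclass
class RunConfig:
    out_dir: str
    seed: int = 1
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    sim: simgen.SimConfig = field(default_factory=simgen.SimConfig)
    window_kb: float = 500.0
    lfsr_cut: float = 0.05
    n_perms: int = 200
    mash_subset_frac: float | None = None
    elastic_net_folds: int = 5

    @classmethod
    def from_toml(cls, path: str) -> "RunConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        sim_raw = raw.pop("sim", {})
        if "theta_beta_params" in sim_raw:
            sim_raw["theta_beta_params"] = tuple(sim_raw["theta_beta_params"])
        cfg = cls(**{k: v for k, v in raw.items() if k in {f.name for f in dataclasses.fields(cls)}})
        cfg.sim = simgen.SimConfig(**sim_raw)
        return cfg

    def validate(self) -> None:
        self.sim.validate()
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if self.seed is None:
            raise ValueError("every stochastic stage needs an explicit seed")


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_all(config: RunConfig) -> dict:
    """Execute the configured stages; returns (and writes) the run manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.StreamHandler(sys.stderr)
    logger.addHandler(handler)
    logfile = logging.FileHandler(out / "run.log")
    logger.addHandler(logfile)
    logger.setLevel(logging.INFO)

    manifest: dict = {"stages": {}, "parameters": {"seed": config.seed}, "outputs": {}}
    state: dict = {}
    try:
        for stage in STAGES:
            if stage not in config.stages:
                continue
            logger.info("stage %s", stage)
            rows = _STAGE_FUNCS[stage](config, state, out)
            manifest["stages"][stage] = {"rows": rows}
    except Exception as exc:  # abort with stage name and partial manifest
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        logger.removeHandler(handler)
        logger.removeHandler(logfile)
        logfile.close()
        raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc

    for f in sorted(out.glob("*.tsv")) + sorted(out.glob("*.vcf")) + sorted(out.glob("*.json")):
        if f.name != "manifest.json":
            manifest["outputs"][f.name] = _digest(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    logger.removeHandler(handler)
    logger.removeHandler(logfile)
    logfile.close()
    return manifest


# ------------------------------------------------------------------ stages
def _stage_simulate(config: RunConfig, state: dict, out: Path) -> int:
    panel = simgen.simulate_panel(config.sim, config.seed)
    geno, truth = simgen.simulate_genotypes(panel, config.sim, config.seed + 10)
    sets, covariates = simgen.simulate_expression(geno, truth, config.sim)
    cpgs = simgen.simulate_methylation(truth, config.sim)
    state.update(panel=panel, geno=geno, truth=truth, sets=sets,
                 covariates=covariates, cpgs=cpgs)
    panel.to_tsv(out / "panel.tsv")
    geno.write_vcf(str(out / "genotypes.vcf"))
    for s in sets:
        s.to_tsv(out / f"counts.{s.region}.tsv")
    covariates.to_csv(out / "covariates.tsv", sep="\t", index=False)
    cpgs.to_tsv(out / "cpgs.tsv")
    truth.to_json(str(out / "truth.json"))
    return len(geno.variant_id)


def _stage_ancestry(config: RunConfig, state: dict, out: Path) -> int:
    panel, geno, truth = state["panel"], state["geno"], state["truth"]
    ref = {
        "afr": simgen.simulate_reference_genotypes(panel, 100, "afr", config.seed + 20),
        "eur": simgen.simulate_reference_genotypes(panel, 100, "eur", config.seed + 21),
    }
    aims = anc.select_aims(panel, ref)
    table = anc.estimate_global_ancestry(geno, panel, aims) if aims else None
    if table is None:
        raise RuntimeError("no AIMs selected")
    table.to_csv(out / "global_ancestry.tsv", sep="\t", index=False)
    post = simgen.tract_posteriors(geno, truth)
    local = anc.local_ancestry_feature_score(
        post, geno.chrom, geno.pos, truth.features, geno.sample_ids
    )
    local.to_csv(out / "local_ancestry.tsv", sep="\t", index=False)
    state.update(ancestry=table, local=local, aims=aims)
    return len(table)


def _covariate_cols(covariates: pd.DataFrame) -> np.ndarray:
    return covariates[[c for c in covariates.columns if c != "sample_id"]].to_numpy(float)


def _stage_de(config: RunConfig, state: dict, out: Path) -> int:
    covs = _covariate_cols(state["covariates"])
    theta = state["ancestry"]["theta_hat"].to_numpy()
    fits = {}
    for s in state["sets"]:
        fits[s.region] = es.fit_ancestry_de(s, theta, covs)
    effects = es.EffectMatrix.from_regions(fits)
    effects.write(str(out / "de_effects"))
    state["effects"] = effects
    return effects.beta.shape[0]


def _stage_mash(config: RunConfig, state: dict, out: Path) -> int:
    fit, posterior = mashlite.run_mash(
        state["effects"], random_subset_frac=config.mash_subset_frac, seed=config.seed + 30
    )
    posterior.write(str(out / "de_mash"))
    state.update(mash_fit=fit, posterior=posterior)
    return posterior.lfsr.shape[0]


def _stage_eqtl(config: RunConfig, state: dict, out: Path) -> int:
    covs = _covariate_cols(state["covariates"])
    theta = state["ancestry"]["theta_hat"].to_numpy()
    geno = state["geno"]
    all_nominal = []
    for s in state["sets"]:
        resid, keep = es.residualize(s, covs)
        nominal = cis_qtl.map_cis_nominal(
            resid, s.features.loc[keep].reset_index(drop=True), geno,
            covariates=None, window_kb=config.window_kb,
        )
        nominal["region"] = s.region
        all_nominal.append(nominal)
        inter = cis_qtl.map_cis_nominal(
            resid, s.features.loc[keep].reset_index(drop=True), geno,
            covariates=None, window_kb=config.window_kb, mode="interaction",
            ancestry=theta,
        )
        inter["region"] = s.region
        all_nominal.append(inter)
    nominal = pd.concat(all_nominal, ignore_index=True)
    nominal.to_csv(out / "eqtl_nominal.tsv", sep="\t", index=False)

    # shrinkage across regions of the per-feature top main-effect association
    main = nominal[nominal["mode"] == "main"]
    top = (
        main.sort_values("p_nominal", kind="stable")
        .groupby(["feature_id", "region"], as_index=False)
        .first()
    )
    pair_beta = top.pivot(index="feature_id", columns="region", values="beta")
    pair_se = top.pivot(index="feature_id", columns="region", values="se")
    effects = es.EffectMatrix(beta=pair_beta, se=pair_se).complete_cases()
    if effects.beta.shape[0] >= 5:
        _, posterior = mashlite.run_mash(effects, seed=config.seed + 40)
        posterior.write(str(out / "eqtl_mash"))
        state["eqtl_posterior"] = posterior
    state["eqtl_nominal"] = nominal
    return len(nominal)


def _stage_predict(config: RunConfig, state: dict, out: Path) -> int:
    geno, truth = state["geno"], state["truth"]
    covs = _covariate_cols(state["covariates"])
    theta = state["ancestry"]["theta_hat"].to_numpy()
    s = state["sets"][0]
    resid, keep = es.residualize(s, covs, scale=False)
    features = s.features.loc[keep].reset_index(drop=True)
    w = int(config.window_kb * 1000)
    models, preds = [], []
    for i, row in enumerate(features.itertuples(index=False)):
        idx = geno.window(row.chrom, row.start - w, row.end + w)
        model = genpred.fit_elastic_net(
            row.feature_id, geno.dosage[idx], geno.variant_id[idx], resid[i],
            k_folds=config.elastic_net_folds, seed=config.seed + 50 + i,
        )
        models.append(model)
        preds.append(model.predict(geno.dosage[idx]) if model.weights.size else
                     np.zeros(resid.shape[1]))
    genpred.models_to_frame(models).to_csv(out / "prediction_models.tsv", sep="\t", index=False)
    observed = state["posterior"].post_mean.iloc[:, 0]
    common = [i for i, f in enumerate(features["feature_id"]) if f in observed.index]
    ve = genpred.ancestry_effect_variance_explained(
        np.asarray(preds)[common], theta, covs,
        observed.loc[features["feature_id"].iloc[common]].to_numpy(),
        region=s.region,
    )
    pd.DataFrame([dataclasses.asdict(ve)]).to_csv(
        out / "variance_explained.tsv", sep="\t", index=False
    )
    state["variance_explained"] = ve
    return len(models)


def _stage_methyl(config: RunConfig, state: dict, out: Path) -> int:
    truth, cpgs = state["truth"], state["cpgs"]
    theta = state["ancestry"]["theta_hat"].to_numpy()
    covs = _covariate_cols(state["covariates"])
    covariates = state["covariates"]
    table = methylvar.coverage_filter(cpgs)
    table = methylvar.smooth_methylation(table)
    sel = methylvar.select_variable_cpgs(table, theta)
    vmrs = methylvar.call_vmrs(table, sel)
    if len(vmrs) == 0:
        raise RuntimeError("no VMRs called")
    pcs = methylvar.methylation_pcs(table.smoothed)
    dmr = methylvar.fit_dmr(vmrs, theta, covariates["age"], covariates["sex"], pcs)
    dmr.to_csv(out / "dmr.tsv", sep="\t", index=False)
    post = simgen.tract_posteriors(state["geno"], truth)
    vmr_feats = pd.DataFrame(
        {
            "feature_id": [f"vmr{i}" for i in range(len(vmrs))],
            "chrom": vmrs.regions["chrom"],
            "start": vmrs.regions["start"],
            "end": vmrs.regions["end"],
        }
    )
    la_vmr = anc.local_ancestry_feature_score(
        post, state["geno"].chrom, state["geno"].pos, vmr_feats, state["geno"].sample_ids
    )[state["geno"].sample_ids].to_numpy()
    resid_vmr = methylvar.residualize_vmr_levels(
        vmrs, la_vmr, covariates["age"], covariates["sex"], pcs
    )
    gene_vmrs = methylvar.annotate_vmrs_to_genes(vmrs, truth.features)
    s = state["sets"][0]
    y = s.log2_cpm()
    rows = []
    fid_to_row = {f: i for i, f in enumerate(s.features["feature_id"])}
    for fid, vidx in gene_vmrs.items():
        i = fid_to_row[fid]
        p0 = methylvar.pst(y[i], theta, covs)
        if p0 <= 0:
            continue
        p1 = methylvar.pst(y[i], theta, covs, vmr_covariates=resid_vmr[vidx].T)
        rows.append((fid, p0, p1, methylvar.delta_pst(p0, p1), len(vidx)))
    pst_table = pd.DataFrame(
        rows, columns=["gene_id", "pst", "pst_vmr", "delta_pst", "n_vmrs_used"]
    )
    pst_table.to_csv(out / "pst.tsv", sep="\t", index=False)
    state["pst"] = pst_table
    return len(pst_table)


def _stage_share(config: RunConfig, state: dict, out: Path) -> int:
    sharing = popshare.pairwise_sharing(state["posterior"], lfsr_cut=config.lfsr_cut)
    sharing.sign_match.to_csv(out / "sharing_sign.tsv", sep="\t")
    sharing.magnitude_share.to_csv(out / "sharing_magnitude.tsv", sep="\t")
    sig = mashlite.significant_features(state["posterior"], config.lfsr_cut)
    regions = [r for r in sig if r != "union"]
    universe = set(state["posterior"].lfsr.index)
    mc = popshare.monte_carlo_overlap(
        [sig[r] for r in regions], universe, n_draws=10_000, seed=config.seed + 60
    )
    (out / "overlap.json").write_text(json.dumps({**mc, "counts": sharing.overlap_counts}))
    return len(universe)


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "ancestry": _stage_ancestry,
    "de": _stage_de,
    "mash": _stage_mash,
    "eqtl": _stage_eqtl,
    "predict": _stage_predict,
    "methyl": _stage_methyl,
    "share": _stage_share,
}
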