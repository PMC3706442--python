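"""End-to-end orchestration: simulate -> QC -> transforms -> twin /
GRM+GREML / GWA -> power -> report, driven by a YAML config.

Every stage writes plain-text tables under the configured output
directory, and a run manifest (seed, thresholds, per-filter counts)
accompanies the outputs so a run is fully reconstructible.
"""

from __future__ import annotations

import json
import os
import platform

import numpy as np
import pandas as pd
import yaml

from . import __version__, io, qc, transforms
from .assoc import apply_genomic_control, fit_longitudinal_null, longitudinal_scan, qq_data, manhattan_data
from .grm import compute_grm, prune_unrelated, reml_h2
from .power import power_table
from .simulate import (
    GenoSimConfig,
    PhenoSimConfig,
    TwinSimConfig,
    simulate_genotypes,
    simulate_longitudinal_phenotypes,
    simulate_twins,
)
from .twin import compare_models, fit_twin_model, twin_correlations

__all__ = ["DEFAULT_CONFIG", "load_config", "run_pipeline", "DependencyError"]


class DependencyError(RuntimeError):
    """A stage's upstream artifact is missing."""


#: Defaults follow the study design where a stated value exists (QC
#: thresholds, relatedness cutoff, 8 PCs, significance tiers); the
#: simulation block defaults are the desk-scale study conditions.
DEFAULT_CONFIG = {
    "seed": 0,
    "out_dir": "triherit_out",
    "stages": ["simulate", "qc", "transform", "twin", "grm", "greml", "gwas", "power", "report"],
    "simulate": {
        "twins": {"n_mz_pairs": 1099, "n_dz_pairs": 1787, "a2": 0.64, "c2": 0.0, "e2": 0.36},
        "genotypes": {"n_individuals": 1000, "n_snps": 20000, "maf_range": [0.05, 0.5],
                      "n_subpops": 1, "fst": 0.0, "missing_rate": 0.005},
        "phenotypes": {"n_causal": 500, "h2_snp": 0.2, "cross_age_corr": 0.5,
                       "beta_covariates": [0.1, 0.05], "missing_rates": [0.2, 0.3, 0.6]},
    },
    "qc": {"info_min": 0.975, "maf_min": 0.01, "missing_max": 0.02,
           "hwe_p_min": 1e-20, "plate_p_min": 1e-6,
           "imputed_info_min": 0.98, "array2_info_min": 0.90,
           "call_rate_min": 0.97, "het_z_max": 3.0, "ibd_max": 0.05,
           "ld_r2_max": 0.2, "n_pcs": 8},
    "greml": {"relatedness_cutoff": 0.025},
    "gwas": {"genomewide_p": 5e-8, "suggestive_p": 5e-6},
    "power": {"n": [2930], "q2": [0.010, 0.013], "alpha": [5e-8]},
}


def load_config(path: str | None = None, overrides: dict | None = None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        _deep_update(cfg, user)
    if overrides:
        _deep_update(cfg, overrides)
    return cfg


def _deep_update(base: dict, extra: dict) -> None:
    for k, v in extra.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _deep_update(base[k], v)
        else:
            base[k] = v


def run_pipeline(config: dict) -> dict:
    """Execute the enabled stages in dependency order.

    Returns the manifest dict (also written to ``manifest.json``).
    Raises :class:`DependencyError` when a stage's input is missing.
    """
    out_dir = config["out_dir"]
    os.makedirs(out_dir, exist_ok=True)
    stages = config["stages"]
    seed = int(config["seed"])
    manifest: dict = {
        "package": "triherit",
        "version": __version__,
        "python": platform.python_version(),
        "seed": seed,
        "stages": stages,
        "thresholds": config.get("qc", {}),
        "counts": {},
    }
    state: dict = {}

    if "simulate" in stages:
        sim = config["simulate"]
        twins = simulate_twins(TwinSimConfig(seed=seed, **sim["twins"]))
        geno_cfg = dict(sim["genotypes"])
        geno_cfg["maf_range"] = tuple(geno_cfg.get("maf_range", (0.05, 0.5)))
        panel = simulate_genotypes(GenoSimConfig(seed=seed + 1, **geno_cfg))
        pheno_cfg = dict(sim["phenotypes"])
        for key in ("beta_covariates", "missing_rates"):
            if key in pheno_cfg:
                pheno_cfg[key] = tuple(pheno_cfg[key])
        pheno = simulate_longitudinal_phenotypes(
            panel, PhenoSimConfig(seed=seed + 2, **pheno_cfg)
        )
        io.write_panel(panel, pheno, out_dir, twins=twins)
        state.update(panel=panel, pheno=pheno, twins=twins)
        manifest["counts"]["simulated_snps"] = panel.n_snps
        manifest["counts"]["simulated_samples"] = panel.n_samples

    def _need(key, stage):
        if key not in state:
            path_guess = {
                "panel": os.path.join(out_dir, "dosages.tsv"),
                "pheno": os.path.join(out_dir, "phenotypes.tsv"),
                "twins": os.path.join(out_dir, "twins.tsv"),
            }[key]
            if os.path.exists(path_guess):
                loader = {
                    "panel": io.read_dosage_tsv,
                    "pheno": io.read_phenotypes,
                    "twins": io.read_twins,
                }[key]
                state[key] = loader(path_guess)
            else:
                raise DependencyError(
                    f"stage {stage!r} requires {key!r} but neither an upstream "
                    f"stage nor {path_guess} provides it"
                )
        return state[key]

    if "qc" in stages:
        panel = _need("panel", "qc")
        qcfg = config["qc"]
        snp_t = qc.SnpQCThresholds(
            **{k: qcfg[k] for k in ("info_min", "maf_min", "missing_max", "hwe_p_min",
                                    "plate_p_min", "imputed_info_min", "array2_info_min")}
        )
        snp_report = qc.snp_filter(panel, snp_t)
        panel = panel.subset_snps(
            panel.snps["snp"].isin(snp_report.kept).to_numpy()
        )
        grm_full = compute_grm(panel)
        sample_t = qc.SampleQCThresholds(
            call_rate_min=qcfg["call_rate_min"], het_z_max=qcfg["het_z_max"],
            ibd_max=qcfg["ibd_max"],
        )
        sample_report = qc.sample_filter(panel, sample_t, grm=grm_full)
        panel = panel.subset_samples(sample_report.kept)
        state["panel"] = panel
        if "pheno" in state:
            state["pheno"] = (
                state["pheno"].set_index("id").loc[panel.ids].reset_index()
            )
        snp_report.items.to_csv(os.path.join(out_dir, "qc_snps.tsv"), sep="\t", index=False)
        sample_report.items.to_csv(os.path.join(out_dir, "qc_samples.tsv"), sep="\t", index=False)
        manifest["counts"]["snp_filter"] = snp_report.counts
        manifest["counts"]["snp_removed_fraction"] = round(snp_report.fraction_removed, 6)
        manifest["counts"]["sample_filter"] = sample_report.counts

        kept_ld = qc.ld_prune(panel, r2_max=qcfg["ld_r2_max"])
        pruned = panel.subset_snps(panel.snps["snp"].isin(kept_ld).to_numpy())
        pcs, eigenvalues = qc.pca(pruned, k=qcfg["n_pcs"])
        n_sig = qc.tracy_widom_count(eigenvalues, pruned.n_samples, pruned.n_snps)
        state["pcs"] = pcs
        manifest["counts"]["ld_pruned_snps"] = len(kept_ld)
        manifest["counts"]["tw_significant_pcs"] = n_sig
        pc_df = pd.DataFrame(pcs, columns=[f"PC{i+1}" for i in range(pcs.shape[1])])
        pc_df.insert(0, "id", panel.ids)
        pc_df.to_csv(os.path.join(out_dir, "pca.tsv"), sep="\t", index=False)

    if "transform" in stages:
        pheno = _need("pheno", "transform")
        for age in (7, 9, 12):
            pheno[f"z{age}"] = transforms.van_der_waerden(pheno[f"y{age}"])
        pheno["composite"] = transforms.composite_mean(
            pheno["y7"], pheno["y9"], pheno["y12"]
        )
        state["pheno"] = pheno
        io.write_phenotypes(
            pheno, os.path.join(out_dir, "phenotypes_transformed.tsv"),
            header_note=f"transform=van_der_waerden+composite seed={seed}",
        )

    if "twin" in stages:
        twins = _need("twins", "twin")
        corr = twin_correlations(twins)
        fits = {m: fit_twin_model(twins, m) for m in ("ACE", "AE", "E")}
        cmp_ae = compare_models(fits["ACE"], fits["AE"])
        rows = []
        for m, f in fits.items():
            rows.append({"model": m, **{k.upper(): v for k, v in f.estimates.items()},
                         "minus2LL": f.minus2ll, "df": f.df, "AIC": f.aic})
        table = pd.DataFrame(rows)
        table.to_csv(os.path.join(out_dir, "twin_models.tsv"), sep="\t", index=False)
        pd.DataFrame([{
            "rMZ": corr.r_mz, "SE_MZ": corr.se_mz, "nMZ": corr.n_mz,
            "rDZ": corr.r_dz, "SE_DZ": corr.se_dz, "nDZ": corr.n_dz,
        }]).to_csv(os.path.join(out_dir, "twin_correlations.tsv"), sep="\t", index=False)
        manifest["twin"] = {
            "r_mz": corr.r_mz, "r_dz": corr.r_dz,
            "ACE": fits["ACE"].estimates, "AE_vs_ACE": cmp_ae,
        }
        state["twin_fits"] = fits

    if "grm" in stages or "greml" in stages:
        panel = _need("panel", "grm")
        grm = compute_grm(panel)
        io.write_grm(grm, os.path.join(out_dir, "cohort"))
        state["grm"] = grm

    if "greml" in stages:
        pheno = _need("pheno", "greml")
        grm = state["grm"]
        if "composite" not in pheno.columns:
            pheno["composite"] = transforms.composite_mean(
                pheno["y7"], pheno["y9"], pheno["y12"]
            )
        kept = prune_unrelated(grm, cutoff=config["greml"]["relatedness_cutoff"])
        keep_idx = [grm.ids.index(i) for i in kept]
        sub = state["panel"].subset_samples(kept)
        grm_u = compute_grm(sub)
        ph = pheno.set_index("id").loc[kept]
        covs = [ph["sex"].to_numpy(dtype=float), ph["cohort"].to_numpy(dtype=float)]
        if "pcs" in state:
            covs.append(np.asarray(state["pcs"])[keep_idx])
        C = np.column_stack(covs)
        fit = reml_h2(ph["composite"].to_numpy(dtype=float), C, grm_u)
        pd.DataFrame([{
            "h2_snp": fit.h2_snp, "se": fit.se, "sigma_g2": fit.sigma_g2,
            "sigma_e2": fit.sigma_e2, "logLik_restricted": fit.loglik_restricted,
            "n": fit.n_used,
        }]).to_csv(os.path.join(out_dir, "greml.tsv"), sep="\t", index=False)
        manifest["greml"] = {"h2_snp": fit.h2_snp, "se": fit.se, "n": fit.n_used}
        manifest["counts"]["greml_unrelated"] = len(kept)

    if "gwas" in stages:
        panel = _need("panel", "gwas")
        pheno = _need("pheno", "gwas")
        zcols = [c for c in ("z7", "z9", "z12") if c in pheno.columns]
        ycols = zcols if len(zcols) == 3 else ["y7", "y9", "y12"]
        Y = pheno[ycols].to_numpy(dtype=float)
        # admissibility: at least one age measured
        keep = ~np.isnan(Y).all(axis=1)
        Y = Y[keep]
        pheno = pheno.loc[keep]
        panel = panel.subset_samples([i for i, k in zip(panel.ids, keep) if k])
        covs = [pheno["sex"].to_numpy(dtype=float), pheno["cohort"].to_numpy(dtype=float)]
        if "pcs" in state:
            covs.append(np.asarray(state["pcs"])[keep])
        C = np.column_stack(covs)
        manifest["counts"]["gwas_samples"] = int(keep.sum())
        null = fit_longitudinal_null(Y, C)
        results = longitudinal_scan(panel, Y, C, null=null)
        results, gc_results = apply_genomic_control(results)
        results.to_csv(os.path.join(out_dir, "gwas.tsv"), sep="\t", index=False)
        qq = qq_data(results["p_gc"].dropna())
        qq.to_csv(os.path.join(out_dir, "qq.tsv"), sep="\t", index=False)
        man = manhattan_data(results.dropna(subset=["p_gc"]))
        man.to_csv(os.path.join(out_dir, "manhattan.tsv"), sep="\t", index=False)
        manifest["gwas"] = {
            "lambda": {g.stratum: g.lambda_gc for g in gc_results},
            "n_genomewide": int((results["tier"] == "genomewide").sum()),
            "n_suggestive": int((results["tier"] == "suggestive").sum()),
        }

    if "power" in stages:
        pw = config["power"]
        table = power_table(pw["n"], pw["q2"], pw["alpha"])
        table.to_csv(os.path.join(out_dir, "power.tsv"), sep="\t", index=False)
        manifest["power"] = table.to_dict(orient="records")

    if "report" in stages:
        with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, default=_jsonable)

    return manifest


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    raise TypeError(f"not JSON serializable: {type(x)}")
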