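"""End-to-end orchestration: simulate (optional) -> SDM per species ->
germination statistics -> trait-environment linkage, with one JSON report
carrying every number needed to re-render the model, germination, and
PLSR summary tables."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, germination, linkage, sdm, simulate
from .grid import trend_surface_ysp

DEFAULT_THRESHOLDS = {"fdr_q": 0.05, "r_max": 0.8, "alpha": 0.05,
                      "threshold": 0.5, "vip_cut": 1.0}


def run_all(config: dict, out_dir: str | Path | None = None) -> dict:
    """Run every stage; deterministic given config['seed'].

    ``config`` keys: seed (int); simulate (bool, default True) or paths
    {sites, occurrences, counts, genotypes}; thresholds (optional override
    of DEFAULT_THRESHOLDS); exclude_species (optional, linkage is rerun
    without it, mirroring the generalist-excluded analysis); responses
    (default ["pc1", "ga", "ge"]).
    """
    seed = int(config.get("seed", 1))
    thresholds = {**DEFAULT_THRESHOLDS, **config.get("thresholds", {})}
    report: dict = {"version": __version__, "seed": seed,
                    "config": {k: v for k, v in config.items() if k != "paths"},
                    "warnings": []}
    out_dir = Path(out_dir) if out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    # ---- stage 0: data
    if config.get("simulate", True):
        sim_cfg = simulate.SimConfig(seed=seed)
        data = simulate.simulate_dataset(sim_cfg)
        sites, counts = data["sites"], data["counts"]
        genotypes = data["genotypes"]
        report["truth_summary"] = {
            sp: {"prevalence": t["prevalence"]}
            for sp, t in data["truth"]["species"].items()}
        if out_dir:
            _dump_inputs(out_dir, data)
    else:
        paths = config["paths"]
        sites = pd.read_csv(paths["sites"])
        counts = pd.read_csv(paths["counts"])
        genotypes = pd.read_csv(paths["genotypes"])

    layer_names = [c for c in sites.columns
                   if c not in ("site_id", "lon", "lat", "hexagon")
                   and not c.startswith(("presence_", "ysp_"))]
    species_names = [c[len("presence_"):] for c in sites.columns
                     if c.startswith("presence_")]

    # ---- stage 1: favourability SDM per species
    report["sdm"] = {}
    fav_frames = []
    for sp in species_names:
        y = sites[f"presence_{sp}"].to_numpy()
        ysp, _ = trend_surface_ysp(sites, y)
        sites[f"ysp_{sp}"] = ysp
        covs = sites[layer_names].copy()
        covs["Ysp"] = ysp
        model = sdm.fit_favourability_model(
            y, covs, q=thresholds["fdr_q"], r_max=thresholds["r_max"],
            alpha=thresholds["alpha"], threshold=thresholds["threshold"])
        report["sdm"][sp] = model.to_dict()
        fav_frames.append(pd.DataFrame({
            "site_id": sites["site_id"], "species": sp,
            "P": model.P, "F": model.F}))
    if out_dir and fav_frames:
        pd.concat(fav_frames).to_csv(out_dir / "favourability.csv", index=False)

    # ---- stage 2: germination statistics
    stats_df = germination.replicate_stats(counts)
    summary = germination.genotype_summary(stats_df)
    profile = germination.germination_profile(stats_df)
    report["germination"] = {
        "n_dishes": int(len(stats_df)),
        "genotype_summary": summary.to_dict(orient="records"),
    }
    if out_dir:
        stats_df.to_csv(out_dir / "replicate_stats.csv", index=False)
        summary.to_csv(out_dir / "genotype_summary.csv", index=False)

    # ---- stage 3: trait-environment linkage
    responses = config.get("responses", ["pc1", "ga", "ge"])
    link = link_analysis(profile, summary, genotypes, sites[
        ["site_id"] + layer_names], responses=responses,
        vip_cut=thresholds["vip_cut"])
    report["linkage"] = link
    excl = config.get("exclude_species")
    if excl:
        keep = summary["species"] != excl
        keep_p = profile["species"] != excl
        report["linkage_excluding"] = {
            excl: link_analysis(profile[keep_p], summary[keep],
                                genotypes, sites[["site_id"] + layer_names],
                                responses=responses,
                                vip_cut=thresholds["vip_cut"])}

    if out_dir:
        with open(out_dir / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, default=_jsonable)
    return report


def link_analysis(profile: pd.DataFrame, summary: pd.DataFrame,
                  genotypes: pd.DataFrame, site_env: pd.DataFrame,
                  responses=("pc1", "ga", "ge"), vip_cut: float = 1.0) -> dict:
    """PCA of the germination profile, then two-stage PLSR of each genotype
    index on the genotype-hexagon environment, then simple regressions on
    the final VIP > 1 predictors."""
    id_cols = [c for c in ("genotype", "species", "harvest")
               if c in profile.columns]
    resp_cols = [c for c in profile.columns if c not in id_cols]
    pca_res = linkage.pca_germination(profile[resp_cols])
    pc1 = profile[id_cols].copy()
    pc1["pc1"] = pca_res.scores["PC1"].to_numpy()
    pc1_geno = pc1.groupby("genotype", sort=True)["pc1"].mean()

    geno = summary.groupby("genotype", sort=True).agg(
        ga=("ga", "mean"), ge=("ge", "mean")).reset_index()
    geno["pc1"] = geno["genotype"].map(pc1_geno)
    merged = geno.merge(genotypes[["genotype", "site_id"]], on="genotype")
    merged = merged.merge(site_env, on="site_id")
    predictors = [c for c in site_env.columns if c != "site_id"]

    out = {"pca": {
        "explained_variance_ratio": pca_res.explained_variance_ratio.tolist(),
        "pc1_pct": float(100 * pca_res.explained_variance_ratio[0]),
        "imputed_cells": pca_res.imputed_cells,
    }, "plsr": {}, "regressions": []}
    for resp in responses:
        y = merged[resp].to_numpy(dtype=float)
        try:
            ts = linkage.two_stage_plsr(merged[predictors], y, vip_cut=vip_cut)
        except ValueError as exc:
            out["plsr"][resp] = {"error": str(exc)}
            continue
        out["plsr"][resp] = ts.report()
        # strict VIP > 1 is unattainable when stage 2 has a single predictor
        # (VIP is then identically 1): fall back to the stage-2 set
        for pred in (ts.final_vip_gt1 or ts.retained):
            reg = linkage.ols_regress(merged[pred].to_numpy(), y)
            reg.update({"response": resp, "predictor": pred})
            out["regressions"].append(reg)
    return out


def _dump_inputs(out_dir: Path, data: dict) -> None:
    sites_flat = data["sites"].drop(columns=["hexagon"], errors="ignore")
    sites_flat.to_csv(out_dir / "sites.csv", index=False)
    data["occurrences"].to_csv(out_dir / "occurrences.csv", index=False)
    data["genotypes"].to_csv(out_dir / "genotypes.csv", index=False)
    data["counts"].to_csv(out_dir / "germination_counts.csv", index=False)
    with open(out_dir / "truth.json", "w") as fh:
        json.dump(data["truth"], fh, default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    raise TypeError(f"not JSON serializable: {type(obj)}")
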