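"""Desk-scale parameter-recovery studies on the virtual study system.

Each experiment simulates data with a known truth, runs the corresponding
estimation pipeline, and scores recovery. They are the quantitative backbone
of the analysis scripts and of the acceptance checks:

* SDM cascade recovery — informative-variable retention, noise admission,
  and coefficient confidence-interval coverage;
* two-stage PLSR driver identification on generic predictors;
* germination linkage — does the dormancy driver layer survive the VIP
  filter, and does the GA-vs-driver regression recover the implied slope;
* specialist vs generalist — classification skill (TSS) of the narrow-niche
  versus the broad-niche virtual species.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from . import germination
from .grid import GridSpec, trend_surface_ysp
from .linkage import ols_regress, two_stage_plsr
from .sdm import fit_favourability_model
from .simulate import (LayerDef, SimConfig, SpeciesDef, place_genotypes,
                       simulate_environment, simulate_germination,
                       simulate_species_occurrence)

RECOVERY_GRID = GridSpec((0.0, 0.0, 10.0, 10.0), apothem_km=0.12,
                         km_per_degree=1.0)  # ~2000 hexagons

RECOVERY_LAYERS = (
    LayerDef("inf1", (0.0, -1.2), 0.8),
    LayerDef("inf2", (1.0, 0.3), 0.8),
    LayerDef("inf3", (0.4, 0.8), 0.8),
    LayerDef("noise1", (0.0, 0.0), 1.0),
    LayerDef("noise2", (0.0, 0.0), 1.0),
    LayerDef("noise3", (0.0, 0.0), 1.0),
    LayerDef("noise4", (0.0, 0.0), 1.0),
    LayerDef("noise5", (0.0, 0.0), 1.0),
)
RECOVERY_BETA = {"inf1": 0.9, "inf2": 0.7, "inf3": -0.6}
RECOVERY_SPECIES = SpeciesDef("virtual", intercept=-0.3, beta=RECOVERY_BETA)


def sdm_recovery(n_reps: int = 25, seed: int = 0) -> dict:
    """Selection-cascade recovery over seeded replicates.

    A replicate succeeds when every informative layer is retained and at
    most one noise layer slips through. Also pools 95% Wald-CI coverage of
    the true coefficients over retained informative variables.
    """
    successes = 0
    covered = 0
    n_cis = 0
    noise_counts = []
    for rep in range(n_reps):
        cfg = SimConfig(seed=seed * 10_000 + rep, grid=RECOVERY_GRID,
                        layers=RECOVERY_LAYERS, species=(RECOVERY_SPECIES,))
        sites, _ = simulate_environment(cfg)
        y, _ = simulate_species_occurrence(sites, RECOVERY_SPECIES, cfg.seed)
        covs = sites[[l.name for l in RECOVERY_LAYERS]]
        model = fit_favourability_model(y, covs)
        kept = set(model.fit.variables)
        informative = set(RECOVERY_BETA)
        n_noise = len(kept - informative)
        noise_counts.append(n_noise)
        if informative <= kept and n_noise <= 1:
            successes += 1
        for name, beta in RECOVERY_BETA.items():
            if name in kept:
                est = model.fit.params[name]
                se = model.fit.bse[name]
                covered += est - 1.96 * se <= beta <= est + 1.96 * se
                n_cis += 1
    return {
        "n_reps": n_reps,
        "success_rate": successes / n_reps,
        "ci_coverage": covered / n_cis if n_cis else float("nan"),
        "mean_noise_vars": float(np.mean(noise_counts)),
    }


def plsr_driver_identification(n_reps: int = 25, seed: int = 0,
                               n: int = 30, p: int = 8) -> dict:
    """Two-stage PLSR on generic predictors with two known drivers; a
    replicate succeeds when both drivers survive to stage 2."""
    hits = 0
    for rep in range(n_reps):
        rng = np.random.default_rng([seed, 7_000 + rep])
        X = pd.DataFrame(rng.normal(size=(n, p)),
                         columns=[f"v{j}" for j in range(p)])
        y = (X["v0"] + 0.8 * X["v4"]).to_numpy() + rng.normal(0, 0.5, n)
        ts = two_stage_plsr(X, y)
        hits += {"v0", "v4"} <= set(ts.retained)
    return {"n_reps": n_reps, "success_rate": hits / n_reps}


def _implied_ga_slope(truth: dict, driver_vals: np.ndarray) -> float:
    """True expected GA regressed on the driver: the slope the germination
    model implies before sampling noise."""
    alpha = truth["dormancy_intercept"]
    gamma = truth["dormancy_slope"]
    etas = np.array(list(truth["stimuli"].values()))
    ga_true = np.array([
        (1.0 / (1.0 + np.exp(-(etas - (alpha + gamma * d))))).sum()
        for d in driver_vals])
    return ols_regress(driver_vals, ga_true)["slope"]


def germination_linkage_recovery(n_reps: int = 25, seed: int = 0) -> dict:
    """Full germination linkage on the virtual system.

    Per replicate: simulate layers + genotypes + assays, summarise GA per
    genotype, run the two-stage PLSR of GA on all eight layers, and regress
    GA on the true driver. Scored: driver retained by the VIP filter; sign
    of the GA-driver slope; slope within 20% of the model-implied value.
    """
    driver_kept = 0
    sign_ok = 0
    magnitude_ok = 0
    for rep in range(n_reps):
        cfg = SimConfig(seed=seed * 10_000 + 31 + rep,
                        grid=replace(RECOVERY_GRID, apothem_km=0.18))
        sites, _ = simulate_environment(cfg)
        genotypes = place_genotypes(sites, cfg)
        counts, truth = simulate_germination(genotypes, cfg)
        stats = germination.replicate_stats(counts)
        summ = germination.genotype_summary(stats, grouping="genotype")
        merged = summ.merge(genotypes[["genotype", "site_id"]], on="genotype")
        merged = merged.merge(
            sites[["site_id"] + [l.name for l in cfg.layers]], on="site_id")
        driver = cfg.germination.driver
        ts = two_stage_plsr(merged[[l.name for l in cfg.layers]],
                            merged["ga"].to_numpy())
        driver_kept += driver in ts.retained
        dv = merged[driver].to_numpy()
        reg = ols_regress(dv, merged["ga"].to_numpy())
        implied = _implied_ga_slope(truth, dv)
        sign_ok += np.sign(reg["slope"]) == np.sign(implied)
        magnitude_ok += abs(reg["slope"] - implied) <= 0.2 * abs(implied)
    return {
        "n_reps": n_reps,
        "driver_retention_rate": driver_kept / n_reps,
        "slope_sign_rate": sign_ok / n_reps,
        "slope_within_20pct_rate": magnitude_ok / n_reps,
    }


def specialist_generalist_comparison(n_reps: int = 25, seed: int = 0) -> dict:
    """Classification skill of the narrow-niche (specialist) versus the
    broad-niche (generalist) virtual species on the same grids, with the
    trend-surface descriptor offered to both cascades."""
    tss = {"sp_broad": [], "sp_narrow": []}
    auc = {"sp_broad": [], "sp_narrow": []}
    for rep in range(n_reps):
        cfg = SimConfig(seed=seed * 10_000 + 61 + rep, grid=RECOVERY_GRID)
        sites, _ = simulate_environment(cfg)
        for k, sp in enumerate(cfg.species):
            y, _ = simulate_species_occurrence(sites, sp, cfg.seed,
                                               stream_offset=100 + k)
            ysp, _ = trend_surface_ysp(sites, y)
            covs = sites[[l.name for l in cfg.layers]].copy()
            covs["Ysp"] = ysp
            model = fit_favourability_model(y, covs)
            tss[sp.name].append(model.evaluation.tss)
            auc[sp.name].append(model.evaluation.auc)
    return {
        "n_reps": n_reps,
        "mean_tss_generalist": float(np.mean(tss["sp_broad"])),
        "mean_tss_specialist": float(np.mean(tss["sp_narrow"])),
        "mean_auc_generalist": float(np.mean(auc["sp_broad"])),
        "mean_auc_specialist": float(np.mean(auc["sp_narrow"])),
    }
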