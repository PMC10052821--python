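"""Seed-germination statistics and germination niche-breadth indices.

Replicate level (one Petri dish followed over scheduled counts):

* FGP  — final germination proportion, germinated / viable seeds, where
  viable = germinated + tetrazolium-positive non-germinated.
* MGT  — mean germination time in days (the free-schedule design),
  MGT = sum(g_i * t_i) / sum(g_i).
* MGS  — mean germination section for the stratification design whose
  incubation switches conditions mid-assay: with k = 6 scheduled counts and
  section index h = i - 1, MGS = k - Tmod where the modified Timson index
  Tmod = sum(g_i * (k - h)) / sum(g_i). Algebraically MGS is the
  germination-weighted mean of h, ranging 0..k-1.
* UG   — uncertainty of germination, the Shannon entropy (bits) of the
  germination fractions f_i = g_i / sum(g_i); 0 = fully synchronous.

Genotype level, over the R = 11 treatment levels of the two designs
(3 stratification levels + 4 temperatures x 2 solutions):

* GA — germination ability, the sum of the 11 mean FGPs (max 11).
* GE — germination evenness, a modified Levins niche-breadth index
  GE = 1 / (R * sum_j p_j^2) with p_j = FGP_j / GA; 1 = perfectly even.

GA and GE jointly proxy dormancy depth and germination niche breadth.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

N_SECTIONS = 6          # scheduled counts in the stratification design
N_LEVELS = 11           # 3 stratification + 8 temperature x solution levels
GE_CLAMP_EPS = 0.005


def compute_fgp(germinated_total: int, viable_nongerm: int) -> float:
    """Final germination proportion; NaN when no seed in the dish was viable."""
    viable = germinated_total + viable_nongerm
    if viable <= 0:
        return float("nan")
    return germinated_total / viable


def compute_mgt(g: np.ndarray, t_days: np.ndarray) -> float:
    """Germination-weighted mean time in days; NaN when nothing germinated."""
    g = np.asarray(g, dtype=float)
    t = np.asarray(t_days, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("count times must be strictly increasing")
    total = g.sum()
    if total == 0:
        return float("nan")
    return float((g * t).sum() / total)


def compute_mgs(g: np.ndarray) -> float:
    """Mean germination section via the modified Timson index (k = 6).

    MGS = k - Tmod = weighted mean of the section index h = i - 1.
    """
    g = np.asarray(g, dtype=float)
    if len(g) != N_SECTIONS:
        raise ValueError(f"stratification design requires exactly {N_SECTIONS} counts")
    total = g.sum()
    if total == 0:
        return float("nan")
    h = np.arange(N_SECTIONS, dtype=float)        # 0..k-1
    tmod = float((g * (N_SECTIONS - h)).sum() / total)
    return N_SECTIONS - tmod


def compute_ug(g: np.ndarray) -> float:
    """Shannon entropy (bits) of the germination distribution over counts,
    with the 0*log2(0) := 0 convention; NaN when nothing germinated."""
    g = np.asarray(g, dtype=float)
    total = g.sum()
    if total == 0:
        return float("nan")
    f = g[g > 0] / total
    return float(-(f * np.log2(f)).sum())


def compute_ga(fgp_levels: np.ndarray, impute_zero: bool = False) -> float:
    """Germination ability: sum of the 11 per-level mean FGPs."""
    fgp = np.asarray(fgp_levels, dtype=float)
    if impute_zero:
        fgp = np.nan_to_num(fgp, nan=0.0)
    if len(fgp) != N_LEVELS or np.isnan(fgp).any():
        raise ValueError(f"GA requires all {N_LEVELS} treatment-level means "
                         "(use impute_zero to treat missing levels as 0)")
    if np.any((fgp < 0) | (fgp > 1)):
        raise ValueError("FGP values must lie in [0, 1]")
    return float(fgp.sum())


def compute_ge(fgp_levels: np.ndarray, impute_zero: bool = False) -> float:
    """Germination evenness (modified Levins): 1 / (R * sum p_j^2)."""
    fgp = np.asarray(fgp_levels, dtype=float)
    if impute_zero:
        fgp = np.nan_to_num(fgp, nan=0.0)
    ga = compute_ga(fgp)
    if ga == 0:
        return float("nan")
    p = fgp / ga
    return float(1.0 / (N_LEVELS * (p ** 2).sum()))


def logit_proportion(germinated: int, viable: int) -> float:
    """Empirical logit ln((g + 0.5) / (n - g + 0.5)), finite at 0 and n."""
    if viable < 1:
        return float("nan")
    if not 0 <= germinated <= viable:
        raise ValueError("germinated must lie in [0, viable]")
    return math.log((germinated + 0.5) / (viable - germinated + 0.5))


def logit_clamped(x: float, eps: float = GE_CLAMP_EPS) -> float:
    """Plain logit after clamping to [eps, 1 - eps]; used for GE, which is a
    proportion without an underlying count."""
    x = min(max(x, eps), 1.0 - eps)
    return math.log(x / (1.0 - x))


# ------------------------------------------------------------- data frames

REPLICATE_KEYS = ["genotype", "species", "harvest", "experiment", "treatment",
                  "replicate"]


def replicate_stats(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-dish statistics from a long count table.

    ``counts`` columns: the REPLICATE_KEYS plus sown, obs_time, germinated,
    viable_nongerm (constant within a dish). Experiment 1 dishes yield MGS,
    experiment 2 dishes MGT; zero-germination dishes get NaN timing/UG.
    """
    rows = []
    for keys, grp in counts.groupby(REPLICATE_KEYS, sort=True):
        grp = grp.sort_values("obs_time")
        g = grp["germinated"].to_numpy(dtype=float)
        t = grp["obs_time"].to_numpy(dtype=float)
        viable_ng = int(grp["viable_nongerm"].iloc[0])
        sown = int(grp["sown"].iloc[0])
        if g.sum() + viable_ng > sown:
            raise ValueError(f"more germinated+viable than sown in dish {keys}")
        experiment = keys[REPLICATE_KEYS.index("experiment")]
        rec = dict(zip(REPLICATE_KEYS, keys))
        rec["fgp"] = compute_fgp(int(g.sum()), viable_ng)
        rec["timing"] = compute_mgs(g) if int(experiment) == 1 else compute_mgt(g, t)
        rec["ug"] = compute_ug(g)
        rec["germinated_total"] = int(g.sum())
        rec["viable"] = int(g.sum()) + viable_ng
        rows.append(rec)
    return pd.DataFrame(rows)


def level_means(stats_df: pd.DataFrame,
                grouping: str = "genotype_harvest") -> pd.DataFrame:
    """Mean FGP / timing / UG per treatment level within each genotype
    (x harvest by default). Timing and UG means skip NaN dishes; an FGP mean
    is NaN only if every dish of the level lacked viable seeds."""
    keys = {"genotype_harvest": ["genotype", "species", "harvest"],
            "genotype": ["genotype", "species"]}[grouping]
    grouped = stats_df.groupby(keys + ["experiment", "treatment"], sort=True)
    out = grouped.agg(fgp=("fgp", "mean"), timing=("timing", "mean"),
                      ug=("ug", "mean")).reset_index()
    return out


def genotype_summary(stats_df: pd.DataFrame,
                     grouping: str = "genotype_harvest",
                     impute_zero: bool = False) -> pd.DataFrame:
    """GA and GE per genotype (x harvest), plus logit transforms.

    Requires each group to cover all 11 treatment levels unless
    ``impute_zero`` fills missing levels with FGP = 0.
    """
    keys = {"genotype_harvest": ["genotype", "species", "harvest"],
            "genotype": ["genotype", "species"]}[grouping]
    lm = level_means(stats_df, grouping=grouping)
    rows = []
    for group_vals, grp in lm.groupby(keys, sort=True):
        fgp = grp["fgp"].to_numpy(dtype=float)
        if len(fgp) != N_LEVELS and not impute_zero:
            raise ValueError(
                f"group {group_vals} covers {len(fgp)} of {N_LEVELS} levels")
        if len(fgp) < N_LEVELS:
            fgp = np.concatenate([fgp, np.zeros(N_LEVELS - len(fgp))])
        ga = compute_ga(fgp, impute_zero=impute_zero)
        ge = compute_ge(fgp, impute_zero=impute_zero)
        rec = dict(zip(keys, group_vals if isinstance(group_vals, tuple)
                       else (group_vals,)))
        rec.update({
            "ga": ga, "ge": ge, "mean_fgp": float(np.nanmean(fgp)),
            "ge_logit": float("nan") if math.isnan(ge) else logit_clamped(ge),
        })
        rows.append(rec)
    return pd.DataFrame(rows)


def germination_profile(stats_df: pd.DataFrame,
                        grouping: str = "genotype_harvest") -> pd.DataFrame:
    """Wide response matrix for ordination: one row per genotype (x harvest),
    FGP / timing / UG columns per treatment level."""
    keys = {"genotype_harvest": ["genotype", "species", "harvest"],
            "genotype": ["genotype", "species"]}[grouping]
    lm = level_means(stats_df, grouping=grouping)
    lm["level"] = "e" + lm["experiment"].astype(str) + "_" + lm["treatment"].astype(str)
    wide = lm.pivot_table(index=keys, columns="level",
                          values=["fgp", "timing", "ug"], aggfunc="first")
    wide.columns = [f"{stat}_{lvl}" for stat, lvl in wide.columns]
    return wide.reset_index()
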