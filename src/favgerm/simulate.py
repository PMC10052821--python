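"""Virtual study system: environmental layers, species, germination assays.

The generator emulates the study design at desk scale so that every
downstream estimate can be scored against a known truth:

* spatially structured environmental layers over a hexagonal grid — each
  layer is a deterministic planar gradient plus Gaussian noise, optionally
  re-mixed linearly to hit a requested inter-layer correlation matrix;
* virtual species with known logistic responses to the layers — one broad
  ("generalist") species with shallow coefficients, and narrow
  ("specialist") species whose response adds a quadratic penalty around an
  environmental optimum — sampled as Bernoulli presence per hexagon;
* germination assays in which each genotype's dormancy depth is a known
  linear function of one climate layer (the "driver"), germination
  probability per treatment level is inverse-logit(stimulus - dormancy),
  counts are binomial, and germination timing spreads over the scheduled
  counts with dispersion increasing in dormancy.

Everything is reproducible from an integer seed; per-species and
per-genotype sub-streams are derived with fixed offsets so edits to one
block of the configuration do not perturb the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import GridSpec, build_hex_grid

EXP1_SCHEDULE_DAYS = [2, 3, 4, 6, 8, 11]  # 3 counts at 30C, then 3 at 20/30C
EXP2_SCHEDULES = {  # alternating-temperature regime -> count days
    "10/20": [2, 4, 7, 9, 11, 14, 16, 18, 21, 23, 25, 28],
    "15/25": [2, 4, 7, 9, 11, 14, 16, 18, 21],
    "20/30": [2, 4, 7, 9, 11, 14, 17],
    "25/35": [2, 4, 7, 9, 11, 14],
}
EXP1_LEVELS = ["none", "cold", "warm"]
EXP2_LEVELS = [f"{t}_{s}" for t in EXP2_SCHEDULES for s in ("water", "nitrate")]

# dormancy-release stimulus per treatment level (logit scale)
DEFAULT_STIMULI = {
    (1, "none"): 0.0, (1, "cold"): 2.0, (1, "warm"): 1.0,
    (2, "10/20_water"): -1.5, (2, "15/25_water"): 0.5,
    (2, "20/30_water"): 1.5, (2, "25/35_water"): 2.0,
    (2, "10/20_nitrate"): -0.5, (2, "15/25_nitrate"): 1.5,
    (2, "20/30_nitrate"): 2.5, (2, "25/35_nitrate"): 3.0,
}


@dataclass(frozen=True)
class LayerDef:
    name: str
    gradient: tuple[float, float] = (0.0, 0.0)  # d(layer)/d(x), d(layer)/d(y)
    noise_sd: float = 0.5


@dataclass(frozen=True)
class SpeciesDef:
    name: str
    intercept: float = 0.0
    beta: dict = field(default_factory=dict)        # layer -> linear coefficient
    quadratic: dict = field(default_factory=dict)   # layer -> (optimum, penalty)


@dataclass(frozen=True)
class GerminationDef:
    n_genotypes: int = 12
    n_harvests: int = 2
    n_replicates: int = 3
    seeds_per_dish: int = 50
    viability: float = 0.95
    driver: str = "Bio17"
    dormancy_intercept: float = 0.5     # alpha
    dormancy_slope: float = -1.0        # gamma: wetter dry season -> shallower dormancy
    dormancy_resid_sd: float = 0.45     # genotype-level residual around the line
    harvest_sd: float = 0.1


DEFAULT_LAYERS = (
    LayerDef("Bio1", (0.0, -1.5), 0.5),
    LayerDef("Bio6", (0.0, -1.2), 0.6),
    LayerDef("Bio12", (1.0, 0.5), 0.6),
    LayerDef("Bio17", (0.9, 0.6), 0.6),
    LayerDef("ETP_An", (0.3, -1.0), 0.7),
    LayerDef("Slope", (0.0, 0.0), 1.0),
    LayerDef("DistRoad", (0.0, 0.0), 1.0),
    LayerDef("Urban", (0.5, 0.0), 1.0),
)

DEFAULT_SPECIES = (
    SpeciesDef("sp_broad", intercept=0.0, beta={"Bio1": 0.8, "Bio12": 0.4}),
    SpeciesDef("sp_narrow", intercept=0.5, beta={"Bio17": 0.6},
               quadratic={"Bio1": (0.8, 3.0)}),
)


@dataclass(frozen=True)
class SimConfig:
    seed: int = 1
    grid: GridSpec = field(
        default_factory=lambda: GridSpec((0.0, 0.0, 10.0, 10.0),
                                         apothem_km=0.12, km_per_degree=1.0))
    layers: tuple = DEFAULT_LAYERS
    target_corr: dict | None = None     # (name_a, name_b) -> r; None = natural
    species: tuple = DEFAULT_SPECIES
    germination: GerminationDef = field(default_factory=GerminationDef)


def _stream(seed: int, offset: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(offset)])


# ------------------------------------------------------------ environment

def simulate_environment(config: SimConfig) -> tuple[pd.DataFrame, dict]:
    """Sites + standardized environmental layers, and the truth record."""
    sites = build_hex_grid(config.grid)
    rng = _stream(config.seed, 0)
    x = sites["lon"].to_numpy()
    y = sites["lat"].to_numpy()
    xn = (x - x.mean()) / x.std()
    yn = (y - y.mean()) / y.std()

    names = [layer.name for layer in config.layers]
    cols = {}
    for layer in config.layers:
        gx, gy = layer.gradient
        field_ = gx * xn + gy * yn + rng.normal(0.0, layer.noise_sd, len(sites))
        cols[layer.name] = field_
    env = pd.DataFrame(cols, index=sites.index)
    env = (env - env.mean()) / env.std(ddof=0)

    if config.target_corr is not None:
        env = _impose_correlation(env, names, config.target_corr)

    for name in names:
        sites[name] = env[name].to_numpy()
    truth = {
        "seed": config.seed,
        "layers": names,
        "realized_corr": env.corr().to_dict(),
    }
    return sites, truth


def _impose_correlation(env: pd.DataFrame, names: list[str],
                        target: dict) -> pd.DataFrame:
    """Re-mix standardized layers so their empirical correlation matrix
    equals the requested one (identity off-diagonals unless specified)."""
    p = len(names)
    C = np.eye(p)
    for (a, b), r in target.items():
        i, j = names.index(a), names.index(b)
        C[i, j] = C[j, i] = float(r)
    try:
        L = np.linalg.cholesky(C)
    except np.linalg.LinAlgError as exc:
        raise ValueError("target correlation matrix is not positive definite") from exc
    B = env[names].to_numpy()
    # whiten the realized columns, then colour with the target factor
    emp = np.corrcoef(B, rowvar=False)
    A = np.linalg.cholesky(emp + 1e-12 * np.eye(p))
    mixed = B @ np.linalg.inv(A).T @ L.T
    out = pd.DataFrame(mixed, columns=names, index=env.index)
    return (out - out.mean()) / out.std(ddof=0)


# ---------------------------------------------------------------- species

def species_logit(covariates: pd.DataFrame, sp: SpeciesDef) -> np.ndarray:
    eta = np.full(len(covariates), float(sp.intercept))
    for name, b in sp.beta.items():
        eta += b * covariates[name].to_numpy()
    for name, (opt, penalty) in sp.quadratic.items():
        eta -= penalty * (covariates[name].to_numpy() - opt) ** 2
    return eta


def simulate_species_occurrence(covariates: pd.DataFrame, sp: SpeciesDef,
                                seed: int, stream_offset: int = 100
                                ) -> tuple[np.ndarray, dict]:
    """Bernoulli presence from the species' true favourability surface."""
    rng = _stream(seed, stream_offset)
    prob = 1.0 / (1.0 + np.exp(-species_logit(covariates, sp)))
    for attempt in range(2):
        presence = rng.binomial(1, prob)
        if 0 < presence.sum() < len(presence):
            break
    else:
        raise ValueError(f"degenerate presence realization for {sp.name}")
    truth = {
        "species": sp.name, "intercept": sp.intercept,
        "beta": dict(sp.beta),
        "quadratic": {k: list(v) for k, v in sp.quadratic.items()},
        "mean_true_probability": float(prob.mean()),
        "prevalence": float(presence.mean()),
        "true_probability": prob.tolist(),
    }
    return presence, truth


# ------------------------------------------------------------ germination

def place_genotypes(sites: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Pick genotype home hexagons at evenly spaced quantiles of the driver
    layer, emulating sampling genotypes across the environmental range."""
    g = config.germination
    driver = sites[g.driver].to_numpy()
    qs = np.linspace(0.05, 0.95, g.n_genotypes)
    idx = [int(np.abs(driver - np.quantile(driver, q)).argmin()) for q in qs]
    # resolve duplicate hexagons deterministically
    seen, resolved = set(), []
    order = np.argsort(driver)
    for i in idx:
        j = i
        while j in seen:
            j = int(order[(np.where(order == j)[0][0] + 1) % len(order)])
        seen.add(j)
        resolved.append(j)
    out = sites.iloc[resolved][["site_id", "lon", "lat", g.driver]].copy()
    out.insert(0, "genotype", [f"g{k + 1:02d}" for k in range(g.n_genotypes)])
    return out.reset_index(drop=True)


def _timing_weights(n_counts: int, dormancy: float) -> np.ndarray:
    """Discrete germination-timing profile: later and more spread out as
    dormancy deepens."""
    s = 1.0 / (1.0 + np.exp(-dormancy))
    mu = (n_counts - 1) * (0.25 + 0.5 * s)
    sd = 0.8 + 0.8 * s
    idx = np.arange(n_counts)
    w = np.exp(-0.5 * ((idx - mu) / sd) ** 2)
    return w / w.sum()


def simulate_germination(genotypes: pd.DataFrame, config: SimConfig,
                         stimuli: dict | None = None
                         ) -> tuple[pd.DataFrame, dict]:
    """Long-format germination count table plus the dormancy truth record.

    One row per (dish, scheduled count). Dormancy per genotype is
    alpha + gamma * driver + residual; each harvest adds a small shift.
    """
    g = config.germination
    stimuli = dict(DEFAULT_STIMULI if stimuli is None else stimuli)
    rows = []
    truth_genotypes = {}
    for gi, grow in genotypes.iterrows():
        rng = _stream(config.seed, 1000 + gi)
        driver_val = float(grow[g.driver])
        resid = rng.normal(0.0, g.dormancy_resid_sd)
        dormancy = g.dormancy_intercept + g.dormancy_slope * driver_val + resid
        harvest_shifts = rng.normal(0.0, g.harvest_sd, g.n_harvests)
        truth_genotypes[grow["genotype"]] = {
            "driver_value": driver_val, "dormancy": dormancy,
            "site_id": int(grow["site_id"]),
            "harvest_shifts": harvest_shifts.tolist(),
        }
        for h in range(g.n_harvests):
            d_h = dormancy + harvest_shifts[h]
            for experiment, levels in ((1, EXP1_LEVELS), (2, EXP2_LEVELS)):
                for level in levels:
                    if experiment == 1:
                        days = EXP1_SCHEDULE_DAYS
                    else:
                        days = EXP2_SCHEDULES[level.split("_")[0]]
                    eta = stimuli[(experiment, level)]
                    prob = 1.0 / (1.0 + np.exp(-(eta - d_h)))
                    for rep in range(1, g.n_replicates + 1):
                        viable = rng.binomial(g.seeds_per_dish, g.viability)
                        germ_total = rng.binomial(viable, prob) if viable else 0
                        w = _timing_weights(len(days), d_h)
                        counts = (rng.multinomial(germ_total, w)
                                  if germ_total else np.zeros(len(days), int))
                        for day, c in zip(days, counts):
                            rows.append({
                                "genotype": grow["genotype"],
                                "species": "virtual",
                                "harvest": f"h{h + 1}",
                                "experiment": experiment,
                                "treatment": level,
                                "replicate": rep,
                                "sown": g.seeds_per_dish,
                                "obs_time": day,
                                "germinated": int(c),
                                "viable_nongerm": int(viable - germ_total),
                            })
    counts_df = pd.DataFrame(rows)
    truth = {
        "seed": config.seed,
        "driver": g.driver,
        "dormancy_intercept": g.dormancy_intercept,
        "dormancy_slope": g.dormancy_slope,
        "stimuli": {f"{e}:{lvl}": v for (e, lvl), v in stimuli.items()},
        "genotypes": truth_genotypes,
    }
    return counts_df, truth


# ------------------------------------------------------------ full dataset

def simulate_dataset(config: SimConfig) -> dict:
    """Generate the complete virtual study: sites, presences, occurrence
    points (hexagon centroids of presence cells), germination counts, truth."""
    sites, env_truth = simulate_environment(config)
    truth = {"environment": env_truth, "species": {}, "germination": None}
    occ_rows = []
    for k, sp in enumerate(config.species):
        presence, sp_truth = simulate_species_occurrence(
            sites, sp, config.seed, stream_offset=100 + k)
        sites[f"presence_{sp.name}"] = presence
        truth["species"][sp.name] = sp_truth
        for _, row in sites.loc[presence.astype(bool)].iterrows():
            occ_rows.append({"species": sp.name,
                             "lon": row["lon"], "lat": row["lat"]})
    occurrences = pd.DataFrame(occ_rows, columns=["species", "lon", "lat"])
    genotypes = place_genotypes(sites, config)
    counts, germ_truth = simulate_germination(genotypes, config)
    truth["germination"] = germ_truth
    return {"sites": sites, "occurrences": occurrences,
            "genotypes": genotypes, "counts": counts, "truth": truth}
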