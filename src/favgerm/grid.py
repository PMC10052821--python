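"""Hexagonal analysis grid and the trend-surface spatial descriptor.

The study area is tiled with pointy-top regular hexagons of a given apothem.
Occurrence records are reduced to per-hexagon presence/absence, and a cubic
trend-surface logistic model of latitude/longitude supplies the single
spatial covariate Ysp (the fitted probability of presence from coordinates
alone), which downstream models treat like any environmental variable.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon, box
from shapely.strtree import STRtree

from ._glm import LogitFit, fit_logit

KM_PER_DEGREE = 111.32  # equatorial scale used to convert an apothem in km

# cubic trend-surface terms in (lon, lat) powers: Lo, Lo2, Lo3, La, La2, La3,
# LaLo, La2Lo, LaLo2
TREND_TERMS: dict[str, tuple[int, int]] = {
    "Lo": (1, 0), "Lo2": (2, 0), "Lo3": (3, 0),
    "La": (0, 1), "La2": (0, 2), "La3": (0, 3),
    "LaLo": (1, 1), "La2Lo": (1, 2), "LaLo2": (2, 1),
}


@dataclass(frozen=True)
class GridSpec:
    """Bounding geometry (shapely polygon or lon/lat bbox) plus hexagon size.

    ``apothem_km`` is converted to map (degree) units with ``km_per_degree``;
    the grid is laid out in the raw lon/lat plane.
    """

    geometry: Polygon | tuple[float, float, float, float]
    apothem_km: float
    km_per_degree: float = KM_PER_DEGREE

    def __post_init__(self):
        if self.apothem_km <= 0:
            raise ValueError("apothem must be positive")
        geom = self.polygon
        if geom.is_empty or geom.area == 0:
            raise ValueError("bounding geometry is empty")

    @property
    def polygon(self) -> Polygon:
        if isinstance(self.geometry, Polygon):
            return self.geometry
        return box(*self.geometry)

    @property
    def apothem(self) -> float:
        """Apothem in map units."""
        return self.apothem_km / self.km_per_degree


def hexagon_vertices(cx: float, cy: float, apothem: float) -> list[tuple[float, float]]:
    """Vertices of a pointy-top regular hexagon (first vertex due north)."""
    r = 2.0 * apothem / math.sqrt(3.0)  # circumradius
    return [
        (cx + r * math.cos(math.radians(90 + 60 * k)),
         cy + r * math.sin(math.radians(90 + 60 * k)))
        for k in range(6)
    ]


def build_hex_grid(spec: GridSpec) -> pd.DataFrame:
    """Tile the bounding geometry with pointy-top hexagons.

    Returns a SiteTable skeleton: one row per hexagon whose centroid lies
    inside the geometry, with ``site_id`` assigned west->east then
    south->north and the hexagon polygon attached.
    """
    geom = spec.polygon
    a = spec.apothem
    r = 2.0 * a / math.sqrt(3.0)
    minx, miny, maxx, maxy = geom.bounds

    dx = 2.0 * a          # centre spacing within a row
    dy = 1.5 * r          # row spacing
    rows = []
    j = 0
    y = miny
    while y <= maxy + 1e-12:
        offset = a if (j % 2) else 0.0
        x = minx + offset
        while x <= maxx + 1e-12:
            rows.append((x, y))
            x += dx
        y = miny + (j + 1) * dy
        j += 1

    centers = [(x, y) for x, y in rows if geom.covers(Point(x, y))]
    if not centers:
        raise ValueError("no sites: no hexagon centroid falls inside the geometry")

    centers.sort(key=lambda c: (c[1], c[0]))  # south->north, then west->east
    records = []
    for sid, (cx, cy) in enumerate(centers):
        records.append({
            "site_id": sid,
            "lon": cx,
            "lat": cy,
            "hexagon": Polygon(hexagon_vertices(cx, cy, a)),
        })
    return pd.DataFrame.from_records(records)


def assign_presence(sites: pd.DataFrame,
                    occurrences: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Per-species presence flags from occurrence points.

    ``occurrences`` needs columns species/lon/lat. A hexagon is a presence
    for a species iff at least one record falls inside it; records on a
    shared boundary go to the lowest touching site_id. Records outside every
    hexagon are excluded and counted in the report.
    """
    if occurrences.empty:
        presence = pd.DataFrame(index=sites.index)
        return presence, {"excluded": 0, "species": []}
    if occurrences["species"].astype(str).str.len().eq(0).any():
        raise ValueError("species names must be non-empty")
    pts = occurrences[["lon", "lat"]].to_numpy(dtype=float)
    if not np.isfinite(pts).all():
        raise ValueError("occurrence coordinates must be finite")

    hexes = list(sites["hexagon"])
    tree = STRtree(hexes)
    species_names = sorted(occurrences["species"].unique())
    presence = pd.DataFrame(
        0, index=sites.index,
        columns=[f"presence_{s}" for s in species_names], dtype=int)
    excluded = 0
    sid = sites["site_id"].to_numpy()
    for sp, lon, lat in occurrences[["species", "lon", "lat"]].itertuples(index=False):
        p = Point(float(lon), float(lat))
        cand = tree.query(p, predicate="covered_by")
        if len(cand) == 0:
            excluded += 1
            continue
        idx = int(min(cand, key=lambda i: sid[i]))  # boundary tie -> lowest id
        presence.iloc[idx, presence.columns.get_loc(f"presence_{sp}")] = 1
    report = {"excluded": excluded, "species": species_names}
    return presence, report


def trend_surface_design(lon: np.ndarray, lat: np.ndarray) -> pd.DataFrame:
    """Nine cubic polynomial terms of z-scored longitude/latitude."""
    lo = (lon - lon.mean()) / (lon.std() if lon.std() > 0 else 1.0)
    la = (lat - lat.mean()) / (lat.std() if lat.std() > 0 else 1.0)
    return pd.DataFrame(
        {name: lo ** i * la ** j for name, (i, j) in TREND_TERMS.items()})


def trend_surface_ysp(sites: pd.DataFrame,
                      presence: np.ndarray | pd.Series) -> tuple[np.ndarray, LogitFit]:
    """Fit the spatial-only model and return Ysp = fitted P(presence).

    Backward-eliminates the nine polynomial terms by AIC, so a species whose
    presence carries no geographic trend collapses to the intercept-only
    model (Ysp == prevalence everywhere).
    """
    y = np.asarray(presence, dtype=float)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("trend surface requires both presences and absences")
    X = trend_surface_design(sites["lon"].to_numpy(), sites["lat"].to_numpy())

    current = list(X.columns)
    fit = fit_logit(y, X, current)
    while current:
        best = None
        for v in current:
            cand = [w for w in current if w != v]
            f = fit_logit(y, X, cand)
            if f.aic < fit.aic - 1e-10 and (best is None or f.aic < best[1].aic):
                best = (v, f)
        if best is None:
            break
        current = [w for w in current if w != best[0]]
        fit = best[1]
    return fit.fitted.copy(), fit


def grid_to_geojson(sites: pd.DataFrame, properties: list[str] | None = None) -> dict:
    """One GeoJSON Feature per hexagon, carrying the requested site columns."""
    properties = properties or [c for c in sites.columns
                                if c not in ("hexagon",)]
    feats = []
    for _, row in sites.iterrows():
        feats.append({
            "type": "Feature",
            "geometry": row["hexagon"].__geo_interface__,
            "properties": {k: (row[k].item() if hasattr(row[k], "item") else row[k])
                           for k in properties},
        })
    return {"type": "FeatureCollection", "features": feats}


def write_geojson(path, sites: pd.DataFrame, properties: list[str] | None = None):
    with open(path, "w") as fh:
        json.dump(grid_to_geojson(sites, properties), fh)
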