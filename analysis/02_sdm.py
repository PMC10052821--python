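"""Fit the favourability models for both virtual species.

For each species: trend-surface spatial descriptor, FDR pre-filter,
correlation pruning, stepwise-AIC selection, Wald trimming, favourability
transform, and evaluation. Prints the Wald importance table (the shape of
the study's explanatory-variable table) and the classification metrics, and
writes model JSON, per-site favourability CSV, and a GeoJSON surface.

Run after 01_simulate.py:  python analysis/02_sdm.py
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from favgerm.grid import trend_surface_ysp
from favgerm.pipeline import _jsonable
from favgerm.sdm import fit_favourability_model


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--data-dir", type=Path, default=Path("results/data"))
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    sites = pd.read_csv(args.data_dir / "sites.csv")
    layer_names = [c for c in sites.columns
                   if c not in ("site_id", "lon", "lat")
                   and not c.startswith(("presence_", "ysp_"))]
    species = [c[len("presence_"):] for c in sites.columns
               if c.startswith("presence_")]
    args.out_dir.mkdir(parents=True, exist_ok=True)

    for sp in species:
        y = sites[f"presence_{sp}"].to_numpy()
        ysp, _ = trend_surface_ysp(sites, y)
        covs = sites[layer_names].copy()
        covs["Ysp"] = ysp
        model = fit_favourability_model(y, covs)
        ev = model.evaluation
        print(f"\n=== {sp} (n1={model.n1}, n0={model.n0}) ===")
        print(model.wald.to_string(index=False))
        if model.vif is not None:
            print(f"max VIF: {model.vif.max():.2f}")
        print(f"sensitivity {ev.sensitivity:.3f}  specificity {ev.specificity:.3f}  "
              f"CCR {ev.ccr:.3f}  TSS {ev.tss:.3f}  AUC {ev.auc:.3f}")
        print(f"favourability classes: {ev.class_counts}")
        with open(args.out_dir / f"model_{sp}.json", "w") as fh:
            json.dump(model.to_dict(), fh, indent=1, default=_jsonable)
        pd.DataFrame({"site_id": sites["site_id"], "P": model.P, "F": model.F}
                     ).to_csv(args.out_dir / f"favourability_{sp}.csv",
                              index=False)


if __name__ == "__main__":
    main()
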