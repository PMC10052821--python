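"""Trait-environment linkage: PCA, two-stage PLSR with VIP, regressions.

Summarises each genotype's germination profile (PC1, GA, GE), links it to
the environmental layers of the genotype's home hexagon through two-stage
partial least squares with VIP > 1 retention, and reports simple linear
regressions on the retained predictors (the shape of the study's PLSR
optimisation table and regression figure).

Run after 01_simulate.py:  python analysis/04_linkage.py
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from favgerm import germination as germ
from favgerm.pipeline import _jsonable, link_analysis


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--data-dir", type=Path, default=Path("results/data"))
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    counts = pd.read_csv(args.data_dir / "germination_counts.csv")
    sites = pd.read_csv(args.data_dir / "sites.csv")
    genotypes = pd.read_csv(args.data_dir / "genotypes.csv")
    stats = germ.replicate_stats(counts)
    summary = germ.genotype_summary(stats)
    profile = germ.germination_profile(stats)
    layer_names = [c for c in sites.columns
                   if c not in ("site_id", "lon", "lat")
                   and not c.startswith(("presence_", "ysp_"))]

    link = link_analysis(profile, summary, genotypes,
                         sites[["site_id"] + layer_names])
    args.out_dir.mkdir(parents=True, exist_ok=True)
    with open(args.out_dir / "plsr_report.json", "w") as fh:
        json.dump(link, fh, indent=1, default=_jsonable)

    print(f"PC1 explains {link['pca']['pc1_pct']:.1f}% of the germination "
          f"profile variance ({link['pca']['imputed_cells']} cells imputed)")
    for resp, rep in link["plsr"].items():
        if "error" in rep:
            print(f"{resp}: {rep['error']}")
            continue
        print(f"{resp}: {rep['n_components']} comp, RMSEP {rep['rmsep']:.3f}, "
              f"{rep['pct_predictor_variance']:.1f}% X var, "
              f"{rep['pct_response_variance']:.1f}% y var, "
              f"VIP>1: {rep['stage1_retained']}")
    if link["regressions"]:
        print("\nsimple regressions on retained predictors:")
        print(pd.DataFrame(link["regressions"]).to_string(index=False))


if __name__ == "__main__":
    main()
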