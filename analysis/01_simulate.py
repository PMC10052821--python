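"""Generate the virtual study dataset.

Simulates the hexagonal grid with eight spatially structured environmental
layers, Bernoulli presences for one broad-niche and one narrow-niche virtual
species, and the two germination assay designs for 12 genotypes whose
dormancy depth follows a known linear function of the dry-season
precipitation layer. Writes the CSV inputs consumed by the later stages,
plus the truth record, under results/data/.

Run:  python analysis/01_simulate.py [--seed 1]
"""

import argparse
from pathlib import Path

from favgerm.pipeline import _dump_inputs
from favgerm.simulate import SimConfig, simulate_dataset


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out-dir", type=Path, default=Path("results/data"))
    args = ap.parse_args()

    data = simulate_dataset(SimConfig(seed=args.seed))
    args.out_dir.mkdir(parents=True, exist_ok=True)
    _dump_inputs(args.out_dir, data)

    sites = data["sites"]
    print(f"grid: {len(sites)} hexagons")
    for sp, t in data["truth"]["species"].items():
        print(f"{sp}: prevalence {t['prevalence']:.3f} "
              f"(mean true probability {t['mean_true_probability']:.3f})")
    print(f"germination: {data['counts'][['genotype', 'harvest', 'experiment', 'treatment', 'replicate']].drop_duplicates().shape[0]} dishes, "
          f"{len(data['counts'])} count rows")
    print(f"wrote sites/occurrences/genotypes/counts/truth to {args.out_dir}")


if __name__ == "__main__":
    main()
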