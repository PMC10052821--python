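"""Parameter-recovery studies on the virtual study system.

Runs the four seeded recovery suites — SDM cascade retention/coverage,
PLSR/VIP driver identification, germination dormancy-slope recovery, and
the specialist-vs-generalist classification-skill comparison — and writes
the rates to results/recovery.json.

Run:  python analysis/05_recovery.py [--seed 1] [--reps 25]
"""

import argparse
import json
from pathlib import Path

from favgerm import experiments as ex


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--reps", type=int, default=25)
    ap.add_argument("--out", type=Path, default=Path("results/recovery.json"))
    args = ap.parse_args()

    out = {
        "sdm": ex.sdm_recovery(args.reps, seed=args.seed),
        "plsr": ex.plsr_driver_identification(args.reps, seed=args.seed),
        "germination": ex.germination_linkage_recovery(args.reps,
                                                       seed=args.seed),
        "specialist_generalist": ex.specialist_generalist_comparison(
            args.reps, seed=args.seed),
    }
    args.out.parent.mkdir(parents=True, exist_ok=True)
    with open(args.out, "w") as fh:
        json.dump(out, fh, indent=1)
    for k, v in out.items():
        print(k, {kk: (round(vv, 3) if isinstance(vv, float) else vv)
                  for kk, vv in v.items()})


if __name__ == "__main__":
    main()
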