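#!/usr/bin/env python
"""Pairwise neural-network classification between the three lines.

Trains the two-layer feed-forward network (10 sigmoid hidden units, 70/30
split) on the recovered per-cell copy numbers for every pair of lines and
reports the held-out classification rates.  Rates near 50% would mean the
per-cell distributions are indistinguishable.
"""

import argparse
import sys
from pathlib import Path

import pandas as pd

from plugcyte.cli_io import classify_stage, load_config

RESULTS = Path("results/analysis")


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()
    cfg = load_config()
    per_cell = {p.stem.removeprefix("cells_"): pd.read_csv(p)
                for p in sorted(RESULTS.glob("cells_*.csv"))}
    reports = classify_stage(cfg, per_cell, args.seed,
                             RESULTS / "classifiers.json")
    for r in reports:
        print(f"{r.pair[0]} vs {r.pair[1]}: {100 * r.rate_overall:.1f}% "
              f"held-out rate (n_test = {r.n_test})")
    if reports:
        weakest = min(reports, key=lambda r: r.rate_overall)
        print(f"Hardest pair: {weakest.pair[0]} vs {weakest.pair[1]} "
              f"(closest copy-number distributions).")
    return 0


if __name__ == "__main__":
    sys.exit(main())
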