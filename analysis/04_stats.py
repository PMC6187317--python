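#!/usr/bin/env python
"""Dispersion statistics and one-way ANOVA across the three lines.

Summarizes each line's recovered copy numbers (mean, SD, CV, quartiles,
quartile coefficient of dispersion) and tests for expression differences
across lines with a one-way ANOVA at the p < 0.01 convention.
"""

import argparse
import sys
from pathlib import Path

import pandas as pd

from plugcyte.cli_io import stats_stage

RESULTS = Path("results/analysis")


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    args = parser.parse_args()
    per_cell = {p.stem.removeprefix("cells_"): pd.read_csv(p)
                for p in sorted(RESULTS.glob("cells_*.csv"))}
    report = stats_stage(per_cell, RESULTS / "stats.json", RESULTS / "stats.md")
    print((RESULTS / "stats.md").read_text())
    a = report["anova"]
    verdict = "significant" if a["significant"] else "not significant"
    print(f"Copy-number differences across lines are {verdict} "
          f"at the p < 0.01 convention.")
    return 0


if __name__ == "__main__":
    sys.exit(main())
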