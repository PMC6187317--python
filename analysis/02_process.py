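#!/usr/bin/env python
"""Detect and fit the trapezoidal pulses in each simulated trace.

Reads the traces written by 01_simulate.py, estimates the baseline, runs
hysteresis detection and trapezoid fitting, applies QC (doublets,
saturation, bad fits), and writes per-pulse feature tables
(T_r, T_s, T_d, I_f) next to the traces.
"""

import argparse
import sys
from pathlib import Path

import pandas as pd

from plugcyte.cli_io import load_config, process_stage

WORKDIR = Path("scratch/analysis")


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    args = parser.parse_args()
    cfg = load_config()
    for trace_path in sorted(WORKDIR.glob("trace_*.txt")):
        label = trace_path.stem.removeprefix("trace_")
        frame = process_stage(cfg, trace_path, WORKDIR / f"features_{label}.csv")
        n_pass = int((frame["qc"] == "pass").sum())
        print(f"{label}: {len(frame)} pulses fitted, {n_pass} pass QC "
              f"({100 * n_pass / max(len(frame), 1):.0f}%)")
    return 0


if __name__ == "__main__":
    sys.exit(main())
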