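#!/usr/bin/env python
"""Convert accepted pulses into per-cell diameter, concentration and
absolute copy number.

Applies the inverse plug-flow model (velocity from the rise/decline
durations, plug length from the plateau duration, volume from the channel
cross-section) and the fitted calibration line to every QC-passing pulse.
Writes per-cell tables to results/ and reports the per-line means.
"""

import argparse
import shutil
import sys
from pathlib import Path

from plugcyte.cli_io import load_config, quantify_stage, read_calibration

WORKDIR = Path("scratch/analysis")
RESULTS = Path("results/analysis")


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    args = parser.parse_args()
    cfg = load_config()
    curve = read_calibration(WORKDIR / "calibration.json")
    RESULTS.mkdir(parents=True, exist_ok=True)
    for feat_path in sorted(WORKDIR.glob("features_*.csv")):
        label = feat_path.stem.removeprefix("features_")
        cells = quantify_stage(cfg, feat_path, curve, WORKDIR / f"cells_{label}.csv")
        shutil.copy(WORKDIR / f"cells_{label}.csv", RESULTS / f"cells_{label}.csv")
        print(f"{label}: {len(cells)} cells quantified; "
              f"mean D_c = {cells['D_c_um'].mean():.1f} um, "
              f"mean n_p = {cells['n_p'].mean():.3g} copies/cell")
    return 0


if __name__ == "__main__":
    sys.exit(main())
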