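"""Optical calibration and conversion of pulse features to per-cell quantities.

The calibration is an ordinary least-squares line ``I = k*C + b`` fitted to
plateau readings of free labelled-antibody solutions of known concentration
run through the same channel.  Because the calibration solution and the cell
plug fill the same optical volume, the gain is expressed per concentration
(mV/uM) and the window volume cancels: a cell's plateau directly reports its
intracellular concentration, ``C_p = (I_f - b)/k``, and the copy number
follows as ``n_p = C_p * V * N_A`` with the plug volume from the inverse
plug-flow model.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .model_core import (
    CalibrationCurve,
    CellQuant,
    ChannelGeometry,
    InvalidFeatureError,
    PulseFeatures,
    copies_from_concentration,
    invert_pulse_times,
)

__all__ = ["fit_calibration", "quantify_cell", "quantify_run"]


def fit_calibration(points: list[tuple[float, float]]) -> CalibrationCurve:
    """OLS fit of the intensity-vs-concentration line.

    ``points`` are ``(concentration uM, intensity mV)`` pairs with at least
    two distinct concentrations.  Raises on a non-positive fitted gain.
    """
    arr = np.asarray(points, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("need at least two (concentration, intensity) points")
    conc, intensity = arr[:, 0], arr[:, 1]
    if np.unique(conc).size < 2:
        raise ValueError("need at least two distinct concentrations")
    fit = stats.linregress(conc, intensity)
    if fit.slope <= 0:
        raise ValueError("non-positive gain")
    r2 = float(fit.rvalue**2)
    return CalibrationCurve(
        gain_k=float(fit.slope),
        offset_b=float(fit.intercept),
        r_squared=min(max(r2, 0.0), 1.0),
        n_points=arr.shape[0],
    )


def quantify_cell(
    features: PulseFeatures,
    geometry: ChannelGeometry | None = None,
    calibration: CalibrationCurve | None = None,
    velocity_mode: str = "mean",
) -> CellQuant:
    """Translate one accepted pulse into per-cell quantities.

    Velocity, plug length, volume and diameter come from the inverse
    plug-flow model; concentration from the calibration line; copies from
    ``C_p * V * N_A``.  Raises ``InvalidFeatureError`` if the plateau does
    not exceed the calibration intercept.
    """
    geometry = geometry or ChannelGeometry()
    if calibration is None:
        raise ValueError("a calibration curve is required")
    velocity, plug_length, volume, diameter = invert_pulse_times(
        features, geometry, velocity_mode=velocity_mode
    )
    concentration = calibration.concentration(features.i_plateau)
    if concentration < 0:
        raise InvalidFeatureError("sub-baseline intensity")
    copies = copies_from_concentration(concentration, volume)
    return CellQuant(velocity, plug_length, volume, diameter, concentration, copies)


def quantify_run(
    features: pd.DataFrame,
    geometry: ChannelGeometry | None = None,
    calibration: CalibrationCurve | None = None,
    velocity_mode: str = "mean",
) -> pd.DataFrame:
    """Row-wise quantification of a feature table.

    Expects columns ``pulse_id, T_r_ms, T_s_ms, T_d_ms, I_f_mV`` (extra
    columns pass through the index only).  Rows that violate the model are
    skipped, with the reason recorded in the returned frame's attrs
    ``skipped`` list.  Output columns carry explicit units.
    """
    cols = ["pulse_id", "D_c_um", "C_p_uM", "n_p", "v_um_per_ms", "V_um3", "L_um"]
    records: list[dict] = []
    skipped: list[dict] = []
    for row in features.itertuples(index=False):
        feat = PulseFeatures(
            t_rise=row.T_r_ms, t_stable=row.T_s_ms, t_decline=row.T_d_ms,
            i_plateau=row.I_f_mV,
        )
        try:
            q = quantify_cell(feat, geometry, calibration, velocity_mode)
        except (InvalidFeatureError, ValueError) as exc:
            skipped.append({"pulse_id": row.pulse_id, "reason": str(exc)})
            continue
        records.append({
            "pulse_id": row.pulse_id,
            "D_c_um": q.diameter,
            "C_p_uM": q.concentration,
            "n_p": q.copies,
            "v_um_per_ms": q.velocity,
            "V_um3": q.volume,
            "L_um": q.plug_length,
        })
    out = pd.DataFrame.from_records(records, columns=cols)
    out.attrs["skipped"] = skipped
    return out
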