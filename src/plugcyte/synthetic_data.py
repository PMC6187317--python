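"""Seeded synthetic cell populations and PMT traces.

This module stands in for the instrument: it draws ground-truth cells
(diameter, copy number, velocity, arrival time) from population
distributions, then renders the trapezoidal fluorescence pulses those cells
would produce in the constriction channel, on a noisy baseline sampled at
100 kHz.  Every pulse maps back to exactly one :class:`TrueCell`, so the
downstream processing chain can be scored against known truth.

The bundled population presets carry the published per-line moments for the
three carcinoma lines (A549 lung, Hep G2 liver, HeLa cervical): diameter
means/SDs of 14.3+-1.9, 13.1+-2.2 and 12.8+-1.6 um and beta-actin copy
numbers of 9.9+-4.6e5, 6.8+-4.0e5 and 11.4+-5.5e5 per cell.  Copy numbers
default to a lognormal law (positive, right-skewed, matching the observed
~50% CVs); diameters are truncated normal, bounded below so the plug-flow
model applies.

The instrument's baseline level, noise magnitude and PMT gain are simulator
conventions chosen to put plateau levels in the observed tens-to-hundreds of
mV range (gain 85 mV/uM puts a 1 uM cell at 85 mV).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .model_core import (
    COPIES_PER_UM3_UM,
    AcquisitionSpec,
    CalibrationCurve,
    ChannelGeometry,
    forward_pulse_times,
    volume_from_diameter,
)

__all__ = [
    "PopulationSpec",
    "TrueCell",
    "Trace",
    "POPULATION_PRESETS",
    "sample_population",
    "synthesize_trace",
    "synthesize_calibration",
    "lognormal_params_from_moments",
    "trace_duration_for",
    "preset_with",
    "match_features_to_cells",
]

#: Minimum plug-length / window ratio for simulated cells.
_MIN_PLUG_RATIO = 1.1

#: Relative noise of the microscopy "image diameter" side channel.
IMAGE_DIAMETER_NOISE = 0.08


@dataclass(frozen=True)
class PopulationSpec:
    """Distributional parameters for one cell population.

    Diameters in um, copies dimensionless, velocities in um/ms, arrival rate
    in cells per second.  ``copies_law`` is ``"lognormal"`` (default) or
    ``"truncnorm"``.
    """

    label: str
    n_cells: int
    diameter_mean: float
    diameter_sd: float
    copies_mean: float
    copies_sd: float
    velocity_mean: float = 1.25
    velocity_sd: float = 0.25
    copies_law: str = "lognormal"
    arrival_rate: float = 6.0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        for name in ("diameter_mean", "copies_mean", "velocity_mean", "arrival_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("diameter_sd", "copies_sd", "velocity_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.copies_law not in ("lognormal", "truncnorm"):
            raise ValueError(f"unknown copies_law: {self.copies_law!r}")


#: Published per-line moments used as simulator defaults.
POPULATION_PRESETS: dict[str, PopulationSpec] = {
    "A549": PopulationSpec("A549", 14754, 14.3, 1.9, 9.9e5, 4.6e5),
    "HepG2": PopulationSpec("HepG2", 36949, 13.1, 2.2, 6.8e5, 4.0e5),
    "HeLa": PopulationSpec("HeLa", 24383, 12.8, 1.6, 11.4e5, 5.5e5),
}


@dataclass(frozen=True)
class TrueCell:
    """Ground-truth record for one simulated cell."""

    cell_id: int
    diameter: float
    copies: float
    velocity: float
    arrival_time: float
    image_diameter: float

    @property
    def volume(self) -> float:
        return volume_from_diameter(self.diameter)

    @property
    def concentration(self) -> float:
        return self.copies / (self.volume * COPIES_PER_UM3_UM)


@dataclass
class Trace:
    """Uniformly sampled PMT trace: time in s, intensity in mV."""

    time: np.ndarray
    intensity: np.ndarray
    sampling_rate: float  # kHz
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.time.shape != self.intensity.shape:
            raise ValueError("time and intensity must have the same shape")

    def __len__(self) -> int:
        return self.time.size


def lognormal_params_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """Solve lognormal (mu, sigma) so draws have arithmetic mean/SD (mean, sd)."""
    if mean <= 0:
        raise ValueError("mean must be positive")
    if sd < 0:
        raise ValueError("sd must be non-negative")
    sigma2 = math.log1p((sd / mean) ** 2)
    if not math.isfinite(sigma2):
        raise ValueError("infeasible moments for a lognormal law")
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def _min_diameter(geometry: ChannelGeometry) -> float:
    """Smallest diameter whose plug is ``_MIN_PLUG_RATIO`` windows long."""
    v_min = _MIN_PLUG_RATIO * geometry.window * geometry.cross_section
    return (6.0 * v_min / math.pi) ** (1.0 / 3.0)


def _draw_positive(
    rng: np.random.Generator, law: str, mean: float, sd: float, n: int, lower: float = 0.0
) -> np.ndarray:
    if sd == 0:
        if mean < lower:
            raise ValueError("degenerate distribution below the lower bound")
        return np.full(n, mean)
    if law == "lognormal":
        mu, sigma = lognormal_params_from_moments(mean, sd)
        draws = rng.lognormal(mu, sigma, size=n)
        if lower > 0.0:  # resample the rare under-bound draws
            bad = draws < lower
            while bad.any():
                draws[bad] = rng.lognormal(mu, sigma, size=int(bad.sum()))
                bad = draws < lower
        return draws
    a = (lower - mean) / sd
    tn = stats.truncnorm(a, np.inf, loc=mean, scale=sd)
    return tn.rvs(size=n, random_state=rng)


def sample_population(
    spec: PopulationSpec,
    seed: int,
    geometry: ChannelGeometry | None = None,
) -> list[TrueCell]:
    """Draw ``spec.n_cells`` ground-truth cells, deterministically per seed.

    Diameters are truncated-normal, bounded below at the diameter whose plug
    is 1.1 optical windows long (the plug-flow validity limit).  Copy numbers
    follow ``spec.copies_law`` with lognormal parameters solved so that the
    *arithmetic* mean and SD of draws match the targets.  Velocities are
    lognormal.  Arrivals form a Poisson process at ``spec.arrival_rate``
    (no enforced separation, so doublets occur naturally).  A microscopy-like
    "image diameter" with 8% relative noise is attached to each cell.
    """
    geometry = geometry or ChannelGeometry()
    rng = np.random.default_rng(seed)
    n = spec.n_cells
    d_lo = _min_diameter(geometry)
    diameters = _draw_positive(
        rng, "truncnorm", spec.diameter_mean, spec.diameter_sd, n, lower=d_lo
    )
    copies = _draw_positive(rng, spec.copies_law, spec.copies_mean, spec.copies_sd, n)
    velocities = _draw_positive(rng, "lognormal", spec.velocity_mean, spec.velocity_sd, n)
    gaps = rng.exponential(1.0 / spec.arrival_rate, size=n)
    arrivals = np.cumsum(gaps)
    image_d = diameters * (1.0 + IMAGE_DIAMETER_NOISE * rng.standard_normal(n))
    return [
        TrueCell(i, float(diameters[i]), float(copies[i]), float(velocities[i]),
                 float(arrivals[i]), float(abs(image_d[i])))
        for i in range(n)
    ]


def _trapezoid_profile(t_ms: np.ndarray, t0_ms: float, tr: float, ts: float,
                       td: float, height: float) -> np.ndarray:
    """Height-above-baseline of one trapezoidal pulse on time grid ``t_ms``."""
    knots = np.array([t0_ms, t0_ms + tr, t0_ms + tr + ts, t0_ms + tr + ts + td])
    return np.interp(t_ms, knots, [0.0, height, height, 0.0], left=0.0, right=0.0)


def synthesize_trace(
    cells: list[TrueCell],
    geometry: ChannelGeometry | None = None,
    acquisition: AcquisitionSpec | None = None,
    calibration: CalibrationCurve | None = None,
    seed: int = 0,
) -> Trace:
    """Render a full PMT trace for ``cells``.

    Each cell contributes a trapezoid whose durations come from
    :func:`forward_pulse_times` and whose plateau height above baseline is
    ``gain_k * C_p`` with ``C_p = copies / (V * N_A)``.  Overlapping pulses
    sum (exercising doublet QC downstream); Gaussian noise of SD
    ``acquisition.noise_sd`` is added and values are clipped at saturation
    when set.  Deterministic for a given seed.
    """
    geometry = geometry or ChannelGeometry()
    acquisition = acquisition or AcquisitionSpec()
    calibration = calibration or CalibrationCurve(gain_k=85.0)
    rng = np.random.default_rng(seed)

    n_samples = int(round(acquisition.duration * acquisition.sampling_rate * 1000.0))
    t_ms = np.arange(n_samples) * acquisition.dt_ms
    signal = np.zeros(n_samples)
    dt = acquisition.dt_ms
    for cell in cells:
        tr, ts, td = forward_pulse_times(cell.diameter, cell.velocity, geometry)
        height = calibration.gain_k * cell.concentration
        t0 = cell.arrival_time * 1000.0
        i0 = max(0, int(t0 / dt) - 2)
        i1 = min(n_samples, int((t0 + tr + ts + td) / dt) + 3)
        if i0 >= n_samples or i1 <= 0:
            continue
        signal[i0:i1] += _trapezoid_profile(t_ms[i0:i1], t0, tr, ts, td, height)

    intensity = acquisition.baseline + signal
    if acquisition.noise_sd > 0:
        intensity = intensity + rng.normal(0.0, acquisition.noise_sd, size=n_samples)
    if acquisition.saturation is not None:
        np.clip(intensity, None, acquisition.saturation, out=intensity)
    meta = {
        "seed": seed,
        "n_cells": len(cells),
        "geometry_side_um": geometry.side,
        "geometry_window_um": geometry.window,
        "sampling_rate_khz": acquisition.sampling_rate,
        "baseline_mv": acquisition.baseline,
        "noise_sd_mv": acquisition.noise_sd,
        "gain_k_mv_per_um": calibration.gain_k,
    }
    return Trace(t_ms / 1000.0, intensity, acquisition.sampling_rate, meta)


def trace_duration_for(cells: list[TrueCell], geometry: ChannelGeometry | None = None,
                       margin_s: float = 0.1) -> float:
    """Duration (s) long enough to contain every cell's pulse plus a margin."""
    geometry = geometry or ChannelGeometry()
    end = margin_s
    for cell in cells:
        tr, ts, td = forward_pulse_times(cell.diameter, cell.velocity, geometry)
        end = max(end, cell.arrival_time + (tr + ts + td) / 1000.0 + margin_s)
    return end


def synthesize_calibration(
    concentrations: list[float],
    gain_k: float = 85.0,
    offset_b: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> list[tuple[float, float]]:
    """Mean plateau readings for free antibody solutions of known concentration.

    Readings are baseline-subtracted plateau means: ``offset_b + gain_k * C``
    plus Gaussian noise.  Deterministic per seed.
    """
    if len(concentrations) == 0:
        raise ValueError("need at least one calibration concentration")
    conc = np.asarray(concentrations, dtype=float)
    if np.any(conc < 0):
        raise ValueError("concentrations must be non-negative")
    rng = np.random.default_rng(seed)
    readings = offset_b + gain_k * conc + rng.normal(0.0, noise_sd, size=conc.size)
    return list(zip(conc.tolist(), readings.tolist()))


def match_features_to_cells(
    features,
    cells: list[TrueCell],
    sampling_rate: float,
    tol_s: float = 0.01,
) -> list[tuple[object, TrueCell]]:
    """Pair fitted pulses with the ground-truth cells that produced them.

    Matches each pulse's start time to the nearest cell arrival within
    ``tol_s`` seconds, one-to-one in time order.  Unmatched pulses and cells
    (e.g. rejected doublets) are dropped.  Used for recovery scoring only.
    """
    arrivals = np.array([c.arrival_time for c in cells])
    order = np.argsort(arrivals)
    pairs: list[tuple[object, TrueCell]] = []
    used: set[int] = set()
    for feat in features:
        start_s = feat.start_index / (sampling_rate * 1000.0)
        idx = int(np.searchsorted(arrivals[order], start_s))
        best, best_gap = None, tol_s
        for j in (idx - 1, idx, idx + 1):
            if 0 <= j < order.size and int(order[j]) not in used:
                gap = abs(arrivals[order[j]] - start_s)
                if gap <= best_gap:
                    best, best_gap = int(order[j]), gap
        if best is not None:
            used.add(best)
            pairs.append((feat, cells[best]))
    return pairs


def preset_with(label: str, **overrides) -> PopulationSpec:
    """A copy of a bundled preset with fields overridden (e.g. ``n_cells``)."""
    return replace(POPULATION_PRESETS[label], **overrides)
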