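"""Domain types, unit conventions, and the plug-flow forward/inverse model.

The physical picture: a cell larger than the 8 um x 8 um constriction channel
deforms into a cylindrical "plug" that fills the channel lumen and translates
at constant velocity past a narrow (2.5 um) opaque-mask optical window.  The
photomultiplier therefore sees a trapezoidal fluorescence pulse per cell:

* rising domain (duration ``T_r``) while the plug front crosses the window,
* stable domain (``T_s``, plateau ``I_f``) while the plug spans the window,
* declining domain (``T_d``) while the plug tail leaves it.

Under plug flow, ``T_r = T_d = window / v`` and ``T_s = (L - window) / v``
where ``L = V / A`` is the plug length for a cell of volume ``V`` squeezed
into a channel of cross-section ``A``.  Inverting the observed durations
yields the cell's velocity, plug length, volume and spherical-equivalent
diameter; the plateau intensity, through a free-solution calibration line,
yields the intracellular concentration and hence the absolute copy number.

Units are fixed package-wide: lengths in um, times in ms, intensities in mV,
concentrations in uM, volumes in um^3; copy numbers are dimensionless counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "COPIES_PER_UM3_UM",
    "ChannelGeometry",
    "AcquisitionSpec",
    "CalibrationCurve",
    "PulseFeatures",
    "CellQuant",
    "SummaryStats",
    "PlugModelError",
    "InvalidFeatureError",
    "forward_pulse_times",
    "invert_pulse_times",
    "copies_from_concentration",
    "diameter_from_volume",
    "volume_from_diameter",
]

#: Avogadro's number expressed as molecules per um^3 per uM
#: (6.02214e23 / L / M * 1e-15 L/um^3 * 1e-6 M/uM = 602.214).
COPIES_PER_UM3_UM = 602.214


class PlugModelError(ValueError):
    """The plug-flow model does not apply (e.g. cell too small for the window)."""


class InvalidFeatureError(ValueError):
    """Pulse features violate the model's preconditions."""


@dataclass(frozen=True)
class ChannelGeometry:
    """Constriction channel and optical-window geometry.

    Parameters
    ----------
    side : float
        Side of the square channel cross-section, um.
    window : float
        Width of the chrome-mask optical gap along the flow axis, um.
    """

    side: float = 8.0
    window: float = 2.5

    def __post_init__(self) -> None:
        if self.side <= 0:
            raise ValueError("channel side must be positive")
        if self.window <= 0:
            raise ValueError("optical window must be positive")

    @property
    def cross_section(self) -> float:
        """Channel cross-sectional area, um^2."""
        return self.side * self.side


@dataclass(frozen=True)
class AcquisitionSpec:
    """PMT acquisition settings.

    ``sampling_rate`` is in kHz (so 100 means one sample every 0.01 ms),
    ``duration`` in seconds; voltages in mV.  ``saturation=None`` disables
    clipping.
    """

    sampling_rate: float = 100.0
    duration: float = 1.0
    baseline: float = 10.0
    noise_sd: float = 1.0
    saturation: float | None = None

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.saturation is not None and self.baseline >= self.saturation:
            raise ValueError("baseline must lie below saturation")

    @property
    def dt_ms(self) -> float:
        """Sample period in ms."""
        return 1.0 / self.sampling_rate


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear intensity-vs-concentration calibration ``I = k*C + b``.

    ``gain_k`` in mV/uM, ``offset_b`` in mV.  Readings are plateau levels
    above the trace baseline, so an ideal system has ``offset_b == 0``; a
    non-zero intercept absorbs residual optical background.
    """

    gain_k: float
    offset_b: float = 0.0
    r_squared: float = 1.0
    n_points: int = 2

    def __post_init__(self) -> None:
        if self.gain_k <= 0:
            raise ValueError("calibration gain must be positive")
        if not 0.0 <= self.r_squared <= 1.0:
            raise ValueError("r_squared must lie in [0, 1]")

    def concentration(self, intensity: float) -> float:
        """Invert the line: concentration (uM) for a plateau level (mV)."""
        return (intensity - self.offset_b) / self.gain_k


@dataclass
class PulseFeatures:
    """Raw per-cell pulse parameters: the three domain durations (ms) and
    the baseline-subtracted plateau level (mV), plus fit bookkeeping."""

    t_rise: float
    t_stable: float
    t_decline: float
    i_plateau: float
    start_index: int = 0
    end_index: int = 0
    fit_residual: float = 0.0
    qc_flags: frozenset[str] = field(default_factory=frozenset)

    @property
    def width_ms(self) -> float:
        return self.t_rise + self.t_stable + self.t_decline

    @property
    def accepted(self) -> bool:
        return not self.qc_flags


@dataclass(frozen=True)
class CellQuant:
    """Derived per-cell quantities.

    velocity um/ms, plug_length um, volume um^3, diameter um,
    concentration uM, copies dimensionless.
    """

    velocity: float
    plug_length: float
    volume: float
    diameter: float
    concentration: float
    copies: float

    def __post_init__(self) -> None:
        for name in ("velocity", "plug_length", "volume", "diameter"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.concentration < 0 or self.copies < 0:
            raise ValueError("concentration and copies must be non-negative")
        expected = self.concentration * self.volume * COPIES_PER_UM3_UM
        tol = 1e-9 * max(1.0, abs(expected))
        if abs(self.copies - expected) > tol:
            raise ValueError("copies != concentration * volume * N_A")
        d = diameter_from_volume(self.volume)
        if abs(self.diameter - d) > 1e-9 * d:
            raise ValueError("diameter inconsistent with volume")


@dataclass(frozen=True)
class SummaryStats:
    """Population summary: moments, quartiles and dispersion measures."""

    n: int
    mean: float
    sd: float
    cv: float
    q1: float
    q2: float
    q3: float
    qcd: float

    def __post_init__(self) -> None:
        if not self.q1 <= self.q2 <= self.q3:
            raise ValueError("quartiles must be ordered")
        if self.cv < 0:
            raise ValueError("cv must be non-negative")


def volume_from_diameter(diameter: float) -> float:
    """Sphere volume (um^3) for diameter ``diameter`` (um)."""
    return math.pi / 6.0 * diameter**3


def diameter_from_volume(volume) -> float:
    """Spherical-equivalent diameter (um) for volume ``volume`` (um^3)."""
    return (6.0 * np.asarray(volume) / math.pi) ** (1.0 / 3.0)


def forward_pulse_times(
    diameter: float, velocity: float, geometry: ChannelGeometry | None = None
) -> tuple[float, float, float]:
    """Predict (T_r, T_s, T_d) in ms for a cell traversing the window.

    The cell of spherical diameter ``diameter`` (um) deforms into a plug of
    length ``L = (pi/6) d^3 / A``; the edges take ``window / v`` to cross the
    optical gap and the plateau lasts ``(L - window) / v``.

    Raises
    ------
    PlugModelError
        If the plug would be shorter than the optical window, i.e. the cell
        is too small for the plug-flow model.
    """
    geometry = geometry or ChannelGeometry()
    if velocity <= 0:
        raise PlugModelError("velocity must be positive")
    plug_length = volume_from_diameter(diameter) / geometry.cross_section
    if plug_length < geometry.window * (1.0 - 1e-12):
        raise PlugModelError(
            f"cell too small for plug-flow model: plug length {plug_length:.3f} um "
            f"< window {geometry.window:.3f} um"
        )
    t_edge = geometry.window / velocity
    t_stable = max(plug_length - geometry.window, 0.0) / velocity
    return t_edge, t_stable, t_edge


def invert_pulse_times(
    features: PulseFeatures,
    geometry: ChannelGeometry | None = None,
    velocity_mode: str = "mean",
) -> tuple[float, float, float, float]:
    """Invert pulse durations to (velocity, plug_length, volume, diameter).

    ``velocity_mode="mean"`` uses ``v = 2*window / (T_r + T_d)`` (robust to
    mild rise/decline asymmetry); ``"rise"`` uses ``v = window / T_r``.
    Exact inverse of :func:`forward_pulse_times` when ``T_r == T_d``.
    """
    geometry = geometry or ChannelGeometry()
    if features.t_rise <= 0 or features.t_decline <= 0:
        raise InvalidFeatureError("rise and decline durations must be positive")
    if features.t_stable < 0:
        raise InvalidFeatureError("stable duration must be non-negative")
    if velocity_mode == "mean":
        velocity = 2.0 * geometry.window / (features.t_rise + features.t_decline)
    elif velocity_mode == "rise":
        velocity = geometry.window / features.t_rise
    else:
        raise ValueError(f"unknown velocity_mode: {velocity_mode!r}")
    plug_length = velocity * features.t_stable + geometry.window
    volume = geometry.cross_section * plug_length
    diameter = diameter_from_volume(volume)
    return velocity, plug_length, volume, diameter


def copies_from_concentration(concentration, volume):
    """Absolute copy number for concentration (uM) in volume (um^3).

    ``n = C * V * 602.214`` — Avogadro's number in these units.  Accepts
    scalars or arrays.
    """
    c = np.asarray(concentration, dtype=float)
    v = np.asarray(volume, dtype=float)
    if np.any(c < 0) or np.any(v < 0):
        raise ValueError("concentration and volume must be non-negative")
    out = c * v * COPIES_PER_UM3_UM
    return float(out) if out.ndim == 0 else out
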