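"""Pulse detection and trapezoid fitting on PMT traces.

A trace is reduced to per-cell :class:`~plugcyte.model_core.PulseFeatures` in
four steps: robust baseline estimation, hysteresis-threshold event detection,
least-squares trapezoid fitting of each segment, and QC filtering (doublets,
saturation, poor fits).

The trapezoid model is piecewise linear with four breakpoints
(baseline | linear rise | plateau | linear decline | baseline).  For fixed
breakpoints the optimal plateau height has a closed form, so the fit searches
only the four breakpoint positions: threshold-crossing initialization
followed by Nelder-Mead refinement of the profiled sum of squares.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .model_core import PulseFeatures
from .synthetic_data import Trace

__all__ = [
    "QCRules",
    "estimate_baseline",
    "detect_pulses",
    "fit_trapezoid",
    "extract_features",
    "qc_filter",
]


def estimate_baseline(trace: Trace, window_fraction: float = 0.01) -> tuple[float, float]:
    """Robust baseline level and noise SD of a trace.

    The trace is chunked into non-overlapping windows of
    ``window_fraction * n`` samples (at least 16); the quietest quarter of
    windows (lowest variance) is pooled, the baseline is their median and the
    SD is 1.4826x the median absolute deviation (Gaussian-consistent).

    Raises ``ValueError`` on an empty trace.
    """
    y = np.asarray(trace.intensity, dtype=float)
    if y.size == 0:
        raise ValueError("empty trace")
    if np.ptp(y) == 0.0:
        return float(y[0]), 0.0
    w = max(16, int(y.size * window_fraction))
    n_win = y.size // w
    if n_win < 2:
        med = float(np.median(y))
        sd = 1.4826 * float(np.median(np.abs(y - med)))
        return med, sd
    chunks = y[: n_win * w].reshape(n_win, w)
    variances = chunks.var(axis=1)
    n_keep = max(1, n_win // 4)
    # ties (e.g. noiseless plateaus) break toward the lower level: the
    # baseline is the quiet *low* state of the trace
    order = np.lexsort((chunks.mean(axis=1), variances))
    quiet = chunks[order[:n_keep]].ravel()
    baseline = float(np.median(quiet))
    sd = 1.4826 * float(np.median(np.abs(quiet - baseline)))
    return baseline, sd


def detect_pulses(
    trace: Trace,
    baseline: float,
    baseline_sd: float,
    k_enter: float = 5.0,
    k_exit: float = 2.0,
    min_duration_ms: float = 0.5,
    pad_samples: int = 3,
) -> list[tuple[int, int]]:
    """Hysteresis-threshold event detection.

    A segment opens where the trace exceeds ``baseline + k_enter*sd`` and
    extends over the surrounding run above ``baseline + k_exit*sd``.
    Segments shorter than ``min_duration_ms`` are dropped; survivors are
    padded by ``pad_samples`` on each side (clamped to the trace).  Returns
    half-open ``(start, end)`` index pairs.  For noiseless traces
    (``baseline_sd == 0``) an epsilon floor on the thresholds is applied.
    """
    if k_enter <= k_exit:
        raise ValueError("k_enter must exceed k_exit")
    y = np.asarray(trace.intensity, dtype=float)
    if y.size == 0:
        return []
    scale = max(np.ptp(y), 1.0)
    sd_eff = max(baseline_sd, 1e-9 * scale)
    hi = baseline + k_enter * sd_eff
    lo = baseline + k_exit * sd_eff

    above_lo = y > lo
    edges = np.diff(above_lo.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if above_lo[0]:
        starts = np.r_[0, starts]
    if above_lo[-1]:
        ends = np.r_[ends, y.size]

    min_len = int(round(min_duration_ms * trace.sampling_rate))
    segments: list[tuple[int, int]] = []
    for s, e in zip(starts, ends):
        if e - s < min_len:
            continue
        if not np.any(y[s:e] > hi):
            continue
        segments.append((max(0, s - pad_samples), min(y.size, e + pad_samples)))
    return segments


def _profiled_sse(taus: np.ndarray, t: np.ndarray, y0: np.ndarray) -> tuple[float, float]:
    """SSE of the trapezoid with breakpoints ``taus`` and closed-form height."""
    w = np.interp(t, taus, [0.0, 1.0, 1.0, 0.0], left=0.0, right=0.0)
    ww = float(w @ w)
    if ww <= 0.0:
        return float(y0 @ y0), 0.0
    h = float(w @ y0) / ww
    r = y0 - h * w
    return float(r @ r), h


def fit_trapezoid(
    trace: Trace,
    segment: tuple[int, int],
    baseline: float,
) -> PulseFeatures:
    """Least-squares trapezoid fit of one detected segment.

    Breakpoints are initialized at the 10%/90% threshold crossings of the
    baseline-subtracted segment, then refined by Nelder-Mead on the profiled
    sum of squares (the plateau height is solved in closed form at each
    step).  Rise and decline durations are floored at one sample period, so a
    sampled rectangle reports one-sample edges.  Returns features with
    durations in ms, plateau in mV above baseline, and the RMS fit residual;
    a segment with no resolvable plateau is flagged ``no_plateau``.
    """
    s, e = segment
    if e - s < 5:
        raise ValueError("segment must contain at least 5 samples")
    t = trace.time[s:e] * 1000.0  # ms
    y0 = trace.intensity[s:e] - baseline
    dt = 1.0 / trace.sampling_rate

    peak = float(y0.max())
    if peak <= 0:
        return PulseFeatures(dt, 0.0, dt, 0.0, s, e, float(np.sqrt(np.mean(y0**2))),
                             frozenset({"no_plateau"}))
    hi_idx = np.flatnonzero(y0 >= 0.9 * peak)
    lo_idx = np.flatnonzero(y0 >= 0.1 * peak)
    tau0 = np.array([t[lo_idx[0]], t[hi_idx[0]], t[hi_idx[-1]], t[lo_idx[-1]]], float)
    # strictly increasing start point for the gap parametrization
    gaps0 = np.maximum(np.diff(tau0), dt)

    # parametrize as (tau1, log-gaps) to keep ordering during the search
    x0 = np.r_[tau0[0], np.log(gaps0)]

    def objective(x: np.ndarray) -> float:
        taus = np.r_[x[0], x[0] + np.cumsum(np.exp(x[1:]))]
        sse, _ = _profiled_sse(taus, t, y0)
        return sse

    res = optimize.minimize(
        objective, x0, method="Nelder-Mead",
        options={"xatol": 1e-4 * dt, "fatol": 1e-12 * max(1.0, peak**2),
                 "maxiter": 600, "maxfev": 900},
    )
    x = res.x
    taus = np.r_[x[0], x[0] + np.cumsum(np.exp(x[1:]))]
    sse, height = _profiled_sse(taus, t, y0)
    rms = float(np.sqrt(sse / y0.size))

    t_rise = max(taus[1] - taus[0], dt)
    t_stable = max(taus[2] - taus[1], 0.0)
    t_decline = max(taus[3] - taus[2], dt)

    flags: set[str] = set()
    n_plateau_samples = int(np.sum((t >= taus[1]) & (t <= taus[2])))
    if height <= 0 or t_stable < dt or n_plateau_samples < 2:
        flags.add("no_plateau")
    return PulseFeatures(
        t_rise=float(t_rise),
        t_stable=float(t_stable),
        t_decline=float(t_decline),
        i_plateau=float(height),
        start_index=int(s),
        end_index=int(e),
        fit_residual=rms,
        qc_flags=frozenset(flags),
    )


@dataclass(frozen=True)
class QCRules:
    """Acceptance rules for fitted pulses.

    The residual rule flags a pulse when its RMS fit residual exceeds
    ``max_residual_frac`` of the plateau *and* ``residual_noise_mult`` times
    the trace noise SD — a fit is bad when its residual is structurally
    larger than the noise, not merely when the signal is small (a purely
    relative rule would trim dim cells and bias population dispersion).
    ``min_stable_ms`` is the shortest credible plateau; ``max_width_ms``
    rejects implausibly long (merged) events; pulses whose extremes deviate
    from the plateau by more than ``doublet_tolerance`` (fractional) are
    flagged as doublets; ``saturation`` (absolute mV, or None) rejects
    clipped pulses.
    """

    max_residual_frac: float = 0.10
    residual_noise_mult: float = 3.0
    min_stable_ms: float = 0.05
    max_width_ms: float = 60.0
    doublet_tolerance: float = 0.25
    saturation: float | None = None


def _count_rising_edges(y0: np.ndarray, baseline_sd: float, rate: float) -> int:
    """Number of distinct rising edges in a (baseline-subtracted) segment.

    The segment is boxcar-smoothed over 0.1 ms, differenced at a 0.3 ms lag,
    and runs above a threshold (well clear of both the noise and mid-pulse
    ripple) are counted; runs closer than the lag merge.  A singlet has one
    rising edge; summed overlapping pulses have two or more.
    """
    w = max(5, int(round(0.1 * rate)))
    s = np.convolve(y0, np.ones(w) / w, mode="same")
    lag = max(5, int(round(0.3 * rate)))
    if s.size <= lag:
        return 1
    d = s[lag:] - s[:-lag]
    peak = float(s.max())
    thresh = max(6.0 * baseline_sd * math.sqrt(2.0 / w), 0.05 * peak)
    idx = np.flatnonzero(d > thresh)
    if idx.size == 0:
        return 1
    # a slow rise can sputter across the threshold; two runs are distinct
    # pulses only if the signal is genuinely flat between them (a plateau),
    # not still climbing just below threshold
    edges = 1
    gap_starts = idx[np.flatnonzero(np.diff(idx) > lag)]
    gap_ends = idx[np.flatnonzero(np.diff(idx) > lag) + 1]
    for g0, g1 in zip(gap_starts, gap_ends):
        gap_d = d[g0:g1]
        if gap_d.size and float(gap_d.mean()) < 0.5 * thresh:
            edges += 1
    return edges


def _doublet_flag(trace: Trace, feat: PulseFeatures, baseline: float,
                  rules: QCRules, baseline_sd: float) -> bool:
    """Overlapping pulses sum, so a merged segment shows multiple rising
    edges and excursions well above the fitted plateau (or a deep dip within
    it).  The excursion band widens by 5x the noise SD so that noise extremes
    over a long plateau (the max of thousands of Gaussian samples) do not
    masquerade as doublets."""
    y0 = trace.intensity[feat.start_index:feat.end_index] - baseline
    h = feat.i_plateau
    if h <= 0:
        return False
    if _count_rising_edges(y0, baseline_sd, trace.sampling_rate) >= 2:
        return True
    margin = rules.doublet_tolerance * h + 5.0 * baseline_sd
    if float(y0.max()) > h + margin:
        return True
    # dip check inside the fitted plateau span
    dt = 1.0 / trace.sampling_rate
    t = trace.time[feat.start_index:feat.end_index] * 1000.0
    t1 = t[0] + feat.t_rise + 0.5 * dt
    t2 = t1 + feat.t_stable - dt
    inside = (t >= t1) & (t <= t2)
    if inside.sum() >= 3 and float(y0[inside].min()) < h - margin:
        return True
    return False


def qc_filter(
    trace: Trace,
    features: list[PulseFeatures],
    baseline: float,
    rules: QCRules | None = None,
    baseline_sd: float = 0.0,
) -> tuple[list[PulseFeatures], list[PulseFeatures]]:
    """Split fitted pulses into (accepted, rejected-with-reasons).

    Reasons accumulate in ``qc_flags``: ``saturated``, ``high_residual``,
    ``short_plateau``, ``doublet``, plus any flags set by the fit itself.
    """
    rules = rules or QCRules()
    accepted: list[PulseFeatures] = []
    rejected: list[PulseFeatures] = []
    for feat in features:
        flags = set(feat.qc_flags)
        seg = trace.intensity[feat.start_index:feat.end_index]
        if rules.saturation is not None and np.any(seg >= rules.saturation):
            flags.add("saturated")
        residual_cut = max(rules.max_residual_frac * feat.i_plateau,
                           rules.residual_noise_mult * baseline_sd)
        if feat.i_plateau > 0 and feat.fit_residual > residual_cut:
            flags.add("high_residual")
        if feat.t_stable < rules.min_stable_ms:
            flags.add("short_plateau")
        if feat.width_ms > rules.max_width_ms:
            flags.add("doublet")
        elif _doublet_flag(trace, feat, baseline, rules, baseline_sd):
            flags.add("doublet")
        out = PulseFeatures(
            feat.t_rise, feat.t_stable, feat.t_decline, feat.i_plateau,
            feat.start_index, feat.end_index, feat.fit_residual, frozenset(flags),
        )
        (accepted if not flags else rejected).append(out)
    return accepted, rejected


def extract_features(
    trace: Trace,
    rules: QCRules | None = None,
    k_enter: float = 5.0,
    k_exit: float = 2.0,
    min_duration_ms: float = 0.5,
) -> tuple[list[PulseFeatures], list[PulseFeatures], float, float]:
    """Full processing of one trace: baseline -> detect -> fit -> QC.

    Returns ``(accepted, rejected, baseline, baseline_sd)``.
    """
    baseline, sd = estimate_baseline(trace)
    segments = detect_pulses(trace, baseline, sd, k_enter=k_enter, k_exit=k_exit,
                             min_duration_ms=min_duration_ms)
    feats = [fit_trapezoid(trace, seg, baseline) for seg in segments]
    accepted, rejected = qc_filter(trace, feats, baseline, rules, baseline_sd=sd)
    return accepted, rejected, baseline, sd
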