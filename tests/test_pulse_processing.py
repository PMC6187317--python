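"""Baseline estimation, pulse detection and trapezoid fitting."""

import numpy as np
import pytest

from plugcyte.pulse_processing import (
    QCRules,
    detect_pulses,
    estimate_baseline,
    extract_features,
    fit_trapezoid,
    qc_filter,
)
from plugcyte.synthetic_data import Trace


class TestEstimateBaseline:
    def test_constant_trace(self, make_trace):
        trace = make_trace([], baseline=5.0)
        b, sd = estimate_baseline(trace)
        assert b == 5.0 and sd == 0.0

    def test_baseline_with_sparse_pulses(self, make_trace):
        # pulses occupy <20% of samples; robust estimate must ignore them
        pulses = [(10, 1, 3, 1, 80.0), (40, 1, 5, 1, 120.0)]
        trace = make_trace(pulses, duration_ms=100, baseline=10.0, noise_sd=1.0,
                           seed=1)
        b, sd = estimate_baseline(trace)
        assert b == pytest.approx(10.0, abs=0.1)
        assert sd == pytest.approx(1.0, rel=0.2)

    def test_mad_consistency_on_pure_noise(self):
        rng = np.random.default_rng(2)
        y = 10.0 + rng.normal(0, 1.0, 100_000)
        trace = Trace(np.arange(y.size) / 1e5, y, 100.0)
        _, sd = estimate_baseline(trace)
        assert sd == pytest.approx(1.0, rel=0.10)

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError):
            estimate_baseline(Trace(np.array([]), np.array([]), 100.0))


class TestDetectPulses:
    def test_flat_trace_yields_nothing(self, make_trace):
        trace = make_trace([], baseline=10.0, noise_sd=1.0, seed=0)
        b, sd = estimate_baseline(trace)
        assert detect_pulses(trace, b, sd) == []

    def test_three_noiseless_trapezoids(self, make_trace):
        pulses = [(10, 2, 5, 2, 80.0), (40, 1, 3, 1, 50.0), (70, 2, 8, 2, 120.0)]
        trace = make_trace(pulses, duration_ms=100, baseline=10.0)
        segments = detect_pulses(trace, 10.0, 0.0)
        assert len(segments) == 3
        for (s, e), (t0, tr, ts, td, _) in zip(segments, pulses):
            # boundaries within one sample of the true span (minus padding)
            assert abs((s + 3) * 0.01 - t0) <= 0.02
            assert abs((e - 3) * 0.01 - (t0 + tr + ts + td)) <= 0.02

    def test_overlapping_pulses_merge(self, make_trace):
        trace = make_trace([(10, 2, 5, 2, 80.0), (13, 2, 5, 2, 60.0)],
                           baseline=10.0)
        assert len(detect_pulses(trace, 10.0, 0.0)) == 1

    def test_short_blips_dropped(self, make_trace):
        trace = make_trace([(10, 0.05, 0.1, 0.05, 80.0)], baseline=10.0)
        assert detect_pulses(trace, 10.0, 0.0, min_duration_ms=0.5) == []

    def test_translation_invariance(self, make_trace):
        p = [(10, 2, 5, 2, 80.0)]
        t1 = make_trace(p, duration_ms=100, baseline=10.0)
        t2 = make_trace([(30, 2, 5, 2, 80.0)], duration_ms=120, baseline=10.0)
        (s1, e1), = detect_pulses(t1, 10.0, 0.0)
        (s2, e2), = detect_pulses(t2, 10.0, 0.0)
        shift = int(round(20 * 100))  # 20 ms at 100 kHz
        assert (s2 - s1, e2 - e1) == (shift, shift)

    def test_threshold_ordering_enforced(self, make_trace):
        trace = make_trace([], baseline=10.0)
        with pytest.raises(ValueError):
            detect_pulses(trace, 10.0, 1.0, k_enter=2.0, k_exit=5.0)


class TestFitTrapezoid:
    def test_exact_trapezoid_recovery(self, make_trace):
        # the published A549 mean row shape: T_r=2.0, T_s=4.5, T_d=1.5 ms
        trace = make_trace([(10, 2.0, 4.5, 1.5, 85.0)], baseline=10.0)
        (seg,) = detect_pulses(trace, 10.0, 0.0)
        feat = fit_trapezoid(trace, seg, 10.0)
        assert feat.t_rise == pytest.approx(2.0, abs=0.01)
        assert feat.t_stable == pytest.approx(4.5, abs=0.01)
        assert feat.t_decline == pytest.approx(1.5, abs=0.01)
        assert feat.i_plateau == pytest.approx(85.0, rel=1e-3)
        assert feat.fit_residual < 0.5

    def test_rectangle_limit(self, make_trace):
        # instantaneous edges: fitted rise/decline floor at one sample period
        trace = make_trace([(10, 1e-9, 5.0, 1e-9, 60.0)], baseline=10.0)
        (seg,) = detect_pulses(trace, 10.0, 0.0)
        feat = fit_trapezoid(trace, seg, 10.0)
        assert feat.t_rise == pytest.approx(0.01, abs=0.011)
        assert feat.t_decline == pytest.approx(0.01, abs=0.011)
        assert feat.i_plateau == pytest.approx(60.0, rel=0.01)

    def test_noisy_ensemble_accuracy(self, make_trace):
        rng = np.random.default_rng(5)
        errs_h, errs_t = [], []
        for i in range(200):
            tr, ts, td = rng.uniform(1.0, 3.0), rng.uniform(2.0, 8.0), rng.uniform(1.0, 3.0)
            h = rng.uniform(40.0, 150.0)
            trace = make_trace([(10, tr, ts, td, h)], duration_ms=10 + tr + ts + td + 10,
                               baseline=10.0, noise_sd=0.02 * h, seed=1000 + i)
            b, sd = estimate_baseline(trace)
            segs = detect_pulses(trace, b, sd)
            assert len(segs) == 1
            feat = fit_trapezoid(trace, segs[0], b)
            errs_h.append(abs(feat.i_plateau - h) / h)
            errs_t.append(abs(feat.t_stable - ts) / ts)
        assert np.median(errs_h) < 0.01
        assert np.median(errs_t) < 0.05

    def test_monotone_segment_flagged(self, make_trace):
        # a pure ramp has no plateau
        n = 1000
        y = 10.0 + np.linspace(0, 50, n)
        trace = Trace(np.arange(n) / 1e5, y, 100.0)
        feat = fit_trapezoid(trace, (0, n), 10.0)
        assert "no_plateau" in feat.qc_flags

    def test_tiny_segment_rejected(self, make_trace):
        trace = make_trace([], duration_ms=1.0, baseline=10.0)
        with pytest.raises(ValueError):
            fit_trapezoid(trace, (0, 4), 10.0)


class TestQcFilter:
    def test_clean_population_fully_accepted(self, make_trace):
        pulses = [(10 + 30 * k, 2, 5, 2, 60 + 10 * k) for k in range(3)]
        trace = make_trace(pulses, duration_ms=120, baseline=10.0, noise_sd=0.5,
                           seed=3)
        accepted, rejected, _, _ = extract_features(trace)
        assert len(accepted) == 3 and rejected == []

    def test_merged_doublet_rejected(self, make_trace):
        trace = make_trace([(10, 2, 5, 2, 80.0), (14, 2, 5, 2, 70.0)],
                           duration_ms=60, baseline=10.0, noise_sd=0.5, seed=4)
        accepted, rejected, _, _ = extract_features(trace)
        assert accepted == []
        assert any("doublet" in r.qc_flags or "high_residual" in r.qc_flags
                   for r in rejected)

    def test_saturated_pulse_rejected(self, make_trace):
        trace = make_trace([(10, 2, 5, 2, 80.0)], duration_ms=40, baseline=10.0,
                           saturation=50.0)
        b, sd = estimate_baseline(trace)
        segs = detect_pulses(trace, b, sd)
        feats = [fit_trapezoid(trace, s, b) for s in segs]
        _, rejected = qc_filter(trace, feats, b, QCRules(saturation=50.0),
                                baseline_sd=sd)
        assert len(rejected) == 1
        assert "saturated" in rejected[0].qc_flags

    def test_overlong_event_rejected(self, make_trace):
        trace = make_trace([(10, 2, 80, 2, 60.0)], duration_ms=120, baseline=10.0)  # plateau-majority trace: tie-break picks the low state
        b, sd = estimate_baseline(trace)
        feats = [fit_trapezoid(trace, s, b) for s in detect_pulses(trace, b, sd)]
        _, rejected = qc_filter(trace, feats, b, QCRules(max_width_ms=60.0))
        assert rejected and "doublet" in rejected[0].qc_flags


def test_noiseless_count_identity(make_trace):
    """On a noiseless trace, accepted pulses = non-overlapping simulated cells."""
    pulses = [(15 + 25 * k, 2, 6, 2, 70.0) for k in range(6)]
    trace = make_trace(pulses, duration_ms=200, baseline=10.0)
    accepted, rejected, _, _ = extract_features(trace)
    assert len(accepted) == 6 and rejected == []
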