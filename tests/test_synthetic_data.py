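"""Population sampling and trace synthesis."""

import numpy as np
import pytest

from plugcyte.model_core import (
    COPIES_PER_UM3_UM,
    AcquisitionSpec,
    CalibrationCurve,
    volume_from_diameter,
)
from plugcyte.synthetic_data import (
    POPULATION_PRESETS,
    PopulationSpec,
    TrueCell,
    lognormal_params_from_moments,
    preset_with,
    sample_population,
    synthesize_calibration,
    synthesize_trace,
)


def _spec(**kw):
    base = dict(label="t", n_cells=100, diameter_mean=14.0, diameter_sd=1.5,
                copies_mean=1e6, copies_sd=4e5)
    base.update(kw)
    return PopulationSpec(**base)


class TestMomentMatching:
    def test_lognormal_moment_inversion_monte_carlo(self):
        # Monte-Carlo oracle: 1e6 draws must reproduce the target arithmetic
        # mean and SD to 1%
        mean, sd = 9.9e5, 4.6e5
        mu, sigma = lognormal_params_from_moments(mean, sd)
        draws = np.random.default_rng(0).lognormal(mu, sigma, 1_000_000)
        assert draws.mean() == pytest.approx(mean, rel=0.01)
        assert draws.std(ddof=1) == pytest.approx(sd, rel=0.01)

    def test_infeasible_moments_raise(self):
        with pytest.raises(ValueError):
            lognormal_params_from_moments(-1.0, 1.0)


class TestSamplePopulation:
    def test_deterministic_given_seed(self):
        a = sample_population(_spec(), 42)
        b = sample_population(_spec(), 42)
        assert a == b

    def test_zero_sd_yields_identical_cells(self):
        cells = sample_population(_spec(diameter_sd=0.0, copies_sd=0.0,
                                        velocity_sd=0.0), 1)
        assert all(c.diameter == 14.0 for c in cells)
        assert all(c.copies == 1e6 for c in cells)

    def test_population_mean_within_three_se(self):
        spec = preset_with("A549", n_cells=10_000)
        cells = sample_population(spec, 7)
        copies = np.array([c.copies for c in cells])
        se = spec.copies_sd / np.sqrt(spec.n_cells)
        assert abs(copies.mean() - 9.9e5) < 3 * se

    def test_diameters_respect_plug_flow_floor(self, geometry):
        cells = sample_population(_spec(diameter_mean=8.0, diameter_sd=3.0), 3)
        min_plug = 1.1 * geometry.window
        for c in cells:
            assert volume_from_diameter(c.diameter) / geometry.cross_section >= min_plug

    def test_arrivals_ordered(self):
        cells = sample_population(_spec(), 5)
        arrivals = [c.arrival_time for c in cells]
        assert arrivals == sorted(arrivals)

    def test_presets_carry_published_moments(self):
        assert POPULATION_PRESETS["A549"].diameter_mean == 14.3
        assert POPULATION_PRESETS["HepG2"].copies_mean == 6.8e5
        assert POPULATION_PRESETS["HeLa"].copies_sd == 5.5e5


class TestSynthesizeTrace:
    def test_empty_cell_list_is_baseline_plus_noise(self):
        acq = AcquisitionSpec(duration=0.1, baseline=10.0, noise_sd=1.0)
        trace = synthesize_trace([], acquisition=acq, seed=3)
        assert len(trace) == 10_000
        assert trace.intensity.mean() == pytest.approx(10.0, abs=0.1)
        assert trace.intensity.std() == pytest.approx(1.0, rel=0.1)

    def test_single_cell_noiseless_plateau_level(self, geometry):
        # a cell at exactly 1.0 uM with gain 85 mV/uM must plateau at 85 mV
        # above baseline (the published A549 row pairs I_f=85.0 mV with
        # C_p=1.0 uM)
        d = 14.3
        copies = 1.0 * volume_from_diameter(d) * COPIES_PER_UM3_UM
        cell = TrueCell(0, d, copies, 1.25, 0.02, d)
        acq = AcquisitionSpec(duration=0.1, baseline=0.0, noise_sd=0.0)
        trace = synthesize_trace([cell], geometry, acq,
                                 CalibrationCurve(gain_k=85.0), seed=0)
        assert trace.intensity.max() == pytest.approx(85.0, abs=1e-9)
        # plateau, not just a peak: many samples at the plateau level
        assert (np.abs(trace.intensity - 85.0) < 1e-9).sum() > 1000

    def test_overlapping_pulses_sum(self, geometry):
        d, v = 14.3, 1.25
        copies = 1.0 * volume_from_diameter(d) * COPIES_PER_UM3_UM
        a = TrueCell(0, d, copies, v, 0.010, d)
        b = TrueCell(1, d, copies, v, 0.012, d)
        acq = AcquisitionSpec(duration=0.1, baseline=0.0, noise_sd=0.0)
        trace = synthesize_trace([a, b], geometry, acq,
                                 CalibrationCurve(gain_k=85.0), seed=0)
        assert trace.intensity.max() > 85.0 * 1.5

    def test_saturation_clips(self, geometry):
        d = 14.3
        copies = 2.0 * volume_from_diameter(d) * COPIES_PER_UM3_UM
        cell = TrueCell(0, d, copies, 1.25, 0.02, d)
        acq = AcquisitionSpec(duration=0.1, baseline=0.0, noise_sd=0.0,
                              saturation=100.0)
        trace = synthesize_trace([cell], geometry, acq,
                                 CalibrationCurve(gain_k=85.0), seed=0)
        assert trace.intensity.max() == pytest.approx(100.0)

    def test_byte_identical_given_seed(self):
        cells = sample_population(_spec(n_cells=5), 1)
        acq = AcquisitionSpec(duration=2.0)
        t1 = synthesize_trace(cells, acquisition=acq, seed=11)
        t2 = synthesize_trace(cells, acquisition=acq, seed=11)
        assert np.array_equal(t1.intensity, t2.intensity)
        assert t1.intensity.tobytes() == t2.intensity.tobytes()


class TestSynthesizeCalibration:
    def test_noiseless_line_evaluation(self):
        points = synthesize_calibration([0.0, 1.0], gain_k=85.0, offset_b=2.0)
        assert points[0][1] == pytest.approx(2.0)
        assert points[1][1] == pytest.approx(87.0)

    def test_empty_concentration_list_rejected(self):
        with pytest.raises(ValueError):
            synthesize_calibration([])

    def test_noisy_series_round_trips_through_fit(self):
        from plugcyte.quantification import fit_calibration

        conc = [0.0, 0.5, 1.0, 1.5, 2.0]
        points = synthesize_calibration(conc, gain_k=85.0, offset_b=2.0,
                                        noise_sd=1.0, seed=4)
        curve = fit_calibration(points)
        # slope SE for this design: sigma / sqrt(sum (c - cbar)^2) = 1/sqrt(2.5)
        assert abs(curve.gain_k - 85.0) < 3 * (1.0 / np.sqrt(2.5))
        assert curve.r_squared > 0.99
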