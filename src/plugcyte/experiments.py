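"""Reusable study drivers: the numbered analysis scripts, the test suite and
the acceptance script all run their experiments through these functions.

Two kinds of computation live here:

* arithmetic on the published per-line summary table (quartile dispersion
  from printed quartiles; the copy-number identity n_p = C_p * V(D_c) * N_A
  applied to printed means), used as consistency checks of the model; and
* seeded simulation experiments (round-trip recovery through the full
  trace -> features -> quantities chain; ANOVA significance at reduced n;
  pairwise classifier runs on population draws).
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .classification import rate_matrix
from .model_core import (
    AcquisitionSpec,
    CalibrationCurve,
    ChannelGeometry,
    copies_from_concentration,
    volume_from_diameter,
)
from .population_stats import anova_oneway, summarize
from .pulse_processing import QCRules, extract_features
from .quantification import quantify_cell
from .synthetic_data import (
    POPULATION_PRESETS,
    PopulationSpec,
    TrueCell,
    lognormal_params_from_moments,
    match_features_to_cells,
    preset_with,
    sample_population,
    synthesize_trace,
    trace_duration_for,
)

__all__ = [
    "PRINTED_QUARTILES",
    "PRINTED_CV_PCT",
    "PRINTED_MEANS",
    "printed_qcd_pct",
    "copy_number_identity",
    "recovery_experiment",
    "significance_experiment",
    "trio_classification",
]

#: Published per-line copy-number quartiles (Q1, Q2, Q3), copies per cell.
PRINTED_QUARTILES: dict[str, tuple[float, float, float]] = {
    "A549": (6.53e5, 9.27e5, 1.25e6),
    "HepG2": (4.11e5, 5.92e5, 8.34e5),
    "HeLa": (7.81e5, 1.05e6, 1.38e6),
}

#: Published per-line copy-number CVs (percent).
PRINTED_CV_PCT: dict[str, float] = {"A549": 46.4, "HepG2": 58.9, "HeLa": 47.8}

#: Published per-line means: diameter (um), concentration (uM), copies.
PRINTED_MEANS: dict[str, tuple[float, float, float]] = {
    "A549": (14.3, 1.0, 9.9e5),
    "HepG2": (13.1, 0.9, 6.8e5),
    "HeLa": (12.8, 1.7, 11.4e5),
}


def printed_qcd_pct(label: str) -> float:
    """Quartile coefficient of dispersion (percent) recomputed from the
    published quartiles, through the same summarize-level arithmetic the
    pipeline applies (a 5-point sample whose type-7 quartiles are exactly
    the printed ones)."""
    q1, q2, q3 = PRINTED_QUARTILES[label]
    sample = [0.5 * q1, q1, q2, q3, 2.0 * q3]  # type-7 quartiles of n=5 hit indices 1..3
    s = summarize(sample)
    assert math.isclose(s.q1, q1) and math.isclose(s.q3, q3)
    return 100.0 * s.qcd


def copy_number_identity(label: str) -> dict[str, float]:
    """Apply n = C * (pi/6) D^3 * N_A to the published mean (C_p, D_c) and
    compare with the published mean copy number.

    Exact equality is not expected (a mean of products is not the product of
    means); agreement within ~10% documents model consistency.
    """
    d_c, c_p, n_p = PRINTED_MEANS[label]
    predicted = copies_from_concentration(c_p, volume_from_diameter(d_c))
    return {
        "diameter_um": d_c,
        "concentration_um": c_p,
        "printed_copies": n_p,
        "predicted_copies": predicted,
        "rel_diff": abs(predicted - n_p) / n_p,
    }


def _recovery_specs(n_cells: int, arrival_rate: float) -> dict[str, PopulationSpec]:
    """Per-line specs with copy-number SD set from the published CVs."""
    specs = {}
    for label in POPULATION_PRESETS:
        base = POPULATION_PRESETS[label]
        specs[label] = preset_with(
            label, n_cells=n_cells, arrival_rate=arrival_rate,
            copies_sd=base.copies_mean * PRINTED_CV_PCT[label] / 100.0,
        )
    return specs


def _process_batch(
    cells: list[TrueCell],
    geometry: ChannelGeometry,
    calibration: CalibrationCurve,
    noise_sd: float,
    seed: int,
) -> list[tuple[object, TrueCell]]:
    """Synthesize one trace for a batch of cells, process it, and return
    accepted pulses matched one-to-one to their ground-truth cells."""
    duration = trace_duration_for(cells, geometry)
    acq = AcquisitionSpec(duration=duration, baseline=10.0, noise_sd=noise_sd)
    trace = synthesize_trace(cells, geometry, acq, calibration, seed=seed)
    accepted, _, _, _ = extract_features(trace, QCRules())
    return match_features_to_cells(accepted, cells, trace.sampling_rate)


def recovery_experiment(
    n_cells: int = 1000,
    noise_frac: float = 0.02,
    seed: int = 1,
    arrival_rate: float = 3.0,
    batch_size: int = 250,
    gain_k: float = 85.0,
) -> dict[str, dict]:
    """Round-trip recovery through the full simulate -> process -> quantify
    chain, per population.

    ``n_cells`` ground-truth cells per line are rendered into traces with
    additive noise of SD ``noise_frac`` times the line's mean plateau level,
    processed, matched back to truth, and quantified.  The modest arrival
    rate keeps coincidence (doublet) losses low so the experiment measures
    the fidelity of the inversion chain itself; doublet QC has its own tests.

    Returns, per line: median relative errors of recovered copy number and
    diameter, recovered vs generating population CV, and counts.
    """
    geometry = ChannelGeometry()
    calibration = CalibrationCurve(gain_k=gain_k)
    specs = _recovery_specs(n_cells, arrival_rate)
    rng_seeds = np.random.SeedSequence(seed).generate_state(4 * len(specs), dtype=np.uint32)
    results: dict[str, dict] = {}
    for i, (label, spec) in enumerate(sorted(specs.items())):
        cells = sample_population(spec, int(rng_seeds[2 * i] & 0x7FFFFFFF), geometry)
        mean_conc = float(np.mean([c.concentration for c in cells]))
        noise_sd = noise_frac * gain_k * mean_conc
        pairs: list[tuple[object, TrueCell]] = []
        base = int(rng_seeds[2 * i + 1] & 0x3FFFFFFF)
        for j in range(0, len(cells), batch_size):
            batch = cells[j:j + batch_size]
            t0 = batch[0].arrival_time
            batch = [dataclasses.replace(c, arrival_time=c.arrival_time - t0 + 0.05)
                     for c in batch]
            pairs.extend(_process_batch(batch, geometry, calibration, noise_sd,
                                        seed=base + j))
        recovered, true_np, true_dc = [], [], []
        for feat, cell in pairs:
            q = quantify_cell(feat, geometry, calibration)
            recovered.append(q)
            true_np.append(cell.copies)
            true_dc.append(cell.diameter)
        rec_np = np.array([q.copies for q in recovered])
        rec_dc = np.array([q.diameter for q in recovered])
        true_np = np.array(true_np)
        true_dc = np.array(true_dc)
        cv_rec = 100.0 * rec_np.std(ddof=1) / rec_np.mean()
        results[label] = {
            "n_simulated": n_cells,
            "n_matched": len(pairs),
            "median_rel_err_np": float(np.median(np.abs(rec_np - true_np) / true_np)),
            "median_rel_err_dc": float(np.median(np.abs(rec_dc - true_dc) / true_dc)),
            "cv_recovered_pct": float(cv_rec),
            "cv_generating_pct": PRINTED_CV_PCT[label],
            "mean_recovered_np": float(rec_np.mean()),
            "recovered_np": rec_np,
            "recovered_dc": rec_dc,
        }
    return results


def significance_experiment(n_per_group: int = 500, seed: int = 1):
    """One-way ANOVA across three lognormal populations drawn with the
    published per-line copy-number means and SDs, at reduced n."""
    rng = np.random.default_rng(seed)
    groups = []
    for label, spec in sorted(POPULATION_PRESETS.items()):
        mu, sigma = lognormal_params_from_moments(spec.copies_mean, spec.copies_sd)
        groups.append(rng.lognormal(mu, sigma, n_per_group))
    return anova_oneway(groups)


def trio_classification(
    n_per_group: int = 2000,
    seed: int = 1,
    hidden_units: int = 10,
) -> dict[tuple[str, str], float]:
    """Pairwise NN classification rates on copy-number draws from the three
    published population laws.  Returns ``{(label_a, label_b): rate}``."""
    rng = np.random.default_rng(seed)
    populations = {}
    for label, spec in sorted(POPULATION_PRESETS.items()):
        mu, sigma = lognormal_params_from_moments(spec.copies_mean, spec.copies_sd)
        populations[label] = rng.lognormal(mu, sigma, n_per_group)
    reports = rate_matrix(populations, hidden_units=hidden_units, seed=seed)
    return {r.pair: r.rate_overall for r in reports}
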