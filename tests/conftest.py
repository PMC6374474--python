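"""Shared fixtures: small tissues and the session-scoped study simulations.

The heavyweight simulate-then-analyze studies (19-recording oscillation
study, full-scale wave, 292-event spike study) are computed once per
session and reused by unit and acceptance tests alike.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.stats import truncnorm

import calwave as cw
from calwave.pipeline import analyze_oscillations, analyze_spikes, analyze_wave


@pytest.fixture(scope="session")
def small_tissue() -> cw.CellLabelMap:
    return cw.make_tissue(
        cw.TissueSpec(image_size_px=(96, 96), pixel_size_um=0.5, n_cells=40, seed=7)
    )


def rim_origin(tissue: cw.CellLabelMap, row: int) -> tuple[int, int]:
    """A pixel just inside the left rim of the tissue disk."""
    col = int(np.argmax(tissue.labels[row] > 0)) + 2
    return (row, col)


@pytest.fixture(scope="session")
def oscillation_study():
    """19 recordings at the observed oscillation statistics, 5% noise.

    Inter-peak gaps truncated-normal (mean 1320 s, SD 515 s, lower bound
    one FWHM), pulse FWHM 291 s, amplitude fold change 0.5; ~123 pooled
    intervals.  Returns (summary, truth gap list, generative mean).
    """
    p = cw.OscillationParams(duration_s=11000.0)
    a = (p.fwhm_s - p.mean_interpeak_s) / p.sd_interpeak_s
    gen_mean = float(
        truncnorm(a, np.inf, loc=p.mean_interpeak_s, scale=p.sd_interpeak_s).mean()
    )
    tissue = cw.make_tissue(
        cw.TissueSpec(image_size_px=(64, 64), pixel_size_um=0.5, n_cells=30, seed=0)
    )
    per_trace, truth_gaps = [], []
    for k in range(19):
        movie, truth = cw.simulate_oscillations(tissue, p, seed=100 + k)
        movie = cw.add_noise(movie, 0.05 * p.baseline_level, seed=200 + k)
        events, _, _ = analyze_oscillations(movie, tissue)
        per_trace.append(events)
        truth_gaps.extend(np.diff(truth.events["onset_s"].to_numpy()).tolist())
    return cw.summarize_oscillations(per_trace), truth_gaps, gen_mean


@pytest.fixture(scope="session")
def spike_study():
    """292 spikes on 100 cells, amplitude fold change 1, noise 10% of it."""
    p = cw.SpikeParams()
    tissue = cw.make_tissue(
        cw.TissueSpec(image_size_px=(176, 176), pixel_size_um=0.5, n_cells=100, seed=1)
    )
    movie, truth = cw.simulate_spikes(
        tissue, p, duration_s=300.0, frame_interval_s=1.0, seed=2, n_events=292
    )
    movie = cw.add_noise(movie, 0.10 * 1000.0 * p.peak_fold_change, seed=3)
    events, _ = analyze_spikes(movie, tissue)
    return events, truth, tissue


@pytest.fixture(scope="session")
def wave_study():
    """Full-scale wave (512x512, 0.5 um/px, 2 -> 0.5 um/s, dt 1 s).

    Returns dict with noise-free and 5%-noise kinematics plus the truth
    table and generator params.
    """
    tissue = cw.make_tissue(
        cw.TissueSpec(image_size_px=(512, 512), pixel_size_um=0.5, n_cells=800, seed=1)
    )
    origin = rim_origin(tissue, 256)
    cents = tissue.centroids_um()
    oy, ox = origin[0] * 0.5, origin[1] * 0.5
    d_max = max(np.hypot(y - oy, x - ox) for y, x in cents.values())
    t_prop = 2 * d_max / (2.0 + 0.5)
    p = cw.WaveParams(
        origin_px=origin,
        stim_time_s=5.0,
        decay_time_s=t_prop + 8.0,
        crescent_onset_s=None,
        crescent_duration_s=None,
    )
    movie, truth = cw.simulate_wave(
        tissue, p, duration_s=5.0 + t_prop + 12.0, frame_interval_s=1.0, seed=2
    )
    kin_clean, act_clean, _ = analyze_wave(movie, tissue)
    noisy = cw.add_noise(movie, 0.05 * p.baseline_level, seed=3)
    kin_noisy, _, _ = analyze_wave(noisy, tissue)
    return {
        "tissue": tissue,
        "params": p,
        "truth": truth,
        "kin_clean": kin_clean,
        "act_clean": act_clean,
        "kin_noisy": kin_noisy,
        "d_max": float(d_max),
    }


@pytest.fixture(scope="session")
def crescent_study():
    """SAM-scale wave with the programmed crescent (23 s / 16 s) and decay
    (73 s); propagation completes before decay as in the small meristem."""
    tissue = cw.make_tissue(
        cw.TissueSpec(image_size_px=(160, 160), pixel_size_um=0.5, n_cells=300, seed=1)
    )
    p = cw.WaveParams(origin_px=rim_origin(tissue, 80))
    movie, truth = cw.simulate_wave(tissue, p, duration_s=100.0, frame_interval_s=1.0, seed=2)
    movie = cw.add_noise(movie, 0.05 * p.baseline_level, seed=3)
    kin, act, fc = analyze_wave(movie, tissue)
    return {"tissue": tissue, "params": p, "truth": truth, "kin": kin}
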