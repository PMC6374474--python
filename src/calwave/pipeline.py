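"""High-level analysis pipelines gluing traces, detectors and summaries.

Each ``analyze_*`` function takes a calibrated movie plus a label map and
returns the module-level result objects; the CLI wraps these and handles
file I/O.  Parameters arrive as plain keyword arguments with the package
defaults, so library users and config files share one vocabulary.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import oscillations as osc
from . import spikes as spk
from . import waves as wav
from .movie import CellLabelMap, Movie
from .traces import (
    BaselineEstimate,
    Trace,
    estimate_baseline,
    extract_cell_traces,
    extract_global_trace,
    fold_change,
    smooth_trace,
)


def analyze_oscillations(
    movie: Movie,
    labels: CellLabelMap | None = None,
    smoothing_penalty: float | None = None,
    baseline_window_s: float = 1455.0,
    baseline_percentile: float = 10.0,
    min_prominence_rel: float = 0.2,
    min_separation_s: float | None = None,
) -> tuple[list[osc.PeakEvent], Trace, BaselineEstimate]:
    """Global-trace peak detection for one recording.

    With ``min_separation_s=None`` the separation floor is chosen
    adaptively as the median FWHM of a first detection pass: the shortest
    admissible inter-peak gap is about one pulse width, so a larger floor
    would censor genuinely close peak pairs and bias the inter-peak mean
    upward.  ``smoothing_penalty=None`` selects the spline penalty by
    generalized cross-validation.
    """
    raw = extract_global_trace(movie, labels)
    smoothed = smooth_trace(raw, smoothing_penalty)
    baseline = estimate_baseline(smoothed, baseline_window_s, baseline_percentile)
    if min_separation_s is None:
        first = osc.detect_peaks(
            smoothed, baseline, min_prominence_rel, min_separation_s=4 * raw.dt
        )
        widths = [e.fwhm_s for e in first if e.fwhm_s]
        if not widths:
            return first, smoothed, baseline
        min_separation_s = float(np.median(widths))
    events = osc.detect_peaks(smoothed, baseline, min_prominence_rel, min_separation_s)
    return events, smoothed, baseline


def analyze_spikes(
    movie: Movie,
    labels: CellLabelMap,
    threshold_fc: float = 0.5,
    min_duration_s: float = 1.0,
    max_gap_s: float = 2.0,
    baseline_percentile: float = 10.0,
) -> tuple[list[spk.SpikeEvent], dict[int, Trace]]:
    """Per-cell spike detection on fold-change traces.

    Spike movies are dominated by resting frames, so the per-cell baseline
    is the constant global percentile of that cell's own trace.
    """
    cell_raw = extract_cell_traces(movie, labels)
    fc_traces: dict[int, Trace] = {}
    for cid, tr in cell_raw.items():
        base = estimate_baseline(tr, mode="constant", percentile=baseline_percentile)
        fc_traces[cid] = fold_change(tr, base)
    events = spk.detect_spikes(fc_traces, threshold_fc, min_duration_s, max_gap_s)
    return events, fc_traces


def _prestim_baseline(tr: Trace, stim_time_s: float, percentile: float) -> BaselineEstimate:
    pre = tr.values[tr.times_s < stim_time_s]
    if pre.size >= 3:
        return BaselineEstimate(np.full(tr.values.size, float(pre.mean())), "prestim_mean")
    return estimate_baseline(tr, mode="constant", percentile=percentile)


def analyze_wave(
    movie: Movie,
    labels: CellLabelMap,
    stim: wav.StimulusContext | None = None,
    threshold_fc: float = 0.5,
    low_fc_threshold: float = 0.2,
    inner_exclusion_um: float = 4.0,
    front_percentile: float = 100.0,
    diminished_frac: float = 0.1,
    baseline_percentile: float = 10.0,
    exclude_cells: tuple[int, ...] = (),
) -> tuple[wav.WaveKinematics, wav.ActivationMap, dict[int, Trace]]:
    """Full wave kinematics for one stimulated recording.

    Per-cell and global baselines are the pre-stimulus mean (cells near the
    origin can stay active for most of the recording, which defeats
    percentile baselines).  ``exclude_cells`` masks wounded or saturated
    cells at the contact point.
    """
    if stim is None:
        if movie.origin_px is None or movie.stim_time_s is None:
            raise ValueError("stimulus origin and time are required for wave analysis")
        stim = wav.StimulusContext(movie.origin_px, movie.stim_time_s, movie.pixel_size_um)

    cell_raw = extract_cell_traces(movie, labels)
    for cid in exclude_cells:
        cell_raw.pop(int(cid), None)
    fc_traces = {
        cid: fold_change(tr, _prestim_baseline(tr, stim.stim_time_s, baseline_percentile))
        for cid, tr in cell_raw.items()
    }
    graw = extract_global_trace(movie, labels)
    gfc = fold_change(graw, _prestim_baseline(graw, stim.stim_time_s, baseline_percentile))

    act = wav.activation_times(fc_traces, stim, threshold_fc)
    centroids = labels.centroids_um()
    curve = wav.front_distance_curve(act, centroids, stim, percentile=front_percentile)
    v1, v2, split = wav.estimate_velocities(curve)
    crescent = wav.detect_crescent(
        fc_traces, act, centroids, stim, low_fc_threshold, inner_exclusion_um
    )
    dec, censored = wav.decay_time(gfc, stim, diminished_frac)
    gmax, _ = wav.wave_max_fold_change(gfc, None)
    kin = wav.WaveKinematics(
        front_curve=curve,
        v_first_half_um_s=v1,
        v_second_half_um_s=v2,
        split_time_s=split,
        max_fold_change=gmax,
        crescent_onset_s=None if crescent is None else crescent[0],
        crescent_duration_s=None if crescent is None else crescent[1],
        decay_time_s=dec,
        decay_censored=censored,
    )
    return kin, act, fc_traces


def activation_table(
    act: wav.ActivationMap,
    labels: CellLabelMap,
    stim: wav.StimulusContext,
) -> pd.DataFrame:
    """Tidy per-cell activation table (cell_id, activation_s, distance_um)."""
    cents = labels.centroids_um()
    oy, ox = stim.origin_um
    rows = []
    for cid in sorted(act.activation_s):
        y, x = cents[cid]
        rows.append(
            {
                "cell_id": cid,
                "activation_s": act.activation_s[cid],
                "distance_um": float(np.hypot(y - oy, x - ox)),
            }
        )
    return pd.DataFrame(rows)
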