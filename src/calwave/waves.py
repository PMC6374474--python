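"""Kinematics of mechanically induced intercellular calcium waves.

From per-cell fold-change traces and the stimulus context this module
derives: the per-cell activation-time map, the front-distance curve, the
two-phase velocity estimate (fast early phase, slow late phase, split at
the temporal midpoint of the propagation), the dark-crescent interval, the
global decay time and the maximum fold change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .traces import Trace


@dataclass
class StimulusContext:
    origin_px: tuple[int, int]
    stim_time_s: float
    pixel_size_um: float

    @property
    def origin_um(self) -> tuple[float, float]:
        return (self.origin_px[0] * self.pixel_size_um,
                self.origin_px[1] * self.pixel_size_um)


@dataclass
class ActivationMap:
    """First threshold-crossing time per cell (None = never activated)."""

    activation_s: dict[int, float | None]
    threshold_fc: float

    def activated(self) -> dict[int, float]:
        return {c: t for c, t in self.activation_s.items() if t is not None}


@dataclass
class WaveKinematics:
    front_curve: pd.DataFrame  # columns t_s, distance_um
    v_first_half_um_s: float
    v_second_half_um_s: float
    split_time_s: float
    max_fold_change: float | None = None
    crescent_onset_s: float | None = None
    crescent_duration_s: float | None = None
    decay_time_s: float | None = None
    decay_censored: bool = False

    def to_dict(self) -> dict:
        return {
            "v_first_half_um_s": self.v_first_half_um_s,
            "v_second_half_um_s": self.v_second_half_um_s,
            "split_time_s": self.split_time_s,
            "max_fold_change": self.max_fold_change,
            "crescent_onset_s": self.crescent_onset_s,
            "crescent_duration_s": self.crescent_duration_s,
            "decay_time_s": self.decay_time_s,
            "decay_censored": self.decay_censored,
        }


def _distances(centroids_um: dict[int, tuple[float, float]], stim: StimulusContext) -> dict[int, float]:
    oy, ox = stim.origin_um
    return {c: float(np.hypot(y - oy, x - ox)) for c, (y, x) in centroids_um.items()}


def activation_times(
    cell_traces: dict[int, Trace],
    stim: StimulusContext,
    threshold_fc: float = 0.5,
) -> ActivationMap:
    """First time at or after the stimulus each cell crosses the threshold.

    The crossing is linearly interpolated between the bracketing frames;
    cells that never cross map to None.
    """
    out: dict[int, float | None] = {}
    for cid, tr in cell_traces.items():
        t, v = tr.times_s, tr.values
        if stim.stim_time_s > t[-1]:
            raise ValueError("stimulus time is after the end of the movie")
        i0 = int(np.searchsorted(t, stim.stim_time_s))
        above = np.flatnonzero(v[i0:] >= threshold_fc)
        if above.size == 0:
            out[int(cid)] = None
            continue
        k = i0 + int(above[0])
        if k == 0 or v[k - 1] >= threshold_fc:
            out[int(cid)] = float(t[k])
        else:
            frac = (threshold_fc - v[k - 1]) / (v[k] - v[k - 1])
            out[int(cid)] = float(t[k - 1] + frac * (t[k] - t[k - 1]))
    return ActivationMap(out, threshold_fc)


def front_distance_curve(
    act: ActivationMap,
    centroids_um: dict[int, tuple[float, float]],
    stim: StimulusContext,
    times_s: np.ndarray | None = None,
    percentile: float = 100.0,
) -> pd.DataFrame:
    """Front distance vs time: running max of a high percentile of
    origin-distances among cells activated by each frame time.

    The default percentile 100 tracks the farthest activated cell — exact
    for a clean radial wave; lower it to trim spurious early activations.
    The curve spans the activation interval only (first to last activation),
    so a flat post-propagation tail never dilutes velocity fits.
    """
    activated = act.activated()
    if len(activated) < 3:
        raise ValueError("need at least 3 activated cells to track a front")
    d = _distances(centroids_um, stim)
    t_act = np.array([activated[c] for c in sorted(activated)])
    dist = np.array([d[c] for c in sorted(activated)])
    t0, t1 = float(t_act.min()), float(t_act.max())
    if times_s is None:
        times_s = np.unique(t_act)
    tsel = np.asarray(times_s, dtype=float)
    tsel = tsel[(tsel >= t0) & (tsel <= t1)]
    rows = []
    best = 0.0
    for t in tsel:
        sel = dist[t_act <= t]
        if sel.size == 0:
            continue
        best = max(best, float(np.percentile(sel, percentile)))
        rows.append((float(t), best))
    return pd.DataFrame(rows, columns=["t_s", "distance_um"])


def estimate_velocities(
    curve: pd.DataFrame,
    split_mode: str = "time_midpoint",
    burn_in_frac: float = 0.05,
) -> tuple[float, float, float]:
    """Least-squares front speeds for the first and second half (by time).

    The split falls at the temporal midpoint between the first and last
    activation in the curve; an initial ``burn_in_frac`` of the span is
    discarded before fitting the first half (the front statistic needs a
    few cells before it stabilizes).  Returns (v_first, v_second, t_split).
    """
    if split_mode != "time_midpoint":
        raise ValueError(f"unknown split_mode {split_mode!r}")
    t = curve["t_s"].to_numpy(float)
    dist = curve["distance_um"].to_numpy(float)
    if t.size < 4:
        raise ValueError("front curve needs at least 4 samples")
    t0, t1 = t[0], t[-1]
    split = (t0 + t1) / 2
    lo = t0 + burn_in_frac * (t1 - t0)
    first = (t >= lo) & (t <= split)
    second = t > split
    if first.sum() < 2 or second.sum() < 2:
        raise ValueError("degenerate half: not enough samples to fit a slope")
    v1 = float(np.polyfit(t[first], dist[first], 1)[0])
    v2 = float(np.polyfit(t[second], dist[second], 1)[0])
    return v1, v2, float(split)


def detect_crescent(
    cell_traces: dict[int, Trace],
    act: ActivationMap,
    centroids_um: dict[int, tuple[float, float]],
    stim: StimulusContext,
    low_fc_threshold: float = 0.2,
    inner_exclusion_um: float = 4.0,
    min_cells: int = 3,
) -> tuple[float, float] | None:
    """Dark-crescent interval: (onset after stimulus, duration), or None.

    Per frame within the propagation interval, among activated cells whose
    origin-distance lies between the inner exclusion radius (the cells
    hugging the stimulation site stay bright longest) and the current front
    distance, the crescent is the longest contiguous run of frames where
    more than half are below ``low_fc_threshold``.  The search stops at the
    last activation because once the wave has decayed everywhere the whole
    tissue is dark and the annulus criterion is no longer meaningful.
    """
    activated = act.activated()
    if len(activated) < 3:
        return None
    d = _distances(centroids_um, stim)
    any_tr = next(iter(cell_traces.values()))
    times = any_tr.times_s
    t_last = max(activated.values())
    curve = front_distance_curve(act, centroids_um, stim, times_s=times)
    front = np.interp(times, curve["t_s"], curve["distance_um"])
    cids = sorted(set(cell_traces) & set(activated))
    vals = np.stack([cell_traces[c].values for c in cids])  # (n_cells, T)
    dist = np.array([d[c] for c in cids])
    t_act = np.array([activated[c] for c in cids])

    dark = np.zeros(times.size, dtype=bool)
    for i, t in enumerate(times):
        if t < stim.stim_time_s or t > t_last:
            continue
        sel = (dist > inner_exclusion_um) & (dist < front[i]) & (t_act <= t)
        if sel.sum() < min_cells:
            continue
        frac = float(np.mean(vals[sel, i] < low_fc_threshold))
        dark[i] = frac > 0.5
    if not dark.any():
        return None
    # longest contiguous dark run
    best_len, best_start, run = 0, 0, 0
    for i, flag in enumerate(dark):
        run = run + 1 if flag else 0
        if run > best_len:
            best_len, best_start = run, i - run + 1
    dt = float(times[1] - times[0])
    onset = float(times[best_start]) - stim.stim_time_s
    return onset, best_len * dt


def decay_time(
    global_fc: Trace,
    stim: StimulusContext,
    diminished_frac: float = 0.1,
) -> tuple[float | None, bool]:
    """Time after the stimulus at which the global response has decayed.

    First time after the post-stimulus global peak when the fold change
    drops to ``diminished_frac`` of the peak, minus the stimulus time.
    Returns (time, censored): censored is True when the trace never decays
    within the recording.
    """
    t, v = global_fc.times_s, global_fc.values
    after = t >= stim.stim_time_s
    if not after.any():
        raise ValueError("no frames after the stimulus")
    i0 = int(np.argmax(after))
    ipk = i0 + int(np.argmax(v[i0:]))
    level = diminished_frac * v[ipk]
    below = np.flatnonzero(v[ipk:] <= level)
    if below.size == 0:
        return None, True
    k = ipk + int(below[0])
    if k > ipk and v[k - 1] > level:
        frac = (v[k - 1] - level) / (v[k - 1] - v[k])
        t_cross = float(t[k - 1] + frac * (t[k] - t[k - 1]))
    else:
        t_cross = float(t[k])
    return t_cross - stim.stim_time_s, False


def wave_max_fold_change(
    global_fc: Trace, cell_traces: dict[int, Trace] | None = None
) -> tuple[float, pd.DataFrame | None]:
    """Maximum of the global fold-change trace, plus per-cell maxima."""
    gmax = float(np.max(global_fc.values))
    table = None
    if cell_traces is not None:
        table = pd.DataFrame(
            {
                "cell_id": sorted(cell_traces),
                "max_fold_change": [
                    float(np.max(cell_traces[c].values)) for c in sorted(cell_traces)
                ],
            }
        )
    return gmax, table
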