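"""Single-cell spike detection, duration classification, rate estimation."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .traces import Trace

DEFAULT_BINS: tuple[tuple[float, float], ...] = ((1.0, 5.0), (5.0, 10.0), (10.0, np.inf))


@dataclass
class SpikeEvent:
    cell_id: int
    onset_s: float
    offset_s: float
    duration_s: float
    peak_fold_change: float
    censored: bool = False


@dataclass
class SpikeSummary:
    n_events: int
    n_classified: int
    n_subthreshold: int
    bin_fractions: list[float]
    bins: tuple[tuple[float, float], ...]
    n_cells: int | None = None
    rate_per_100_cells: float | None = None
    rate_window_s: float | None = None

    def to_dict(self) -> dict:
        return {
            "n_events": self.n_events,
            "n_classified": self.n_classified,
            "n_subthreshold": self.n_subthreshold,
            "bins_s": [[lo, None if np.isinf(hi) else hi] for lo, hi in self.bins],
            "bin_fractions": self.bin_fractions,
            "n_cells": self.n_cells,
            "rate_per_100_cells": self.rate_per_100_cells,
            "rate_window_s": self.rate_window_s,
        }


def _interp_crossing(t0: float, v0: float, t1: float, v1: float, level: float) -> float:
    if v1 == v0:
        return float(t1)
    return float(t0 + (level - v0) / (v1 - v0) * (t1 - t0))


def detect_spikes(
    cell_traces: dict[int, Trace],
    threshold_fc: float = 0.5,
    min_duration_s: float = 1.0,
    max_gap_s: float = 2.0,
) -> list[SpikeEvent]:
    """Threshold-crossing spike events on per-cell fold-change traces.

    An event is a maximal run with fold change >= ``threshold_fc``; runs in
    the same cell separated by at most ``max_gap_s`` are merged (cells that
    spike repeatedly over minutes stay resolvable by setting the gap to 0).
    Onset and offset are linearly interpolated at the threshold crossing.
    Events clipped by the start or end of the recording are flagged
    ``censored``; their duration is a lower bound.
    """
    events: list[SpikeEvent] = []
    for cid, tr in sorted(cell_traces.items()):
        v = tr.values
        t = tr.times_s
        above = v >= threshold_fc
        if not above.any():
            continue
        # run boundaries in sample indices
        edges = np.flatnonzero(np.diff(above.astype(np.int8)))
        starts = [0] if above[0] else []
        starts += (edges[~above[edges]] + 1).tolist()
        ends = (edges[above[edges]]).tolist()
        if above[-1]:
            ends.append(v.size - 1)
        runs = list(zip(starts, ends))
        # merge runs separated by short gaps
        merged: list[list[int]] = []
        for s, e in runs:
            if merged and (t[s] - t[merged[-1][1]]) <= max_gap_s:
                merged[-1][1] = e
            else:
                merged.append([s, e])
        for s, e in merged:
            censored = False
            if s == 0:
                onset = float(t[0])
                censored = True
            else:
                onset = _interp_crossing(t[s - 1], v[s - 1], t[s], v[s], threshold_fc)
            if e == v.size - 1:
                offset = float(t[-1])
                censored = True
            else:
                offset = _interp_crossing(t[e], v[e], t[e + 1], v[e + 1], threshold_fc)
            dur = float(offset - onset)
            if dur < min_duration_s and not censored:
                continue
            events.append(
                SpikeEvent(int(cid), onset, offset, dur, float(v[s : e + 1].max()), censored)
            )
    events.sort(key=lambda ev: (ev.onset_s, ev.cell_id))
    return events


def classify_durations(
    events: list[SpikeEvent],
    bins: tuple[tuple[float, float], ...] = DEFAULT_BINS,
) -> SpikeSummary:
    """Fractions of events per duration bin.

    Censored events are excluded (duration unknown); events shorter than the
    lowest bin edge are counted separately, so bin counts + sub-threshold
    count = number of classified candidates.
    """
    for (lo, hi), (lo2, _) in zip(bins, bins[1:]):
        if hi > lo2 or lo >= hi:
            raise ValueError("bins must be increasing and non-overlapping")
    usable = [e for e in events if not e.censored]
    lowest = bins[0][0]
    sub = sum(e.duration_s < lowest for e in usable)
    n_classified = len(usable) - sub
    counts = []
    for lo, hi in bins:
        counts.append(sum(lo <= e.duration_s < hi for e in usable if e.duration_s >= lowest))
    fractions = [c / n_classified if n_classified else 0.0 for c in counts]
    return SpikeSummary(
        n_events=len(events),
        n_classified=n_classified,
        n_subthreshold=sub,
        bin_fractions=fractions,
        bins=bins,
    )


def spike_rate(
    events: list[SpikeEvent],
    n_cells: int,
    observation_span_s: float,
    window_s: float = 30.0,
) -> float:
    """Events per 100 cells per ``window_s`` of observation."""
    if n_cells < 1 or observation_span_s <= 0:
        raise ValueError("need n_cells >= 1 and a positive span")
    if observation_span_s < window_s:
        raise ValueError("observation span shorter than the rate window")
    return len(events) * (100.0 / n_cells) * (window_s / observation_span_s)


def events_to_frame(events: list[SpikeEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cell_id": e.cell_id,
                "onset_s": e.onset_s,
                "offset_s": e.offset_s,
                "duration_s": e.duration_s,
                "peak_fold_change": e.peak_fold_change,
                "censored": e.censored,
            }
            for e in events
        ],
        columns=["cell_id", "onset_s", "offset_s", "duration_s",
                 "peak_fold_change", "censored"],
    )
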