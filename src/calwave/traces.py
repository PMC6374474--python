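"""Intensity traces: extraction, spline smoothing, baseline, fold change.

The normalized amplitude statistic used throughout is the fold change
(I - I0)/I0, where I is the instantaneous mean intensity of a region (the
whole tissue or one cell) and I0 its estimated resting baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline
from scipy.ndimage import percentile_filter, uniform_filter1d

from .movie import CellLabelMap, Movie


@dataclass
class Trace:
    """Uniformly sampled intensity time series.

    ``kind`` is one of raw / smoothed / fold_change; ``source`` is "global"
    or the integer cell id.
    """

    times_s: np.ndarray
    values: np.ndarray
    kind: str = "raw"
    source: object = "global"

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times_s.shape != self.values.shape:
            raise ValueError("times and values must have equal length")

    @property
    def dt(self) -> float:
        return float(self.times_s[1] - self.times_s[0])

    def is_uniform(self, rtol: float = 1e-6) -> bool:
        steps = np.diff(self.times_s)
        return bool(np.allclose(steps, steps[0], rtol=rtol))


@dataclass
class BaselineEstimate:
    """Resting-level series I0(t) on the same grid as its trace."""

    values: np.ndarray
    method: str
    window_s: float | None = None
    percentile: float = 10.0


def extract_global_trace(movie: Movie, mask: CellLabelMap | None = None) -> Trace:
    """Mean intensity over a region of interest, per frame.

    The ROI is the foreground of ``mask`` (labels > 0) or the whole frame.
    """
    if mask is not None:
        fg = mask.foreground
        if mask.labels.shape != movie.data.shape[1:]:
            raise ValueError("mask shape does not match movie frames")
        if not fg.any():
            raise ValueError("mask selects no pixels")
        vals = movie.data[:, fg].mean(axis=1, dtype=np.float64)
    else:
        vals = movie.data.reshape(movie.n_frames, -1).mean(axis=1, dtype=np.float64)
    return Trace(movie.times_s, vals, kind="raw", source="global")


def extract_cell_traces(movie: Movie, labels: CellLabelMap) -> dict[int, Trace]:
    """One raw trace per nonzero label (mean over that cell's pixels)."""
    if labels.labels.shape != movie.data.shape[1:]:
        raise ValueError("label image does not match movie frames")
    ids = labels.cell_ids
    if ids.size == 0:
        raise ValueError("label image contains no cells")
    lab = labels.labels.ravel()
    nmax = int(lab.max())
    counts = np.bincount(lab, minlength=nmax + 1)
    sums = np.empty((movie.n_frames, nmax + 1))
    for t in range(movie.n_frames):
        sums[t] = np.bincount(lab, weights=movie.data[t].ravel(), minlength=nmax + 1)
    times = movie.times_s
    return {
        int(c): Trace(times, sums[:, c] / counts[c], kind="raw", source=int(c))
        for c in ids
    }


def smooth_trace(trace: Trace, smoothing_penalty: float | None = None) -> Trace:
    """Natural cubic smoothing spline evaluated on the input grid.

    ``smoothing_penalty`` is the roughness penalty lambda: 0 interpolates the
    data, very large values converge to the least-squares line.  ``None``
    selects the penalty by generalized cross-validation.
    """
    if not trace.is_uniform():
        raise ValueError("smoothing requires a uniform time grid")
    if trace.times_s.size < 4:
        raise ValueError("need at least 4 samples to fit a cubic spline")
    if smoothing_penalty is not None and smoothing_penalty < 0:
        raise ValueError("penalty must be >= 0")
    if smoothing_penalty == 0:
        vals = trace.values.copy()
    else:
        spl = make_smoothing_spline(trace.times_s, trace.values, lam=smoothing_penalty)
        vals = spl(trace.times_s)
    return Trace(trace.times_s, vals, kind="smoothed", source=trace.source)


def estimate_baseline(
    trace: Trace,
    window_s: float | None = None,
    percentile: float = 10.0,
    mode: str = "rolling",
) -> BaselineEstimate:
    """Rolling lower-percentile baseline (robust to sparse transients).

    A centred percentile filter of width ``window_s`` followed by mild box
    smoothing; ``mode='constant'`` (or a window longer than the trace)
    returns the global percentile instead.
    """
    n = trace.values.size
    if mode not in ("rolling", "constant"):
        raise ValueError(f"unknown baseline mode {mode!r}")
    if mode == "constant" or window_s is None:
        level = float(np.percentile(trace.values, percentile))
        return BaselineEstimate(np.full(n, level), "constant", None, percentile)
    dt = trace.dt
    if window_s < 5 * dt:
        raise ValueError("baseline window must span at least 5 frames")
    win = int(round(window_s / dt))
    if win >= n:
        warnings.warn("baseline window exceeds trace span; using constant mode")
        return estimate_baseline(trace, mode="constant", percentile=percentile)
    win += win % 2 == 0  # centred filter wants an odd width
    base = percentile_filter(trace.values, percentile, size=win, mode="nearest")
    base = uniform_filter1d(base, size=max(3, win // 4), mode="nearest")
    base = np.minimum(base, trace.values.max())
    return BaselineEstimate(base, "rolling_percentile", window_s, percentile)


def fold_change(trace: Trace, baseline: BaselineEstimate) -> Trace:
    """Pointwise (I - I0)/I0; dimensionless and scale invariant."""
    base = np.asarray(baseline.values, dtype=float)
    if base.shape != trace.values.shape:
        raise ValueError("baseline grid does not match trace")
    if np.any(base <= 0):
        raise ValueError("baseline must be strictly positive for fold change")
    return Trace(trace.times_s, (trace.values - base) / base,
                 kind="fold_change", source=trace.source)


def traces_to_frame(traces: dict[int, Trace] | list[Trace]) -> pd.DataFrame:
    """Tidy long-format table (source, time_s, value, kind) for CSV export."""
    items = traces.values() if isinstance(traces, dict) else traces
    parts = [
        pd.DataFrame(
            {"source": t.source, "time_s": t.times_s, "value": t.values, "kind": t.kind}
        )
        for t in items
    ]
    return pd.concat(parts, ignore_index=True)
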