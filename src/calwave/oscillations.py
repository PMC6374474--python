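"""Global oscillation statistics: peaks, inter-peak times, FWHM, height.

Summaries follow the convention mean ± relative standard error (SE/mean),
with inter-peak intervals pooled across recordings but never computed across
recording boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .stats import SampleSummary, summarize_sample
from .traces import BaselineEstimate, Trace


@dataclass
class PeakEvent:
    """A detected oscillation peak with its FWHM geometry."""

    peak_time_s: float
    peak_value: float
    baseline_at_peak: float
    height: float
    fwhm_s: float | None = None
    left_half_s: float | None = None
    right_half_s: float | None = None
    truncated: bool = False


@dataclass
class OscillationSummary:
    n_peaks: int
    n_intervals: int
    inter_peak_times_s: list[float]
    interpeak: SampleSummary | None
    fwhm: SampleSummary | None
    height: SampleSummary | None

    def to_dict(self) -> dict:
        def block(s: SampleSummary | None) -> dict | None:
            return None if s is None else s.to_dict()

        return {
            "n_peaks": self.n_peaks,
            "n_intervals": self.n_intervals,
            "interpeak_s": block(self.interpeak),
            "fwhm_s": block(self.fwhm),
            "height": block(self.height),
        }


def detect_peaks(
    smoothed: Trace,
    baseline: BaselineEstimate,
    min_prominence_rel: float = 0.2,
    min_separation_s: float = 60.0,
) -> list[PeakEvent]:
    """Local maxima with relative prominence and a minimum separation.

    Prominence threshold is ``min_prominence_rel`` times the dynamic range
    (global max minus the median baseline), so detection is invariant under
    positive affine intensity transforms.  Each peak is returned with its
    FWHM measured against the local baseline.
    """
    if min_separation_s <= 0:
        raise ValueError("min_separation_s must be positive")
    vals = smoothed.values
    base = np.asarray(baseline.values)
    span = float(vals.max() - np.median(base))
    if span <= 0:
        return []
    dt = smoothed.dt
    idx, _ = find_peaks(
        vals,
        prominence=min_prominence_rel * span,
        distance=max(1, int(round(min_separation_s / dt))),
    )
    events = []
    for i in idx:
        b = float(base[i])
        ev = PeakEvent(
            peak_time_s=float(smoothed.times_s[i]),
            peak_value=float(vals[i]),
            baseline_at_peak=b,
            height=float(vals[i] - b),
        )
        measure_fwhm(smoothed, ev, baseline)
        events.append(ev)
    return events


def measure_fwhm(
    trace: Trace, peak: PeakEvent, baseline: BaselineEstimate
) -> float | None:
    """Full width at half maximum of one peak, against its local baseline.

    The half level is baseline + height/2; each crossing is located by
    linear interpolation between the bracketing samples.  Peaks whose half
    level is never crossed on one side (truncated by the recording) are
    flagged and excluded from summaries.
    """
    vals = trace.values
    times = trace.times_s
    i = int(np.argmin(np.abs(times - peak.peak_time_s)))
    half = peak.baseline_at_peak + peak.height / 2

    def crossing(direction: int) -> float | None:
        j = i
        while 0 <= j + direction < vals.size:
            k = j + direction
            if vals[k] < half:
                # interpolate between j (>= half) and k (< half)
                frac = (vals[j] - half) / (vals[j] - vals[k])
                return float(times[j] + frac * (times[k] - times[j]))
            j = k
        return None

    left = crossing(-1)
    right = crossing(+1)
    if left is None or right is None:
        peak.truncated = True
        peak.fwhm_s = None
        return None
    peak.left_half_s, peak.right_half_s = left, right
    peak.fwhm_s = right - left
    return peak.fwhm_s


def summarize_oscillations(events_per_trace: list[list[PeakEvent]]) -> OscillationSummary:
    """Pool inter-peak intervals and FWHM across recordings.

    Intervals are differences of consecutive peak times *within* each
    recording; a recording with fewer than two peaks contributes none.
    """
    intervals: list[float] = []
    fwhms: list[float] = []
    heights: list[float] = []
    n_peaks = 0
    for events in events_per_trace:
        ts = sorted(e.peak_time_s for e in events)
        n_peaks += len(events)
        intervals.extend(np.diff(ts).tolist())
        fwhms.extend(e.fwhm_s for e in events if not e.truncated and e.fwhm_s)
        heights.extend(e.height for e in events)
    return OscillationSummary(
        n_peaks=n_peaks,
        n_intervals=len(intervals),
        inter_peak_times_s=intervals,
        interpeak=summarize_sample(intervals) if intervals else None,
        fwhm=summarize_sample(fwhms) if fwhms else None,
        height=summarize_sample(heights) if heights else None,
    )
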