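"""Synthetic calcium-imaging movies with ground-truth event tables.

Real shoot-apical-meristem (SAM) recordings show three kinds of cytoplasmic
Ca2+ signal: slow tissue-wide *oscillations* (inter-peak time ~22 min, pulse
FWHM ~4 min 51 s, relative amplitude ~0.5), sporadic single-cell *spikes*
(mostly 1-5 s, a minority longer than 10 s), and mechanically induced radial
*waves* (front speed ~2 um/s slowing to ~0.5 um/s, peak fold change ~2.3,
a transient dark crescent behind the front, global decay by ~73 s).  This
module renders calibrated movies with exactly those statistics as defaults
and returns a table of every rendered event, so detector output can be
scored against known truth.

The tissue is a Voronoi mosaic of roughly isodiametric cells tiling a
centred disk — a minimal stand-in for the SAM epidermis.  Intensities are
kept as floats; writers quantize to 16-bit.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import truncnorm

from .movie import CellLabelMap, Movie

BACKGROUND_FRACTION = 0.1  # background level as fraction of tissue baseline

TRUTH_COLUMNS = ["kind", "cell_id", "onset_s", "duration_s", "amplitude"]


@dataclass
class TissueSpec:
    """Geometry of the synthetic cell mosaic.

    ``cell_diameter_um`` is a target mean; the Voronoi construction yields
    cells of comparable but not identical size.
    """

    image_size_px: tuple[int, int] = (256, 256)
    pixel_size_um: float = 0.5
    n_cells: int = 100
    cell_diameter_um: float = 4.0
    seed: int = 0

    def validate(self) -> None:
        h, w = self.image_size_px
        if h < 16 or w < 16:
            raise ValueError("image must be at least 16x16 pixels")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.cell_diameter_um <= 0:
            raise ValueError("cell_diameter_um must be positive")


@dataclass
class OscillationParams:
    """Tissue-wide oscillation model: Gaussian pulses on a flat baseline.

    Inter-pulse gaps are truncated-normal (lower bound = one FWHM so pulses
    stay resolved); each pulse multiplies the whole tissue by
    ``1 + peak_fold_change * g(t)`` with ``g`` a unit Gaussian of the
    requested FWHM.
    """

    mean_interpeak_s: float = 1320.0   # 22 min
    sd_interpeak_s: float = 515.0      # 8 min 35 s
    fwhm_s: float = 291.0              # 4 min 51 s
    peak_fold_change: float = 0.5
    baseline_level: float = 1000.0
    duration_s: float = 7200.0
    frame_interval_s: float = 5.0

    def validate(self) -> None:
        vals = [self.mean_interpeak_s, self.sd_interpeak_s, self.fwhm_s,
                self.baseline_level, self.duration_s, self.frame_interval_s]
        if any(v <= 0 for v in vals) or self.peak_fold_change < 0:
            raise ValueError("oscillation parameters must be positive")
        if self.fwhm_s >= self.mean_interpeak_s:
            raise ValueError("fwhm_s must be below mean_interpeak_s")
        if self.frame_interval_s > self.fwhm_s / 4:
            raise ValueError("frame interval too coarse for the pulse width")


@dataclass
class SpikeParams:
    """Single-cell spike model: rectangular transients from a duration mixture.

    The default mixture reproduces the observed duration fractions (70% at
    1-5 s, 13% longer than 10 s) and the default rate the observed
    "one cell in a hundred every 20-40 s" (1/3000 per cell per second).
    """

    rate_per_cell_per_s: float = 1.0 / 3000.0
    duration_mixture: tuple[tuple[float, float, float], ...] = (
        (0.70, 1.0, 5.0),
        (0.17, 5.0, 10.0),
        (0.13, 10.0, 20.0),
    )
    peak_fold_change: float = 1.0

    def validate(self) -> None:
        if self.rate_per_cell_per_s < 0 or self.peak_fold_change <= 0:
            raise ValueError("rate must be >= 0, amplitude > 0")
        w = [m[0] for m in self.duration_mixture]
        if any(x < 0 for x in w) or abs(sum(w) - 1.0) > 1e-9:
            raise ValueError("mixture weights must be >= 0 and sum to 1")
        edges = [(lo, hi) for _, lo, hi in self.duration_mixture]
        for (lo, hi), (lo2, _) in zip(edges, edges[1:]):
            if hi > lo2 or lo >= hi:
                raise ValueError("duration bins must be increasing and disjoint")


@dataclass
class WaveParams:
    """Mechanically induced radial wave.

    A front expands from ``origin_px`` at ``v_fast_um_s`` for the first half
    (by time) of the propagation, then at ``v_slow_um_s``; a cell activates
    when the front reaches its centroid and rises to ``peak_fold_change``.
    Between ``crescent_onset_s`` and onset+duration (relative to the
    stimulus) cells strictly between the origin and the current front drop
    to ``crescent_level`` (the dark crescent).  All cells switch off around
    ``decay_time_s`` after the stimulus, except those within
    ``inner_radius_um`` of the origin, which are the last to dim.
    """

    origin_px: tuple[int, int] = (0, 0)
    stim_time_s: float = 5.0
    v_fast_um_s: float = 2.0
    v_slow_um_s: float = 0.5
    switch_mode: str = "half_time"
    peak_fold_change: float = 2.3
    crescent_onset_s: float | None = 23.0
    crescent_duration_s: float | None = 16.0
    decay_time_s: float = 73.0
    baseline_level: float = 1000.0
    rise_s: float = 1.5
    off_ramp_s: float = 1.0
    crescent_level: float = 0.0
    inner_radius_um: float = 4.0
    inner_extra_delay_s: float = 12.0

    def validate(self) -> None:
        if self.v_fast_um_s <= 0 or self.v_slow_um_s <= 0:
            raise ValueError("velocities must be positive")
        if self.v_fast_um_s < self.v_slow_um_s:
            raise ValueError("v_fast must be >= v_slow")
        if self.crescent_onset_s is not None:
            end = self.crescent_onset_s + (self.crescent_duration_s or 0.0)
            if self.crescent_onset_s < 0 or end > self.decay_time_s:
                raise ValueError("crescent interval must fall before decay_time_s")


@dataclass
class GroundTruth:
    """Event table plus an echo of the generator parameters.

    One row per rendered transient: kind in {oscillation_peak, spike,
    wave_activation}; ``onset_s`` is the pulse centre for oscillations and
    the activation/onset time otherwise; ``cell_id`` 0 marks tissue-wide
    events.
    """

    events: pd.DataFrame
    params: dict

    def to_csv(self, path: str | Path) -> None:
        self.events.to_csv(path, index=False)

    def params_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.params, indent=2, sort_keys=True))


def _empty_truth(params: dict) -> GroundTruth:
    return GroundTruth(pd.DataFrame(columns=TRUTH_COLUMNS), params)


# ---------------------------------------------------------------------------
# tissue


def make_tissue(spec: TissueSpec) -> CellLabelMap:
    """Voronoi mosaic of ``n_cells`` cells tiling a centred disk.

    Seeds are a jittered square grid clipped to the disk; each foreground
    pixel takes the label of its nearest seed.  Deterministic for a fixed
    ``spec.seed``.
    """
    spec.validate()
    h, w = spec.image_size_px
    radius_px = min(h, w) / 2 - 2
    radius_um = radius_px * spec.pixel_size_um
    cell_area = np.pi * (spec.cell_diameter_um / 2) ** 2
    if spec.n_cells * cell_area > np.pi * radius_um**2:
        raise ValueError(
            f"{spec.n_cells} cells of diameter {spec.cell_diameter_um} um "
            f"do not fit in a disk of radius {radius_um:.1f} um"
        )
    rng = np.random.default_rng(spec.seed)
    cy, cx = (h - 1) / 2, (w - 1) / 2
    spacing = spec.cell_diameter_um / spec.pixel_size_um
    seeds = np.empty((0, 2))
    for _ in range(60):
        ax0 = np.arange(cy % spacing, h, spacing)
        ax1 = np.arange(cx % spacing, w, spacing)
        gy, gx = np.meshgrid(ax0, ax1, indexing="ij")
        pts = np.column_stack([gy.ravel(), gx.ravel()])
        pts = pts + rng.uniform(-0.3 * spacing, 0.3 * spacing, pts.shape)
        inside = np.hypot(pts[:, 0] - cy, pts[:, 1] - cx) <= radius_px * 0.98
        seeds = pts[inside]
        if len(seeds) >= spec.n_cells:
            break
        spacing *= 0.92
    else:  # pragma: no cover - area check above prevents this
        raise ValueError("could not place the requested number of cells")
    order = np.argsort(np.hypot(seeds[:, 0] - cy, seeds[:, 1] - cx), kind="stable")
    seeds = seeds[order[: spec.n_cells]]

    yy, xx = np.mgrid[0:h, 0:w]
    fg = np.hypot(yy - cy, xx - cx) <= radius_px
    labels = np.zeros((h, w), dtype=np.int32)
    tree = cKDTree(seeds)
    pix = np.column_stack([yy[fg], xx[fg]])
    _, nearest = tree.query(pix)
    labels[fg] = nearest + 1
    return CellLabelMap(labels, spec.pixel_size_um)


# ---------------------------------------------------------------------------
# rendering helpers


def _render(values: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Expand a (T, n_cells+1) per-label value matrix to a (T, H, W) stack."""
    return values[:, labels].astype(np.float32)


def _time_grid(duration_s: float, dt: float) -> np.ndarray:
    n = int(np.floor(duration_s / dt)) + 1
    return np.arange(n) * dt


# ---------------------------------------------------------------------------
# oscillations


def draw_pulse_centers(
    p: OscillationParams, rng: np.random.Generator
) -> np.ndarray:
    """Pulse centres with truncated-normal gaps (lower bound one FWHM)."""
    a = (p.fwhm_s - p.mean_interpeak_s) / p.sd_interpeak_s
    dist = truncnorm(a, np.inf, loc=p.mean_interpeak_s, scale=p.sd_interpeak_s)
    centers = []
    t = float(dist.rvs(random_state=rng))
    while t <= p.duration_s:
        centers.append(t)
        t += float(dist.rvs(random_state=rng))
    return np.asarray(centers)


def simulate_oscillations(
    tissue: CellLabelMap,
    p: OscillationParams,
    seed: int = 0,
    pulse_centers: np.ndarray | None = None,
) -> tuple[Movie, GroundTruth]:
    """Tissue-wide Gaussian pulses added multiplicatively to the baseline.

    ``pulse_centers`` overrides the random draw (construction tests).
    """
    p.validate()
    rng = np.random.default_rng(seed)
    if pulse_centers is None:
        pulse_centers = draw_pulse_centers(p, rng)
    pulse_centers = np.asarray(pulse_centers, dtype=float)

    times = _time_grid(p.duration_s, p.frame_interval_s)
    sigma = p.fwhm_s / (2 * np.sqrt(2 * np.log(2)))
    g = np.zeros_like(times)
    for c in pulse_centers:
        g += np.exp(-((times - c) ** 2) / (2 * sigma**2))
    profile = p.baseline_level * (1 + p.peak_fold_change * g)

    n = int(tissue.labels.max())
    values = np.empty((times.size, n + 1), dtype=np.float64)
    values[:, 0] = BACKGROUND_FRACTION * p.baseline_level
    values[:, 1:] = profile[:, None]
    movie = Movie(_render(values, tissue.labels), p.frame_interval_s, tissue.pixel_size_um)

    params = {"kind": "oscillation", **asdict(p), "seed": seed}
    if pulse_centers.size == 0:
        warnings.warn("movie span too short for a single pulse; truth is empty")
        return movie, _empty_truth(params)
    truth = pd.DataFrame(
        {
            "kind": "oscillation_peak",
            "cell_id": 0,
            "onset_s": pulse_centers,
            "duration_s": p.fwhm_s,
            "amplitude": p.peak_fold_change,
        }
    )[TRUTH_COLUMNS]
    return movie, GroundTruth(truth, params)


# ---------------------------------------------------------------------------
# spikes


def _draw_duration(p: SpikeParams, rng: np.random.Generator) -> float:
    w = np.array([m[0] for m in p.duration_mixture])
    k = rng.choice(len(w), p=w / w.sum())
    _, lo, hi = p.duration_mixture[k]
    return float(rng.uniform(lo, hi))


def simulate_spikes(
    tissue: CellLabelMap,
    p: SpikeParams,
    duration_s: float,
    frame_interval_s: float = 1.0,
    seed: int = 0,
    n_events: int | None = None,
    scheduled: list[tuple[int, float, float]] | None = None,
    baseline_level: float = 1000.0,
) -> tuple[Movie, GroundTruth]:
    """Sparse rectangular single-cell transients.

    Three entry modes: a homogeneous per-cell point process at
    ``p.rate_per_cell_per_s`` (default); exactly ``n_events`` events on
    uniformly chosen cells; or an explicit ``scheduled`` list of
    (cell_id, onset_s, duration_s).  Events within one cell never overlap
    (later colliding draws are rejected), so every truth row has an
    unambiguous rendered support.
    """
    p.validate()
    rng = np.random.default_rng(seed)
    cell_ids = tissue.cell_ids
    times = _time_grid(duration_s, frame_interval_s)

    events: list[tuple[int, float, float]] = []
    if scheduled is not None:
        events = [(int(c), float(o), float(d)) for c, o, d in scheduled]
    else:
        if n_events is None:
            counts = rng.poisson(p.rate_per_cell_per_s * duration_s, size=cell_ids.size)
            cells = np.repeat(cell_ids, counts)
        else:
            cells = rng.choice(cell_ids, size=n_events, replace=True)
        busy: dict[int, list[tuple[float, float]]] = {}
        for cid in cells:
            for _ in range(50):  # reject draws that overlap a prior event
                onset = float(rng.uniform(0, duration_s))
                dur = _draw_duration(p, rng)
                spans = busy.setdefault(int(cid), [])
                if all(
                    onset + dur + frame_interval_s < lo or onset > lo + d + frame_interval_s
                    for lo, d in spans
                ):
                    spans.append((onset, dur))
                    events.append((int(cid), onset, dur))
                    break
        events.sort(key=lambda e: (e[1], e[0]))

    n = int(tissue.labels.max())
    values = np.empty((times.size, n + 1), dtype=np.float64)
    values[:, 0] = BACKGROUND_FRACTION * baseline_level
    values[:, 1:] = baseline_level
    dt = frame_interval_s
    for cid, onset, dur in events:
        # frame-averaged rendering: a frame integrates over [t_k, t_k + dt),
        # so edge frames carry the fractional overlap with the event
        cover = np.clip(
            np.minimum(times + dt, onset + dur) - np.maximum(times, onset), 0, dt
        ) / dt
        values[:, cid] += baseline_level * p.peak_fold_change * cover

    movie = Movie(_render(values, tissue.labels), frame_interval_s, tissue.pixel_size_um)
    params = {"kind": "spike", **asdict(p), "duration_s": duration_s,
              "frame_interval_s": frame_interval_s, "seed": seed}
    if not events:
        return movie, _empty_truth(params)
    truth = pd.DataFrame(events, columns=["cell_id", "onset_s", "duration_s"])
    truth.insert(0, "kind", "spike")
    truth["amplitude"] = p.peak_fold_change
    return movie, GroundTruth(truth[TRUTH_COLUMNS], params)


# ---------------------------------------------------------------------------
# waves


def wave_front_radius(p: WaveParams, t_after_stim: np.ndarray, max_distance_um: float) -> np.ndarray:
    """Front radius (um) at times after the stimulus: fast then slow phase.

    With ``switch_mode='half_time'`` the switch falls at the temporal
    midpoint of the full propagation to ``max_distance_um``.
    """
    t = np.asarray(t_after_stim, dtype=float)
    if p.switch_mode != "half_time":
        raise ValueError(f"unknown switch_mode {p.switch_mode!r}")
    total = 2 * max_distance_um / (p.v_fast_um_s + p.v_slow_um_s)
    t_sw = total / 2
    r = np.where(
        t <= t_sw,
        p.v_fast_um_s * t,
        p.v_fast_um_s * t_sw + p.v_slow_um_s * (t - t_sw),
    )
    return np.clip(r, 0, None)


def wave_activation_time(p: WaveParams, distance_um: np.ndarray, max_distance_um: float) -> np.ndarray:
    """Time after the stimulus at which the front reaches each distance."""
    d = np.asarray(distance_um, dtype=float)
    total = 2 * max_distance_um / (p.v_fast_um_s + p.v_slow_um_s)
    t_sw = total / 2
    r_sw = p.v_fast_um_s * t_sw
    return np.where(d <= r_sw, d / p.v_fast_um_s, t_sw + (d - r_sw) / p.v_slow_um_s)


def simulate_wave(
    tissue: CellLabelMap,
    p: WaveParams,
    duration_s: float,
    frame_interval_s: float = 1.0,
    seed: int = 0,
) -> tuple[Movie, GroundTruth]:
    """Radial two-phase wave with dark crescent and programmed decay."""
    p.validate()
    r0, c0 = p.origin_px
    if not (0 <= r0 < tissue.labels.shape[0] and 0 <= c0 < tissue.labels.shape[1]) \
            or tissue.labels[r0, c0] == 0:
        raise ValueError("stimulus origin must lie inside the tissue")

    cents = tissue.centroids_um()
    cell_ids = np.array(sorted(cents))
    origin_um = (r0 * tissue.pixel_size_um, c0 * tissue.pixel_size_um)
    d = np.array(
        [np.hypot(cents[c][0] - origin_um[0], cents[c][1] - origin_um[1]) for c in cell_ids]
    )
    d_max = float(d.max())

    times = _time_grid(duration_s, frame_interval_s)
    act = p.stim_time_s + wave_activation_time(p, d, d_max)

    # switch-off: all cells at stim + decay_time_s except the innermost,
    # which dim inner_extra_delay_s later; never before the cell has risen
    t_off = np.full_like(d, p.stim_time_s + p.decay_time_s)
    t_off[d <= p.inner_radius_um] += p.inner_extra_delay_s
    t_off = np.maximum(t_off, act + p.rise_s + 2 * frame_interval_s)

    tt = times[:, None]
    rise = np.clip((tt - act[None, :]) / p.rise_s, 0, 1)
    fall = np.clip((t_off[None, :] + p.off_ramp_s - tt) / p.off_ramp_s, 0, 1)
    fc = p.peak_fold_change * rise * fall

    if p.crescent_onset_s is not None and p.crescent_duration_s is not None:
        t_rel = times - p.stim_time_s
        in_window = (t_rel >= p.crescent_onset_s) & (
            t_rel <= p.crescent_onset_s + p.crescent_duration_s
        )
        front = wave_front_radius(p, np.clip(t_rel, 0, None), d_max)
        mask = (
            in_window[:, None]
            & (d[None, :] > p.inner_radius_um)
            & (d[None, :] < front[:, None])
            & (tt >= act[None, :] + p.rise_s)
        )
        fc = np.where(mask, p.crescent_level, fc)

    n = int(tissue.labels.max())
    values = np.empty((times.size, n + 1), dtype=np.float64)
    values[:, 0] = BACKGROUND_FRACTION * p.baseline_level
    values[:, cell_ids] = p.baseline_level * (1 + fc)
    movie = Movie(
        _render(values, tissue.labels),
        frame_interval_s,
        tissue.pixel_size_um,
        origin_px=(r0, c0),
        stim_time_s=p.stim_time_s,
    )
    truth = pd.DataFrame(
        {
            "kind": "wave_activation",
            "cell_id": cell_ids,
            "onset_s": act,
            "duration_s": t_off - act,
            "amplitude": p.peak_fold_change,
        }
    )[TRUTH_COLUMNS]
    params = {"kind": "wave", **asdict(p), "duration_s": duration_s,
              "frame_interval_s": frame_interval_s, "seed": seed}
    return movie, GroundTruth(truth, params)


# ---------------------------------------------------------------------------
# noise


def add_noise(movie: Movie, gaussian_sd_counts: float, seed: int = 0) -> Movie:
    """Independent additive Gaussian noise per pixel, clipped at zero."""
    if gaussian_sd_counts < 0:
        raise ValueError("noise SD must be >= 0")
    if gaussian_sd_counts == 0:
        return Movie(movie.data.copy(), movie.frame_interval_s, movie.pixel_size_um,
                     movie.origin_px, movie.stim_time_s)
    rng = np.random.default_rng(seed)
    noisy = movie.data + rng.normal(0, gaussian_sd_counts, movie.data.shape).astype(np.float32)
    np.clip(noisy, 0, None, out=noisy)
    return Movie(noisy, movie.frame_interval_s, movie.pixel_size_um,
                 movie.origin_px, movie.stim_time_s)
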