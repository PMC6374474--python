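"""Calibrated movie and cell-label containers with TIFF I/O.

A :class:`Movie` is a single-channel time-lapse stack (T, H, W) with the two
calibrations every downstream statistic needs: the frame interval in seconds
and the pixel size in micrometres.  A :class:`CellLabelMap` is an integer
segmentation of the image plane (label 0 = background) sharing the movie's
pixel grid.  Stacks are exchanged as plain multi-page TIFF (16-bit on write,
float internally).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile


@dataclass
class Movie:
    """Single-channel fluorescence time-lapse stack.

    Parameters
    ----------
    data
        Intensities, shape (T, H, W), non-negative counts (float internally).
    frame_interval_s
        Time between consecutive frames, seconds.
    pixel_size_um
        Side length of one pixel, micrometres.
    origin_px, stim_time_s
        Optional stimulus metadata for wave experiments: pixel (row, col) of
        the mechanical stimulus and the time it was applied.
    """

    data: np.ndarray
    frame_interval_s: float
    pixel_size_um: float
    origin_px: tuple[int, int] | None = None
    stim_time_s: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3 or self.data.shape[0] < 2:
            raise ValueError("movie must be a (T, H, W) stack with T >= 2")
        if self.frame_interval_s <= 0 or self.pixel_size_um <= 0:
            raise ValueError("calibrations must be positive")
        if self.data.min() < 0:
            raise ValueError("intensities must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def times_s(self) -> np.ndarray:
        """Frame times in seconds, starting at 0."""
        return np.arange(self.n_frames) * self.frame_interval_s


@dataclass
class CellLabelMap:
    """Integer cell segmentation over the image plane.

    ``labels[r, c]`` is the cell id at that pixel (0 = background).  Labels
    are contiguous 1..n_cells.
    """

    labels: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be a 2-D image")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def cell_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    @property
    def n_cells(self) -> int:
        return int(self.cell_ids.size)

    @property
    def foreground(self) -> np.ndarray:
        return self.labels > 0

    def centroids_um(self) -> dict[int, tuple[float, float]]:
        """Per-cell centroid as (row_um, col_um)."""
        rows, cols = np.nonzero(self.labels)
        ids = self.labels[rows, cols]
        out: dict[int, tuple[float, float]] = {}
        n = int(self.labels.max())
        counts = np.bincount(ids, minlength=n + 1)
        rsum = np.bincount(ids, weights=rows, minlength=n + 1)
        csum = np.bincount(ids, weights=cols, minlength=n + 1)
        for cid in self.cell_ids:
            out[int(cid)] = (
                float(rsum[cid] / counts[cid] * self.pixel_size_um),
                float(csum[cid] / counts[cid] * self.pixel_size_um),
            )
        return out


def write_movie(path: str | Path, movie: Movie) -> None:
    """Write a movie as multi-page 16-bit grayscale TIFF."""
    data = np.clip(np.round(movie.data), 0, np.iinfo(np.uint16).max)
    tifffile.imwrite(str(path), data.astype(np.uint16))


def read_movie(
    path: str | Path,
    frame_interval_s: float,
    pixel_size_um: float,
    origin_px: tuple[int, int] | None = None,
    stim_time_s: float | None = None,
) -> Movie:
    """Read a multi-page TIFF stack; calibrations are supplied by the caller."""
    data = tifffile.imread(str(path))
    if data.ndim == 2:  # single page -> treat as T=1, invalid anyway
        data = data[None]
    return Movie(
        data=data.astype(np.float32),
        frame_interval_s=frame_interval_s,
        pixel_size_um=pixel_size_um,
        origin_px=origin_px,
        stim_time_s=stim_time_s,
    )


def write_labels(path: str | Path, labels: CellLabelMap) -> None:
    tifffile.imwrite(str(path), labels.labels.astype(np.uint16))


def read_labels(path: str | Path, pixel_size_um: float) -> CellLabelMap:
    return CellLabelMap(tifffile.imread(str(path)).astype(np.int32), pixel_size_um)
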