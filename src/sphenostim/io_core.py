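"""Domain types and file I/O shared by every analysis stage.

Conventions used throughout the package:

* pixel coordinates are 0-based, row-major ``(row, col)`` — row is y,
  col is x;
* time origin ``t = 0`` is the first sample/frame of a recording;
  stimulation-schedule times are relative to schedule start and are
  aligned to recordings via ``t0_s``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "ImageStack",
    "TimeSeries",
    "ROI",
    "StimProtocol",
    "VALID_UNITS",
    "expand_schedule",
    "read_image_stack",
    "write_image_stack",
    "read_timeseries_csv",
    "write_timeseries_csv",
]

#: unit tags accepted by :class:`TimeSeries`
VALID_UNITS = frozenset({"doppler_au", "ecog_uv", "intensity_iu", "percent"})


@dataclass
class ImageStack:
    """Time-ordered stack of 2-D frames with physical metadata.

    Parameters
    ----------
    frames
        Array of shape ``(T, H, W)`` for grayscale or ``(T, H, W, 3)``
        for RGB. Integer intensities are kept as-is, never rescaled.
    pixel_size_um
        Edge length of one pixel in micrometres.
    frame_interval_s
        Seconds between consecutive frames.
    t0_s
        Acquisition start offset relative to the experiment clock.
    """

    frames: np.ndarray
    pixel_size_um: float
    frame_interval_s: float
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim not in (3, 4):
            raise ValueError(
                f"frames must be T×H×W or T×H×W×3, got shape {self.frames.shape}"
            )
        if self.frames.ndim == 4 and self.frames.shape[-1] != 3:
            raise ValueError(
                f"RGB stacks need 3 channels, frames has {self.frames.shape[-1]}"
            )
        if self.frames.shape[0] < 1:
            raise ValueError("frames must contain at least one frame (T >= 1)")
        if not self.pixel_size_um > 0:
            raise ValueError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        if not self.frame_interval_s > 0:
            raise ValueError(
                f"frame_interval_s must be > 0, got {self.frame_interval_s}"
            )

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def is_rgb(self) -> bool:
        return self.frames.ndim == 4

    @property
    def times_s(self) -> np.ndarray:
        """Acquisition time of each frame, ``t0_s + i * frame_interval_s``."""
        return self.t0_s + np.arange(self.n_frames) * self.frame_interval_s


@dataclass
class TimeSeries:
    """Uniformly sampled 1-D signal with sampling rate and unit tag."""

    values: np.ndarray
    fs_hz: float
    unit: str
    t0_s: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not self.fs_hz > 0:
            raise ValueError(f"fs_hz must be > 0, got {self.fs_hz}")
        if self.values.size < 2:
            raise ValueError("TimeSeries needs at least 2 samples")
        if self.unit not in VALID_UNITS:
            raise ValueError(f"unit must be one of {sorted(VALID_UNITS)}, got {self.unit!r}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(
                "TimeSeries must have no missing samples; split gaps into separate series"
            )

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def duration_s(self) -> float:
        return self.n / self.fs_hz

    @property
    def times_s(self) -> np.ndarray:
        return self.t0_s + np.arange(self.n) / self.fs_hz


@dataclass
class ROI:
    """Region of interest: a labelled mask or polygon in pixel coordinates.

    Either ``mask`` (boolean H×W) or ``polygon`` (sequence of (row, col)
    vertices) must be given. ``to_mask`` rasterises a polygon against a
    frame shape.
    """

    label: str
    mask: np.ndarray | None = None
    polygon: Sequence[tuple[float, float]] | None = None

    _LABELS = frozenset({"artery", "vein", "parenchyma", "other"})

    def __post_init__(self) -> None:
        if self.label not in self._LABELS:
            raise ValueError(f"ROI label must be one of {sorted(self._LABELS)}")
        if self.mask is None and self.polygon is None:
            raise ValueError("ROI needs a mask or a polygon")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.ndim != 2:
                raise ValueError("ROI mask must be 2-D")
            if not self.mask.any():
                raise ValueError(f"ROI {self.label!r} mask is empty")
        if self.polygon is not None and len(self.polygon) < 3:
            raise ValueError("ROI polygon needs at least 3 vertices")

    def to_mask(self, frame_shape: tuple[int, int]) -> np.ndarray:
        """Boolean mask of this ROI for a frame of the given (H, W)."""
        if self.mask is not None:
            if self.mask.shape != tuple(frame_shape):
                raise ValueError(
                    f"ROI {self.label!r} mask shape {self.mask.shape} does not "
                    f"fit frame {tuple(frame_shape)}"
                )
            return self.mask
        from skimage.draw import polygon as _draw_polygon

        verts = np.asarray(self.polygon, dtype=float)
        if (verts < 0).any() or (verts[:, 0] >= frame_shape[0]).any() or (
            verts[:, 1] >= frame_shape[1]
        ).any():
            raise ValueError(f"ROI {self.label!r} polygon exceeds frame bounds")
        rr, cc = _draw_polygon(verts[:, 0], verts[:, 1], shape=tuple(frame_shape))
        out = np.zeros(frame_shape, dtype=bool)
        out[rr, cc] = True
        if not out.any():
            raise ValueError(f"ROI {self.label!r} rasterises to an empty mask")
        return out


@dataclass
class StimProtocol:
    """Sphenopalatine-ganglion stimulation schedule (representation only).

    A protocol is ``n_trains`` trains; each train is ``sets_per_train``
    ON sets of ``set_duration_s`` seconds separated by
    ``inter_set_gap_s``, followed by ``off_time_s`` of OFF time before
    the next train. Electrical parameters (pulse width, intensity,
    frequency) are carried as metadata; no hardware is driven.

    ``total_treatment_min`` is stored verbatim when supplied and is
    never recomputed from the per-train parameters.
    """

    n_trains: int = 12
    sets_per_train: int = 2
    set_duration_s: float = 60.0
    inter_set_gap_s: float = 12.0
    off_time_s: float = 816.0  # 13.6 min
    pulse_width_us: float = 500.0
    intensity_ma: float = 2.0
    frequency_hz: float = 10.0
    total_treatment_min: float | None = None

    def __post_init__(self) -> None:
        if self.n_trains < 1:
            raise ValueError("n_trains must be >= 1")
        if self.sets_per_train < 1:
            raise ValueError("sets_per_train must be >= 1")
        for name in ("set_duration_s", "inter_set_gap_s", "off_time_s", "pulse_width_us"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def expand_schedule(p: StimProtocol) -> list[tuple[float, float]]:
    """Expand a protocol into sorted, non-overlapping ON intervals.

    Returns ``n_trains * sets_per_train`` tuples ``(on_start_s, on_end_s)``
    relative to schedule start. Within a train consecutive sets are
    separated by ``inter_set_gap_s``; the next train starts
    ``off_time_s`` after the end of the previous train's last set.
    """
    intervals: list[tuple[float, float]] = []
    t = 0.0
    for _ in range(p.n_trains):
        for s in range(p.sets_per_train):
            intervals.append((t, t + p.set_duration_s))
            t += p.set_duration_s
            if s < p.sets_per_train - 1:
                t += p.inter_set_gap_s
        t += p.off_time_s
    return intervals


# ---------------------------------------------------------------------------
# TIFF stacks
# ---------------------------------------------------------------------------

def read_image_stack(
    path: str | os.PathLike,
    pixel_size_um: float,
    frame_interval_s: float,
    t0_s: float = 0.0,
) -> ImageStack:
    """Read a multi-page TIFF (or a directory of ordered single-page
    TIFFs) into an :class:`ImageStack`.

    Frames are ordered by page index or, for a directory, by sorted
    filename. Integer intensities are preserved without rescaling.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image stack path does not exist: {path}")
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in (".tif", ".tiff"))
        if not files:
            raise FileNotFoundError(f"no TIFF files in directory {path}")
        pages = [tifffile.imread(f) for f in files]
        shapes = {p.shape for p in pages}
        if len(shapes) > 1:
            raise ValueError(f"inconsistent frame shapes in {path}: {sorted(shapes)}")
        frames = np.stack(pages)
    else:
        frames = tifffile.imread(path)
        if frames.ndim == 2:
            frames = frames[None]
    return ImageStack(
        frames=frames,
        pixel_size_um=pixel_size_um,
        frame_interval_s=frame_interval_s,
        t0_s=t0_s,
    )


def write_image_stack(stack: ImageStack, path: str | os.PathLike) -> None:
    """Write a stack as a multi-page TIFF (lossless for integer data)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, stack.frames, photometric="rgb" if stack.is_rgb else "minisblack")


# ---------------------------------------------------------------------------
# CSV time series
# ---------------------------------------------------------------------------

def read_timeseries_csv(
    path: str | os.PathLike,
    unit: str,
    fs_hz: float | None = None,
) -> TimeSeries:
    """Read a time series from CSV.

    Two dialects are accepted: two columns ``time_s, value`` with a
    header (sampling rate inferred from the median time step, which
    must be uniform to 1 ppm), or a single ``value`` column with
    ``fs_hz`` supplied by the caller (e.g. from a sidecar metadata
    file).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"time-series CSV does not exist: {path}")
    df = pd.read_csv(path)
    if "time_s" in df.columns and "value" in df.columns:
        t = df["time_s"].to_numpy(dtype=float)
        dt = np.diff(t)
        if dt.size == 0 or not np.all(dt > 0):
            raise ValueError(f"time_s column in {path} is not strictly increasing")
        step = float(np.median(dt))
        if np.max(np.abs(dt - step)) > 1e-6 * step:
            raise ValueError(
                f"non-uniform sampling in {path}; split gaps into separate series"
            )
        return TimeSeries(df["value"].to_numpy(dtype=float), fs_hz=1.0 / step, unit=unit, t0_s=float(t[0]))
    if "value" in df.columns:
        if fs_hz is None:
            raise ValueError(
                f"{path} has a single value column; fs_hz must be supplied"
            )
        return TimeSeries(df["value"].to_numpy(dtype=float), fs_hz=fs_hz, unit=unit)
    raise ValueError(f"{path} must have columns (time_s, value) or (value)")


def write_timeseries_csv(ts: TimeSeries, path: str | os.PathLike) -> None:
    """Write a series as two-column ``time_s, value`` CSV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"time_s": ts.times_s, "value": ts.values}).to_csv(path, index=False)
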