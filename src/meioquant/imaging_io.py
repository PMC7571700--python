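"""Reading, writing, and projecting multi-channel time-lapse stacks.

Movies are normalized to a single ``(C, T, Z, Y, X)`` array with physical
calibration carried alongside (pixel size, z-spacing, frame interval, and the
frame marking the end of meiosis I used as the ``t = 0`` origin).  Projection
conventions used by the downstream quantifications live here: maximum
projection over z, clip-free sum projection over a plane window, and automatic
selection of the most spindle-associated z-planes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml
from shapely.geometry import Polygon

__all__ = [
    "MovieStack",
    "ImageSeries",
    "PolygonROI",
    "read_movie",
    "write_movie",
    "max_project",
    "sum_project",
    "select_spindle_planes",
    "write_table",
    "load_config",
]

_AXIS_ORDER = "CTZYX"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class MovieStack:
    """Multi-channel movie with axes ``(C, T, Z, Y, X)`` and calibration.

    Parameters
    ----------
    data:
        Non-negative intensity array, one leading axis per channel.
    channel_names:
        Channel labels, one per leading-axis entry.
    pixel_size_xy:
        Lateral calibration in micrometres per pixel.
    z_spacing:
        Axial plane spacing in micrometres (1 um in the emulated acquisition).
    frame_interval:
        Seconds between frames (10 s in the emulated acquisition).
    t0_frame:
        Optional frame index marking the end of meiosis I; times are reported
        relative to this frame when set.
    """

    data: np.ndarray
    channel_names: list[str]
    pixel_size_xy: float
    z_spacing: float
    frame_interval: float
    t0_frame: int | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 5:
            raise ValueError(f"expected (C,T,Z,Y,X) data, got ndim={self.data.ndim}")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError("channel_names length does not match channel axis")
        for name, value in (
            ("pixel_size_xy", self.pixel_size_xy),
            ("z_spacing", self.z_spacing),
            ("frame_interval", self.frame_interval),
        ):
            if not value > 0:
                raise ValueError(f"{name} must be positive, got {value}")
        if self.t0_frame is not None and not 0 <= self.t0_frame < self.n_frames:
            raise ValueError(f"t0_frame {self.t0_frame} outside [0, {self.n_frames})")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]

    @property
    def n_planes(self) -> int:
        return self.data.shape[2]

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def channel(self, label: str) -> np.ndarray:
        """Return the ``(T, Z, Y, X)`` array for one channel label."""
        try:
            idx = self.channel_names.index(label)
        except ValueError:
            raise KeyError(
                f"unknown channel {label!r}; have {self.channel_names}"
            ) from None
        return self.data[idx]

    def times_rel(self) -> np.ndarray:
        """Frame times in seconds relative to ``t0_frame`` (or frame 0)."""
        origin = self.t0_frame if self.t0_frame is not None else 0
        return (np.arange(self.n_frames) - origin) * float(self.frame_interval)


@dataclass
class ImageSeries:
    """A projected or single-plane time series with axes ``(T, Y, X)``."""

    frames: np.ndarray
    times_rel: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.times_rel = np.asarray(self.times_rel, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (T, Y, X)")
        if self.times_rel.shape != (self.frames.shape[0],):
            raise ValueError("times_rel length must match frame count")
        if self.times_rel.size > 1 and not np.all(np.diff(self.times_rel) > 0):
            raise ValueError("times_rel must be strictly increasing")


@dataclass
class PolygonROI:
    """Simple polygonal region of interest in pixel coordinates ``(x, y)``."""

    vertices: np.ndarray
    frame_index: int | None = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError("vertices must be an (M, 2) array of (x, y)")
        if len(self.vertices) < 3:
            raise ValueError("a polygon needs at least 3 vertices")
        poly = Polygon(self.vertices)
        if not poly.is_valid:
            raise ValueError("polygon is self-intersecting or degenerate")
        if not poly.area > 0:
            raise ValueError("polygon area must be positive")

    @property
    def area(self) -> float:
        return Polygon(self.vertices).area


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def _normalize_axes(arr: np.ndarray, axes: str) -> np.ndarray:
    """Rearrange an array with labelled axes into ``(C, T, Z, Y, X)``."""
    axes = axes.upper().replace("S", "C")
    if len(axes) != arr.ndim:
        raise ValueError(f"axes string {axes!r} does not match ndim={arr.ndim}")
    unknown = [a for a in axes if a not in _AXIS_ORDER]
    if unknown:
        raise ValueError(f"unsupported axes {unknown} in {axes!r}")
    if len(set(axes)) != len(axes):
        raise ValueError(f"repeated axis label in {axes!r}")
    for ax in _AXIS_ORDER:
        if ax not in axes:
            arr = arr[np.newaxis]
            axes = ax + axes
    return np.transpose(arr, [axes.index(ax) for ax in _AXIS_ORDER])


def read_movie(
    path: str | Path,
    channel_map: Mapping[str, int] | None = None,
    *,
    pixel_size_xy: float = 1.0,
    z_spacing: float = 1.0,
    frame_interval: float = 1.0,
    t0_frame: int | None = None,
    axes: str | None = None,
) -> MovieStack:
    """Read a TIFF stack and normalize its axes to ``(C, T, Z, Y, X)``.

    ``channel_map`` maps channel labels to indices on the channel axis; if
    omitted, channels are labelled ``ch0, ch1, ...``.  Calibration arguments
    always override any file metadata.  ``axes`` overrides the axis labels
    recorded in the file (useful for plain TIFFs without metadata).
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        series = tf.series[0]
        arr = series.asarray()
        file_axes = axes if axes is not None else series.axes
    arr = _normalize_axes(arr, file_axes)
    n_channels = arr.shape[0]
    if channel_map is None:
        channel_map = {f"ch{i}": i for i in range(n_channels)}
    if len(channel_map) > n_channels or any(
        not 0 <= i < n_channels for i in channel_map.values()
    ):
        raise ValueError(
            f"channel_map {dict(channel_map)} inconsistent with {n_channels} channels"
        )
    # reorder/subset the channel axis according to the map
    order = sorted(channel_map, key=channel_map.get)
    arr = arr[[channel_map[name] for name in order]]
    return MovieStack(
        data=arr,
        channel_names=order,
        pixel_size_xy=pixel_size_xy,
        z_spacing=z_spacing,
        frame_interval=frame_interval,
        t0_frame=t0_frame,
    )


def write_movie(stack: MovieStack, path: str | Path) -> None:
    """Write a MovieStack as a TIFF with axis labels recorded in metadata."""
    tifffile.imwrite(
        Path(path),
        stack.data,
        photometric="minisblack",
        metadata={
            "axes": _AXIS_ORDER,
            "channel_names": list(stack.channel_names),
            "pixel_size_xy_um": stack.pixel_size_xy,
            "z_spacing_um": stack.z_spacing,
            "frame_interval_s": stack.frame_interval,
        },
    )


def write_series(series: ImageSeries, path: str | Path) -> None:
    """Write a projected series as a (T, Y, X) TIFF."""
    tifffile.imwrite(Path(path), series.frames, metadata={"axes": "TYX"})


# ---------------------------------------------------------------------------
# projections and plane selection
# ---------------------------------------------------------------------------

def max_project(stack: MovieStack, channel: str) -> ImageSeries:
    """Maximum-intensity projection over all z-planes of one channel."""
    data = stack.channel(channel)
    return ImageSeries(
        frames=data.max(axis=1),
        times_rel=stack.times_rel(),
        provenance={
            "projection": "max",
            "channel": channel,
            "z_range": (0, stack.n_planes - 1),
            "t0_set": stack.t0_frame is not None,
        },
    )


def sum_project(
    stack: MovieStack, channel: str, z_range: tuple[int, int] | None = None
) -> ImageSeries:
    """Sum projection over an inclusive z-plane window, without saturation.

    The accumulation happens in a widened dtype (float64 for floats, int64 for
    integers) so sums may exceed the source bit depth, mirroring how FIJI sum
    projections behave.
    """
    data = stack.channel(channel)
    if z_range is None:
        z_range = (0, stack.n_planes - 1)
    lo, hi = int(z_range[0]), int(z_range[1])
    if not (0 <= lo <= hi < stack.n_planes):
        raise ValueError(f"z_range {z_range} outside [0, {stack.n_planes})")
    wide = np.int64 if np.issubdtype(data.dtype, np.integer) else np.float64
    frames = data[:, lo : hi + 1].sum(axis=1, dtype=wide)
    return ImageSeries(
        frames=frames,
        times_rel=stack.times_rel(),
        provenance={
            "projection": "sum",
            "channel": channel,
            "z_range": (lo, hi),
            "t0_set": stack.t0_frame is not None,
        },
    )


def single_plane(stack: MovieStack, channel: str, z: int) -> ImageSeries:
    """Extract one z-plane of a channel as a time series."""
    if not 0 <= z < stack.n_planes:
        raise ValueError(f"plane {z} outside [0, {stack.n_planes})")
    return ImageSeries(
        frames=stack.channel(channel)[:, z],
        times_rel=stack.times_rel(),
        provenance={
            "projection": "single-plane",
            "channel": channel,
            "z_range": (z, z),
            "t0_set": stack.t0_frame is not None,
        },
    )


def select_spindle_planes(
    stack: MovieStack, chromosome_channel: str, k: int = 5
) -> tuple[int, int]:
    """Pick the contiguous window of ``k`` planes richest in chromosome signal.

    Automates the manual "most spindle-associated planes" choice as the
    contiguous window maximizing total chromosome-channel intensity summed
    over all frames; ties resolve to the lowest z index.  Returns an inclusive
    ``(lo, hi)`` plane interval.
    """
    n_planes = stack.n_planes
    if not 0 < k <= n_planes:
        raise ValueError(f"k={k} outside [1, {n_planes}]")
    data = stack.channel(chromosome_channel)
    plane_totals = data.sum(axis=(0, 2, 3), dtype=np.float64)
    window_sums = np.array(
        [plane_totals[i : i + k].sum() for i in range(n_planes - k + 1)]
    )
    lo = int(np.argmax(window_sums))  # argmax returns the first (lowest) maximum
    return lo, lo + k - 1


# ---------------------------------------------------------------------------
# tabular output
# ---------------------------------------------------------------------------

def write_table(
    records: Sequence[Mapping] | pd.DataFrame,
    path: str | Path,
    *,
    config: Mapping | None = None,
    seed: int | None = None,
) -> None:
    """Write result records as CSV with a JSON run-metadata sidecar.

    Raises on empty input before touching the filesystem.  Floats are written
    at full round-trip precision.  The sidecar (``<path stem>.meta.json``)
    records the run configuration and seed for provenance.
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        df = pd.DataFrame(list(records))
    if df.empty:
        raise ValueError("no records to write")
    path = Path(path)
    df.to_csv(path, index=False, float_format="%.17g")
    sidecar = path.with_suffix(".meta.json")
    meta = {
        "table": path.name,
        "n_rows": int(len(df)),
        "columns": list(df.columns),
        "config": dict(config) if config else None,
        "seed": seed,
    }
    sidecar.write_text(json.dumps(meta, indent=2, default=str))


def load_config(path: str | Path) -> dict:
    """Load a YAML run-configuration file (channel map, calibration, t0)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("configuration file must contain a mapping")
    return cfg
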