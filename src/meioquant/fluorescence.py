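"""Fluorescence quantifications: spindle intensity, ratios, patch fractions.

Implements the three intensity read-outs used for the meiosis-I phenotypes:

- total spindle microtubule pixel intensity,
  ``(mean grey(spindle) / mean grey(cytoplasm)) * spindle ROI area``;
- spindle-to-cytoplasm mean-grey ratio per timepoint (AIR-2/CYK-4-style
  markers), on the t = 0 = end-of-meiosis-I time convention;
- cortical patch area fraction via Otsu or Li thresholding with dark
  background and a single stack-histogram threshold over the 360 s window
  preceding the end of meiosis I.

Polygon ROI membership uses the pixel-center even-odd rule: a pixel belongs
to the ROI when its center lies inside the polygon by even-odd ray casting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .imaging_io import ImageSeries, PolygonROI

__all__ = [
    "SpindleIntensityRecord",
    "RatioSeries",
    "PatchAreaSeries",
    "roi_mask",
    "mean_grey",
    "total_spindle_intensity",
    "ratio_series",
    "stack_histogram",
    "otsu_threshold",
    "li_threshold",
    "patch_area_fraction",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class SpindleIntensityRecord:
    time_rel: float
    mean_spindle: float
    mean_cyto: float
    spindle_area: int           # member-pixel count
    total_intensity: float      # (mean_spindle / mean_cyto) * spindle_area

    def __post_init__(self) -> None:
        if self.mean_cyto <= 0:
            raise ValueError("cytoplasm mean grey value must be positive")
        if self.spindle_area <= 0:
            raise ValueError("spindle area must be positive")


@dataclass
class RatioSeries:
    times_rel: np.ndarray
    ratio: np.ndarray
    marker: str = ""

    def __post_init__(self) -> None:
        self.times_rel = np.asarray(self.times_rel, dtype=float)
        self.ratio = np.asarray(self.ratio, dtype=float)
        if self.times_rel.shape != self.ratio.shape:
            raise ValueError("times and ratios must align")
        if (self.ratio <= 0).any():
            raise ValueError("ratios must be positive")


@dataclass
class PatchAreaSeries:
    times_rel: np.ndarray
    fraction: np.ndarray
    method: str
    threshold: float

    def __post_init__(self) -> None:
        self.times_rel = np.asarray(self.times_rel, dtype=float)
        self.fraction = np.asarray(self.fraction, dtype=float)
        if ((self.fraction < 0) | (self.fraction > 1)).any():
            raise ValueError("area fractions must lie in [0, 1]")


# ---------------------------------------------------------------------------
# ROI membership and mean grey value
# ---------------------------------------------------------------------------

def roi_mask(shape: tuple[int, int], roi: PolygonROI) -> np.ndarray:
    """Boolean pixel-membership mask by the pixel-center even-odd rule.

    Pixel ``(row, col)`` has its center at ``(x=col, y=row)``.  Membership is
    decided by even-odd (crossing-number) ray casting from the pixel center;
    centers exactly on an edge resolve by the half-open segment convention,
    which is deterministic.
    """
    h, w = shape
    verts = roi.vertices
    x1 = np.roll(verts[:, 0], -1)
    y1 = np.roll(verts[:, 1], -1)
    x0, y0 = verts[:, 0], verts[:, 1]
    cols = np.arange(w, dtype=float)
    rows = np.arange(h, dtype=float)
    px, py = np.meshgrid(cols, rows)
    inside = np.zeros((h, w), dtype=bool)
    for ax, ay, bx, by in zip(x0, y0, x1, y1):
        if ay == by:
            continue
        # half-open in y: edge spans [min, max) so shared vertices count once
        cond = (ay > py) != (by > py)
        with np.errstate(divide="ignore", invalid="ignore"):
            x_int = ax + (py - ay) * (bx - ax) / (by - ay)
        inside ^= cond & (px < x_int)
    return inside


def mean_grey(frame: np.ndarray, roi: PolygonROI) -> float:
    """Arithmetic mean intensity over ROI member pixels."""
    frame = np.asarray(frame)
    mask = roi_mask(frame.shape, roi)
    if not mask.any():
        raise ValueError("ROI contains no pixel centers")
    return float(frame[mask].mean())


def total_spindle_intensity(
    frame: np.ndarray,
    spindle_roi: PolygonROI,
    cyto_roi: PolygonROI,
    time_rel: float = 0.0,
) -> SpindleIntensityRecord:
    """Total spindle microtubule pixel intensity for one frame.

    ``(mean grey(spindle) / mean grey(cytoplasm)) * area(spindle)``, the
    spindle area being the ROI member-pixel count.  The cytoplasm ROI must
    be drawn clear of confounding signal (e.g. adjacent sperm); that is the
    caller's annotation responsibility.
    """
    frame = np.asarray(frame)
    mask_s = roi_mask(frame.shape, spindle_roi)
    mask_c = roi_mask(frame.shape, cyto_roi)
    if not mask_s.any() or not mask_c.any():
        raise ValueError("ROI contains no pixel centers")
    mean_s = float(frame[mask_s].mean())
    mean_c = float(frame[mask_c].mean())
    if mean_c == 0:
        raise ValueError("cytoplasm mean grey value is zero")
    area = int(mask_s.sum())
    return SpindleIntensityRecord(
        time_rel=time_rel,
        mean_spindle=mean_s,
        mean_cyto=mean_c,
        spindle_area=area,
        total_intensity=(mean_s / mean_c) * area,
    )


def ratio_series(
    series: ImageSeries,
    spindle_rois: PolygonROI | Sequence[PolygonROI],
    cyto_rois: PolygonROI | Sequence[PolygonROI],
    marker: str = "",
) -> RatioSeries:
    """Per-timepoint spindle-to-cytoplasm mean-grey ratio.

    Static ROIs may be given once; otherwise supply one ROI per frame.
    Times are reported on the series' relative-time axis (t = 0 at the end
    of meiosis I when the source stack declared ``t0_frame``).
    """
    t_frames = series.frames.shape[0]

    def _per_frame(rois):
        if isinstance(rois, PolygonROI):
            return [rois] * t_frames
        rois = list(rois)
        if len(rois) != t_frames:
            raise ValueError("need one ROI per frame")
        return rois

    s_rois = _per_frame(spindle_rois)
    c_rois = _per_frame(cyto_rois)
    ratios = np.empty(t_frames)
    for t in range(t_frames):
        mean_c = mean_grey(series.frames[t], c_rois[t])
        if mean_c == 0:
            raise ValueError(f"zero cytoplasm mean at frame {t}")
        ratios[t] = mean_grey(series.frames[t], s_rois[t]) / mean_c
    return RatioSeries(times_rel=series.times_rel, ratio=ratios, marker=marker)


# ---------------------------------------------------------------------------
# histogram thresholds
# ---------------------------------------------------------------------------

def stack_histogram(
    values: np.ndarray, n_bins: int = 256
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram (counts, bin centers) of pooled stack values.

    Integer data with range within [0, 255] use the native 8-bit integer
    bins; anything else uses ``n_bins`` equal bins spanning the data range,
    mirroring how FIJI builds its stack histogram for thresholding.
    """
    values = np.asarray(values).ravel()
    if values.size == 0:
        raise ValueError("empty data")
    if np.issubdtype(values.dtype, np.integer) and values.min() >= 0 and values.max() <= 255:
        counts = np.bincount(values.astype(np.int64), minlength=256)
        return counts.astype(np.int64), np.arange(256, dtype=float)
    lo, hi = float(values.min()), float(values.max())
    if hi == lo:
        raise ValueError("single-valued data has no threshold")
    counts, edges = np.histogram(values, bins=n_bins, range=(lo, hi))
    centers = (edges[:-1] + edges[1:]) / 2.0
    return counts.astype(np.int64), centers


def _validate_hist(counts, bin_centers):
    counts = np.asarray(counts, dtype=float)
    if bin_centers is None:
        bin_centers = np.arange(len(counts), dtype=float)
    else:
        bin_centers = np.asarray(bin_centers, dtype=float)
    if counts.shape != bin_centers.shape:
        raise ValueError("counts and bin_centers must align")
    if (counts > 0).sum() < 2:
        raise ValueError("histogram needs at least 2 non-empty bins")
    return counts, bin_centers


def otsu_threshold(
    counts: np.ndarray, bin_centers: np.ndarray | None = None
) -> float:
    """Otsu's threshold on a histogram: maximize between-class variance.

    Returns the bin-center value ``t`` of the optimal cut; foreground is
    "strictly greater than t" (the dark-background convention).  Ties
    resolve to the lowest cut.
    """
    counts, centers = _validate_hist(counts, bin_centers)
    w0 = np.cumsum(counts)
    total = w0[-1]
    w1 = total - w0
    sum0 = np.cumsum(counts * centers)
    mu0 = np.divide(sum0, w0, out=np.zeros_like(sum0), where=w0 > 0)
    mu1 = np.divide(sum0[-1] - sum0, w1, out=np.zeros_like(sum0), where=w1 > 0)
    between = w0 * w1 * (mu0 - mu1) ** 2
    between[w1 == 0] = -np.inf  # no valid cut above the last populated bin
    return float(centers[int(np.argmax(between))])


def li_threshold(
    counts: np.ndarray, bin_centers: np.ndarray | None = None
) -> float:
    """Li's minimum cross-entropy threshold on a histogram.

    Minimizes the cross-entropy objective
    ``-(sum_below c*x) log(mu_below) - (sum_above c*x) log(mu_above)`` over
    all candidate cuts (foreground strictly greater than the returned bin
    center; ties to the lowest cut).  Exhaustive minimization is used rather
    than Li's fixed-point iteration: it reaches the same optimum without a
    convergence parameter.  Values must be positive; data containing
    non-positive values are shifted internally and the threshold shifted
    back, as FIJI does.
    """
    counts, centers = _validate_hist(counts, bin_centers)
    shift = 0.0
    if centers.min() <= 0:
        step = np.diff(centers).min() if len(centers) > 1 else 1.0
        shift = step - centers.min()
        centers = centers + shift
    w0 = np.cumsum(counts)
    total = w0[-1]
    w1 = total - w0
    sum0 = np.cumsum(counts * centers)
    sum1 = sum0[-1] - sum0
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = sum0 / w0
        mu1 = sum1 / w1
        objective = -(sum0 * np.log(mu0)) - (sum1 * np.log(mu1))
    objective[~np.isfinite(objective)] = np.inf
    objective[w1 == 0] = np.inf
    objective[w0 == 0] = np.inf
    return float(centers[int(np.argmin(objective))] - shift)


_THRESHOLD_METHODS = {"otsu": otsu_threshold, "li": li_threshold}


def patch_area_fraction(
    series: ImageSeries,
    rois: PolygonROI | Sequence[PolygonROI] | None = None,
    method: str = "otsu",
    window: tuple[float, float] | None = (-360.0, 0.0),
    n_bins: int = 256,
) -> PatchAreaSeries:
    """Thresholded cortical patch area fraction per timepoint.

    One threshold is computed from the pooled stack histogram of the frames
    inside ``window`` (default: the 360 s preceding the end of meiosis I) and
    applied to every windowed frame; the per-frame fraction is the share of
    ROI member pixels strictly above the threshold.  ``rois`` may be a single
    static polygon, one polygon per windowed frame, or ``None`` for the whole
    frame.
    """
    if method not in _THRESHOLD_METHODS:
        raise ValueError(f"method must be one of {sorted(_THRESHOLD_METHODS)}")
    times = series.times_rel
    if window is None:
        sel = np.ones(len(times), dtype=bool)
    else:
        sel = (times >= window[0]) & (times <= window[1])
    if not sel.any():
        raise ValueError("no frames inside the analysis window")
    frames = series.frames[sel]
    counts, centers = stack_histogram(frames, n_bins=n_bins)
    threshold = _THRESHOLD_METHODS[method](counts, centers)

    t_frames = frames.shape[0]
    if rois is None:
        masks = [np.ones(frames.shape[1:], dtype=bool)] * t_frames
    elif isinstance(rois, PolygonROI):
        masks = [roi_mask(frames.shape[1:], rois)] * t_frames
    else:
        rois = list(rois)
        if len(rois) != t_frames:
            raise ValueError("need one ROI per windowed frame")
        masks = [roi_mask(frames.shape[1:], r) for r in rois]
    fractions = np.empty(t_frames)
    for t in range(t_frames):
        members = frames[t][masks[t]]
        if members.size == 0:
            raise ValueError(f"empty ROI at frame {t}")
        fractions[t] = float((members > threshold).mean())
    return PatchAreaSeries(
        times_rel=times[sel],
        fraction=fractions,
        method=method,
        threshold=float(threshold),
    )
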