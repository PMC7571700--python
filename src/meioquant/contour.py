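"""Membrane contour extraction and signed-curvature estimation.

The oocyte membrane is analyzed at a single central z-plane: each frame is
segmented to a filled interior mask, the boundary is traced at sub-pixel
resolution, optionally refined onto the intensity ridge of the membrane tube,
resampled to a fixed number of equal-arc-length points anchored at the
centroid-angle-0 ray, and differentiated to a per-point signed curvature.

Sign convention: contours are oriented counterclockwise, so convex cortex is
positive curvature and ingressing furrows are negative, in units of 1/um.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from shapely.geometry import Polygon
from skimage import filters, measure, morphology

from .imaging_io import ImageSeries, MovieStack, single_plane

__all__ = [
    "ClosedContour",
    "ContourSeries",
    "CurvatureField",
    "central_plane",
    "segment_membrane",
    "extract_closed_contour",
    "refine_to_ridge",
    "resample_arclength",
    "align_series",
    "signed_curvature",
    "extract_frame_contour",
    "extract_contour_series",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

def _signed_area(points: np.ndarray) -> float:
    x, y = points[:, 0], points[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def _polygon_centroid(points: np.ndarray) -> np.ndarray:
    """Area (shoelace) centroid of a closed polygon."""
    x, y = points[:, 0], points[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    area = 0.5 * cross.sum()
    if area == 0:
        return points.mean(axis=0)
    cx = np.sum((x + xn) * cross) / (6.0 * area)
    cy = np.sum((y + yn) * cross) / (6.0 * area)
    return np.array([cx, cy])


@dataclass
class ClosedContour:
    """Closed planar contour in micrometres, counterclockwise.

    The last point connects implicitly back to the first.  ``anchor_index``
    is the index of the point nearest the angle-0 ray from the centroid.
    """

    points: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be (N, 2)")
        if len(self.points) < 16:
            raise ValueError("contour needs at least 16 points")

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def centroid(self) -> np.ndarray:
        return _polygon_centroid(self.points)

    @property
    def signed_area(self) -> float:
        return _signed_area(self.points)

    @property
    def perimeter(self) -> float:
        seg = np.diff(np.vstack([self.points, self.points[:1]]), axis=0)
        return float(np.hypot(seg[:, 0], seg[:, 1]).sum())

    @property
    def anchor_index(self) -> int:
        rel = self.points - self.centroid
        angles = np.mod(np.arctan2(rel[:, 1], rel[:, 0]), 2 * np.pi)
        wrapped = np.minimum(angles, 2 * np.pi - angles)
        return int(np.argmin(wrapped))

    def is_simple(self) -> bool:
        return Polygon(self.points).is_valid


@dataclass
class ContourSeries:
    """Per-frame contours with identical point count and angle-bin indexing.

    Index ``i`` refers to the same centroid-angle bin (``2*pi*i/N``) in every
    frame; correspondence across time is by angle, not by boundary tracking.
    """

    contours: list[ClosedContour]
    times_rel: np.ndarray

    def __post_init__(self) -> None:
        self.times_rel = np.asarray(self.times_rel, dtype=float)
        if len(self.contours) != len(self.times_rel):
            raise ValueError("one time per contour required")
        ns = {c.n_points for c in self.contours}
        if len(ns) > 1:
            raise ValueError(f"contours have differing point counts {ns}")

    @property
    def n_frames(self) -> int:
        return len(self.contours)

    @property
    def n_points(self) -> int:
        return self.contours[0].n_points

    def coords(self) -> np.ndarray:
        """Stacked coordinates of shape ``(T, N, 2)``."""
        return np.stack([c.points for c in self.contours])


@dataclass
class CurvatureField:
    """Signed curvature per (frame, point), 1/um."""

    kappa: np.ndarray
    sigma_s: float
    times_rel: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.kappa = np.asarray(self.kappa, dtype=float)
        if self.kappa.ndim != 2:
            raise ValueError("kappa must be (T, N)")
        if self.times_rel is None:
            self.times_rel = np.arange(self.kappa.shape[0], dtype=float)
        else:
            self.times_rel = np.asarray(self.times_rel, dtype=float)


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def central_plane(stack: MovieStack, channel: str) -> int:
    """Index of the z-plane with the highest total channel intensity."""
    totals = stack.channel(channel).sum(axis=(0, 2, 3), dtype=np.float64)
    return int(np.argmax(totals))


def segment_membrane(
    frame: np.ndarray,
    *,
    smooth_sigma: float = 2.0,
    min_area: int = 500,
) -> np.ndarray:
    """Segment the oocyte interior from a membrane-channel frame.

    Gaussian-smooth, Otsu-threshold, morphologically close, fill holes, and
    keep the largest connected component.  Raises if no component reaches
    ``min_area`` or if a second component comes within 20% of the largest
    (ambiguous field of view).
    """
    frame = np.asarray(frame, dtype=float)
    smoothed = ndimage.gaussian_filter(frame, smooth_sigma)
    if smoothed.max() == smoothed.min():
        raise ValueError("no component: frame is constant")
    binary = smoothed > filters.threshold_otsu(smoothed)
    binary = morphology.closing(binary, morphology.disk(3))
    binary = ndimage.binary_fill_holes(binary)
    labels, n = ndimage.label(binary)
    if n == 0:
        raise ValueError("no component found in frame")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, np.arange(1, n + 1))
    order = np.argsort(sizes)[::-1]
    if sizes[order[0]] < min_area:
        raise ValueError(
            f"no component >= min_area ({sizes[order[0]]:.0f} < {min_area})"
        )
    if n > 1 and sizes[order[1]] >= 0.8 * sizes[order[0]]:
        raise ValueError("ambiguous oocyte: two comparable components")
    mask = labels == order[0] + 1
    return ndimage.binary_fill_holes(mask)


def extract_closed_contour(
    mask: np.ndarray, pixel_size_xy: float = 1.0
) -> ClosedContour:
    """Trace the mask boundary at the 0.5 iso-level, in micrometres, CCW.

    Coordinates are ``(x=column, y=row)`` pixel centers scaled by the lateral
    calibration.  Raises if the mask touches the image border (the boundary
    would be clipped).
    """
    mask = np.asarray(mask, dtype=bool)
    if mask[0].any() or mask[-1].any() or mask[:, 0].any() or mask[:, -1].any():
        raise ValueError("mask touches the image border")
    contours = measure.find_contours(mask.astype(float), 0.5)
    if not contours:
        raise ValueError("no boundary found")
    rc = max(contours, key=len)
    if np.allclose(rc[0], rc[-1]):
        rc = rc[:-1]
    points = np.column_stack([rc[:, 1], rc[:, 0]]) * float(pixel_size_xy)
    if _signed_area(points) < 0:
        points = points[::-1]
    return ClosedContour(points=points)


def refine_to_ridge(
    contour: ClosedContour,
    frame: np.ndarray,
    pixel_size_xy: float,
    *,
    search_radius_um: float = 1.0,
    n_samples: int = 21,
) -> ClosedContour:
    """Snap contour points onto the membrane-intensity ridge.

    For each point, the image is sampled along the local normal within
    ``search_radius_um`` and the point is moved to the sub-pixel intensity
    maximum (quadratic fit around the sampled peak).  This corrects the
    offset between a thresholded-mask boundary (outer tube edge) and the
    membrane tube centerline.
    """
    pts = contour.points / pixel_size_xy  # to pixel units, (x, y)
    n = len(pts)
    tangents = np.roll(pts, -1, axis=0) - np.roll(pts, 1, axis=0)
    norms = np.hypot(tangents[:, 0], tangents[:, 1])
    norms[norms == 0] = 1.0
    # normal of a CCW contour pointing outward: rotate tangent by -90 deg
    normals = np.column_stack([tangents[:, 1], -tangents[:, 0]]) / norms[:, None]
    offsets = np.linspace(
        -search_radius_um / pixel_size_xy, search_radius_um / pixel_size_xy, n_samples
    )
    # sample positions: (n_points, n_samples, 2)
    samples = pts[:, None, :] + offsets[None, :, None] * normals[:, None, :]
    values = ndimage.map_coordinates(
        np.asarray(frame, dtype=float),
        [samples[..., 1].ravel(), samples[..., 0].ravel()],
        order=1,
        mode="nearest",
    ).reshape(n, n_samples)
    peak = np.argmax(values, axis=1)
    best = offsets[peak].copy()
    interior = (peak > 0) & (peak < n_samples - 1)
    step = offsets[1] - offsets[0]
    idx = np.arange(n)[interior]
    y0 = values[idx, peak[interior] - 1]
    y1 = values[idx, peak[interior]]
    y2 = values[idx, peak[interior] + 1]
    denom = y0 - 2 * y1 + y2
    ok = denom < 0
    shift = np.zeros_like(y1)
    shift[ok] = 0.5 * (y0[ok] - y2[ok]) / denom[ok]
    best[idx] += np.clip(shift, -1.0, 1.0) * step
    refined = pts + best[:, None] * normals
    return ClosedContour(points=refined * pixel_size_xy)


# ---------------------------------------------------------------------------
# resampling and alignment
# ---------------------------------------------------------------------------

def _ray_crossing_arclength(points: np.ndarray) -> float:
    """Arc-length position where the contour crosses the centroid +x ray."""
    c = _polygon_centroid(points)
    rel = points - c
    closed = np.vstack([rel, rel[:1]])
    seg = np.diff(closed, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    y0, y1 = closed[:-1, 1], closed[1:, 1]
    x0, x1 = closed[:-1, 0], closed[1:, 0]
    best_s, best_x = None, -np.inf
    # upward crossings of y=0 with x>0 (CCW contour crosses angle 0 upward)
    for i in np.nonzero((y0 <= 0) & (y1 > 0))[0]:
        t = -y0[i] / (y1[i] - y0[i]) if y1[i] != y0[i] else 0.0
        x = x0[i] + t * (x1[i] - x0[i])
        if x > 0 and x > best_x:
            best_x = x
            best_s = cum[i] + t * seg_len[i]
    if best_s is None:
        # fall back to the vertex nearest the ray
        angles = np.mod(np.arctan2(rel[:, 1], rel[:, 0]), 2 * np.pi)
        wrapped = np.minimum(angles, 2 * np.pi - angles)
        best_s = cum[int(np.argmin(wrapped))]
    return float(best_s)


def resample_arclength(contour: ClosedContour, n_points: int = 200) -> ClosedContour:
    """Resample to ``n_points`` equally spaced in arc length, anchored.

    Point 0 is placed at the intersection of the contour with the
    centroid-angle-0 ray; the remaining points follow counterclockwise by
    linear interpolation along the polyline.
    """
    if n_points < 16:
        raise ValueError("n_points must be >= 16")
    pts = contour.points
    if _signed_area(pts) < 0:
        pts = pts[::-1]
    closed = np.vstack([pts, pts[:1]])
    seg = np.diff(closed, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    total = seg_len.sum()
    if total == 0:
        raise ValueError("degenerate contour with zero perimeter")
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    s0 = _ray_crossing_arclength(pts)
    targets = np.mod(s0 + np.arange(n_points) * total / n_points, total)
    x = np.interp(targets, cum, closed[:, 0])
    y = np.interp(targets, cum, closed[:, 1])
    return ClosedContour(points=np.column_stack([x, y]))


def align_series(
    contours: Sequence[ClosedContour],
    times: Sequence[float],
    *,
    max_centroid_jump: float = 0.25,
) -> ContourSeries:
    """Assemble per-frame contours into an angle-indexed series.

    All contours must share the same point count (resample first).  Each
    frame is re-anchored so point ``i`` sits in centroid-angle bin
    ``2*pi*i/N``.  Raises if the centroid jumps between consecutive frames by
    more than ``max_centroid_jump`` of the mean radius, which would violate
    the near-stationary assumption behind angle-bin correspondence.
    """
    contours = list(contours)
    if len(contours) < 2:
        raise ValueError("need at least 2 frames")
    ns = {c.n_points for c in contours}
    if len(ns) > 1:
        raise ValueError("contours must share a point count; resample first")
    n = ns.pop()
    aligned = [resample_arclength(c, n) for c in contours]
    for prev, cur in zip(aligned, aligned[1:]):
        jump = np.linalg.norm(cur.centroid - prev.centroid)
        mean_radius = prev.perimeter / (2 * np.pi)
        if jump > max_centroid_jump * mean_radius:
            raise ValueError(
                f"centroid jump {jump:.2f} um exceeds "
                f"{max_centroid_jump:.0%} of mean radius {mean_radius:.2f} um"
            )
    return ContourSeries(contours=aligned, times_rel=np.asarray(times, dtype=float))


# ---------------------------------------------------------------------------
# curvature
# ---------------------------------------------------------------------------

def _curvature_one(points: np.ndarray, sigma_s: float) -> np.ndarray:
    """Signed curvature of one closed contour by periodic finite differences."""
    if len(points) < 5:
        raise ValueError("need at least 5 points for the curvature stencil")
    x = points[:, 0].astype(float)
    y = points[:, 1].astype(float)
    if sigma_s > 0:
        x = ndimage.gaussian_filter1d(x, sigma_s, mode="wrap")
        y = ndimage.gaussian_filter1d(y, sigma_s, mode="wrap")
    dx = (np.roll(x, -1) - np.roll(x, 1)) / 2.0
    dy = (np.roll(y, -1) - np.roll(y, 1)) / 2.0
    ddx = np.roll(x, -1) - 2 * x + np.roll(x, 1)
    ddy = np.roll(y, -1) - 2 * y + np.roll(y, 1)
    denom = (dx * dx + dy * dy) ** 1.5
    denom[denom == 0] = np.inf
    return (dx * ddy - dy * ddx) / denom


def signed_curvature(
    series: ContourSeries | ClosedContour, sigma_s: float = 2.0
) -> CurvatureField:
    """Per-point signed curvature (1/um) for every frame of a series.

    Coordinates are smoothed along the contour with a periodic Gaussian of
    scale ``sigma_s`` (in points) before central-difference differentiation.
    Convex regions of a counterclockwise contour are positive; indentations
    are negative.
    """
    if sigma_s < 0:
        raise ValueError("sigma_s must be >= 0")
    if isinstance(series, ClosedContour):
        series = ContourSeries(contours=[series], times_rel=np.array([0.0]))
    kappa = np.stack([_curvature_one(c.points, sigma_s) for c in series.contours])
    return CurvatureField(kappa=kappa, sigma_s=sigma_s, times_rel=series.times_rel)


def arc_lengths(series: ContourSeries, sigma_s: float = 2.0) -> np.ndarray:
    """Per-point arc-length element ds (um) matching the curvature stencil."""
    out = []
    for c in series.contours:
        x = c.points[:, 0].astype(float)
        y = c.points[:, 1].astype(float)
        if sigma_s > 0:
            x = ndimage.gaussian_filter1d(x, sigma_s, mode="wrap")
            y = ndimage.gaussian_filter1d(y, sigma_s, mode="wrap")
        dx = (np.roll(x, -1) - np.roll(x, 1)) / 2.0
        dy = (np.roll(y, -1) - np.roll(y, 1)) / 2.0
        out.append(np.hypot(dx, dy))
    return np.stack(out)


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def extract_frame_contour(
    frame: np.ndarray,
    pixel_size_xy: float,
    *,
    refine: bool = True,
    smooth_sigma: float = 2.0,
    min_area: int = 500,
) -> ClosedContour:
    """Segment one membrane frame and trace its boundary at native density.

    Returns the sub-pixel boundary before any fixed-N resampling, which is
    the right object for assessing boundary-localization accuracy.
    """
    mask = segment_membrane(frame, smooth_sigma=smooth_sigma, min_area=min_area)
    contour = extract_closed_contour(mask, pixel_size_xy)
    if refine:
        contour = refine_to_ridge(contour, frame, pixel_size_xy)
    return contour


def extract_contour_series(
    movie: MovieStack,
    membrane_channel: str,
    *,
    n_points: int = 200,
    z: int | None = None,
    refine: bool = True,
    smooth_sigma: float = 2.0,
    min_area: int = 500,
) -> ContourSeries:
    """Segment the membrane channel at one central plane into a ContourSeries.

    ``z`` overrides the automatic central-plane choice (plane of maximal
    membrane-channel intensity).  When ``refine`` is set, contour points are
    snapped to the membrane intensity ridge before resampling.
    """
    if z is None:
        z = central_plane(movie, membrane_channel)
    plane: ImageSeries = single_plane(movie, membrane_channel, z)
    contours = []
    for frame in plane.frames:
        contour = extract_frame_contour(
            frame,
            movie.pixel_size_xy,
            refine=refine,
            smooth_sigma=smooth_sigma,
            min_area=min_area,
        )
        contours.append(resample_arclength(contour, n_points))
    return align_series(contours, plane.times_rel)
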