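"""Synthetic oocyte movies and contour series with known ground truth.

No live-imaging data are deposited with the study this pipeline emulates, so
every analysis stage is exercised on synthetic inputs whose furrow geometry,
spindle intensities, and cortical patch coverage are known exactly.

The oocyte cross-section is an ellipse (default 25 x 15 um semi-axes) whose
radial profile is indented by Gaussian furrows::

    r(theta, t) = r_ellipse(theta) - sum_j d_j * env_j(t) * exp(-dtheta_j^2 / (2 w_j^2))

where ``env_j(t) = clip(g(t) + eta * xi_t, 0, inf)`` combines a
ramp/plateau/ramp temporal envelope ``g`` with per-frame depth jitter.  The
jitter elevates the temporal SD of curvature only at furrow sites, which is
exactly the signature the furrow rule detects.  Every generator output is a
pure function of (params, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from shapely.geometry import Polygon
from skimage.draw import disk as _draw_disk
from skimage.draw import polygon as _draw_polygon

from .contour import ClosedContour, ContourSeries, resample_arclength
from .imaging_io import ImageSeries, MovieStack, PolygonROI

__all__ = [
    "SynthParams",
    "GroundTruth",
    "generate_contour_series",
    "render_movie",
    "generate_patchy_cortex",
]


@dataclass
class SynthParams:
    """Parameters of the synthetic oocyte world.

    Defaults emulate the acquisition geometry of the study: a 25 x 15 um
    half-axis ellipse imaged at 0.1 um/pixel every 10 s for 37 frames (the
    360 s window preceding the end of meiosis I), furrows ~2 um deep with
    angular half-width 0.15 rad, membrane tube of PSF width 0.2 um.
    """

    # geometry
    semi_axis_a: float = 25.0           # um
    semi_axis_b: float = 15.0           # um
    pixel_size_xy: float = 0.1          # um/pixel
    z_spacing: float = 1.0              # um
    n_planes: int = 1
    margin: float = 3.0                 # um of canvas padding around the cell
    # furrows
    n_furrows: int = 3
    furrow_theta: Sequence[float] | None = None  # radians; random if None
    furrow_width_um: float = 1.5        # arc-length sigma of the indentation
    furrow_half_width_rad: float | Sequence[float] | None = None  # override
    furrow_depth: float = 2.0           # um
    jitter: float = 0.3                 # depth jitter amplitude eta
    allow_overlap: bool = False
    ramp_fraction: float = 0.25         # envelope ramp up/down fraction of T
    # time base
    n_frames: int = 37
    frame_interval: float = 10.0        # s
    # contour sampling
    n_points: int = 200
    # rendering
    membrane_intensity: float = 1000.0
    sigma_psf: float = 0.2              # um
    cytoplasm: float = 100.0
    chromatin_background: float = 50.0
    spindle_offset: float = 4.0         # um inward from the cortex at angle 0
    spindle_axes: tuple[float, float] = (2.5, 1.5)  # um
    spindle_intensity: float = 600.0
    n_puncta: int = 6
    puncta_sigma: float = 0.4           # um
    puncta_intensity: float = 800.0
    z_attenuation_sigma: float = 1.5    # planes
    # cortical patch texture
    patch_field_px: int = 128
    n_patches: int = 25
    patch_radius_um: float = 1.0
    patch_intensity: float = 300.0
    patch_background: float = 50.0
    patch_turnover: float = 0.1         # per-patch per-frame reposition prob
    # noise model: photon counts ~ Poisson(gain * clean) + N(0, read_noise_sd)
    noise: bool = True
    poisson_gain: float = 1.0
    read_noise_sd: float = 10.0

    def __post_init__(self) -> None:
        if self.semi_axis_a <= 0 or self.semi_axis_b <= 0:
            raise ValueError("semi-axes must be positive")
        if self.n_furrows < 0:
            raise ValueError("n_furrows must be >= 0")
        if self.furrow_width_um <= 0:
            raise ValueError("furrow_width_um must be positive")
        if self.furrow_depth < 0:
            raise ValueError("furrow_depth must be >= 0")
        if self.n_points < 16:
            raise ValueError("n_points must be >= 16")
        if self.furrow_theta is not None:
            th = np.mod(np.asarray(self.furrow_theta, dtype=float), 2 * np.pi)
            if len(th) != self.n_furrows:
                raise ValueError("furrow_theta length must equal n_furrows")
        if self.patch_intensity <= self.patch_background:
            raise ValueError("patch intensity must exceed the background")

    def with_(self, **kwargs) -> "SynthParams":
        return replace(self, **kwargs)


@dataclass
class GroundTruth:
    """What the generator knows: the quantities the analysis should recover."""

    n_furrows: int
    furrows: list[tuple[float, float, float]]   # (theta, half_width, depth)
    seed: int
    contour_coords: np.ndarray | None = None    # (T, N, 2) um
    patch_fraction: np.ndarray | None = None    # per frame, noiseless mask
    spindle_mean: float | None = None           # noiseless chromatin mean
    cyto_mean: float | None = None
    spindle_roi: PolygonROI | None = None
    cyto_roi: PolygonROI | None = None


# ---------------------------------------------------------------------------
# contour-series generator
# ---------------------------------------------------------------------------

def _ellipse_radius(theta: np.ndarray, a: float, b: float) -> np.ndarray:
    return a * b / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)


def _envelope(n_frames: int, ramp_fraction: float) -> np.ndarray:
    """Ramp-up / plateau / ramp-down temporal envelope in [0, 1]."""
    t = np.arange(n_frames, dtype=float)
    ramp = max(1.0, ramp_fraction * n_frames)
    up = np.clip((t + 1) / ramp, 0, 1)
    down = np.clip((n_frames - t) / ramp, 0, 1)
    return np.minimum(up, down)


def _draw_furrow_positions(
    rng: np.random.Generator, k: int, min_gap: float
) -> np.ndarray:
    """k angles on the circle with pairwise circular gaps >= min_gap."""
    if k == 0:
        return np.empty(0)
    slack = 2 * np.pi - k * min_gap
    if slack < 0:
        raise ValueError(
            f"{k} non-overlapping furrows of gap {min_gap:.2f} rad do not fit"
        )
    gaps = min_gap + rng.dirichlet(np.ones(k)) * slack
    start = rng.uniform(0, 2 * np.pi)
    return np.mod(start + np.concatenate([[0.0], np.cumsum(gaps[:-1])]), 2 * np.pi)


def _wrap_angle(dtheta: np.ndarray) -> np.ndarray:
    return np.mod(dtheta + np.pi, 2 * np.pi) - np.pi


def _furrow_widths(
    params: SynthParams, theta_f: np.ndarray
) -> np.ndarray:
    """Per-furrow angular half-widths w_j (radians).

    By default the indentation has a fixed physical arc-length sigma
    (``furrow_width_um``), so w_j = width / r(theta_j): a furrow is the same
    physical size wherever it sits on the cortex.  ``furrow_half_width_rad``
    overrides with explicit angular widths.
    """
    if params.furrow_half_width_rad is not None:
        w = np.broadcast_to(
            np.asarray(params.furrow_half_width_rad, dtype=float), theta_f.shape
        ).copy()
    else:
        w = params.furrow_width_um / _ellipse_radius(
            theta_f, params.semi_axis_a, params.semi_axis_b
        )
    if (w <= 0).any():
        raise ValueError("angular half-widths must be positive")
    return w


def generate_contour_series(
    params: SynthParams, seed: int
) -> tuple[ContourSeries, GroundTruth]:
    """Sample the furrowed radial model into equal-arc-length contours.

    The radial model is evaluated on a dense angular grid and each frame is
    resampled to ``n_points`` equal-arc-length points anchored at the
    centroid-angle-0 ray — the same discretization the imaging pipeline
    produces, so index ``i`` corresponds to a fixed cortical position across
    frames.  Raises if requested furrows cannot be placed without overlap
    (supports of +-3 half-widths must be disjoint unless ``allow_overlap``),
    or if any generated frame self-intersects.
    """
    rng = np.random.default_rng(seed)
    k, d = params.n_furrows, params.furrow_depth
    w_max = params.furrow_width_um / min(params.semi_axis_a, params.semi_axis_b)
    if params.furrow_theta is not None:
        theta_f = np.mod(np.asarray(params.furrow_theta, dtype=float), 2 * np.pi)
        w_j = _furrow_widths(params, theta_f)
        if k >= 2 and not params.allow_overlap:
            order = np.argsort(theta_f)
            srt, wsrt = theta_f[order], w_j[order]
            gaps = np.diff(np.concatenate([srt, [srt[0] + 2 * np.pi]]))
            supports = 3 * (wsrt + np.roll(wsrt, -1))
            if (gaps < supports).any():
                raise ValueError("furrow supports overlap; set allow_overlap=True")
    elif params.allow_overlap:
        theta_f = rng.uniform(0, 2 * np.pi, size=k)
        w_j = _furrow_widths(params, theta_f)
    else:
        theta_f = _draw_furrow_positions(rng, k, min_gap=6 * w_max)
        w_j = _furrow_widths(params, theta_f)

    n, t_frames = params.n_points, params.n_frames
    dense = max(4 * n, 720)
    theta = 2 * np.pi * np.arange(dense) / dense
    base_r = _ellipse_radius(theta, params.semi_axis_a, params.semi_axis_b)
    env = _envelope(t_frames, params.ramp_fraction)
    xi = rng.standard_normal((k, t_frames))
    # per-furrow, per-frame depth with jitter, clipped at zero
    depth = d * np.clip(env[None, :] + params.jitter * xi, 0.0, None)  # (k, T)
    profile = np.zeros((dense, k))
    for j in range(k):
        profile[:, j] = np.exp(
            -_wrap_angle(theta - theta_f[j]) ** 2 / (2 * w_j[j] ** 2)
        )

    coords = np.empty((t_frames, n, 2))
    contours = []
    for t in range(t_frames):
        r = base_r - profile @ depth[:, t]
        if (r <= 0).any():
            raise ValueError("furrows deeper than the cell radius")
        pts = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
        if not Polygon(pts).is_valid:
            raise ValueError(f"generated contour self-intersects at frame {t}")
        contour = resample_arclength(ClosedContour(points=pts), n)
        coords[t] = contour.points
        contours.append(contour)

    times = (np.arange(t_frames) - (t_frames - 1)) * params.frame_interval
    series = ContourSeries(contours=contours, times_rel=times)
    truth = GroundTruth(
        n_furrows=k,
        furrows=[(float(th), float(w), d) for th, w in zip(theta_f, w_j)],
        seed=seed,
        contour_coords=coords,
    )
    return series, truth


# ---------------------------------------------------------------------------
# movie renderer
# ---------------------------------------------------------------------------

def _dense_polyline(points: np.ndarray, step: float) -> np.ndarray:
    """Resample a closed polyline at spacing <= step (same units as input)."""
    closed = np.vstack([points, points[:1]])
    seg = np.diff(closed, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    out = []
    for p, v, ell in zip(closed[:-1], seg, seg_len):
        m = max(1, int(np.ceil(ell / step)))
        ts = np.arange(m) / m
        out.append(p + ts[:, None] * v)
    return np.vstack(out)


def _regular_polygon(center: np.ndarray, radius: float, n: int = 24) -> np.ndarray:
    ang = 2 * np.pi * np.arange(n) / n
    return center + radius * np.column_stack([np.cos(ang), np.sin(ang)])


def apply_noise(
    clean: np.ndarray, gain: float, read_sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Photon shot noise then Gaussian read noise: Poisson(gain*I) + N(0, sd)."""
    counts = rng.poisson(np.clip(clean, 0, None) * gain).astype(float)
    if read_sd > 0:
        counts = counts + rng.normal(0.0, read_sd, size=counts.shape)
    return np.clip(counts, 0, None)


def render_movie(
    contours: ContourSeries, params: SynthParams, seed: int
) -> tuple[MovieStack, GroundTruth]:
    """Render a two-channel movie (membrane, chromatin) from a contour series.

    The membrane channel is a Gaussian tube of width ``sigma_psf`` along each
    frame's contour plus a diffuse cytoplasm fill; the chromatin channel holds
    a spindle-associated blob and chromosome puncta near the cortex at angle
    0.  Z-planes replicate the central plane with Gaussian attenuation.
    Poisson and read noise are applied when ``params.noise`` is set.
    """
    rng = np.random.default_rng(seed)
    px = params.pixel_size_xy
    coords = contours.coords()  # (T, N, 2) um, centered near origin
    margin_um = max(params.margin, 3.0 * params.sigma_psf)
    x_min, y_min = coords.reshape(-1, 2).min(axis=0) - margin_um
    x_max, y_max = coords.reshape(-1, 2).max(axis=0) + margin_um
    offset = np.array([-x_min, -y_min])
    nx = int(np.ceil((x_max - x_min) / px))
    ny = int(np.ceil((y_max - y_min) / px))
    shifted = coords + offset  # um, in canvas frame
    lo = shifted.reshape(-1, 2).min(axis=0)
    hi = shifted.reshape(-1, 2).max(axis=0)
    if (lo < 3 * params.sigma_psf).any() or (
        hi > np.array([nx, ny]) * px - 3 * params.sigma_psf
    ).any():
        raise ValueError("contour exits the field of view margin")

    sigma_px = params.sigma_psf / px
    yy, xx = np.mgrid[0:ny, 0:nx]
    # pixel centers sit at integer indices: pixel (r, c) is at (x=c, y=r)
    grid = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)

    t_frames = contours.n_frames
    membrane = np.empty((t_frames, ny, nx), dtype=np.float64)
    for t in range(t_frames):
        pts_px = shifted[t] / px
        dense = _dense_polyline(pts_px, step=0.2)
        # exact point-to-curve distance, evaluated only in a band around the
        # contour (coarse EDT locates the band; the tube is ~0 outside 4 sigma)
        raster = np.zeros((ny, nx), dtype=bool)
        ij = np.clip(np.rint(dense).astype(int), 0, [nx - 1, ny - 1])
        raster[ij[:, 1], ij[:, 0]] = True
        coarse = ndimage.distance_transform_edt(~raster)
        band = coarse <= 4 * sigma_px + 2
        dist, _ = cKDTree(dense).query(
            np.column_stack([np.nonzero(band)[1], np.nonzero(band)[0]]).astype(
                float
            ),
            workers=-1,
        )
        tube = np.zeros((ny, nx))
        tube[band] = params.membrane_intensity * np.exp(
            -(dist**2) / (2 * sigma_px**2)
        )
        interior = ndimage.binary_fill_holes(raster).astype(float)
        cyto = params.cytoplasm * ndimage.gaussian_filter(interior, sigma_px)
        membrane[t] = tube + cyto

    # chromatin channel: spindle blob + puncta near the cortex at angle 0
    cell_center = offset  # generator contours are centered at the origin
    r_edge = _ellipse_radius(np.zeros(1), params.semi_axis_a, params.semi_axis_b)[0]
    spindle_center = cell_center + np.array([r_edge - params.spindle_offset, 0.0])
    sx, sy = params.spindle_axes
    blob = params.spindle_intensity * np.exp(
        -((grid[:, 0] * px - spindle_center[0]) ** 2) / (2 * sx**2)
        - ((grid[:, 1] * px - spindle_center[1]) ** 2) / (2 * sy**2)
    ).reshape(ny, nx)
    puncta_pos = spindle_center + rng.normal(0, 1.0, size=(params.n_puncta, 2))
    puncta = np.zeros((ny, nx))
    for p in puncta_pos:
        puncta += params.puncta_intensity * np.exp(
            -((grid[:, 0] * px - p[0]) ** 2 + (grid[:, 1] * px - p[1]) ** 2)
            / (2 * params.puncta_sigma**2)
        ).reshape(ny, nx)
    chromatin_base = blob + puncta

    chromatin = np.empty_like(membrane)
    for t in range(t_frames):
        pts_px = shifted[t] / px
        raster = np.zeros((ny, nx), dtype=bool)
        ij = np.clip(
            np.rint(_dense_polyline(pts_px, step=0.5)).astype(int),
            0,
            [nx - 1, ny - 1],
        )
        raster[ij[:, 1], ij[:, 0]] = True
        interior = ndimage.binary_fill_holes(raster).astype(float)
        chromatin[t] = chromatin_base + params.chromatin_background * (
            ndimage.gaussian_filter(interior, sigma_px)
        )

    # replicate the central plane across z with Gaussian attenuation
    z = np.arange(params.n_planes)
    zc = (params.n_planes - 1) / 2.0
    atten = np.exp(-((z - zc) ** 2) / (2 * params.z_attenuation_sigma**2))
    clean = np.stack(
        [
            membrane[:, None] * atten[None, :, None, None],
            chromatin[:, None] * atten[None, :, None, None],
        ]
    )  # (C, T, Z, Y, X)

    if params.noise:
        data = apply_noise(clean, params.poisson_gain, params.read_noise_sd, rng)
        data = np.clip(np.rint(data), 0, 65535).astype(np.uint16)
    else:
        data = clean.astype(np.float32)

    stack = MovieStack(
        data=data,
        channel_names=["membrane", "chromatin"],
        pixel_size_xy=px,
        z_spacing=params.z_spacing,
        frame_interval=params.frame_interval,
        t0_frame=t_frames - 1,
    )

    spindle_roi = PolygonROI(
        _regular_polygon(spindle_center / px, max(sx, sy) * 1.5 / px)
    )
    cyto_center = cell_center + np.array([-params.semi_axis_a / 2, 0.0])
    cyto_roi = PolygonROI(_regular_polygon(cyto_center / px, 3.0 / px))
    zc_i = int(round(zc))
    chrom0 = clean[1, 0, zc_i] if params.n_planes > 1 else chromatin[0]
    truth = GroundTruth(
        n_furrows=0,
        furrows=[],
        seed=seed,
        contour_coords=shifted,  # canvas-frame um coordinates
        spindle_mean=float(
            chrom0[_roi_mask_px(spindle_roi, (ny, nx))].mean()
        ),
        cyto_mean=float(chrom0[_roi_mask_px(cyto_roi, (ny, nx))].mean()),
        spindle_roi=spindle_roi,
        cyto_roi=cyto_roi,
    )
    return stack, truth


def _roi_mask_px(roi: PolygonROI, shape: tuple[int, int]) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    rr, cc = _draw_polygon(roi.vertices[:, 1], roi.vertices[:, 0], shape=shape)
    mask[rr, cc] = True
    return mask


# ---------------------------------------------------------------------------
# cortical patch texture
# ---------------------------------------------------------------------------

def generate_patchy_cortex(
    params: SynthParams, seed: int
) -> tuple[ImageSeries, GroundTruth]:
    """Disk-shaped bright patches on a dark background, with turnover.

    Emulates a maximum-projected cortical patch channel: ``n_patches`` disks
    of radius ``patch_radius_um`` at intensity ``patch_intensity`` over a
    ``patch_background`` baseline.  Each patch is independently repositioned
    with probability ``patch_turnover`` per frame.  The ground-truth area
    fraction per frame is counted on the noiseless mask.
    """
    rng = np.random.default_rng(seed)
    size = params.patch_field_px
    t_frames = params.n_frames
    radius_px = params.patch_radius_um / params.pixel_size_xy
    pos = rng.uniform(0, size, size=(params.n_patches, 2))
    frames = np.empty((t_frames, size, size), dtype=float)
    fractions = np.empty(t_frames)
    for t in range(t_frames):
        if t > 0 and params.n_patches > 0:
            move = rng.uniform(size=params.n_patches) < params.patch_turnover
            pos[move] = rng.uniform(0, size, size=(int(move.sum()), 2))
        mask = np.zeros((size, size), dtype=bool)
        for cy, cx in pos:
            rr, cc = _draw_disk((cy, cx), radius_px, shape=(size, size))
            mask[rr, cc] = True
        fractions[t] = mask.mean()
        clean = params.patch_background + (
            params.patch_intensity - params.patch_background
        ) * mask.astype(float)
        if params.noise:
            frames[t] = apply_noise(
                clean, params.poisson_gain, params.read_noise_sd, rng
            )
        else:
            frames[t] = clean
    times = (np.arange(t_frames) - (t_frames - 1)) * params.frame_interval
    series = ImageSeries(
        frames=frames,
        times_rel=times,
        provenance={"projection": "max", "channel": "cortex", "synthetic": True},
    )
    truth = GroundTruth(
        n_furrows=0, furrows=[], seed=seed, patch_fraction=fractions
    )
    return series, truth
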