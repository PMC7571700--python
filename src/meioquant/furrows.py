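"""Cortical furrow classification and counting from membrane curvature.

A furrow is at least two consecutive membrane points whose temporal-mean
curvature is negative and whose temporal standard deviation of curvature is at
least two standard deviations above the cortex-average standard deviation.
Qualifying runs separated by a single non-qualifying point count as one
furrow; the contour is circular, so runs and merges wrap across the index
origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from skimage.draw import line as _draw_line

from .contour import ContourSeries, CurvatureField, signed_curvature

__all__ = [
    "CurvatureProfile",
    "FurrowCall",
    "FurrowCountResult",
    "curvature_profile",
    "qualify_points",
    "detect_furrows",
    "count_furrows",
    "temporal_overlay",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class CurvatureProfile:
    """Per-point temporal summary of signed curvature over a time window.

    ``mu``/``sigma`` are the temporal mean and sample standard deviation of
    curvature at each membrane point; ``sigma_bar`` and ``s_sigma`` are the
    mean and SD of ``sigma`` across points (the cortex-wide scale the furrow
    rule thresholds against).
    """

    mu: np.ndarray
    sigma: np.ndarray
    sigma_bar: float
    s_sigma: float
    window: tuple[float, float]
    n_frames: int

    @property
    def n_points(self) -> int:
        return len(self.mu)


@dataclass
class FurrowCall:
    """One detected furrow: a maximal circular run of qualifying points."""

    indices: list[int]          # full run, including single-point bridges
    n_points: int               # count of qualifying (non-bridged) points
    min_mu: float               # most negative mean curvature in the run
    location_deg: float         # circular-mean angle of qualifying points


@dataclass
class FurrowCountResult:
    oocyte_id: str
    furrow_count: int
    calls: list[FurrowCall]
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.furrow_count != len(self.calls):
            raise ValueError("furrow_count must equal number of calls")


# ---------------------------------------------------------------------------
# profile and qualification
# ---------------------------------------------------------------------------

def curvature_profile(
    field_: CurvatureField,
    window: tuple[float, float] | None = None,
) -> CurvatureProfile:
    """Temporal mean/SD of curvature per point over ``window`` (seconds).

    SDs use the sample convention (denominator n-1).  ``window`` is an
    inclusive ``[t_start, t_end]`` on the field's relative times; ``None``
    uses every frame.  At least two frames must fall inside.
    """
    times = field_.times_rel
    if window is None:
        sel = np.ones(len(times), dtype=bool)
    else:
        t0, t1 = window
        sel = (times >= t0) & (times <= t1)
    if sel.sum() < 2:
        raise ValueError("window must contain at least 2 frames")
    kappa = field_.kappa[sel]
    mu = kappa.mean(axis=0)
    sigma = kappa.std(axis=0, ddof=1)
    return CurvatureProfile(
        mu=mu,
        sigma=sigma,
        sigma_bar=float(sigma.mean()),
        s_sigma=float(sigma.std(ddof=1)),
        window=(float(times[sel][0]), float(times[sel][-1])),
        n_frames=int(sel.sum()),
    )


def qualify_points(
    profile: CurvatureProfile, *, sd_rule: str = "twice_mean"
) -> np.ndarray:
    """Boolean flags: which membrane points meet both furrow criteria.

    A point qualifies when its temporal-mean curvature is negative AND its
    curvature SD clears the cortex-wide threshold.  ``sd_rule`` selects the
    reading of "two standard deviations above the average standard
    deviation":

    - ``"twice_mean"`` (default): sigma_i >= 2 * sigma_bar.
    - ``"above_spread"``: sigma_i >= sigma_bar + 2 * s_sigma, i.e. two SDs
      of the per-point-SD distribution above its mean.  With a quiet
      baseline this threshold converges to the spike height itself as more
      of the cortex furrows, saturating the count around 4-5 furrows, which
      is why it is not the default (see the methods note).

    The comparison is ``>=`` so the all-equal-sigma case qualifies on the
    SD criterion alone under either rule when the threshold ties sigma_i.
    """
    if sd_rule == "above_spread":
        threshold = profile.sigma_bar + 2.0 * profile.s_sigma
    elif sd_rule == "twice_mean":
        threshold = 2.0 * profile.sigma_bar
    else:
        raise ValueError(f"unknown sd_rule {sd_rule!r}")
    return (profile.mu < 0) & (profile.sigma >= threshold)


# ---------------------------------------------------------------------------
# run detection with circular merge rule
# ---------------------------------------------------------------------------

def _circular_runs(flags: np.ndarray) -> list[list[int]]:
    """Maximal circular runs of True indices, each in circular order."""
    n = len(flags)
    if flags.all():
        return [list(range(n))]
    if not flags.any():
        return []
    start = int(np.argmin(flags))  # a False index to cut the circle at
    order = [(start + i) % n for i in range(n)]
    runs: list[list[int]] = []
    current: list[int] = []
    for idx in order:
        if flags[idx]:
            current.append(idx)
        elif current:
            runs.append(current)
            current = []
    if current:
        runs.append(current)
    return runs


def detect_furrows(flags: Sequence[bool] | np.ndarray) -> list[dict]:
    """Group qualifying points into furrow runs under the circular merge rule.

    Maximal circular runs of qualifying points are found; any two runs
    separated by exactly one non-qualifying point are merged (the bridge point
    joins the run), iterated to closure; merged runs containing fewer than two
    qualifying points are discarded.  Returns one dict per furrow with keys
    ``indices`` (full run) and ``qualifying`` (original qualifying indices).
    """
    flags = np.asarray(flags, dtype=bool)
    n = len(flags)
    if n == 0:
        return []
    runs = _circular_runs(flags)
    if not runs:
        return []
    if len(runs) == 1 and len(runs[0]) == n:
        if n < 2:
            return []
        return [{"indices": list(range(n)), "qualifying": list(range(n))}]

    # merge runs separated by exactly one gap index, to closure
    changed = True
    while changed and len(runs) >= 1:
        changed = False
        runs.sort(key=lambda r: r[0])
        k = len(runs)
        for i in range(k):
            a = runs[i]
            b = runs[(i + 1) % k]
            gap = (b[0] - a[-1] - 1) % n
            if gap == 1:
                bridge = (a[-1] + 1) % n
                if a is b:
                    # a single run separated from itself by one gap: close the circle
                    merged = a + [bridge]
                    runs = [merged]
                else:
                    merged = a + [bridge] + b
                    rest = [r for j, r in enumerate(runs) if j not in (i, (i + 1) % k)]
                    runs = rest + [merged]
                changed = True
                break

    out = []
    for run in runs:
        qualifying = [i for i in run if flags[i]]
        if len(qualifying) >= 2:
            out.append({"indices": run, "qualifying": qualifying})
    # report in circular order of first index
    out.sort(key=lambda d: d["indices"][0])
    return out


def _calls_from_runs(
    runs: list[dict],
    profile: CurvatureProfile,
    point_angles: np.ndarray | None = None,
) -> list[FurrowCall]:
    n = profile.n_points
    if point_angles is None:
        point_angles = 2 * np.pi * np.arange(n) / n
    calls = []
    for run in runs:
        q = np.asarray(run["qualifying"])
        angles = point_angles[q]
        mean_angle = np.arctan2(np.sin(angles).mean(), np.cos(angles).mean())
        calls.append(
            FurrowCall(
                indices=list(run["indices"]),
                n_points=len(q),
                min_mu=float(profile.mu[q].min()),
                location_deg=float(np.degrees(mean_angle) % 360.0),
            )
        )
    return calls


def count_furrows(
    series: ContourSeries,
    *,
    window: tuple[float, float] | None = None,
    sigma_s: float = 2.0,
    sd_rule: str = "twice_mean",
    exclude_deg: tuple[float, float] | None = None,
    oocyte_id: str = "oocyte",
) -> FurrowCountResult:
    """Full furrow count for one oocyte contour series.

    Composes curvature estimation, temporal profiling over ``window``
    (default: all frames; pass ``(-360.0, 0.0)`` for the standard window
    preceding the end of meiosis I), qualification, and circular run
    detection.  ``exclude_deg`` optionally masks an angular sector (e.g. the
    spindle-associated cortex) from qualification; it is off by default.
    """
    field_ = signed_curvature(series, sigma_s=sigma_s)
    profile = curvature_profile(field_, window=window)
    flags = qualify_points(profile, sd_rule=sd_rule)
    # centroid angles of the (time-averaged) points, for locations and masks
    mean_pts = series.coords().mean(axis=0)
    centroid = mean_pts.mean(axis=0)
    point_angles = np.mod(
        np.arctan2(mean_pts[:, 1] - centroid[1], mean_pts[:, 0] - centroid[0]),
        2 * np.pi,
    )
    if exclude_deg is not None:
        angles = np.degrees(point_angles)
        lo, hi = exclude_deg
        if lo <= hi:
            excluded = (angles >= lo) & (angles <= hi)
        else:  # sector wrapping through 0
            excluded = (angles >= lo) | (angles <= hi)
        flags = flags & ~excluded
    runs = detect_furrows(flags)
    calls = _calls_from_runs(runs, profile, point_angles)
    return FurrowCountResult(
        oocyte_id=oocyte_id,
        furrow_count=len(calls),
        calls=calls,
        parameters={
            "n_points": series.n_points,
            "sigma_s": sigma_s,
            "window": profile.window,
            "sd_rule": sd_rule,
            "exclude_deg": exclude_deg,
        },
    )


# ---------------------------------------------------------------------------
# membrane temporal overlay
# ---------------------------------------------------------------------------

def temporal_overlay(
    series: ContourSeries,
    shape: tuple[int, int],
    pixel_size_xy: float,
    *,
    mode: str = "count",
) -> np.ndarray:
    """Rasterize every frame's contour into one image.

    Each contour is drawn as a 1-pixel closed polyline on a ``shape`` canvas
    (rows, cols) at the given calibration.  In ``"count"`` mode the output
    pixel value is the number of frames whose contour passes through it; in
    ``"union"`` mode it is binary.
    """
    if mode not in ("count", "union"):
        raise ValueError(f"unknown overlay mode {mode!r}")
    if series.n_frames < 1:
        raise ValueError("need at least one frame")
    h, w = shape
    overlay = np.zeros((h, w), dtype=np.int64)
    for contour in series.contours:
        px = np.rint(contour.points / pixel_size_xy).astype(int)
        if (px < 0).any() or (px[:, 0] >= w).any() or (px[:, 1] >= h).any():
            raise ValueError("contour outside canvas")
        layer = np.zeros((h, w), dtype=bool)
        closed = np.vstack([px, px[:1]])
        for (x0, y0), (x1, y1) in zip(closed[:-1], closed[1:]):
            rr, cc = _draw_line(y0, x0, y1, x1)
            layer[rr, cc] = True
        overlay += layer
    if mode == "union":
        return (overlay > 0).astype(np.uint8)
    return overlay
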