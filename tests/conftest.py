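"""Shared fixtures: small synthetic worlds sized for fast unit tests."""

import numpy as np
import pytest

import meioquant as mq


@pytest.fixture(scope="session")
def small_params() -> mq.SynthParams:
    """A small oocyte (8 x 6 um at 0.2 um/px) so rendering stays cheap."""
    return mq.SynthParams(
        semi_axis_a=8.0,
        semi_axis_b=6.0,
        pixel_size_xy=0.2,
        n_furrows=2,
        furrow_depth=1.0,
        furrow_width_um=0.8,
        n_frames=12,
        n_points=100,
        n_planes=1,
        spindle_offset=2.0,
        spindle_axes=(1.2, 0.8),
    )


@pytest.fixture(scope="session")
def small_noiseless_movie(small_params):
    """One rendered noiseless movie plus its generating truth."""
    params = small_params.with_(noise=False)
    series, truth = mq.generate_contour_series(params, seed=7)
    stack, render_truth = mq.render_movie(series, params, seed=7)
    return params, series, truth, stack, render_truth


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def circle_contour(radius: float = 10.0, n: int = 200, center=(0.0, 0.0)):
    theta = 2 * np.pi * np.arange(n) / n
    pts = np.column_stack(
        [center[0] + radius * np.cos(theta), center[1] + radius * np.sin(theta)]
    )
    return mq.ClosedContour(points=pts)


def ellipse_contour(a: float = 25.0, b: float = 15.0, n: int = 2000):
    theta = 2 * np.pi * np.arange(n) / n
    return mq.ClosedContour(
        points=np.column_stack([a * np.cos(theta), b * np.sin(theta)])
    )


def random_star_contour(rng, n: int = 400, r0: float = 10.0):
    """Random smooth star-shaped (hence simple) closed contour."""
    theta = 2 * np.pi * np.arange(n) / n
    r = np.full(n, r0)
    for harmonic in range(2, 7):
        amp = rng.uniform(0, 0.06) * r0
        phase = rng.uniform(0, 2 * np.pi)
        r += amp * np.cos(harmonic * theta + phase)
    return mq.ClosedContour(
        points=np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    )
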