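"""Intensity metrics: mean grey, spindle formulas, thresholds, patch fractions."""

import numpy as np
import pytest
from skimage import filters as skfilters

import meioquant as mq
from meioquant.fluorescence import stack_histogram


def square_roi(x0, y0, x1, y1):
    return mq.PolygonROI(vertices=[(x0, y0), (x1, y0), (x1, y1), (x0, y1)])


def point_in_polygon_loop(x, y, verts):
    """Scalar even-odd crossing test, the textbook way."""
    inside = False
    n = len(verts)
    for i in range(n):
        ax, ay = verts[i]
        bx, by = verts[(i + 1) % n]
        if (ay > y) != (by > y):
            x_int = ax + (y - ay) * (bx - ax) / (by - ay)
            if x < x_int:
                inside = not inside
    return inside


def otsu_oracle(counts, centers):
    """Exhaustive between-class variance maximization, plain loops."""
    counts = np.asarray(counts, float)
    best_t, best_v = None, -1.0
    total = counts.sum()
    for t in range(len(counts) - 1):
        w0 = counts[: t + 1].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (counts[: t + 1] * centers[: t + 1]).sum() / w0
        mu1 = (counts[t + 1 :] * centers[t + 1 :]).sum() / w1
        v = w0 * w1 * (mu0 - mu1) ** 2
        if v > best_v:
            best_v, best_t = v, t
    return centers[best_t]


def li_oracle(counts, centers):
    """Exhaustive cross-entropy minimization, plain loops."""
    counts = np.asarray(counts, float)
    best_t, best_obj = None, np.inf
    for t in range(len(counts) - 1):
        w0 = counts[: t + 1].sum()
        w1 = counts[t + 1 :].sum()
        if w0 == 0 or w1 == 0:
            continue
        s0 = (counts[: t + 1] * centers[: t + 1]).sum()
        s1 = (counts[t + 1 :] * centers[t + 1 :]).sum()
        mu0, mu1 = s0 / w0, s1 / w1
        if mu0 <= 0 or mu1 <= 0:
            continue
        obj = -s0 * np.log(mu0) - s1 * np.log(mu1)
        if obj < best_obj:
            best_obj, best_t = obj, t
    return centers[best_t]


class TestMeanGrey:
    def test_constant_image(self):
        frame = np.full((20, 20), 4.5)
        assert mq.mean_grey(frame, square_roi(2.5, 2.5, 10.5, 12.5)) == 4.5

    def test_enclosed_2x2_region(self):
        frame = np.zeros((10, 10))
        frame[3, 3], frame[3, 4], frame[4, 3], frame[4, 4] = 1, 2, 3, 4
        roi = square_roi(2.5, 2.5, 4.5, 4.5)
        assert mq.mean_grey(frame, roi) == 2.5

    def test_matches_point_in_polygon_loop(self, rng):
        frame = rng.uniform(size=(30, 30))
        verts = np.column_stack(
            [15 + 10 * np.cos(2 * np.pi * np.arange(7) / 7) + rng.normal(0, 1.3, 7),
             15 + 10 * np.sin(2 * np.pi * np.arange(7) / 7) + rng.normal(0, 1.3, 7)]
        )
        roi = mq.PolygonROI(vertices=verts)
        members = [
            frame[y, x]
            for y in range(30)
            for x in range(30)
            if point_in_polygon_loop(x, y, verts)
        ]
        assert abs(mq.mean_grey(frame, roi) - np.mean(members)) < 1e-12

    def test_permutation_invariance(self, rng):
        frame = rng.uniform(size=(20, 20))
        roi = square_roi(3.5, 3.5, 12.5, 12.5)
        mask = mq.roi_mask(frame.shape, roi)
        shuffled = frame.copy()
        vals = shuffled[mask]
        shuffled[mask] = vals[rng.permutation(len(vals))]
        assert abs(mq.mean_grey(frame, roi) - mq.mean_grey(shuffled, roi)) < 1e-12

    def test_empty_roi(self):
        with pytest.raises(ValueError):
            mq.mean_grey(np.ones((50, 50)), square_roi(10.2, 10.2, 10.4, 10.4))


class TestTotalSpindleIntensity:
    def test_forced_formula_case(self):
        """Means 100 and 50 over a 200-pixel spindle ROI give 400 exactly."""
        frame = np.full((40, 40), 50.0)
        spindle = square_roi(0.5, 0.5, 20.5, 10.5)  # 20 x 10 = 200 pixels
        frame[mq.roi_mask(frame.shape, spindle)] = 100.0
        cyto = square_roi(24.5, 24.5, 34.5, 34.5)
        rec = mq.total_spindle_intensity(frame, spindle, cyto)
        assert rec.spindle_area == 200
        assert rec.total_intensity == 400.0
        assert rec.total_intensity == (rec.mean_spindle / rec.mean_cyto) * rec.spindle_area

    def test_ratio_one_gives_area(self, rng):
        frame = np.full((30, 30), 77.0)
        rec = mq.total_spindle_intensity(
            frame, square_roi(1.5, 1.5, 9.5, 9.5), square_roi(14.5, 14.5, 24.5, 24.5)
        )
        assert rec.total_intensity == rec.spindle_area

    def test_scale_invariance(self, rng):
        frame = rng.uniform(10, 100, size=(30, 30))
        s, c = square_roi(1.5, 1.5, 10.5, 8.5), square_roi(15.5, 15.5, 25.5, 25.5)
        r1 = mq.total_spindle_intensity(frame, s, c)
        r2 = mq.total_spindle_intensity(frame * 13.0, s, c)
        assert abs(r1.total_intensity - r2.total_intensity) < 1e-8

    def test_synthetic_render_matches_hand_computation(self, small_noiseless_movie):
        _, _, _, stack, render_truth = small_noiseless_movie
        frame = stack.channel("chromatin")[0, 0].astype(float)
        rec = mq.total_spindle_intensity(
            frame, render_truth.spindle_roi, render_truth.cyto_roi
        )
        mask_s = mq.roi_mask(frame.shape, render_truth.spindle_roi)
        mask_c = mq.roi_mask(frame.shape, render_truth.cyto_roi)
        expected = (frame[mask_s].mean() / frame[mask_c].mean()) * mask_s.sum()
        assert abs(rec.total_intensity - expected) < 1e-9


class TestRatioSeries:
    def test_uniform_image_ratio_one(self):
        series = mq.ImageSeries(
            frames=np.full((4, 20, 20), 9.0), times_rel=np.arange(4.0)
        )
        out = mq.ratio_series(series, square_roi(1.5, 1.5, 8.5, 8.5), square_roi(10.5, 10.5, 18.5, 18.5))
        np.testing.assert_allclose(out.ratio, 1.0)

    def test_blob_over_background(self, small_noiseless_movie):
        params, _, _, stack, render_truth = small_noiseless_movie
        series = mq.single_plane(stack, "chromatin", 0)
        out = mq.ratio_series(
            series, render_truth.spindle_roi, render_truth.cyto_roi, marker="AIR-2-like"
        )
        assert (out.ratio > 2.0).all()

    def test_meiosis_end_time_convention(self):
        """37 frames at 10 s with t0 on the last frame span -360..0 s."""
        frames = np.full((37, 8, 8), 5.0)
        stack = mq.MovieStack(
            frames[None, :, None], ["m"], 0.1, 1.0, 10.0, t0_frame=36
        )
        series = mq.max_project(stack, "m")
        out = mq.ratio_series(series, square_roi(0.5, 0.5, 4.5, 4.5), square_roi(4.5, 4.5, 7.5, 7.5))
        np.testing.assert_allclose(out.times_rel, np.arange(-360.0, 1.0, 10.0))


class TestThresholds:
    def test_otsu_separates_delta_peaks(self):
        counts = np.zeros(256)
        counts[10], counts[200] = 400, 600
        t = mq.otsu_threshold(counts)
        assert 10 <= t < 200

    def test_li_separates_delta_peaks(self):
        counts = np.zeros(256)
        counts[10], counts[200] = 400, 600
        centers = np.arange(1.0, 257.0)
        t = mq.li_threshold(counts, centers)
        assert centers[10] <= t < centers[200]

    def test_otsu_matches_exhaustive_oracle(self, rng):
        centers = np.arange(256, dtype=float)
        for _ in range(100):
            counts = rng.integers(0, 50, size=256).astype(float)
            counts[counts < 10] = 0
            if (counts > 0).sum() < 2:
                continue
            assert mq.otsu_threshold(counts, centers) == otsu_oracle(counts, centers)

    def test_li_matches_exhaustive_oracle(self, rng):
        centers = np.arange(1.0, 257.0)
        for _ in range(100):
            counts = rng.integers(0, 50, size=256).astype(float)
            counts[counts < 10] = 0
            if (counts > 0).sum() < 2:
                continue
            assert mq.li_threshold(counts, centers) == li_oracle(counts, centers)

    def test_otsu_shift_equivariance(self, rng):
        counts = rng.integers(0, 100, size=64).astype(float)
        counts[:4] += 200
        counts[-6:] += 150
        centers = np.arange(64, dtype=float)
        t0 = mq.otsu_threshold(counts, centers)
        t1 = mq.otsu_threshold(counts, centers + 17.0)
        assert t1 == t0 + 17.0

    def test_li_scale_equivariance(self, rng):
        counts = rng.integers(1, 100, size=64).astype(float)
        centers = np.linspace(1.0, 40.0, 64)
        t0 = mq.li_threshold(counts, centers)
        t1 = mq.li_threshold(counts, centers * 3.0)
        assert abs(t1 - 3.0 * t0) < 1e-9

    def test_agrees_with_skimage_on_images(self, rng):
        """Same foreground classification as skimage's implementations.

        Threshold values may sit anywhere on a tied plateau of the objective
        (ours breaks ties low, skimage's Li iteration lands mid-plateau), so
        the meaningful comparison is the induced pixel classification.
        """
        image = np.concatenate(
            [rng.normal(40, 5, 4000), rng.normal(180, 12, 2000)]
        ).clip(0, 255).astype(np.uint8)
        counts, centers = stack_histogram(image)
        t_otsu = mq.otsu_threshold(counts, centers)
        np.testing.assert_array_equal(
            image > t_otsu, image > skfilters.threshold_otsu(image)
        )
        t_li = mq.li_threshold(counts, centers)
        np.testing.assert_array_equal(
            image > t_li, image.astype(float) > skfilters.threshold_li(image.astype(float))
        )

    def test_single_valued_histogram_rejected(self):
        counts = np.zeros(256)
        counts[40] = 100
        with pytest.raises(ValueError):
            mq.otsu_threshold(counts)


class TestPatchAreaFraction:
    def _series(self, frames, dt=10.0):
        t = np.arange(len(frames), dtype=float)
        times = (t - (len(frames) - 1)) * dt
        return mq.ImageSeries(frames=np.asarray(frames, float), times_rel=times)

    def test_half_above(self):
        frame = np.zeros((10, 10))
        frame[:, 5:] = 200.0
        frames = [frame, frame]
        out = mq.patch_area_fraction(self._series(frames), method="otsu", window=None)
        np.testing.assert_allclose(out.fraction, 0.5)

    def test_bounds(self):
        lo = np.zeros((8, 8))
        hi = np.full((8, 8), 250.0)
        out = mq.patch_area_fraction(
            self._series([lo, hi]), method="otsu", window=None
        )
        assert out.fraction[0] == 0.0
        assert out.fraction[1] == 1.0

    def test_synthetic_patches_within_002(self):
        params = mq.SynthParams(n_patches=20, n_frames=10, noise=False)
        series, truth = mq.generate_patchy_cortex(params, seed=12)
        for method in ("otsu", "li"):
            out = mq.patch_area_fraction(series, method=method, window=None)
            assert np.abs(out.fraction - truth.patch_fraction).max() < 0.02

    def test_single_stack_threshold(self):
        params = mq.SynthParams(n_patches=15, n_frames=8, noise=False)
        series, _ = mq.generate_patchy_cortex(params, seed=2)
        out = mq.patch_area_fraction(series, method="otsu", window=None)
        assert np.isscalar(out.threshold) or np.ndim(out.threshold) == 0

    def test_window_restricts_frames(self):
        params = mq.SynthParams(n_patches=10, n_frames=40, noise=False)
        series, _ = mq.generate_patchy_cortex(params, seed=4)
        out = mq.patch_area_fraction(series, method="otsu", window=(-360.0, 0.0))
        assert len(out.fraction) == 37  # frames at -360..0 s inclusive

    def test_fraction_recount_at_reported_threshold(self):
        """Per-frame fractions are exactly the strict-exceedance counts."""
        params = mq.SynthParams(n_patches=15, n_frames=6, noise=False)
        series, _ = mq.generate_patchy_cortex(params, seed=7)
        out = mq.patch_area_fraction(series, method="li", window=None)
        for frame, frac in zip(series.frames, out.fraction):
            assert frac == (frame > out.threshold).mean()
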