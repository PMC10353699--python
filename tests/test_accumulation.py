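"""Concentration profiles, smoothing and swarm-area metrics."""

import numpy as np
import pytest

from ptep import (
    ConcentrationProfile,
    ImageStack,
    accumulation_area,
    accumulation_speed,
    binarize_frame,
    concentration_profiles,
    make_filter_windows,
    moving_average,
    normalize_stack,
    rlowess_smooth,
)


def _stack(frames, fps=28.0):
    return ImageStack(np.asarray(frames, dtype=float), frame_rate=fps,
                      pixel_size_um=0.89)


def _profile(values, fps=28.0):
    values = np.asarray(values, dtype=float)
    times = np.arange(len(values)) / fps
    return ConcentrationProfile(values=values, times_s=times, frame_rate=fps)


class TestNormalizeStack:
    def test_already_uniform_stack_unchanged(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(40, 230, size=(24, 24))
        stack = _stack([base] * 6)
        out = normalize_stack(stack)
        assert np.abs(out.frames - stack.frames).max() <= 1.0

    def test_offset_drift_removed(self):
        rng = np.random.default_rng(1)
        base = rng.uniform(40, 230, size=(32, 32))
        drifting = [np.clip(base + 3.0 * k, 0, 255) for k in range(8)]
        out = normalize_stack(_stack(drifting))
        means = out.frames.mean(axis=(1, 2))
        assert np.ptp(means) < 1.0

    def test_flicker_leaves_small_discontinuity(self):
        rng = np.random.default_rng(2)
        base = rng.uniform(40, 220, size=(32, 32))
        frames = [base.copy() for _ in range(6)]
        frames[3] = np.clip(base * 1.1, 0, 255)
        out = normalize_stack(_stack(frames))
        grid = make_filter_windows((16, 16), (32, 32), grid_n=2, window_px=8,
                                   offset_px=0, side="below")
        prof = concentration_profiles(out, grid)
        jumps = np.abs(np.diff(prof.values, axis=0))
        assert jumps.max() < 2.0

    def test_constant_frame_flagged_passed_through(self):
        frames = [np.full((16, 16), 128.0)] * 3
        with pytest.warns(UserWarning):
            out = normalize_stack(_stack(frames))
        assert np.allclose(out.frames, 128.0)


class TestFilterWindows:
    def test_centered_tip_sixteen_disjoint_windows(self):
        grid = make_filter_windows((100.0, 100.0), (200, 200))
        assert grid.n_windows == 16
        pixels = set()
        for w in range(16):
            rows, cols = grid.window_pixels(w)
            for r in range(rows.start, rows.stop):
                for c in range(cols.start, cols.stop):
                    pixels.add((r, c))
        assert len(pixels) == 16 * 100  # disjoint 10×10 windows

    def test_block_is_contiguous_40px_square(self):
        grid = make_filter_windows((100.0, 100.0), (200, 200))
        r0, c0 = grid.anchor
        rows = [r for w in range(16) for r in [grid.rects[w][0]]]
        assert min(rows) == r0 and max(rows) == r0 + 30

    def test_tip_near_edge_raises(self):
        with pytest.raises(ValueError):
            make_filter_windows((195.0, 100.0), (200, 200))
        with pytest.raises(ValueError):
            make_filter_windows((100.0, 5.0), (200, 200))

    def test_nearest_windows_face_the_tip(self):
        grid = make_filter_windows((100.0, 100.0), (200, 200), offset_px=2)
        near = grid.nearest_to_tip(4)
        centers = grid.window_centers()[near]
        assert np.all(centers[:, 0] == centers[0, 0])  # first column


class TestConcentration:
    def test_extremes(self):
        white = _stack([np.full((60, 60), 255.0)])
        black = _stack([np.zeros((60, 60))])
        grid = make_filter_windows((30.0, 30.0), (60, 60), grid_n=2,
                                   window_px=5, offset_px=0)
        assert np.allclose(concentration_profiles(white, grid).values, 0.0)
        assert np.allclose(concentration_profiles(black, grid).values, 255.0)

    def test_invariant_to_window_pixel_permutation(self):
        rng = np.random.default_rng(3)
        frame = rng.uniform(0, 255, size=(60, 60))
        grid = make_filter_windows((12.0, 30.0), (60, 60))
        base = concentration_profiles(_stack([frame]), grid).values
        shuffled = frame.copy()
        rows, cols = grid.window_pixels(0)
        block = shuffled[rows, cols].ravel()
        rng.shuffle(block)
        shuffled[rows, cols] = block.reshape(10, 10)
        after = concentration_profiles(_stack([shuffled]), grid).values
        assert np.allclose(base, after)

    def test_tip_windows_nondecreasing_during_accumulation(self,
                                                           accumulation_run):
        truth, stack, scene = accumulation_run
        norm = normalize_stack(stack)
        grid = make_filter_windows(scene.fiber_tip_px, stack.shape)
        prof = concentration_profiles(norm, grid)
        smooth = moving_average(prof, 29)
        near = grid.nearest_to_tip(2)
        c = smooth.values[:, near].mean(axis=1)
        peak = int(np.argmax(c))
        drops = np.diff(c[: peak + 1])
        assert c[peak] > c[0] + 10
        assert drops.min() > -2.0  # monotone rise up to saturation, small jitter


class TestSmoothers:
    def test_moving_average_preserves_constants(self):
        prof = _profile(np.full(400, 7.0))
        out = moving_average(prof, 300)
        assert np.allclose(out.values, 7.0)

    def test_default_windows_match_printed_durations(self):
        # 300 frames at 28 fps = 10.7 s; 200 frames at 28 fps = 7.1 s
        assert round(300 / 28.0, 1) == 10.7
        assert round(200 / 28.0, 1) == 7.1

    def test_impulse_becomes_box_of_height_inverse_window(self):
        x = np.zeros(901)
        x[450] = 1.0
        out = moving_average(_profile(x), 300).values[:, 0]
        inside = out[(np.arange(901) > 450 - 150) & (np.arange(901) < 450 + 149)]
        assert np.allclose(inside, 1.0 / 300)

    def test_rlowess_reproduces_quadratic_exactly(self):
        t = np.arange(260, dtype=float)
        y = 0.002 * t ** 2 - 0.3 * t + 40.0
        out = rlowess_smooth(_profile(y), 200).values[:, 0]
        assert np.abs(out - y).max() <= 1e-6

    def test_rlowess_rejects_outlier_spikes(self):
        rng = np.random.default_rng(4)
        t = np.arange(300, dtype=float)
        clean = 30.0 + 0.2 * t
        spiky = clean.copy()
        idx = rng.choice(300, size=3, replace=False)
        spiky[idx] += 120.0
        smooth_clean = rlowess_smooth(_profile(clean), 60).values[:, 0]
        smooth_spiky = rlowess_smooth(_profile(spiky), 60).values[:, 0]
        assert np.abs(smooth_spiky - smooth_clean).max() <= 2.0

    def test_smoothers_commute_with_intensity_offset(self):
        rng = np.random.default_rng(5)
        y = rng.uniform(10, 40, size=240)
        for smoother, kw in ((moving_average, dict(window_frames=60)),
                             (rlowess_smooth, dict(window_frames=60))):
            a = smoother(_profile(y + 25.0), **kw).values
            b = smoother(_profile(y), **kw).values + 25.0
            assert np.abs(a - b).max() < 1e-8

    def test_rlowess_agrees_with_reference_lowess_on_smooth_data(self):
        """Cross-check against the established locally weighted regression
        implementation on slowly varying noiseless data."""
        import statsmodels.api as sm

        t = np.arange(280, dtype=float)
        y = 50.0 + 30.0 * np.sin(t / 90.0)
        ours = rlowess_smooth(_profile(y), 70).values[:, 0]
        ref = sm.nonparametric.lowess(y, t, frac=70 / 280.0,
                                      return_sorted=False)
        interior = slice(40, 240)
        assert np.abs(ours[interior] - ref[interior]).max() < 0.5

    def test_window_longer_than_series_rejected(self):
        with pytest.raises(ValueError):
            moving_average(_profile(np.zeros(100)), 101)
        with pytest.raises(ValueError):
            rlowess_smooth(_profile(np.zeros(100)), 101)


class TestAccumulationSpeed:
    def test_constant_profile_zero_slope(self):
        assert accumulation_speed(_profile(np.full(400, 12.0)),
                                  0.0, 10.0) == pytest.approx(0.0)

    def test_exact_ramp_slope(self):
        fps = 28.0
        t = np.arange(400) / fps
        prof = _profile(2.0 * t)
        assert accumulation_speed(prof, 0.0, 10.0) == pytest.approx(2.0)

    def test_monotone_in_attraction_strength(self):
        from ptep.scenarios import accumulation_scenario

        speeds = []
        for k in (0.4e-6, 0.8e-6):
            _, stack, scene = accumulation_scenario(
                seed=33, attraction_per_mv=k, n_particles=90,
                duration_s=11.0)
            norm = normalize_stack(stack)
            grid = make_filter_windows(scene.fiber_tip_px, stack.shape)
            prof = concentration_profiles(norm, grid)
            smooth = rlowess_smooth(prof.slice(0.0, 10.0), 60)
            speeds.append(accumulation_speed(smooth, 0.0, 10.0))
        assert speeds[1] > speeds[0]

    def test_insufficient_span_rejected(self):
        with pytest.raises(ValueError):
            accumulation_speed(_profile(np.zeros(100)), 0.0, 10.0)


class TestBinarizeAndArea:
    def test_bimodal_frame_both_methods_agree(self):
        rng = np.random.default_rng(6)
        frame = np.where(rng.random((50, 50)) < 0.3, 50.0, 220.0)
        dark = frame == 50.0
        assert np.array_equal(binarize_frame(frame, "otsu"), dark)
        assert np.array_equal(binarize_frame(frame, "fixed", 128.0), dark)

    def test_all_white_no_foreground(self):
        frame = np.full((30, 30), 255.0)
        assert binarize_frame(frame, "otsu").sum() == 0
        with pytest.raises(ValueError):
            binarize_frame(frame, "fixed")

    def test_rendered_swarm_area_near_occlusion_oracle(self,
                                                       accumulation_run):
        truth, stack, scene = accumulation_run
        # oracle: pixels covered by captured particles in the final frame
        captured = truth.positions_um[-1][truth.captured[-1]]
        px = scene.um_to_px(captured)
        r_px = 1.0 / scene.pixel_size_um
        h, w = scene.image_shape
        yy, xx = np.mgrid[0:h, 0:w]
        occluded = np.zeros((h, w), dtype=bool)
        depth = np.zeros((h, w), dtype=int)
        for cx, cy in px:
            depth += np.hypot(xx - cx, yy - cy) <= r_px
        occluded = depth >= 2  # two stacked cells render darker than one
        binary = binarize_frame(normalize_stack(stack).frames[-1],
                                "fixed", 128.0)
        roi = (60, 140, 90, 170)
        count = binary[roi[0]:roi[1], roi[2]:roi[3]].sum()
        oracle = occluded[roi[0]:roi[1], roi[2]:roi[3]].sum()
        assert oracle > 0
        assert abs(count - oracle) / oracle <= 0.35

    def test_area_arithmetic(self):
        binary = np.zeros((50, 50), dtype=bool)
        binary[10:20, 10:20] = True  # 100 dark px
        area = accumulation_area(binary, (0, 50, 0, 50), 0.89)
        assert area == pytest.approx(100 * 0.7921)

    def test_empty_roi_zero(self):
        binary = np.zeros((20, 20), dtype=bool)
        assert accumulation_area(binary, (0, 10, 0, 10), 0.89) == 0.0

    def test_fiber_mask_excluded(self):
        binary = np.ones((20, 20), dtype=bool)
        fiber = np.zeros((20, 20), dtype=bool)
        fiber[:, :10] = True
        area = accumulation_area(binary, (0, 20, 0, 20), 1.0,
                                 fiber_mask=fiber)
        assert area == pytest.approx(200.0)

    def test_roi_outside_frame_rejected(self):
        with pytest.raises(ValueError):
            accumulation_area(np.zeros((10, 10), bool), (0, 11, 0, 5), 1.0)
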