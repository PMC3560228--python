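import numpy as np
import pytest

from microcirc import exceptions as exc
from microcirc.preprocess import (DEFAULT_QUANTILES, LevelEntry, LevelSchedule,
                                  adaptive_quantiles, adjust, build_schedule,
                                  clahe, median_smooth, preprocess_level,
                                  sliding_mean_frames, training_schedule,
                                  vessel_fraction_estimate, weighted_mean)


class TestWeightedMean:
    def test_identical_frames_unchanged(self, rng):
        f = rng.random((8, 8))
        out = weighted_mean([f] * 5, [1, 5, 2, 7, 1])
        np.testing.assert_allclose(out, f)

    def test_arithmetic_on_single_pixel(self):
        frames = [np.full((2, 2), v) for v in (0, 0, 1, 0, 0)]
        out = weighted_mean(frames, [1, 2, 3, 2, 1])
        np.testing.assert_allclose(out, 3 / 9)

    def test_selector_weights_return_middle_frame(self, rng):
        frames = [rng.random((6, 6)) for _ in range(5)]
        out = weighted_mean(frames, [0, 0, 1, 0, 0])
        np.testing.assert_array_equal(out, frames[2])

    def test_shape_mismatch_rejected(self):
        frames = [np.zeros((4, 4))] * 4 + [np.zeros((5, 5))]
        with pytest.raises(exc.ShapeError):
            weighted_mean(frames)

    def test_wrong_count_rejected(self):
        with pytest.raises(exc.ParameterError):
            weighted_mean([np.zeros((4, 4))] * 4)


class TestClahe:
    def test_constant_frame_unchanged(self):
        f = np.full((32, 32), 0.4)
        np.testing.assert_array_equal(clahe(f, 8), f)

    def test_checkerboard_contrast_not_decreased(self):
        f = np.indices((32, 32)).sum(axis=0) % 2 * 0.2 + 0.4
        out = clahe(f, 8)
        assert out.max() - out.min() >= 0.2 - 1e-9

    def test_vessel_background_separation_increases(self):
        # low-contrast band phantom: CLAHE must widen the mean gap
        rng = np.random.default_rng(0)
        f = np.full((64, 64), 0.62) + rng.normal(0, 0.005, (64, 64))
        band = np.zeros((64, 64), dtype=bool)
        band[30:34] = True
        f[band] -= 0.05
        f = np.clip(f, 0, 1)
        out = clahe(f, 16)
        gap_before = f[~band].mean() - f[band].mean()
        gap_after = out[~band].mean() - out[band].mean()
        assert gap_after > gap_before

    def test_tile_larger_than_frame_rejected(self):
        with pytest.raises(exc.ParameterError):
            clahe(np.zeros((16, 16)), 32)


class TestMedianSmooth:
    def test_k1_is_identity(self, rng):
        f = rng.random((10, 10))
        np.testing.assert_array_equal(median_smooth(f, 1), f)

    def test_salt_pixel_removed(self):
        f = np.full((9, 9), 0.5)
        f[4, 4] = 1.0
        np.testing.assert_allclose(median_smooth(f, 3), 0.5)

    def test_matches_bruteforce_window_median(self, rng):
        f = rng.random((15, 15))
        out = median_smooth(f, 5)
        padded = np.pad(f, 2, mode="edge")
        for r in range(15):
            for c in range(15):
                expected = np.median(padded[r:r + 5, c:c + 5])
                assert out[r, c] == pytest.approx(expected)

    def test_even_kernel_rejected(self):
        with pytest.raises(exc.ParameterError):
            median_smooth(np.zeros((5, 5)), 4)


class TestAdjust:
    def test_full_range_frame_nearly_unchanged(self, rng):
        f = rng.random((50, 50))
        out = adjust(f)
        # only the clipped tails move appreciably
        mid = (f > np.percentile(f, 2)) & (f < np.percentile(f, 98))
        np.testing.assert_allclose(out[mid], (f[mid] - np.percentile(f, 1)) /
                                   (np.percentile(f, 99) - np.percentile(f, 1)),
                                   atol=1e-12)

    def test_affine_invariance(self, rng):
        f = rng.random((30, 30))
        np.testing.assert_allclose(adjust(0.5 * f + 0.2), adjust(f), atol=1e-12)

    def test_ramp_stretched_to_unit_range(self):
        f = np.tile(np.linspace(0.2, 0.6, 200), (20, 1))
        out = adjust(f)
        assert out.min() == 0.0 and out.max() == 1.0
        # interior stays linear
        assert np.all(np.diff(out[0, 3:-3]) >= 0)

    def test_constant_frame_warns_and_passes_through(self):
        f = np.full((8, 8), 0.3)
        with pytest.warns(UserWarning):
            out = adjust(f)
        np.testing.assert_array_equal(out, f)


class TestBuildSchedule:
    def test_uniform_histogram_gives_quantile_thresholds(self):
        # a ramp already spanning [0,1]: quantile q sits at intensity q
        f = np.tile(np.linspace(0, 1, 1000), (30, 1))
        sched = build_schedule(f)
        th = [e.threshold_value for e in sched]
        np.testing.assert_allclose(th, DEFAULT_QUANTILES, atol=0.02)

    def test_ten_entries_with_monotone_parameters(self, rng):
        sched = build_schedule(rng.random((40, 40)))
        assert len(sched) == 10
        th = [e.threshold_value for e in sched]
        assert all(b > a for a, b in zip(th, th[1:]))
        tiles = [e.clahe_tile for e in sched]
        kernels = [e.median_kernel for e in sched]
        assert all(b >= a for a, b in zip(tiles, tiles[1:]))
        assert all(b <= a for a, b in zip(kernels, kernels[1:]))

    def test_bimodal_frame_low_thresholds_between_modes(self, rng):
        # 12% vessel at 0.4, background at 0.8 (after adjust the modes
        # map near 0 and 1): the lowest thresholds must fall between
        f = np.full((100, 100), 0.8) + rng.normal(0, 0.01, (100, 100))
        f[:12, :] = 0.4 + rng.normal(0, 0.01, (12, 100))
        sched = build_schedule(np.clip(f, 0, 1))
        adjusted_vessel_mode = 0.0  # maps to bottom after stretch
        assert adjusted_vessel_mode < sched.entries[0].threshold_value < 0.9

    def test_constant_input_degenerate(self):
        with pytest.raises(exc.DegenerateHistogramError):
            build_schedule(np.full((20, 20), 0.5))


class TestLevelSchedule:
    def _entries(self, **over):
        kw = dict(tiles=[8] * 10, kernels=[7] * 10, th=np.linspace(.1, .55, 10))
        kw.update(over)
        return [LevelEntry(i + 1, float(kw["th"][i]), kw["tiles"][i], 0.01,
                           kw["kernels"][i]) for i in range(10)]

    def test_wrong_length_rejected(self):
        with pytest.raises(exc.ParameterError):
            LevelSchedule(self._entries()[:9])

    def test_decreasing_tiles_rejected(self):
        tiles = [8] * 9 + [4]
        with pytest.raises(exc.ParameterError):
            LevelSchedule(self._entries(tiles=tiles))

    def test_increasing_kernels_rejected(self):
        kernels = [3] * 9 + [5]
        with pytest.raises(exc.ParameterError):
            LevelSchedule(self._entries(kernels=kernels))


class TestTrainingSchedule:
    def test_adaptive_quantiles_scale_with_vessel_fraction(self):
        q = adaptive_quantiles(0.15)
        assert q.shape == (10,)
        assert q[0] == pytest.approx(0.045)
        assert q[-1] == pytest.approx(0.225)
        assert np.all(np.diff(q) > 0)

    def test_vessel_fraction_estimate_on_known_mixture(self, rng):
        f = np.full((100, 100), 0.8) + rng.normal(0, 0.01, (100, 100))
        f[:15, :] = 0.5
        frac = vessel_fraction_estimate(np.clip(f, 0, 1))
        assert 0.10 <= frac <= 0.25

    def test_levels_binarize_about_their_quantile(self, small_phantom):
        import warnings

        _, video, _ = small_phantom
        mfs = sliding_mean_frames(video.frames, 8)
        sched = training_schedule(np.stack(mfs))
        q = adaptive_quantiles(vessel_fraction_estimate(np.stack(mfs)))
        for entry, qk in zip(sched, q):
            e = clahe(mfs[4], entry.clahe_tile, entry.clahe_clip)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pre = adjust(median_smooth(e, entry.median_kernel))
            fg = (pre <= entry.threshold_value).mean()
            assert abs(fg - qk) < 0.08

    def test_constant_frames_degenerate(self):
        with pytest.raises(exc.DegenerateHistogramError):
            training_schedule(np.full((3, 40, 40), 0.5))


class TestPreprocessLevel:
    def test_deterministic_and_bounded(self, small_phantom, rng):
        _, video, _ = small_phantom
        f = video.frames[0]
        sched = training_schedule(video.frames[:4])
        for entry in sched:
            a = preprocess_level(f, entry)
            b = preprocess_level(f, entry)
            np.testing.assert_array_equal(a, b)
            assert a.min() >= 0.0 and a.max() <= 1.0


class TestSlidingMeanFrames:
    def test_one_mean_frame_per_position_clamped_at_ends(self, rng):
        frames = rng.random((6, 8, 8))
        out = sliding_mean_frames(frames, 6)
        assert len(out) == 6
        # first window clamps indices (0,0,0,1,2) with weights 1,2,3,2,1
        expected = (frames[0] * 6 + frames[1] * 2 + frames[2] * 1) / 9
        np.testing.assert_allclose(out[0], expected)
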