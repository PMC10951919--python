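import numpy as np
import pytest

from cryosr.fourier import fourier_shift
from cryosr.mrcio import MovieStack
from cryosr.preprocess import (build_lr_inputs, downsample, estimate_shift,
                               moving_average, radial_power_spectrum,
                               shift_image, split_exposure)

from conftest import make_movie


class TestEstimateShift:
    def test_self_alignment_is_zero(self, clean_lr_frame):
        assert estimate_shift(clean_lr_frame, clean_lr_frame) == (0.0, 0.0)

    def test_integer_circular_shift_exact(self, clean_lr_frame):
        moved = np.roll(np.roll(clean_lr_frame, 3, axis=0), -2, axis=1)
        dy, dx = estimate_shift(moved, clean_lr_frame)
        # brute-force argmax over all integer circular shifts agrees
        corr = np.fft.ifft2(np.fft.fft2(clean_lr_frame)
                            * np.conj(np.fft.fft2(moved))).real
        iy, ix = np.unravel_index(np.argmax(corr), corr.shape)
        h, w = corr.shape
        brute = ((iy + h // 2) % h - h // 2, (ix + w // 2) % w - w // 2)
        assert (dy, dx) == (-3.0, 2.0) == brute

    def test_subpixel_recovery_noiseless(self, clean_lr_frame):
        moved = fourier_shift(clean_lr_frame, 0.4, -0.7)
        dy, dx = estimate_shift(moved, clean_lr_frame)
        assert abs(dy + 0.4) < 0.1
        assert abs(dx - 0.7) < 0.1

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            estimate_shift(np.ones((8, 8)), np.ones((8, 8)))

    def test_shift_then_estimate_round_trip(self, clean_lr_frame, rng):
        for _ in range(5):
            dy, dx = rng.uniform(-2, 2, 2)
            moved = fourier_shift(clean_lr_frame, dy, dx)
            ey, ex = estimate_shift(moved, clean_lr_frame)
            realigned = shift_image(moved, ey, ex)
            resid = realigned - clean_lr_frame
            assert resid.std() < 0.05 * clean_lr_frame.std()


class TestMovingAverage:
    def test_constant_frames(self):
        stack = MovieStack(np.full((4, 16, 16), 7.0), 1.0)
        np.testing.assert_array_equal(moving_average(stack, 0, 3, 1),
                                      np.full((16, 16), 7.0))

    def test_zero_motion_equals_plain_mean(self):
        gt = make_movie(seed=2, noise_sigma=0.0, motion_sigma=0.0,
                        n_frames=8, hr=128)
        avg = moving_average(gt.movie, 1, 6, 3)
        plain = gt.movie.frames[1:7].mean(axis=0)
        rel = np.abs(avg - plain).max() / np.abs(plain).max()
        assert rel <= 1e-6

    def test_known_motion_matches_true_shift_alignment(self):
        gt = make_movie(seed=4, noise_sigma=0.0, motion_sigma=0.8,
                        n_frames=8, hr=128)
        r = 3
        avg = moving_average(gt.movie, 0, 7, r)
        # oracle: align with the simulator's true shifts (LR px = HR/2)
        lr_shifts = gt.true_shifts / 2.0
        oracle = np.mean([
            fourier_shift(f, lr_shifts[r, 0] - lr_shifts[i, 0],
                          lr_shifts[r, 1] - lr_shifts[i, 1])
            for i, f in enumerate(gt.movie.frames.astype(float))], axis=0)
        rms = np.sqrt(np.mean((avg - oracle) ** 2))
        assert rms <= 0.02 * np.sqrt(np.mean(oracle ** 2))

    def test_shift_equivariance(self):
        gt = make_movie(seed=5, noise_sigma=0.0, motion_sigma=0.5,
                        n_frames=4, hr=64)
        shifted = MovieStack(
            np.stack([fourier_shift(f, 2.0, -1.0)
                      for f in gt.movie.frames.astype(float)]),
            gt.movie.pixel_size)
        a = moving_average(gt.movie, 0, 3, 1)
        b = moving_average(shifted, 0, 3, 1)
        np.testing.assert_allclose(b, fourier_shift(a, 2.0, -1.0), atol=5e-3)

    def test_range_validation(self):
        stack = MovieStack(np.random.default_rng(0).normal(size=(4, 8, 8)), 1.0)
        with pytest.raises(ValueError):
            moving_average(stack, 2, 1, 2)
        with pytest.raises(ValueError):
            moving_average(stack, 0, 4, 1)


class TestSplitExposure:
    @pytest.mark.parametrize("m,early,late", [(50, 25, 25), (38, 19, 19),
                                              (7, 4, 3)])
    def test_split_sizes(self, m, early, late):
        stack = MovieStack(np.random.default_rng(m).normal(size=(m, 8, 8)),
                           1.5, exposure_per_frame=2.0)
        e, l = split_exposure(stack)
        assert (e.n_frames, l.n_frames) == (early, late)
        assert e.pixel_size == l.pixel_size == 1.5
        assert e.exposure_per_frame == l.exposure_per_frame == 2.0

    def test_partition_preserves_order_and_content(self):
        stack = MovieStack(np.arange(6 * 4 * 4, dtype=float).reshape(6, 4, 4),
                           1.0)
        e, l = split_exposure(stack)
        np.testing.assert_array_equal(
            np.concatenate([e.frames, l.frames]), stack.frames)


class TestBuildLrInputs:
    def test_references_distinct_and_in_range(self):
        gt = make_movie(seed=6, n_frames=8, hr=64)
        fas = build_lr_inputs(gt.movie, 4, seed=11)
        assert fas.k == 4
        assert len(set(fas.reference_indices)) == 4
        assert all(0 <= r < 8 for r in fas.reference_indices)
        assert list(fas.reference_indices) == sorted(fas.reference_indices)

    def test_k1_zero_motion_is_plain_mean(self):
        gt = make_movie(seed=6, noise_sigma=0.0, motion_sigma=0.0,
                        n_frames=4, hr=64)
        fas = build_lr_inputs(gt.movie, 1, seed=0)
        np.testing.assert_allclose(fas.averages[0],
                                   gt.movie.frames.mean(axis=0), atol=1e-6)

    def test_determinism(self):
        gt = make_movie(seed=6, n_frames=8, hr=64)
        a = build_lr_inputs(gt.movie, 3, seed=5)
        b = build_lr_inputs(gt.movie, 3, seed=5)
        assert a.reference_indices == b.reference_indices
        np.testing.assert_array_equal(a.averages, b.averages)

    def test_k_exceeding_frames(self):
        gt = make_movie(seed=6, n_frames=4, hr=64)
        with pytest.raises(ValueError):
            build_lr_inputs(gt.movie, 5, seed=0)


class TestDownsample:
    def test_constant_preserved(self):
        img = np.full((8, 8), 3.25)
        for method in ("fourier_crop", "binning"):
            out = downsample(img, 2, method)
            assert out.shape == (4, 4)
            np.testing.assert_allclose(out, 3.25, atol=1e-12)

    def test_binning_hand_computed(self):
        img = np.arange(16, dtype=float).reshape(4, 4)
        np.testing.assert_array_equal(downsample(img, 2, "binning"),
                                      [[2.5, 4.5], [10.5, 12.5]])

    def test_fourier_crop_preserves_mean(self, rng):
        img = rng.standard_normal((64, 64))
        out = downsample(img, 2, "fourier_crop")
        assert out.mean() == pytest.approx(img.mean(), abs=1e-12)

    def test_indivisible_dims_rejected(self):
        with pytest.raises(ValueError):
            downsample(np.zeros((9, 8)), 2)


class TestRadialPowerSpectrum:
    def test_constant_image_power_in_dc_bin(self):
        centers, prof = radial_power_spectrum(np.full((32, 32), 2.0), 8)
        assert prof[0] > 0
        np.testing.assert_array_equal(prof[1:], 0)

    def test_sinusoid_lands_in_its_bin(self):
        h = 64
        k0 = 0.25
        xx = np.arange(h)[None, :] * np.ones((h, 1))
        img = np.sin(2 * np.pi * k0 * xx)
        centers, prof = radial_power_spectrum(img, 16)
        dominant = np.argmax(prof[1:]) + 1
        width = centers[1] - centers[0]
        assert abs(centers[dominant] - k0) <= width / 2 + 1e-12

    def test_white_noise_is_flat(self):
        profs = []
        for seed in range(50):
            img = np.random.default_rng(seed).standard_normal((64, 64))
            _, p = radial_power_spectrum(img, 8)
            profs.append(p)
        mean_prof = np.mean(profs, axis=0)[1:]  # skip DC
        assert np.abs(mean_prof / mean_prof.mean() - 1).max() < 0.2
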