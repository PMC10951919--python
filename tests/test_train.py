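import numpy as np
import pytest

from cryosr.preprocess import build_lr_inputs, downsample, moving_average, \
    split_exposure
from cryosr.srnet import SRNetConfig
from cryosr.train import (TrainConfig, adapt_learning_rate, frequency_loss,
                          frequency_loss_grad, make_training_pair, total_loss,
                          train_movie)

from conftest import make_movie


def brute_force_frequency_loss(sr, target, sigma):
    """Independent oracle: explicit DFT sums, explicit per-coefficient
    (real, imaginary) Euclidean distances and Gaussian weights."""
    h, w = sr.shape
    total = 0.0
    for u in range(h):
        for v in range(w):
            fs = fi = gs = gi = 0.0
            for y in range(h):
                for x in range(w):
                    ang = -2 * np.pi * (u * y / h + v * x / w)
                    c, s = np.cos(ang), np.sin(ang)
                    fs += sr[y, x] * c
                    fi += sr[y, x] * s
                    gs += target[y, x] * c
                    gi += target[y, x] * s
            dist = np.sqrt((fs - gs) ** 2 + (fi - gi) ** 2)
            ku = u / h if u <= h // 2 else u / h - 1
            kv = v / w if v <= w // 2 else v / w - 1
            weight = np.exp(-(ku * ku + kv * kv) / (2 * sigma ** 2))
            total += weight * dist
    return total / (h * w)


class TestFrequencyLoss:
    def test_identity_is_zero(self, rng):
        x = rng.standard_normal((16, 16))
        assert frequency_loss(x, x, 0.125) == 0.0

    def test_matches_brute_force_dft(self, rng):
        for _ in range(5):
            a = rng.standard_normal((8, 8))
            b = rng.standard_normal((8, 8))
            got = frequency_loss(a, b, 0.2)
            want = brute_force_frequency_loss(a, b, 0.2)
            assert got == pytest.approx(want, rel=1e-10)

    def test_single_pixel_difference(self, rng):
        a = rng.standard_normal((8, 8))
        b = a.copy()
        b[2, 5] += 1.0
        assert frequency_loss(a, b, 0.15) == pytest.approx(
            brute_force_frequency_loss(a, b, 0.15), rel=1e-10)

    def test_monotone_in_sigma_for_highband_difference(self):
        """A difference confined above 0.25 cycles/px is down-weighted more
        by a narrower Gaussian."""
        h = 32
        xx = np.arange(h)[None, :] * np.ones((h, 1))
        a = np.zeros((h, h))
        b = 0.5 * np.sin(2 * np.pi * 0.4 * xx)  # pure 0.4 cycles/px
        losses = [frequency_loss(a, b, s) for s in (0.05, 0.125, 0.3)]
        assert losses[0] < losses[1] < losses[2]

    def test_gradient_matches_finite_differences(self, rng):
        x = rng.standard_normal((8, 8))
        t = rng.standard_normal((8, 8))
        g = frequency_loss_grad(x, t, 0.2)
        for (i, j) in [(0, 0), (3, 5), (7, 1)]:
            eps = 1e-6
            xp, xm = x.copy(), x.copy()
            xp[i, j] += eps
            xm[i, j] -= eps
            fd = (frequency_loss(xp, t, 0.2)
                  - frequency_loss(xm, t, 0.2)) / (2 * eps)
            assert g[i, j] == pytest.approx(fd, rel=1e-5)


class TestTotalLoss:
    def test_identity_is_zero(self, rng):
        x = rng.standard_normal((8, 8))
        assert total_loss(x, x) == 0.0

    def test_lambda_zero_is_mae(self, rng):
        a = rng.standard_normal((8, 8))
        b = rng.standard_normal((8, 8))
        assert total_loss(a, b, lam=0.0) == pytest.approx(
            np.mean(np.abs(a - b)), rel=1e-14)

    def test_flip_invariance(self, rng):
        a = rng.standard_normal((8, 8))
        b = rng.standard_normal((8, 8))
        assert total_loss(a[::-1, ::-1], b[::-1, ::-1]) == pytest.approx(
            total_loss(a, b), rel=1e-10)


class TestTrainingPair:
    def _inputs(self):
        gt = make_movie(seed=9, n_frames=8, hr=192)
        early, late = split_exposure(gt.movie)
        avgs = build_lr_inputs(late, 4, seed=1)
        hr = moving_average(early, 0, early.n_frames - 1, 1)
        return avgs, hr

    def test_dimension_contract(self):
        avgs, hr = self._inputs()
        cfg = TrainConfig(crop_hr=64, k=4)
        pair = make_training_pair(avgs, hr, cfg, np.random.default_rng(0))
        assert len(pair.lr_patches) == 4
        assert all(p.shape == (32, 32) for p in pair.lr_patches)
        assert pair.hr_patch.shape == (64, 64)

    def test_augmentation_is_involution(self):
        avgs, hr = self._inputs()
        cfg = TrainConfig(crop_hr=32, k=4)
        for s in range(6):
            pair = make_training_pair(avgs, hr, cfg,
                                      np.random.default_rng(s))
            y, x = pair.crop_origin
            fv, fh = pair.augmentation
            undone = pair.hr_patch
            if fh:
                undone = undone[:, ::-1]
            if fv:
                undone = undone[::-1]
            np.testing.assert_array_equal(undone, hr[y:y + 32, x:x + 32])

    def test_constant_average_gives_constant_lr(self):
        avgs, hr = self._inputs()
        avgs.averages[:] = 4.5
        cfg = TrainConfig(crop_hr=32, k=4)
        pair = make_training_pair(avgs, hr, cfg, np.random.default_rng(1))
        for p in pair.lr_patches:
            np.testing.assert_allclose(p, 4.5, atol=1e-10)

    def test_crop_larger_than_image_rejected(self):
        avgs, hr = self._inputs()
        cfg = TrainConfig(crop_hr=256, k=4)
        with pytest.raises(ValueError, match="crop"):
            make_training_pair(avgs, hr, cfg, np.random.default_rng(0))


class TestAdaptLearningRate:
    CFG = TrainConfig()

    def test_steep_decrease_keeps_lr(self):
        hist = list(np.linspace(10, 1, 30))  # slope >> residual noise
        lr, stop = adapt_learning_rate(hist, 1e-3, self.CFG)
        assert lr == 1e-3 and not stop

    def test_constant_history_decays(self):
        lr, stop = adapt_learning_rate([5.0] * 30, 1e-3, self.CFG)
        assert lr == pytest.approx(1e-4)
        assert not stop

    def test_at_most_three_decays_to_floor(self):
        lr = 1e-3
        decays = 0
        for _ in range(10):
            lr, stop = adapt_learning_rate([1.0] * 30, lr, self.CFG)
            decays += 1
            if stop:
                break
        assert decays == 3  # 1e-3 -> 1e-4 -> 1e-5 -> 1e-6 (floor)
        assert lr == pytest.approx(1e-6)

    def test_empty_history_rejected(self):
        with pytest.raises(ValueError):
            adapt_learning_rate([], 1e-3, self.CFG)


class TestTrainMovie:
    TRAIN = TrainConfig(max_iterations=45, crop_hr=32, k=3, seed=0,
                        plateau_window=15)
    NET = SRNetConfig(n_channels=8, n_encoder_layers=1, seed=0)

    def test_loss_decreases(self):
        gt = make_movie(seed=11, n_frames=16, hr=128, noise_sigma=2.0)
        res = train_movie(gt.movie, self.TRAIN, self.NET)
        losses = [h["total"] for h in res.loss_history]
        assert np.mean(losses[-10:]) < np.mean(losses[:10])

    def test_deterministic(self):
        gt = make_movie(seed=11, n_frames=16, hr=128, noise_sigma=2.0)
        a = train_movie(gt.movie, self.TRAIN, self.NET)
        b = train_movie(gt.movie, self.TRAIN, self.NET)
        assert [h["total"] for h in a.loss_history] == \
               [h["total"] for h in b.loss_history]
        for k in a.net.params:
            np.testing.assert_array_equal(a.net.params[k], b.net.params[k])

    def test_iteration_cap(self):
        gt = make_movie(seed=11, n_frames=8, hr=64, noise_sigma=2.0)
        cfg = TrainConfig(max_iterations=12, crop_hr=16, k=2, seed=0,
                          plateau_window=50)
        res = train_movie(gt.movie, cfg, self.NET)
        assert len(res.loss_history) <= 12

    def test_references_propagate_to_global_indices(self):
        gt = make_movie(seed=11, n_frames=16, hr=128, noise_sigma=2.0)
        res = train_movie(gt.movie, self.TRAIN, self.NET)
        offset = 8  # early half of a 16-frame movie
        assert res.global_references == tuple(offset + r
                                              for r in res.late_references)

    def test_degenerate_movie_rejected(self):
        from cryosr.mrcio import MovieStack
        stack = MovieStack(np.zeros((8, 32, 32)), 1.0)
        with pytest.raises(ValueError, match="degenerate"):
            train_movie(stack, self.TRAIN, self.NET)


def test_train_config_validation():
    with pytest.raises(ValueError):
        TrainConfig(lr_floor=1e-2)  # above lr_init
    with pytest.raises(ValueError):
        TrainConfig(crop_hr=33, s=2)
    with pytest.raises(ValueError):
        TrainConfig(freq_sigma=0.0)
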