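"""Zero-shot per-movie training.

Self-supervision exploits two internal statistics of dose-fractionated
movies: early-exposure frames carry more high-frequency signal than
late-exposure frames (radiation damage), and the field of view repeats the
same particle many times.  The pseudo high-resolution target is the aligned
average of the early half of the exposure; the inputs are K reference-
aligned averages of the late half, *further downsampled* by the upscale
factor s.  The network therefore learns, from this movie alone, the mapping
from coarse/damaged to fine/less-damaged — and is afterwards applied one
scale up, on the full-size all-frame averages.

The loss is the sum of a mean-absolute-error term and a Fourier-domain
frequency term: per Fourier coefficient, the Euclidean distance between the
(real, imaginary) vectors of prediction and target, down-weighted at high
frequency by a Gaussian kernel so that the noise-dominated band does not
drive the fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mrcio import MovieStack
from .nn_ops import Adam
from .preprocess import (FrameAverageSet, build_lr_inputs, downsample,
                         moving_average, split_exposure)
from .srnet import SRNet, SRNetConfig

__all__ = [
    "TrainConfig",
    "TrainingPair",
    "TrainResult",
    "make_training_pair",
    "frequency_loss",
    "frequency_loss_grad",
    "total_loss",
    "total_loss_grad",
    "adapt_learning_rate",
    "train_movie",
]

_EPS = 1e-12


@dataclass(frozen=True)
class TrainConfig:
    """Zero-shot training hyperparameters.

    lr_init : Adam learning rate at the start (0.001)
    lr_floor : training stops once the learning rate falls to this value
    lr_decay_factor : divisor applied when the loss plateaus
    max_iterations : hard cap on iterations
    crop_hr : side length of the pseudo-HR patch, px on the acquisition
        grid; must be divisible by s
    s : upscale factor
    freq_loss_weight : weight of the frequency term (1 = plain sum)
    freq_sigma : Gaussian reweighting width, cycles/px
    k : number of reference-aligned LR input averages
    plateau_window : iterations in the plateau detector's sliding window
    plateau_factor : slope-vs-noise ratio below which lr is decayed
    downsample_method : degradation used to build temporary LRs
    seed : reference selection, crop sampling and augmentation seed
    """

    lr_init: float = 1e-3
    lr_floor: float = 1e-6
    lr_decay_factor: float = 10.0
    max_iterations: int = 400
    crop_hr: int = 64
    s: int = 2
    freq_loss_weight: float = 1.0
    freq_sigma: float = 0.125
    k: int = 4
    plateau_window: int = 80
    plateau_factor: float = 0.3
    downsample_method: str = "fourier_crop"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.lr_floor < self.lr_init:
            raise ValueError("need 0 < lr_floor < lr_init")
        if self.crop_hr % self.s:
            raise ValueError("crop_hr must be divisible by s")
        if self.freq_loss_weight < 0 or self.freq_sigma <= 0:
            raise ValueError("freq_loss_weight >= 0 and freq_sigma > 0 required")
        if self.lr_decay_factor <= 1:
            raise ValueError("lr_decay_factor must exceed 1")


@dataclass
class TrainingPair:
    """One co-located pseudo HR-LR example.

    The K lr_patches are (crop_hr/s)^2 degraded crops; hr_patch is the
    crop_hr^2 pseudo-HR crop covering exactly their s-times footprint.
    """

    lr_patches: list
    hr_patch: np.ndarray
    crop_origin: tuple[int, int]
    augmentation: tuple[bool, bool]


def make_training_pair(lr_averages: FrameAverageSet, pseudo_hr: np.ndarray,
                       config: TrainConfig,
                       rng: np.random.Generator) -> TrainingPair:
    """Sample one crop, degrade the inputs, mirror-augment consistently."""
    pseudo_hr = np.asarray(pseudo_hr, dtype=np.float64)
    if lr_averages.averages.shape[1:] != pseudo_hr.shape:
        raise ValueError("averages and pseudo-HR must share dimensions")
    c = config.crop_hr
    h, w = pseudo_hr.shape
    if c > h or c > w:
        raise ValueError("crop larger than image")
    y = int(rng.integers(0, h - c + 1))
    x = int(rng.integers(0, w - c + 1))
    flip_v = bool(rng.integers(0, 2))
    flip_h = bool(rng.integers(0, 2))

    def _augment(img: np.ndarray) -> np.ndarray:
        if flip_v:
            img = img[::-1]
        if flip_h:
            img = img[:, ::-1]
        return np.ascontiguousarray(img)

    lr_patches = []
    for avg in lr_averages.averages:
        crop = np.asarray(avg, dtype=np.float64)[y:y + c, x:x + c]
        lr_patches.append(_augment(downsample(crop, config.s,
                                              config.downsample_method)))
    hr_patch = _augment(pseudo_hr[y:y + c, x:x + c])
    return TrainingPair(lr_patches, hr_patch, (y, x), (flip_v, flip_h))


def _gaussian_weights(shape: tuple[int, int], sigma: float) -> np.ndarray:
    fy = np.fft.fftfreq(shape[0])[:, None]
    fx = np.fft.fftfreq(shape[1])[None, :]
    k2 = fy * fy + fx * fx
    return np.exp(-k2 / (2.0 * sigma * sigma))


def frequency_loss(sr: np.ndarray, target: np.ndarray, sigma: float) -> float:
    """Gaussian-reweighted Fourier distance.

    Mean over coefficients of w(u,v) * ||(Re, Im) difference||_2 with
    w = exp(-|k|^2 / (2 sigma^2)), |k| in cycles/px (w = 1 at DC).
    """
    sr = np.asarray(sr, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if sr.shape != target.shape:
        raise ValueError("images must share dimensions")
    d = np.fft.fft2(sr) - np.fft.fft2(target)
    w = _gaussian_weights(sr.shape, sigma)
    return float(np.mean(w * np.abs(d)))


def frequency_loss_grad(sr: np.ndarray, target: np.ndarray,
                        sigma: float) -> np.ndarray:
    """d(frequency_loss)/d(sr), derived analytically.

    With D = F(sr) - F(target) and L = mean_k w_k |D_k|, the gradient is
    Re(F(w * conj(D) / |D|)) / n_coefficients (zero sub-gradient at
    D_k = 0).
    """
    sr = np.asarray(sr, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    d = np.fft.fft2(sr) - np.fft.fft2(target)
    w = _gaussian_weights(sr.shape, sigma)
    mag = np.abs(d)
    unit = np.where(mag > _EPS, np.conj(d) / np.maximum(mag, _EPS), 0.0)
    return np.fft.fft2(w * unit).real / d.size


def total_loss(sr: np.ndarray, target: np.ndarray, lam: float = 1.0,
               sigma: float = 0.125) -> float:
    """Mean absolute error plus lam times the weighted frequency loss."""
    sr = np.asarray(sr, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if sr.shape != target.shape:
        raise ValueError("images must share dimensions")
    mae = float(np.mean(np.abs(sr - target)))
    if lam == 0:
        return mae
    return mae + lam * frequency_loss(sr, target, sigma)


def total_loss_grad(sr: np.ndarray, target: np.ndarray, lam: float = 1.0,
                    sigma: float = 0.125) -> np.ndarray:
    g = np.sign(sr - target) / sr.size
    if lam != 0:
        g = g + lam * frequency_loss_grad(sr, target, sigma)
    return g


def adapt_learning_rate(loss_history, current_lr: float,
                        config: TrainConfig) -> tuple[float, bool]:
    """Plateau-triggered decay of the learning rate.

    Fits a line to the last ``plateau_window`` losses; when the projected
    decrease over the window (|slope| * window) does not exceed
    ``plateau_factor`` times the residual noise, the learning rate is
    divided by ``lr_decay_factor``.  Returns (new_lr, stop) where stop
    signals new_lr <= lr_floor.
    """
    hist = np.asarray(loss_history, dtype=np.float64)
    if hist.size == 0:
        raise ValueError("loss history is empty")
    win = min(config.plateau_window, hist.size)
    tail = hist[-win:]
    if win < 3:
        slope, resid_std = 0.0, 0.0
    else:
        t = np.arange(win, dtype=np.float64)
        coef = np.polyfit(t, tail, 1)
        slope = float(coef[0])
        resid_std = float(np.std(tail - np.polyval(coef, t)))
    new_lr = current_lr
    # tiny atol so an exactly constant history (slope and std both ~0
    # to rounding) still registers as a plateau
    if abs(slope) * win <= config.plateau_factor * resid_std + 1e-12:
        new_lr = current_lr / config.lr_decay_factor
    return new_lr, new_lr <= config.lr_floor * (1 + 1e-9)


@dataclass
class TrainResult:
    """Outcome of zero-shot training on one movie."""

    net: SRNet
    loss_history: list
    stop_iteration: int
    late_references: tuple[int, ...]
    global_references: tuple[int, ...]
    pseudo_hr: np.ndarray
    lr_averages: FrameAverageSet


def _standardize(img: np.ndarray, mu: float, sd: float) -> np.ndarray:
    return (img - mu) / sd


def train_movie(stack: MovieStack, train_config: TrainConfig,
                net_config: SRNetConfig) -> TrainResult:
    """Train a movie-specific network from the raw stack alone.

    Supervision never leaves the movie: the pseudo-HR target is the early
    half aligned to its centre frame, the inputs are K late-half averages.
    """
    if stack.n_frames < 4:
        raise ValueError("need at least 4 frames for exposure splitting")
    if float(np.std(stack.frames)) == 0:
        raise ValueError("degenerate (constant) movie")
    if train_config.s != net_config.upscale_factor:
        raise ValueError("train and network upscale factors disagree")

    early, late = split_exposure(stack)
    lr_avgs = build_lr_inputs(late, train_config.k, train_config.seed,
                              provenance="late")
    centre = (early.n_frames - 1) // 2
    pseudo_hr = moving_average(early, 0, early.n_frames - 1, centre)

    net = SRNet(net_config)
    net.trained_k = train_config.k
    opt = Adam(net.params, lr=train_config.lr_init)

    rng = np.random.default_rng(train_config.seed + 1)
    lam, sigma = train_config.freq_loss_weight, train_config.freq_sigma
    history: list[dict] = []
    lr = train_config.lr_init
    last_decay = 0
    stop_iter = train_config.max_iterations
    for it in range(train_config.max_iterations):
        pair = make_training_pair(lr_avgs, pseudo_hr, train_config, rng)
        mu = float(pair.hr_patch.mean())
        sd = max(float(pair.hr_patch.std()), 1e-8)
        lrs = [_standardize(p, mu, sd) for p in pair.lr_patches]
        hr = _standardize(pair.hr_patch, mu, sd)

        sr, tape = net.forward(lrs, return_tape=True)
        mae = float(np.mean(np.abs(sr - hr)))
        freq = frequency_loss(sr, hr, sigma) if lam else 0.0
        loss = mae + lam * freq
        grads = net.backward(total_loss_grad(sr, hr, lam, sigma), tape)
        opt.lr = lr
        opt.step(grads)
        history.append({"iteration": it, "lr": lr, "mae": mae,
                        "freq": freq, "total": loss})

        if it - last_decay >= train_config.plateau_window:
            new_lr, stop = adapt_learning_rate(
                [h["total"] for h in history], lr, train_config)
            if new_lr != lr:
                lr = new_lr
                last_decay = it
            if stop:
                stop_iter = it + 1
                break
    late_refs = lr_avgs.reference_indices
    global_refs = tuple(early.n_frames + r for r in late_refs)
    return TrainResult(net=net, loss_history=history, stop_iteration=stop_iter,
                       late_references=late_refs, global_references=global_refs,
                       pseudo_hr=pseudo_hr, lr_averages=lr_avgs)
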