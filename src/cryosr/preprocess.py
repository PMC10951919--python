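"""Frame alignment, exposure splitting and reference-aligned moving averages.

A movie's raw frames are far too noisy to super-resolve individually, so
the network's low-resolution inputs are *moving averages*: all frames in a
range aligned to a chosen reference frame and averaged.  Aligning the same
range to K different references yields K averages that differ by residual
sub-pixel motion — exactly the multi-image information the fusion network
exploits.  Alignment is global rigid translation by phase correlation with
sub-pixel refinement, accumulated against a running mean to stabilise
registration at per-frame SNR far below 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from skimage.registration import phase_cross_correlation

from .fourier import bin_downsample, fourier_crop, fourier_shift
from .mrcio import MovieStack

__all__ = [
    "FrameAverageSet",
    "estimate_shift",
    "shift_image",
    "moving_average",
    "split_exposure",
    "build_lr_inputs",
    "average_with_references",
    "downsample",
    "radial_power_spectrum",
]

shift_image = fourier_shift


@dataclass
class FrameAverageSet:
    """K reference-aligned averages of one frame range.

    averages : (K, H, W) array
    reference_indices : the K reference frame indices, relative to the
        stack the averages were built from
    frame_range : (m, n) inclusive range that was averaged
    provenance : which part of the exposure ("early" | "late" | "all")
    pixel_size : A/px, propagated from the source stack
    """

    averages: np.ndarray
    reference_indices: tuple[int, ...]
    frame_range: tuple[int, int]
    provenance: str
    pixel_size: float

    def __post_init__(self) -> None:
        self.averages = np.asarray(self.averages)
        if self.averages.ndim != 3 or self.averages.shape[0] < 1:
            raise ValueError("averages must be a non-empty (K, H, W) array")
        m, n = self.frame_range
        for r in self.reference_indices:
            if not m <= r <= n:
                raise ValueError("reference index outside averaged range")

    @property
    def k(self) -> int:
        return self.averages.shape[0]


def estimate_shift(moving: np.ndarray, reference: np.ndarray,
                   upsample_factor: int = 50,
                   lowpass_sigma: float = 0.1) -> tuple[float, float]:
    """Sub-pixel (dy, dx) such that shift_image(moving, dy, dx) aligns onto
    reference.

    Phase correlation on the unnormalised cross-power spectrum (a matched
    filter, which is what survives SNR << 1) with local upsampled-DFT
    refinement of the correlation peak.  Both images are first low-pass
    weighted by exp(-|k|^2 / (2 lowpass_sigma^2)) — cryo-EM signal
    concentrates at low frequency while the noise is white, so down-
    weighting the high band sharpens the correlation peak dramatically at
    low SNR (the B-factor weighting of standard motion-correction tools).
    Set lowpass_sigma to 0 to disable.
    """
    moving = np.asarray(moving, dtype=np.float64)
    reference = np.asarray(reference, dtype=np.float64)
    if moving.shape != reference.shape:
        raise ValueError("images must share dimensions")
    if moving.std() == 0 or reference.std() == 0:
        raise ValueError("constant image: correlation undefined")
    if lowpass_sigma and lowpass_sigma > 0:
        fy = np.fft.fftfreq(moving.shape[0])[:, None]
        fx = np.fft.fftfreq(moving.shape[1])[None, :]
        w = np.exp(-(fy * fy + fx * fx) / (2.0 * lowpass_sigma ** 2))
        moving = np.fft.ifft2(np.fft.fft2(moving) * w).real
        reference = np.fft.ifft2(np.fft.fft2(reference) * w).real
    shift, _, _ = phase_cross_correlation(
        reference, moving, upsample_factor=upsample_factor,
        normalization=None)
    return float(shift[0]), float(shift[1])


def split_exposure(stack: MovieStack) -> tuple[MovieStack, MovieStack]:
    """Split into early/late exposure halves; early gets the odd frame.

    Early frames carry more high-frequency signal (less radiation damage)
    and serve as the pseudo-high-resolution side of self-supervision, so
    ceil(M/2) frames go to the early half.
    """
    m = stack.n_frames
    if m < 2:
        raise ValueError("need at least 2 frames to split")
    cut = (m + 1) // 2
    return stack.subset(0, cut), stack.subset(cut, m)


def moving_average(stack: MovieStack, m: int, n: int, r: int) -> np.ndarray:
    """Align frames [m, n] to reference frame r and average.

    Frames are visited outward from r; each is registered against the
    running mean of the frames accumulated so far, which keeps the
    reference definition but stabilises registration of very noisy
    individual frames.
    """
    if not 0 <= m <= r <= n < stack.n_frames:
        raise ValueError("need 0 <= m <= r <= n < M")
    frames = stack.frames.astype(np.float64)
    order = sorted(range(m, n + 1), key=lambda i: (abs(i - r), i))
    acc = frames[order[0]].copy()
    count = 1
    for i in order[1:]:
        ref = acc / count
        if frames[i].std() == 0 or ref.std() == 0:
            aligned = frames[i]
        else:
            dy, dx = estimate_shift(frames[i], ref)
            aligned = shift_image(frames[i], dy, dx)
        acc += aligned
        count += 1
    return acc / count


def average_with_references(stack: MovieStack, references: Sequence[int],
                            provenance: str = "all") -> FrameAverageSet:
    """Full-range moving averages for each given reference index."""
    refs = tuple(int(r) for r in references)
    avgs = np.stack([moving_average(stack, 0, stack.n_frames - 1, r)
                     for r in refs])
    return FrameAverageSet(avgs, refs, (0, stack.n_frames - 1),
                           provenance, stack.pixel_size)


def build_lr_inputs(stack: MovieStack, k: int, seed: int,
                    provenance: str = "late") -> FrameAverageSet:
    """K full-range averages aligned to K distinct random reference frames.

    Reference indices are drawn uniformly without replacement (seeded) and
    the averages are ordered by reference index.
    """
    if k < 1 or k > stack.n_frames:
        raise ValueError("K must be in [1, frame count]")
    rng = np.random.default_rng(seed)
    refs = np.sort(rng.choice(stack.n_frames, size=k, replace=False))
    return average_with_references(stack, refs, provenance)


def downsample(image: np.ndarray, factor: int,
               method: Literal["fourier_crop", "binning"] = "fourier_crop"
               ) -> np.ndarray:
    """Integer-factor downsampling: ideal low-pass or block binning."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if method == "binning":
        return bin_downsample(image, factor)
    if method == "fourier_crop":
        return fourier_crop(image, factor)
    raise ValueError(f"unknown downsampling method {method!r}")


def radial_power_spectrum(image: np.ndarray, n_bins: int = 64
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Radially averaged periodogram up to Nyquist.

    Returns (bin_centers in cycles/px on [0, 0.5], mean |F|^2 per annulus).
    Frequencies beyond Nyquist (grid corners) are discarded.
    """
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    image = np.asarray(image, dtype=np.float64)
    power = np.abs(np.fft.fft2(image)) ** 2
    fy = np.fft.fftfreq(image.shape[0])[:, None]
    fx = np.fft.fftfreq(image.shape[1])[None, :]
    k = np.hypot(fy, fx)
    edges = np.linspace(0.0, 0.5, n_bins + 1)
    # put DC in its own first bin by nudging the first edge
    idx = np.clip(np.searchsorted(edges, k.ravel(), side="right") - 1,
                  0, n_bins - 1)
    keep = k.ravel() <= 0.5
    sums = np.bincount(idx[keep], weights=power.ravel()[keep],
                       minlength=n_bins)
    counts = np.bincount(idx[keep], minlength=n_bins)
    profile = np.divide(sums, counts, out=np.zeros(n_bins),
                        where=counts > 0)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, profile
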