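"""Shared frequency-domain primitives.

All shifts assume periodic boundaries (phase ramps); downsampling by
Fourier cropping is an ideal low-pass, so band-limits are exact — the same
operators are used by the simulator, the preprocessing stages and the
self-supervision degradation, which is what makes the internal-learning
assumption (training degradation == acquisition degradation) hold by
construction on synthetic data.
"""

from __future__ import annotations

import numpy as np
from skimage.transform import resize

__all__ = [
    "freq_grid_cpp",
    "fourier_shift",
    "fourier_crop",
    "bin_downsample",
    "bilinear_upsample",
]


def freq_grid_cpp(shape: tuple[int, int]) -> np.ndarray:
    """Magnitude of spatial frequency in cycles/pixel on the fft2 grid."""
    fy = np.fft.fftfreq(shape[0])[:, None]
    fx = np.fft.fftfreq(shape[1])[None, :]
    return np.hypot(fy, fx)


def fourier_shift(image: np.ndarray, dy: float, dx: float) -> np.ndarray:
    """Sub-pixel translation by a Fourier phase ramp (periodic boundary).

    Positive (dy, dx) moves content toward larger row/column indices.
    """
    image = np.asarray(image, dtype=np.float64)
    fy = np.fft.fftfreq(image.shape[0])[:, None]
    fx = np.fft.fftfreq(image.shape[1])[None, :]
    ramp = np.exp(-2j * np.pi * (fy * dy + fx * dx))
    return np.fft.ifft2(np.fft.fft2(image) * ramp).real


def fourier_crop(image: np.ndarray, factor: int) -> np.ndarray:
    """Downsample by retaining the central spectrum (ideal low-pass).

    The image mean is preserved exactly; all energy above the new Nyquist
    is removed.  Dimensions must be divisible by ``factor``.
    """
    image = np.asarray(image, dtype=np.float64)
    h, w = image.shape
    if factor == 1:
        return image.copy()
    if h % factor or w % factor:
        raise ValueError("dimensions must be divisible by the crop factor")
    nh, nw = h // factor, w // factor
    spec = np.fft.fftshift(np.fft.fft2(image))
    cy, cx = h // 2, w // 2
    crop = spec[cy - nh // 2: cy + (nh + 1) // 2,
                cx - nw // 2: cx + (nw + 1) // 2]
    out = np.fft.ifft2(np.fft.ifftshift(crop)).real / factor**2
    return out


def bin_downsample(image: np.ndarray, factor: int) -> np.ndarray:
    """Average ``factor`` x ``factor`` pixel blocks (detector-style binning)."""
    image = np.asarray(image, dtype=np.float64)
    h, w = image.shape
    if h % factor or w % factor:
        raise ValueError("dimensions must be divisible by the binning factor")
    return image.reshape(h // factor, factor, w // factor, factor).mean(axis=(1, 3))


def bilinear_upsample(image: np.ndarray, factor: int) -> np.ndarray:
    """Bilinear interpolation to ``factor`` x the input size."""
    image = np.asarray(image, dtype=np.float64)
    out_shape = (image.shape[0] * factor, image.shape[1] * factor)
    return resize(image, out_shape, order=1, mode="edge",
                  anti_aliasing=False, preserve_range=True)
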