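"""Synthetic dose-fractionated movie generator with known ground truth.

The forward model per frame i is

    f_i = D( CTF * E_i * T_i(x) ) + n_i

applied in the Fourier domain: ``x`` is a noise-free high-resolution scene
built from repeated copies of one particle template (mimicking the natural
repetition of identical projections across a micrograph), ``T_i`` a
sub-pixel drift (phase ramp), ``CTF`` the contrast transfer function of the
microscope optics, ``E_i`` a dose-dependent B-factor envelope standing in
for radiation damage, ``D`` integer-factor downsampling (Fourier crop by
default), and ``n_i`` additive Gaussian noise scaled so per-frame SNR is
far below 1.  Everything is reproducible from a single seed, and all
noise-free intermediates are retained so every downstream stage has an
oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fourier import bin_downsample, fourier_crop, fourier_shift, freq_grid_cpp
from .mrcio import MovieStack

__all__ = [
    "CTFParams",
    "SyntheticSpec",
    "SyntheticGroundTruth",
    "electron_wavelength",
    "ctf_evaluate",
    "damage_envelope",
    "synthesize_movie",
]


def electron_wavelength(voltage_kv: float) -> float:
    """Relativistic electron wavelength in Angstrom for voltage in kV."""
    if voltage_kv <= 0:
        raise ValueError("voltage must be positive")
    v = voltage_kv * 1e3
    return 12.2639 / np.sqrt(v * (1.0 + 0.97845e-6 * v))


@dataclass(frozen=True)
class CTFParams:
    """Microscope optics defining the oscillating frequency-domain blur.

    defocus : A, positive = underfocus
    voltage : accelerating voltage, kV
    cs : spherical aberration, mm
    amplitude_contrast : dimensionless fraction in [0, 1)
    phase_shift : additional phase, radians
    pixel_size : A/px of the grid the CTF is sampled on
    """

    defocus: float = 15000.0
    voltage: float = 300.0
    cs: float = 2.7
    amplitude_contrast: float = 0.07
    phase_shift: float = 0.0
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        if self.defocus <= 0:
            raise ValueError("defocus must be positive (underfocus)")
        if self.voltage <= 0:
            raise ValueError("voltage must be positive")
        if self.cs < 0:
            raise ValueError("cs must be non-negative")
        if not 0 <= self.amplitude_contrast < 1:
            raise ValueError("amplitude_contrast must lie in [0, 1)")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    def gamma(self, freq: np.ndarray) -> np.ndarray:
        """Aberration phase gamma(k) for spatial frequency k in 1/A."""
        lam = electron_wavelength(self.voltage)
        cs_a = self.cs * 1e7  # mm -> A
        k2 = np.square(freq)
        return (np.pi * lam * self.defocus * k2
                - 0.5 * np.pi * cs_a * lam**3 * k2 * k2
                + self.phase_shift)


def ctf_evaluate(params: CTFParams, freq: np.ndarray) -> np.ndarray:
    """CTF(k) = -sqrt(1-A^2) sin(gamma(k)) - A cos(gamma(k)), k in 1/A.

    Bounded in [-1, 1]; CTF(0) = -A.  Underfocus positive, single defocus
    (no astigmatism) — the common single-particle sign convention.
    """
    freq = np.asarray(freq, dtype=np.float64)
    if np.any(freq < 0):
        raise ValueError("spatial frequencies must be non-negative")
    a = params.amplitude_contrast
    g = params.gamma(freq)
    return -np.sqrt(1.0 - a * a) * np.sin(g) - a * np.cos(g)


def damage_envelope(cumulative_exposure, freq, beta: float):
    """Dose-dependent high-frequency attenuation, exp(-beta*d*k^2/4).

    A B-factor growing linearly with accumulated exposure ``d`` (e-/A^2);
    ``beta`` has units A^2 per (e-/A^2).  Equals 1 at d=0 or k=0 and decays
    monotonically in both arguments.
    """
    d = np.asarray(cumulative_exposure, dtype=np.float64)
    k = np.asarray(freq, dtype=np.float64)
    if np.any(d < 0) or np.any(k < 0) or beta < 0:
        raise ValueError("exposure, frequency and beta must be non-negative")
    return np.exp(-beta * d * np.square(k) / 4.0)


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic movie.

    hr_size is the ground-truth grid; frames come out at hr_size / D.
    ``noise_sigma`` is the per-frame noise std relative to the std of the
    noise-free frame signal (noise_sigma=4 gives per-frame SNR of power
    ~1/16).  ``motion_sigma`` is the random-walk step std in HR pixels.
    """

    hr_size: tuple[int, int] = (192, 192)
    downsample_factor: int = 2
    n_frames: int = 16
    n_particles: int = 40
    motion_sigma: float = 0.6
    ctf: CTFParams = field(default_factory=lambda: CTFParams(pixel_size=1.5))
    dose_per_frame: float = 2.0
    damage_coefficient: float = 8.0
    noise_sigma: float = 4.0
    seed: int = 0
    apply_ctf: bool = True
    downsample_method: str = "fourier_crop"  # or "binning"

    def __post_init__(self) -> None:
        h, w = self.hr_size
        d = self.downsample_factor
        if d < 1 or h % (2 * d) or w % (2 * d):
            raise ValueError("hr_size must be divisible by 2*downsample_factor")
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")
        if self.noise_sigma < 0 or self.motion_sigma < 0:
            raise ValueError("scales must be non-negative")
        if self.downsample_method not in ("fourier_crop", "binning"):
            raise ValueError("unknown downsample_method")


@dataclass
class SyntheticGroundTruth:
    """Noise-free intermediates kept alongside the observable movie.

    hr_image : the CTF-free, noise-free scene x
    hr_ctf_image : CTF-modulated noise-free scene — the recovery target of
        the super-resolution method (CTF modulation is *kept*, as the
        downstream single-particle pipeline expects it)
    true_shifts : (M, 2) per-frame cumulative (dy, dx) drift in HR pixels
    movie : the observable low-resolution, noisy MovieStack
    """

    hr_image: np.ndarray
    hr_ctf_image: np.ndarray
    true_shifts: np.ndarray
    movie: MovieStack
    spec: SyntheticSpec


def _particle_template(rng: np.random.Generator) -> list[tuple[float, float, float, float]]:
    """One blob-cluster template: (dy, dx, sigma, amplitude) Gaussians."""
    parts = []
    for _ in range(4):
        ang = rng.uniform(0, 2 * np.pi)
        rad = rng.uniform(0, 4.0)
        parts.append((rad * np.sin(ang), rad * np.cos(ang),
                      rng.uniform(1.2, 2.5), rng.uniform(0.6, 1.0)))
    return parts

def _render_scene(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    h, w = spec.hr_size
    yy = np.arange(h, dtype=np.float64)[:, None]
    xx = np.arange(w, dtype=np.float64)[None, :]
    scene = np.zeros((h, w))
    template = _particle_template(rng)
    margin = 8.0
    for _ in range(spec.n_particles):
        cy = rng.uniform(margin, h - margin)
        cx = rng.uniform(margin, w - margin)
        theta = rng.uniform(0, 2 * np.pi)
        c, s = np.cos(theta), np.sin(theta)
        for dy, dx, sig, amp in template:
            # rotate the template offsets -> random particle orientation
            ry = c * dy - s * dx
            rx = s * dy + c * dx
            scene += amp * np.exp(-((yy - cy - ry) ** 2 + (xx - cx - rx) ** 2)
                                  / (2 * sig * sig))
    # smooth large-scale background (ice-thickness style gradient)
    ky, kx = rng.uniform(-1, 1, 2)
    scene += 0.3 * np.cos(2 * np.pi * (ky * yy / h + kx * xx / w)
                          + rng.uniform(0, 2 * np.pi))
    return scene


def _downsample(image: np.ndarray, factor: int, method: str) -> np.ndarray:
    if method == "binning":
        return bin_downsample(image, factor)
    return fourier_crop(image, factor)


def synthesize_movie(spec: SyntheticSpec,
                     scene: np.ndarray | None = None) -> SyntheticGroundTruth:
    """Run the full forward model for one movie.

    ``scene`` overrides the rendered ground truth (used by linearity
    tests); it must match ``spec.hr_size``.  With ``noise_sigma=0``,
    ``damage_coefficient=0``, ``motion_sigma=0`` and ``apply_ctf=False``
    every frame equals the plain downsampling of the scene.
    """
    rng = np.random.default_rng(spec.seed)
    x = _render_scene(spec, rng) if scene is None else np.asarray(scene, float)
    if x.shape != tuple(spec.hr_size):
        raise ValueError("scene does not match hr_size")

    h, w = spec.hr_size
    freq = freq_grid_cpp((h, w)) / spec.ctf.pixel_size  # 1/A
    ctf = ctf_evaluate(spec.ctf, freq) if spec.apply_ctf else np.ones((h, w))

    x_f = np.fft.fft2(x)
    hr_ctf = np.fft.ifft2(x_f * ctf).real

    # random walk drift; drawn even when motion_sigma == 0 to keep the
    # noise stream independent of the motion setting
    steps = rng.normal(0.0, 1.0, size=(spec.n_frames, 2)) * spec.motion_sigma
    shifts = np.cumsum(steps, axis=0)
    shifts -= shifts[0]  # frame 0 defines the reference position

    dose_mid = (np.arange(spec.n_frames) + 0.5) * spec.dose_per_frame
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.fftfreq(w)[None, :]

    frames = np.empty((spec.n_frames, h // spec.downsample_factor,
                       w // spec.downsample_factor), dtype=np.float64)
    for i in range(spec.n_frames):
        env = damage_envelope(dose_mid[i], freq, spec.damage_coefficient)
        ramp = np.exp(-2j * np.pi * (fy * shifts[i, 0] + fx * shifts[i, 1]))
        clean_hr = np.fft.ifft2(x_f * ctf * env * ramp).real
        clean_lr = _downsample(clean_hr, spec.downsample_factor,
                               spec.downsample_method)
        sigma = spec.noise_sigma * clean_lr.std()
        frames[i] = clean_lr + rng.normal(0.0, 1.0, clean_lr.shape) * sigma

    movie = MovieStack(frames.astype(np.float32),
                       pixel_size=spec.ctf.pixel_size * spec.downsample_factor,
                       exposure_per_frame=spec.dose_per_frame)
    return SyntheticGroundTruth(hr_image=x, hr_ctf_image=hr_ctf,
                                true_shifts=shifts, movie=movie, spec=spec)
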