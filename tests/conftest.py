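import numpy as np
import pytest

from cryosr.simulate import CTFParams, SyntheticSpec, synthesize_movie


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def clean_lr_frame():
    """A realistic noise-free LR frame (192 px) used as registration content."""
    spec = SyntheticSpec(hr_size=(384, 384), n_particles=160,
                         noise_sigma=0.0, motion_sigma=0.0, seed=42,
                         ctf=CTFParams(pixel_size=1.5))
    return synthesize_movie(spec).movie.frames[0].astype(np.float64)


def make_movie(seed=0, noise_sigma=4.0, motion_sigma=0.6, n_frames=16,
               hr=192, beta=8.0, method="fourier_crop", apply_ctf=True,
               n_particles=40):
    spec = SyntheticSpec(hr_size=(hr, hr), downsample_factor=2,
                         n_frames=n_frames, n_particles=n_particles,
                         noise_sigma=noise_sigma, motion_sigma=motion_sigma,
                         damage_coefficient=beta, seed=seed,
                         downsample_method=method, apply_ctf=apply_ctf,
                         ctf=CTFParams(pixel_size=1.5))
    return synthesize_movie(spec)
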