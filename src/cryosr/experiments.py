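"""Reproducible synthetic end-to-end experiments.

One place defines the scaled-down zero-shot study: simulate a binned,
drifting, CTF-modulated, heavily noised movie; run the full per-movie
pipeline; score the super-resolved output against the CTF-modulated ground
truth and against bilinear upsampling of the aligned all-frame average.
Binning (rather than ideal Fourier cropping) is used as the acquisition
downsampling here because real binned movies alias super-Nyquist signal
into the low-resolution band — the physical channel multi-image
super-resolution exploits — and the self-supervision degradation is
matched to it.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .fourier import bilinear_upsample
from .infer import InferenceConfig, run_pipeline
from .metrics import compare_sr
from .simulate import CTFParams, SyntheticSpec, synthesize_movie
from .srnet import SRNetConfig
from .train import TrainConfig

__all__ = ["study_spec", "study_train_config", "study_net_config",
           "run_zero_shot_trial", "zero_shot_gain_experiment"]


def study_spec(seed: int) -> SyntheticSpec:
    """The canonical study conditions: 96x96 LR movies, 16 frames,
    per-frame SNR ~ 0.06, binned 2x from a 192x192 CTF-modulated scene."""
    return SyntheticSpec(hr_size=(192, 192), downsample_factor=2,
                         n_frames=16, noise_sigma=4.0, seed=seed,
                         downsample_method="binning",
                         ctf=CTFParams(defocus=15000.0, pixel_size=1.5))


def study_train_config(seed: int, max_iterations: int = 400) -> TrainConfig:
    return TrainConfig(max_iterations=max_iterations, crop_hr=64, k=4,
                       seed=seed, downsample_method="binning")


def study_net_config(seed: int) -> SRNetConfig:
    # reduced CPU budget: narrow net, single residual block
    return SRNetConfig(n_channels=16, n_encoder_layers=1, seed=seed)


def run_zero_shot_trial(seed: int, max_iterations: int = 400) -> dict:
    """Simulate one movie, run the pipeline, return the scorecard.

    The scorecard is compare_sr() of the SR output and of the bilinear
    baseline (upsampled aligned all-frame average) against the
    CTF-modulated noise-free scene, plus bookkeeping fields.
    """
    gt = synthesize_movie(study_spec(seed))
    result = run_pipeline(None, study_train_config(seed, max_iterations),
                          study_net_config(seed), InferenceConfig(),
                          stack=gt.movie)
    baseline = bilinear_upsample(result.inference_averages.averages[0],
                                 result.train_result.net.config.upscale_factor)
    card = compare_sr(gt.hr_ctf_image, result.sr, baseline)
    card["seed"] = seed
    card["stop_iteration"] = result.train_result.stop_iteration
    card["final_loss"] = result.train_result.loss_history[-1]["total"]
    return card


def zero_shot_gain_experiment(n_movies: int = 10, seed0: int = 0,
                              max_iterations: int = 400) -> dict:
    """Run n_movies seeded trials and summarize the gains."""
    cards = [run_zero_shot_trial(seed0 + i, max_iterations)
             for i in range(n_movies)]
    pearson_wins = sum(c["pearson_sr"] > c["pearson_baseline"] for c in cards)
    frc_wins = sum(c["frc_gain_high"] > 0 for c in cards)
    both_wins = sum((c["pearson_sr"] > c["pearson_baseline"])
                    and (c["frc_gain_high"] > 0) for c in cards)
    return {
        "cards": cards,
        "n_movies": n_movies,
        "pearson_wins": pearson_wins,
        "frc_wins": frc_wins,
        "both_wins": both_wins,
        "mean_pearson_sr": float(np.mean([c["pearson_sr"] for c in cards])),
        "mean_pearson_baseline": float(np.mean([c["pearson_baseline"]
                                                for c in cards])),
        "mean_frc_gain_high": float(np.mean([c["frc_gain_high"]
                                             for c in cards])),
    }
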