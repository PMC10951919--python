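"""Inference: apply the trained network to the full movie and correct by
back-projection.

At inference the network's inputs are *all-frame* averages aligned to the
same reference frames used during training, so the learned cross-scale
mapping is applied one scale up.  The result is made consistent with the
observed data by iterative back-projection: the super-resolved estimate is
repeatedly corrected so its downsampling matches the aligned average.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .fourier import bilinear_upsample
from .mrcio import MovieStack, read_movie, write_image
from .preprocess import FrameAverageSet, average_with_references, downsample
from .srnet import SRNet, SRNetConfig
from .train import TrainConfig, TrainResult, train_movie

__all__ = ["InferenceConfig", "super_resolve", "back_project",
           "run_pipeline", "PipelineResult"]


@dataclass(frozen=True)
class InferenceConfig:
    """Full-image application settings.

    tile_size : LR-grid tile side (0 = process the whole image at once)
    tile_overlap : overlap between tiles, px, blended by linear feathering
    n_backprojection_iters : data-consistency correction iterations
    backprojection_step : relaxation step in (0, 1]
    anchor : which LR image anchors back-projection — "mean" of the K
        averages or "first_ref" (the average aligned to the first
        reference)

    The default is a single damped correction pass against the mean of
    the K averages: at per-frame SNR far below 1 the observation itself is
    noise-dominated, and iterating to full data consistency re-injects
    the anchor's noise into the denoised estimate.  Full iterative
    consistency remains available through the config.
    """

    tile_size: int = 0
    tile_overlap: int = 16
    n_backprojection_iters: int = 1
    backprojection_step: float = 0.5
    anchor: str = "mean"

    def __post_init__(self) -> None:
        if self.tile_size and self.tile_overlap >= self.tile_size:
            raise ValueError("overlap must be smaller than tile_size")
        if not 0 < self.backprojection_step <= 1:
            raise ValueError("backprojection_step must lie in (0, 1]")
        if self.n_backprojection_iters < 0:
            raise ValueError("iteration count must be >= 0")
        if self.anchor not in ("first_ref", "mean"):
            raise ValueError("anchor must be 'first_ref' or 'mean'")


def _feather_weight(h: int, w: int, overlap: int) -> np.ndarray:
    """Linear ramp from the tile edge over the overlap band."""
    def ramp(n: int) -> np.ndarray:
        prof = np.ones(n)
        e = min(overlap, n // 2)
        if e > 0:
            edge = (np.arange(e) + 1.0) / (e + 1.0)
            prof[:e] = edge
            prof[-e:] = edge[::-1]
        return prof
    return np.outer(ramp(h), ramp(w))


def super_resolve(net: SRNet, lr_averages: FrameAverageSet,
                  config: InferenceConfig = InferenceConfig()) -> np.ndarray:
    """Forward pass on full-size averages, tiled when configured.

    Inputs are standardized by the statistics of the mean of the K
    averages; the output is mapped back to micrograph scale.
    """
    if net.trained_k is not None and lr_averages.k != net.trained_k:
        raise ValueError(
            f"network trained with K={net.trained_k} inputs, "
            f"got {lr_averages.k}")
    avgs = lr_averages.averages.astype(np.float64)
    anchor = avgs.mean(axis=0)
    mu = float(anchor.mean())
    sd = max(float(anchor.std()), 1e-8)
    frames = [(a - mu) / sd for a in avgs]
    s = net.config.upscale_factor
    h, w = frames[0].shape

    if config.tile_size <= 0 or config.tile_size >= min(h, w):
        sr = net.forward(frames)
        return sr * sd + mu

    t, o = config.tile_size, config.tile_overlap
    stride = t - o
    out = np.zeros((h * s, w * s))
    weight = np.zeros((h * s, w * s))
    ys = list(range(0, max(h - t, 0) + 1, stride))
    if ys[-1] != h - t:
        ys.append(h - t)
    xs = list(range(0, max(w - t, 0) + 1, stride))
    if xs[-1] != w - t:
        xs.append(w - t)
    margin = 2 * s  # trim interpolation edge effects at interior seams
    for y in ys:
        for x in xs:
            tile_sr = net.forward([f[y:y + t, x:x + t] for f in frames])
            wgt = _feather_weight(t * s, t * s, o * s)
            top = margin if y > 0 else 0
            bot = margin if y < h - t else 0
            left = margin if x > 0 else 0
            right = margin if x < w - t else 0
            sl = (slice(top, t * s - bot), slice(left, t * s - right))
            oy, ox = y * s, x * s
            osl = (slice(oy + top, oy + t * s - bot),
                   slice(ox + left, ox + t * s - right))
            out[osl] += tile_sr[sl] * wgt[sl]
            weight[osl] += wgt[sl]
    return (out / weight) * sd + mu


def back_project(sr: np.ndarray, lr_anchor: np.ndarray, s: int,
                 config: InferenceConfig = InferenceConfig(),
                 downsample_method: str = "fourier_crop") -> np.ndarray:
    """Iterative back-projection toward data consistency.

    sr <- sr + step * U(lr_anchor - D(sr)) with D the package downsampler
    and U bilinear upsampling.  Iterations stop early when the residual
    norm stops improving (it is never allowed to increase) or when the
    relative improvement drops below 1e-6.
    """
    sr = np.asarray(sr, dtype=np.float64).copy()
    lr_anchor = np.asarray(lr_anchor, dtype=np.float64)
    if sr.shape != (lr_anchor.shape[0] * s, lr_anchor.shape[1] * s):
        raise ValueError("sr must be s-times the anchor size")
    if config.n_backprojection_iters == 0:
        return sr
    res = lr_anchor - downsample(sr, s, downsample_method)
    res_norm = float(np.linalg.norm(res))
    for _ in range(config.n_backprojection_iters):
        if res_norm == 0.0:
            break
        candidate = sr + config.backprojection_step * bilinear_upsample(res, s)
        new_res = lr_anchor - downsample(candidate, s, downsample_method)
        new_norm = float(np.linalg.norm(new_res))
        if new_norm > res_norm:  # never increase the data residual
            break
        improved = (res_norm - new_norm) / max(res_norm, 1e-30)
        sr, res, res_norm = candidate, new_res, new_norm
        if improved < 1e-6:
            break
    return sr


@dataclass
class PipelineResult:
    sr: np.ndarray
    train_result: TrainResult
    inference_averages: FrameAverageSet
    anchor: np.ndarray
    pixel_size_out: float


def run_pipeline(movie_path, train_config: TrainConfig,
                 net_config: SRNetConfig,
                 infer_config: InferenceConfig = InferenceConfig(),
                 out_path=None,
                 exposure_per_frame: float = 0.0,
                 stack: MovieStack | None = None) -> PipelineResult:
    """Movie in, super-resolved micrograph out.

    split -> late-half averages + early-half pseudo-HR -> zero-shot
    training -> all-frame averages aligned to the same references ->
    network forward -> back-projection -> MRC with pixel size divided by s.
    A YAML manifest (config echo, seeds, stopping iteration, final loss)
    is written alongside the output.
    """
    if stack is None:
        stack = read_movie(movie_path, exposure_per_frame)
    tr = train_movie(stack, train_config, net_config)
    full_avgs = average_with_references(stack, tr.global_references,
                                        provenance="all")
    sr = super_resolve(tr.net, full_avgs, infer_config)
    if infer_config.anchor == "mean":
        anchor = full_avgs.averages.mean(axis=0)
    else:
        anchor = full_avgs.averages[0]
    sr = back_project(sr, anchor, train_config.s, infer_config,
                      train_config.downsample_method)
    px_out = stack.pixel_size / train_config.s

    if out_path is not None:
        out_path = Path(out_path)
        write_image(sr, px_out, out_path)
        manifest = {
            "package": "cryosr",
            "version": __version__,
            "input": str(movie_path),
            "train_config": asdict(train_config),
            "net_config": asdict(net_config),
            "infer_config": asdict(infer_config),
            "stop_iteration": tr.stop_iteration,
            "final_loss": tr.loss_history[-1]["total"],
            "late_references": list(tr.late_references),
            "global_references": list(tr.global_references),
            "pixel_size_out": px_out,
        }
        with open(out_path.with_suffix(out_path.suffix + ".manifest.yaml"),
                  "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=False)
    return PipelineResult(sr=sr, train_result=tr,
                          inference_averages=full_avgs, anchor=anchor,
                          pixel_size_out=px_out)
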