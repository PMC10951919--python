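"""Encode-fuse-decode super-resolution network.

The network receives N low-resolution frames of the same field of view,
bilinearly pre-upsampled to the output size, and predicts a *residual* on
top of their pixel-wise median:

* **Encode** — the median of the upsampled frames serves as a shared
  reference; it is concatenated to each frame and a weight-shared embedding
  (convolution + leaky rectifier + residual blocks) encodes every
  frame/reference pair.  The shared reference anchors implicit alignment.
* **Fuse** — hidden states are merged pairwise and recursively: each merge
  concatenates two states and projects back to one with a single shared
  convolution, halving the count per step; after ceil(log2 N) steps one
  state remains.  Odd counts duplicate the last state before pairing.
* **Decode** — the fused state is decoded to a single-channel residual,
  added to the median reference.

All operators are local and weight-shared across frames, so the parameter
count is independent of N and of the input size: the network can be trained
on small crops and applied to full micrographs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fourier import bilinear_upsample
from .nn_ops import (Adam, conv2d_backward, conv2d_forward, he_init,
                     leaky_relu_backward, leaky_relu_forward)

__all__ = ["SRNetConfig", "SRNet", "median_reference", "fusion_schedule"]


@dataclass(frozen=True)
class SRNetConfig:
    """Architecture hyperparameters.

    upscale_factor : integer output/input size ratio s (2 reproduces the
        intended acquisition-rate doubling)
    n_channels : hidden width of every convolution
    n_encoder_layers : number of residual blocks after the embedding
    n_decoder_layers : decoder depth (last layer projects to 1 channel)
    kernel_size : odd spatial kernel extent
    seed : weight-initialisation seed
    """

    upscale_factor: int = 2
    n_channels: int = 64
    n_encoder_layers: int = 2
    n_decoder_layers: int = 2
    kernel_size: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.upscale_factor < 2:
            raise ValueError("upscale_factor must be >= 2")
        if self.n_encoder_layers < 1 or self.n_decoder_layers < 1:
            raise ValueError("depths must be >= 1")
        if self.kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd")


def median_reference(frames) -> np.ndarray:
    """Element-wise median across a sequence of equally sized frames."""
    frames = [np.asarray(f) for f in frames]
    if len(frames) == 0:
        raise ValueError("need at least one frame")
    shape = frames[0].shape
    if any(f.shape != shape for f in frames):
        raise ValueError("frames must share dimensions")
    return np.median(np.stack(frames), axis=0)


def fusion_schedule(n: int) -> tuple[int, list[list[tuple[int, int]]]]:
    """Pairing plan for recursive fusion of n states.

    Returns (T, plan): T = ceil(log2 n) steps; plan[t] lists the index
    pairs merged at step t, on the state list of that step.  When the
    count is odd the last state is duplicated, encoded as the pair
    (i, i).
    """
    if n < 1:
        raise ValueError("need at least one state")
    plan: list[list[tuple[int, int]]] = []
    count = n
    while count > 1:
        step = []
        if count % 2:
            for i in range(0, count - 1, 2):
                step.append((i, i + 1))
            step.append((count - 1, count - 1))  # duplicate the last state
        else:
            for i in range(0, count, 2):
                step.append((i, i + 1))
        plan.append(step)
        count = len(step)
    t = int(np.ceil(np.log2(n))) if n > 1 else 0
    assert t == len(plan)
    return t, plan


class SRNet:
    """The movie-specific network with explicit forward/backward passes."""

    def __init__(self, config: SRNetConfig):
        self.config = config
        c, k = config.n_channels, config.kernel_size
        rng = np.random.default_rng(config.seed)
        p: dict[str, np.ndarray] = {}
        p["embed_w"] = he_init(rng, (c, 2, k, k))
        p["embed_b"] = np.zeros(c, dtype=np.float32)
        for i in range(config.n_encoder_layers):
            p[f"enc{i}a_w"] = he_init(rng, (c, c, k, k))
            p[f"enc{i}a_b"] = np.zeros(c, dtype=np.float32)
            p[f"enc{i}b_w"] = he_init(rng, (c, c, k, k))
            p[f"enc{i}b_b"] = np.zeros(c, dtype=np.float32)
        p["fuse_w"] = he_init(rng, (c, 2 * c, k, k))
        p["fuse_b"] = np.zeros(c, dtype=np.float32)
        for i in range(config.n_decoder_layers - 1):
            p[f"dec{i}_w"] = he_init(rng, (c, c, k, k))
            p[f"dec{i}_b"] = np.zeros(c, dtype=np.float32)
        p["out_w"] = he_init(rng, (1, c, k, k))
        p["out_b"] = np.zeros(1, dtype=np.float32)
        self.params = p
        self.trained_k: int | None = None

    # -- bookkeeping ---------------------------------------------------

    @property
    def param_count(self) -> int:
        return int(sum(v.size for v in self.params.values()))

    def zero_residual_(self) -> "SRNet":
        """Silence the decoder output: forward then returns the median of
        the bilinearly upsampled inputs exactly (analytic reference
        configuration used by tests)."""
        self.params["out_w"][:] = 0
        self.params["out_b"][:] = 0
        return self

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, v in state.items():
            self.params[k] = np.asarray(v, dtype=np.float32).copy()

    # -- forward -------------------------------------------------------

    def _encode_stream(self, x: np.ndarray, tape: list) -> np.ndarray:
        p = self.params
        h, cache = conv2d_forward(x, p["embed_w"], p["embed_b"])
        h, mask = leaky_relu_forward(h)
        tape.append(("embed", cache, mask))
        for i in range(self.config.n_encoder_layers):
            r, ca = conv2d_forward(h, p[f"enc{i}a_w"], p[f"enc{i}a_b"])
            r, ma = leaky_relu_forward(r)
            r, cb = conv2d_forward(r, p[f"enc{i}b_w"], p[f"enc{i}b_b"])
            tape.append((f"enc{i}", ca, ma, cb))
            h = h + r  # residual block
        return h

    def _encode_stream_backward(self, dh: np.ndarray, tape: list,
                                grads: dict) -> None:
        for i in reversed(range(self.config.n_encoder_layers)):
            name, ca, ma, cb = tape.pop()
            dr = dh  # grad into the residual branch; skip path keeps dh
            dr, dwb, dbb = conv2d_backward(dr, cb)
            grads[f"enc{i}b_w"] += dwb
            grads[f"enc{i}b_b"] += dbb
            dr = leaky_relu_backward(dr, ma)
            dr, dwa, dba = conv2d_backward(dr, ca)
            grads[f"enc{i}a_w"] += dwa
            grads[f"enc{i}a_b"] += dba
            dh = dh + dr
        name, cache, mask = tape.pop()
        dh = leaky_relu_backward(dh, mask)
        _, dw, db = conv2d_backward(dh, cache)
        grads["embed_w"] += dw
        grads["embed_b"] += db

    def forward(self, lr_frames, return_tape: bool = False):
        """Super-resolve N equally sized LR frames to one s-times image."""
        frames = [np.asarray(f, dtype=np.float64) for f in lr_frames]
        if len(frames) < 1:
            raise ValueError("need at least one frame")
        shape = frames[0].shape
        if any(f.shape != shape for f in frames):
            raise ValueError("frames must share dimensions")
        s = self.config.upscale_factor
        up = [bilinear_upsample(f, s) for f in frames]
        ref = median_reference(up)

        p = self.params
        tape: dict = {"enc": [], "fuse": [], "dec": []}
        states = []
        for u in up:
            x = np.stack([u, ref]).astype(np.float32)
            stream_tape: list = []
            states.append(self._encode_stream(x, stream_tape))
            tape["enc"].append(stream_tape)

        _, plan = fusion_schedule(len(states))
        for step_pairs in plan:
            nxt = []
            step_tape = []
            for (i, j) in step_pairs:
                cat = np.concatenate([states[i], states[j]], axis=0)
                m, cache = conv2d_forward(cat, p["fuse_w"], p["fuse_b"])
                m, mask = leaky_relu_forward(m)
                nxt.append(m)
                step_tape.append((i, j, cache, mask))
            tape["fuse"].append((len(states), step_tape))
            states = nxt
        h = states[0]

        for i in range(self.config.n_decoder_layers - 1):
            h, cache = conv2d_forward(h, p[f"dec{i}_w"], p[f"dec{i}_b"])
            h, mask = leaky_relu_forward(h)
            tape["dec"].append((f"dec{i}", cache, mask))
        residual, out_cache = conv2d_forward(h, p["out_w"], p["out_b"])
        tape["dec"].append(("out", out_cache, None))

        sr = residual[0].astype(np.float64) + ref
        if return_tape:
            return sr, tape
        return sr

    # -- backward ------------------------------------------------------

    def backward(self, dsr: np.ndarray, tape: dict) -> dict[str, np.ndarray]:
        """Gradients of a scalar loss wrt all weights, given dL/d(output).

        The median reference and the upsampled inputs are constants of the
        graph (no learnable parameters upstream), so gradient flow stops
        at the embedding inputs.
        """
        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        d = dsr.astype(np.float32)[None, :, :]

        name, out_cache, _ = tape["dec"][-1]
        d, dw, db = conv2d_backward(d, out_cache)
        grads["out_w"] += dw
        grads["out_b"] += db
        for (name, cache, mask) in reversed(tape["dec"][:-1]):
            d = leaky_relu_backward(d, mask)
            d, dw, db = conv2d_backward(d, cache)
            grads[f"{name}_w"] += dw
            grads[f"{name}_b"] += db

        # fusion tree: propagate one upstream grad per surviving state
        upstream = [d]
        for (n_states, step_tape) in reversed(tape["fuse"]):
            acc = [None] * n_states
            for (i, j, cache, mask), dm in zip(step_tape, upstream):
                dm = leaky_relu_backward(dm, mask)
                dcat, dw, db = conv2d_backward(dm, cache)
                grads["fuse_w"] += dw
                grads["fuse_b"] += db
                c = dcat.shape[0] // 2
                for idx, dpart in ((i, dcat[:c]), (j, dcat[c:])):
                    acc[idx] = dpart if acc[idx] is None else acc[idx] + dpart
            upstream = [a for a in acc]
        for stream_tape, dstate in zip(tape["enc"], upstream):
            self._encode_stream_backward(dstate, list(stream_tape), grads)
        return grads
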