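"""Minimal CPU neural-network primitives for the movie-specific SR network.

Only what the encode/fuse/decode architecture needs: same-padding 2-D
convolution (im2col + matmul) with explicit backward passes, a leaky
rectifier, and Adam.  Arrays are (C, H, W) float32; weight layouts are
(C_out, C_in, k, k).  Everything is deterministic for fixed inputs in
single-threaded execution.
"""

from __future__ import annotations

import numpy as np

__all__ = ["conv2d_forward", "conv2d_backward", "leaky_relu_forward",
           "leaky_relu_backward", "Adam", "he_init"]

LEAKY_SLOPE = 0.1


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(C, H, W) -> (C*k*k, H*W) patch matrix for same-padding convolution."""
    c, h, w = x.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (p, p), (p, p)))
    s = xp.strides
    patches = np.lib.stride_tricks.as_strided(
        xp, shape=(c, k, k, h, w), strides=(s[0], s[1], s[2], s[1], s[2]),
        writeable=False)
    return patches.reshape(c * k * k, h * w)


def conv2d_forward(x: np.ndarray, weight: np.ndarray, bias: np.ndarray):
    """Same-padding convolution; returns (out, cache)."""
    c_out, c_in, k, _ = weight.shape
    if x.shape[0] != c_in:
        raise ValueError("channel mismatch")
    cols = np.ascontiguousarray(_im2col(x, k))
    out = (weight.reshape(c_out, -1) @ cols) + bias[:, None]
    h, w = x.shape[1:]
    return out.reshape(c_out, h, w), (cols, x.shape, weight)


def conv2d_backward(dout: np.ndarray, cache):
    """Returns (dx, dweight, dbias) for conv2d_forward."""
    cols, x_shape, weight = cache
    c_out, c_in, k, _ = weight.shape
    c, h, w = x_shape
    g = dout.reshape(c_out, h * w)
    dw = (g @ cols.T).reshape(weight.shape)
    db = g.sum(axis=1)
    dcols = (weight.reshape(c_out, -1).T @ g).reshape(c, k, k, h, w)
    p = k // 2
    dxp = np.zeros((c, h + 2 * p, w + 2 * p), dtype=dout.dtype)
    for dy in range(k):
        for dx_ in range(k):
            dxp[:, dy:dy + h, dx_:dx_ + w] += dcols[:, dy, dx_]
    dx = dxp[:, p:p + h, p:p + w]
    return dx, dw, db


def leaky_relu_forward(x: np.ndarray):
    out = np.where(x > 0, x, LEAKY_SLOPE * x)
    return out, x > 0


def leaky_relu_backward(dout: np.ndarray, mask: np.ndarray) -> np.ndarray:
    return np.where(mask, dout, LEAKY_SLOPE * dout)


def he_init(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    """He-normal initialisation scaled by the fan-in of the kernel."""
    fan_in = int(np.prod(shape[1:]))
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Adam:
    """Adam optimiser over a dict of named parameter arrays."""

    def __init__(self, params: dict, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1.0 - b1 ** self.t
        corr2 = 1.0 - b2 ** self.t
        for name, g in grads.items():
            p = self.params[name]
            m = self.m[name]
            v = self.v[name]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * np.square(g)
            p -= self.lr * (m / corr1) / (np.sqrt(v / corr2) + self.eps)
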