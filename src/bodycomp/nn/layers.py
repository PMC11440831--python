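"""Minimal float32 CNN primitives with explicit backward passes.

Layout is channels-last, (N, H, W, C).  3x3 convolutions are computed as
nine shifted matmuls (one per kernel tap) so the heavy lifting stays in
BLAS without im2col copies; all layers are deterministic pure functions, so
a seeded training run is bit-reproducible.  Analytic gradients are covered
by finite-difference tests.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "conv3x3_forward", "conv3x3_backward",
    "conv1x1_forward", "conv1x1_backward",
    "relu_forward", "relu_backward",
    "maxpool2_forward", "maxpool2_backward",
    "upsample2_forward", "upsample2_backward",
    "softmax_channels",
]


def conv3x3_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Same-padding 3x3 convolution; ``w`` has shape (3, 3, C_in, C_out)."""
    n, h, wd, _ = x.shape
    k = w.shape[-1]
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
    out = np.empty((n, h, wd, k), dtype=np.result_type(x.dtype, w.dtype))
    out[:] = b
    for u in range(3):
        for v in range(3):
            out += xp[:, u:u + h, v:v + wd, :] @ w[u, v]
    return out


def conv3x3_backward(x: np.ndarray, w: np.ndarray, dout: np.ndarray):
    n, h, wd, c = x.shape
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
    dp = np.pad(dout, ((0, 0), (1, 1), (1, 1), (0, 0)))
    dw = np.empty_like(w)
    dx = np.zeros_like(x)
    db = dout.sum(axis=(0, 1, 2))
    for u in range(3):
        for v in range(3):
            xs = xp[:, u:u + h, v:v + wd, :]
            dw[u, v] = np.einsum("nhwc,nhwk->ck", xs, dout, optimize=True)
            # dx accumulates the full correlation with the transposed taps
            dx += dp[:, 2 - u:2 - u + h, 2 - v:2 - v + wd, :] @ w[u, v].T
    if dx.dtype == np.float32:
        dx[np.abs(dx) < 1e-30] = 0.0  # keep subnormals out of the next GEMM
    return dx, dw, db


def conv1x1_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pointwise convolution; ``w`` has shape (C_in, C_out)."""
    return x @ w + b


def conv1x1_backward(x: np.ndarray, w: np.ndarray, dout: np.ndarray):
    dw = np.einsum("nhwc,nhwk->ck", x, dout, optimize=True)
    db = dout.sum(axis=(0, 1, 2))
    return dout @ w.T, dw, db


def relu_forward(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def relu_backward(x: np.ndarray, dout: np.ndarray) -> np.ndarray:
    return dout * (x > 0)


def maxpool2_forward(x: np.ndarray):
    """2x2 max pooling as two axis reductions (no transposes).

    Ties break toward the first occurrence, deterministically.
    """
    n, h, w, c = x.shape
    r1 = x.reshape(n, h // 2, 2, w, c)
    i1 = r1.argmax(axis=2)
    m1 = np.take_along_axis(r1, i1[:, :, None], axis=2)[:, :, 0]
    r2 = m1.reshape(n, h // 2, w // 2, 2, c)
    i2 = r2.argmax(axis=3)
    out = np.take_along_axis(r2, i2[:, :, :, None], axis=3)[:, :, :, 0]
    return out, (i1, i2)


def maxpool2_backward(dout: np.ndarray, idx, in_shape) -> np.ndarray:
    n, h, w, c = in_shape
    i1, i2 = idx
    d2 = np.zeros((n, h // 2, w // 2, 2, c), dtype=dout.dtype)
    np.put_along_axis(d2, i2[:, :, :, None], dout[:, :, :, None], axis=3)
    d1 = np.zeros((n, h // 2, 2, w, c), dtype=dout.dtype)
    np.put_along_axis(d1, i1[:, :, None], d2.reshape(n, h // 2, w, c)[:, :, None], axis=2)
    return d1.reshape(n, h, w, c)


def upsample2_forward(x: np.ndarray) -> np.ndarray:
    return x.repeat(2, axis=1).repeat(2, axis=2)


def upsample2_backward(dout: np.ndarray) -> np.ndarray:
    n, h, w, c = dout.shape
    return dout.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))


def softmax_channels(logits: np.ndarray) -> np.ndarray:
    """Numerically stable softmax over the channel (last) axis."""
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)
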