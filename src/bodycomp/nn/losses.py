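"""Dice loss: 1 - soft Dice overlap, with analytic gradient w.r.t. logits."""

from __future__ import annotations

import numpy as np

from .layers import softmax_channels

__all__ = ["dice_loss", "dice_loss_and_grad"]


def dice_loss(pred: np.ndarray, target: np.ndarray, smooth: float = 1.0) -> float:
    """``1 - (2 sum(p*g) + s) / (sum(p) + sum(g) + s)`` over the whole map.

    ``pred`` is a probability map, ``target`` a binary map of the same shape.
    Zero iff the prediction is binary and agrees perfectly; by the smoothing
    convention two empty maps give 0.
    """
    p = np.asarray(pred, dtype=np.float64)
    g = np.asarray(target, dtype=np.float64)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")
    inter = float((p * g).sum())
    denom = float(p.sum() + g.sum())
    return 1.0 - (2.0 * inter + smooth) / (denom + smooth)


def dice_loss_and_grad(logits: np.ndarray, target_onehot: np.ndarray,
                       fg_classes: np.ndarray, smooth: float = 1.0):
    """Mean soft-dice loss over foreground classes, per sample.

    ``logits`` and ``target_onehot`` are channels-last (N, H, W, C).
    Returns ``(loss, dlogits)`` where the gradient is taken through the
    channel softmax.  Sums run per sample and per class, so a class absent
    from one sample contributes a well-defined (smoothed) term.
    """
    p = softmax_channels(logits)
    g = target_onehot
    inter = (p * g).sum(axis=(1, 2))          # (N, C)
    sp = p.sum(axis=(1, 2))
    sg = g.sum(axis=(1, 2))
    a = 2.0 * inter + smooth
    b = sp + sg + smooth
    d = a / b
    n = d.shape[0]
    nf = len(fg_classes)
    loss = float(1.0 - d[:, fg_classes].mean())

    dldp = np.zeros_like(p)
    scale = -1.0 / (n * nf)
    for c in fg_classes:
        bc = b[:, c, None, None]
        dldp[..., c] = scale * (2.0 * g[..., c] * bc - a[:, c, None, None]) / (bc * bc)
    inner = (dldp * p).sum(axis=-1, keepdims=True)
    dlogits = (p * (dldp - inner)).astype(logits.dtype)
    # flush values near the subnormal range: once the network is confident,
    # subnormal float32 gradients would stall downstream BLAS calls
    dlogits[np.abs(dlogits) < 1e-30] = 0.0
    return loss, dlogits
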