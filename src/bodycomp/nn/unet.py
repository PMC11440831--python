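"""The U-net: encoder/decoder with skip connections, in pure numpy.

The full-scale profiles mirror the clinical setup — depth 4 with 64 base
filters (L3 detection, 1088 x 512 input) or 32 base filters (body
composition, 512 x 512 input), 3 x 3 kernels, filters doubling per level
down and halving per level up, softmax class probabilities per pixel.
Reduced "desk" profiles run the same code at CPU-friendly sizes.

Arrays are channels-last: inputs (N, H, W, C_in), outputs (N, H, W, classes).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .layers import (
    conv1x1_backward, conv1x1_forward, conv3x3_backward, conv3x3_forward,
    maxpool2_backward, maxpool2_forward, relu_backward, relu_forward,
    softmax_channels, upsample2_backward, upsample2_forward,
)

__all__ = ["UNetConfig", "UNet", "build_unet"]


class UNetConfigError(ValueError):
    pass


@dataclass(frozen=True)
class UNetConfig:
    depth: int = 4
    base_filters: int = 64
    in_channels: int = 1
    n_classes: int = 2
    seed: int = 0

    @classmethod
    def l3_full(cls, seed: int = 0) -> "UNetConfig":
        return cls(depth=4, base_filters=64, n_classes=2, seed=seed)

    @classmethod
    def body_full(cls, seed: int = 0) -> "UNetConfig":
        return cls(depth=4, base_filters=32, n_classes=5, seed=seed)

    @classmethod
    def l3_desk(cls, seed: int = 0) -> "UNetConfig":
        return cls(depth=3, base_filters=16, n_classes=2, seed=seed)

    @classmethod
    def body_desk(cls, seed: int = 0) -> "UNetConfig":
        return cls(depth=3, base_filters=16, n_classes=5, seed=seed)

    @property
    def encoder_filters(self) -> list[int]:
        return [self.base_filters * 2 ** k for k in range(self.depth)]

    @property
    def bottleneck_filters(self) -> int:
        return self.base_filters * 2 ** self.depth


class UNet:
    """Seeded U-net with forward, backward and (de)serialization."""

    def __init__(self, config: UNetConfig):
        if config.depth < 1 or config.base_filters < 1:
            raise UNetConfigError("depth and base_filters must be positive")
        self.config = config
        self.params: dict[str, np.ndarray] = {}
        rng = np.random.default_rng(config.seed)
        filters = config.encoder_filters
        c_in = config.in_channels
        for lvl, f in enumerate(filters):
            self._init_conv(rng, f"enc{lvl}_1", c_in, f)
            self._init_conv(rng, f"enc{lvl}_2", f, f)
            c_in = f
        self._init_conv(rng, "bot_1", c_in, config.bottleneck_filters)
        self._init_conv(rng, "bot_2", config.bottleneck_filters, config.bottleneck_filters)
        up_in = config.bottleneck_filters
        for lvl in reversed(range(config.depth)):
            f = filters[lvl]
            self._init_conv(rng, f"dec{lvl}_1", up_in + f, f)
            self._init_conv(rng, f"dec{lvl}_2", f, f)
            up_in = f
        # zero-initialized pointwise classifier: training starts from
        # uniform class probabilities so every class receives gradient
        self.params["out_W"] = np.zeros((filters[0], config.n_classes), dtype=np.float32)
        self.params["out_b"] = np.zeros(config.n_classes, dtype=np.float32)

    def _init_conv(self, rng, name: str, c_in: int, c_out: int) -> None:
        std = np.sqrt(2.0 / (c_in * 9))  # He initialization for ReLU
        self.params[f"{name}_W"] = rng.normal(0.0, std, (3, 3, c_in, c_out)).astype(np.float32)
        self.params[f"{name}_b"] = np.zeros(c_out, dtype=np.float32)

    # ---- forward / backward -------------------------------------------------

    def _check_input(self, x: np.ndarray) -> None:
        if x.ndim != 4 or x.shape[-1] != self.config.in_channels:
            raise UNetConfigError(
                f"expected (N, H, W, {self.config.in_channels}), got {x.shape}")
        div = 2 ** self.config.depth
        if x.shape[1] % div or x.shape[2] % div:
            raise UNetConfigError(
                f"spatial size {x.shape[1:3]} not divisible by 2^depth = {div}")

    def forward(self, x: np.ndarray, want_cache: bool = False):
        """Logits of shape (N, H, W, n_classes); optionally an autodiff cache."""
        self._check_input(x)
        x = np.ascontiguousarray(x, dtype=np.float32)
        p = self.params
        cache = {"enc": [], "pool": [], "dec": []}
        h = x
        for lvl in range(self.config.depth):
            a1 = conv3x3_forward(h, p[f"enc{lvl}_1_W"], p[f"enc{lvl}_1_b"])
            r1 = relu_forward(a1)
            a2 = conv3x3_forward(r1, p[f"enc{lvl}_2_W"], p[f"enc{lvl}_2_b"])
            r2 = relu_forward(a2)
            pooled, idx = maxpool2_forward(r2)
            cache["enc"].append((h, a1, r1, a2, r2))
            cache["pool"].append(idx)
            h = pooled
        a1 = conv3x3_forward(h, p["bot_1_W"], p["bot_1_b"])
        r1 = relu_forward(a1)
        a2 = conv3x3_forward(r1, p["bot_2_W"], p["bot_2_b"])
        r2 = relu_forward(a2)
        cache["bot"] = (h, a1, r1, a2)
        h = r2
        for lvl in reversed(range(self.config.depth)):
            up = upsample2_forward(h)
            skip = cache["enc"][lvl][4]
            cat = np.concatenate([skip, up], axis=-1)
            a1 = conv3x3_forward(cat, p[f"dec{lvl}_1_W"], p[f"dec{lvl}_1_b"])
            r1 = relu_forward(a1)
            a2 = conv3x3_forward(r1, p[f"dec{lvl}_2_W"], p[f"dec{lvl}_2_b"])
            r2 = relu_forward(a2)
            cache["dec"].append((cat, a1, r1, a2, r2))
            h = r2
        logits = conv1x1_forward(h, p["out_W"], p["out_b"])
        cache["head_in"] = h
        return (logits, cache) if want_cache else logits

    def backward(self, dlogits: np.ndarray, cache) -> dict[str, np.ndarray]:
        """Parameter gradients given d(loss)/d(logits)."""
        p = self.params
        grads: dict[str, np.ndarray] = {}
        dh, grads["out_W"], grads["out_b"] = conv1x1_backward(
            cache["head_in"], p["out_W"], dlogits)
        dskips = {}
        # decoder ran levels depth-1 .. 0; gradient flows back 0 .. depth-1
        for lvl in range(self.config.depth):
            cat, a1, r1, a2, r2 = cache["dec"][self.config.depth - 1 - lvl]
            da2 = relu_backward(a2, dh)
            dr1, grads[f"dec{lvl}_2_W"], grads[f"dec{lvl}_2_b"] = conv3x3_backward(
                r1, p[f"dec{lvl}_2_W"], da2)
            da1 = relu_backward(a1, dr1)
            dcat, grads[f"dec{lvl}_1_W"], grads[f"dec{lvl}_1_b"] = conv3x3_backward(
                cat, p[f"dec{lvl}_1_W"], da1)
            n_skip = cache["enc"][lvl][4].shape[-1]
            dskips[lvl] = dcat[..., :n_skip]
            dh = upsample2_backward(dcat[..., n_skip:])
        hin, a1, r1, a2 = cache["bot"]
        da2 = relu_backward(a2, dh)
        dr1, grads["bot_2_W"], grads["bot_2_b"] = conv3x3_backward(r1, p["bot_2_W"], da2)
        da1 = relu_backward(a1, dr1)
        dh, grads["bot_1_W"], grads["bot_1_b"] = conv3x3_backward(hin, p["bot_1_W"], da1)
        for lvl in reversed(range(self.config.depth)):
            h_in, a1, r1, a2, r2 = cache["enc"][lvl]
            dr2 = maxpool2_backward(dh, cache["pool"][lvl], r2.shape)
            dr2 += dskips[lvl]
            da2 = relu_backward(a2, dr2)
            dr1, grads[f"enc{lvl}_2_W"], grads[f"enc{lvl}_2_b"] = conv3x3_backward(
                r1, p[f"enc{lvl}_2_W"], da2)
            da1 = relu_backward(a1, dr1)
            dh, grads[f"enc{lvl}_1_W"], grads[f"enc{lvl}_1_b"] = conv3x3_backward(
                h_in, p[f"enc{lvl}_1_W"], da1)
        return grads

    def predict_proba(self, x: np.ndarray, batch_size: int = 8) -> np.ndarray:
        """Per-pixel class probabilities, (N, H, W, C); channels sum to 1."""
        x = np.asarray(x, dtype=np.float32)
        outs = [softmax_channels(self.forward(x[i:i + batch_size]))
                for i in range(0, len(x), batch_size)]
        return np.concatenate(outs, axis=0)

    # ---- persistence --------------------------------------------------------

    def copy_params(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_params(self, params: dict[str, np.ndarray]) -> None:
        self.params = {k: v.copy() for k, v in params.items()}

    def save(self, path) -> None:
        path = Path(path)
        np.savez_compressed(path, __config__=json.dumps(asdict(self.config)),
                            **self.params)

    @classmethod
    def load(cls, path) -> "UNet":
        with np.load(path, allow_pickle=False) as data:
            config = UNetConfig(**json.loads(str(data["__config__"])))
            model = cls(config)
            model.params = {k: data[k] for k in data.files if k != "__config__"}
        return model


def build_unet(config: UNetConfig) -> UNet:
    """Construct a seeded, randomly initialized U-net."""
    return UNet(config)
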