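"""Training loop: Adam, dice loss, early stopping, best-checkpoint return,
and the 5-fold cross-validation harness.

The clinical profile trains with Adam (lr 1e-4), batch size 8, up to 100
epochs with early stopping on the validation loss; after every epoch the
model is scored on the validation set with the DICE coefficient and the
best-scoring weights are the ones returned.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .losses import dice_loss_and_grad
from .unet import UNet, UNetConfig, build_unet

__all__ = ["TrainConfig", "train_model", "run_5fold_cv", "one_hot", "TrainingDivergedError"]


class TrainingDivergedError(RuntimeError):
    pass


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-4
    batch_size: int = 8
    max_epochs: int = 100
    patience: int = 10
    min_delta: float = 1e-4
    dice_smooth: float = 1.0
    # global-norm gradient clipping guards the tiny-foreground dice loss
    # against spikes that would otherwise poison Adam's moment estimates
    clip_grad_norm: float = 1.0
    # classes entering the dice loss; None = all non-background classes.
    # Including background stabilizes extremely imbalanced binary tasks.
    loss_classes: tuple | None = None
    seed: int = 0
    verbose: bool = False

    @classmethod
    def desk(cls, seed: int = 0, **overrides) -> "TrainConfig":
        base = dict(max_epochs=15, seed=seed)
        base.update(overrides)
        return cls(**base)

    def validate(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("batch_size and max_epochs must be >= 1")


class Adam:
    """Adam with float64 moment state.

    Squared gradients of small-but-meaningful float32 gradients underflow
    into subnormal float32, which both distorts the update and stalls CPU
    arithmetic; float64 state avoids that while parameters stay float32.
    """

    def __init__(self, params: dict, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros(v.shape, dtype=np.float64) for k, v in params.items()}
        self.v = {k: np.zeros(v.shape, dtype=np.float64) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for k, g in grads.items():
            g = g.astype(np.float64)
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            step = self.lr * (self.m[k] / bc1) / (np.sqrt(self.v[k] / bc2) + self.eps)
            params[k] -= step.astype(params[k].dtype)


def one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    """(N, H, W) integer labels -> channels-last (N, H, W, C) float32 one-hot."""
    return (labels[..., None] == np.arange(n_classes)).astype(np.float32)


def _foreground_classes(n_classes: int) -> np.ndarray:
    return np.arange(1, n_classes) if n_classes > 1 else np.array([0])


def hard_dice(pred_labels: np.ndarray, true_labels: np.ndarray, classes) -> float:
    """Mean binary DICE over the given classes (empty-vs-empty counts as 1)."""
    scores = []
    for c in classes:
        a = pred_labels == c
        b = true_labels == c
        denom = a.sum() + b.sum()
        scores.append(1.0 if denom == 0 else 2.0 * np.logical_and(a, b).sum() / denom)
    return float(np.mean(scores))


def _evaluate(model: UNet, x: np.ndarray, y: np.ndarray, cfg: TrainConfig):
    fg = _foreground_classes(model.config.n_classes)
    loss_cls = np.asarray(cfg.loss_classes) if cfg.loss_classes is not None else fg
    losses, dices = [], []
    for i in range(0, len(x), cfg.batch_size):
        xb = x[i:i + cfg.batch_size]
        yb = y[i:i + cfg.batch_size]
        logits = model.forward(xb)
        g = one_hot(yb, model.config.n_classes)
        loss, _ = dice_loss_and_grad(logits, g, loss_cls, cfg.dice_smooth)
        losses.append(loss * len(xb))
        pred = logits.argmax(axis=-1)
        dices.extend(hard_dice(pred[j], yb[j], fg) for j in range(len(xb)))
    return float(np.sum(losses) / len(x)), float(np.mean(dices))


def train_model(model: UNet, train_set, val_set, config: TrainConfig | None = None):
    """Train with dice loss; return (best model, per-epoch history).

    ``train_set`` / ``val_set`` are ``(images, labels)`` with channels-last
    images (N, H, W, C) normalized to [0, 1] and integer label maps (N, H, W).
    Stops at ``max_epochs`` or when the validation loss has not improved by
    ``min_delta`` for ``patience`` epochs; the returned weights are from the
    epoch with the best validation DICE.
    """
    config = config or TrainConfig()
    config.validate()
    x_tr, y_tr = (np.asarray(a) for a in train_set)
    x_va, y_va = (np.asarray(a) for a in val_set)
    if len(x_tr) == 0 or len(x_va) == 0:
        raise ValueError("training and validation sets must be nonempty")
    x_tr = np.ascontiguousarray(x_tr, dtype=np.float32)
    x_va = np.ascontiguousarray(x_va, dtype=np.float32)

    rng = np.random.default_rng(config.seed)
    opt = Adam(model.params, config.learning_rate)
    fg = _foreground_classes(model.config.n_classes)
    loss_cls = np.asarray(config.loss_classes) if config.loss_classes is not None else fg
    history: list[dict] = []
    best_dice, best_params = -np.inf, model.copy_params()
    best_val_loss, since_improve = np.inf, 0

    for epoch in range(config.max_epochs):
        order = rng.permutation(len(x_tr))
        epoch_loss = 0.0
        for i in range(0, len(order), config.batch_size):
            idx = order[i:i + config.batch_size]
            xb = x_tr[idx]
            gb = one_hot(y_tr[idx], model.config.n_classes)
            logits, cache = model.forward(xb, want_cache=True)
            loss, dlogits = dice_loss_and_grad(logits, gb, loss_cls, config.dice_smooth)
            if not np.isfinite(loss):
                raise TrainingDivergedError(f"non-finite loss at epoch {epoch}")
            grads = model.backward(dlogits, cache)
            if config.clip_grad_norm:
                norm = np.sqrt(sum(float((g * g).sum()) for g in grads.values()))
                if norm > config.clip_grad_norm:
                    scale = config.clip_grad_norm / norm
                    grads = {k: g * scale for k, g in grads.items()}
            opt.step(model.params, grads)
            epoch_loss += loss * len(idx)
        val_loss, val_dice = _evaluate(model, x_va, y_va, config)
        history.append({"epoch": epoch, "train_loss": epoch_loss / len(x_tr),
                        "val_loss": val_loss, "val_dice": val_dice})
        if config.verbose:
            print(f"epoch {epoch:3d}  train {epoch_loss / len(x_tr):.4f}  "
                  f"val {val_loss:.4f}  dice {val_dice:.4f}")
        if val_dice > best_dice:
            best_dice, best_params = val_dice, model.copy_params()
        if val_loss < best_val_loss - config.min_delta:
            best_val_loss, since_improve = val_loss, 0
        else:
            since_improve += 1
            if since_improve >= config.patience:
                break
    model.set_params(best_params)
    return model, history


def run_5fold_cv(images: np.ndarray, labels: np.ndarray, unet_config: UNetConfig,
                 train_config: TrainConfig | None = None, n_folds: int = 5,
                 metric_fn=None, seed: int = 0):
    """Seeded k-fold cross-validation; every sample is validated exactly once.

    ``metric_fn(model, x_val, y_val) -> dict`` may add task-specific metrics
    per fold.  Returns ``{"folds": [...], "mean": ..., "sd": ...}``.
    """
    train_config = train_config or TrainConfig()
    n = len(images)
    if n < n_folds:
        raise ValueError(f"need at least {n_folds} samples, got {n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, n_folds)
    results = []
    for f, val_idx in enumerate(folds):
        tr_idx = np.setdiff1d(order, val_idx)
        model = build_unet(replace(unet_config, seed=int(rng.integers(2**31))))
        model, history = train_model(
            model, (images[tr_idx], labels[tr_idx]), (images[val_idx], labels[val_idx]),
            replace(train_config, seed=int(rng.integers(2**31))))
        entry = {"fold": f, "val_indices": val_idx,
                 "val_dice": max(h["val_dice"] for h in history),
                 "val_loss": min(h["val_loss"] for h in history)}
        if metric_fn is not None:
            entry.update(metric_fn(model, images[val_idx], labels[val_idx]))
        results.append(entry)
    keys = [k for k in results[0] if isinstance(results[0][k], float)]
    agg = {"folds": results,
           "mean": {k: float(np.mean([r[k] for r in results])) for k in keys},
           "sd": {k: float(np.std([r[k] for r in results], ddof=1)) for k in keys}}
    return agg
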