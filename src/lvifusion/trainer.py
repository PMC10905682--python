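"""Training loop: class-weighted cross-entropy, Adam, flip augmentation,
checkpoint selection by minimum training loss.

The LVI-positive class is the rare one, so the loss weights default to
(0.25, 0.75) for (negative, positive).  Training is fully deterministic
given the config seed: initialization lives in the model seed, while data
order and flip masks derive from ``TrainConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import nn
from .backbone import Network
from .preprocess import flip_tensor

__all__ = ["TrainConfig", "TrainHistory", "weighted_cross_entropy", "train_model",
           "select_checkpoint", "argmin_epoch"]

_EPS = 1e-12


@dataclass
class TrainConfig:
    loss_weights: tuple[float, float] = (0.25, 0.75)
    learning_rate: float = 1e-4
    batch_size: int = 48
    epochs: int = 100
    seed: int = 0
    checkpoint_rule: str = "min_train_loss"  # or "min_val_loss"
    augment: bool = True
    betas: tuple[float, float] = (0.9, 0.999)

    def __post_init__(self) -> None:
        if any(w <= 0 for w in self.loss_weights):
            raise ValueError("loss weights must be positive")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")
        if self.checkpoint_rule not in ("min_train_loss", "min_val_loss"):
            raise ValueError(f"unknown checkpoint rule {self.checkpoint_rule!r}")


@dataclass
class TrainHistory:
    train_losses: list[float] = field(default_factory=list)
    val_losses: list[float] = field(default_factory=list)
    val_aucs: list[float] = field(default_factory=list)
    snapshots: dict[str, tuple[int, dict]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.train_losses)

    def save_log(self, path) -> None:
        """Write one JSON record per epoch (training log)."""
        import json

        with open(path, "w") as fh:
            for e, loss in enumerate(self.train_losses):
                rec: dict = {"epoch": e, "train_loss": loss}
                if e < len(self.val_losses):
                    rec["val_loss"] = self.val_losses[e]
                    rec["val_auc"] = self.val_aucs[e]
                fh.write(json.dumps(rec) + "\n")


def weighted_cross_entropy(
    probs: np.ndarray, labels: np.ndarray, weights: Sequence[float] = (0.25, 0.75)
) -> float:
    """Mean of -w_label * log(p_label) over the batch (epsilon-clamped)."""
    probs = np.atleast_2d(np.asarray(probs, dtype=float))
    labels = np.atleast_1d(np.asarray(labels))
    if np.any((labels != 0) & (labels != 1)):
        raise ValueError("labels must be binary")
    w = np.asarray(weights, dtype=float)[labels]
    p = np.clip(probs[np.arange(len(labels)), labels], _EPS, None)
    return float(np.mean(-w * np.log(p)))


def _loss_and_grad(logits: np.ndarray, labels: np.ndarray, weights) -> tuple[float, np.ndarray]:
    probs = nn.softmax(logits)
    loss = weighted_cross_entropy(probs, labels, weights)
    onehot = np.eye(logits.shape[1], dtype=np.float32)[labels]
    w = np.asarray(weights, dtype=np.float32)[labels][:, None]
    dlogits = w * (probs.astype(np.float32) - onehot) / len(labels)
    return loss, dlogits


def _eval_loss(model: Network, x: np.ndarray, y: np.ndarray, weights, batch: int) -> tuple[float, np.ndarray]:
    losses, scores = [], []
    for i in range(0, len(y), batch):
        logits = model.forward(x[i : i + batch], training=False)
        p = nn.softmax(logits)
        losses.append(weighted_cross_entropy(p, y[i : i + batch], weights) * len(p))
        scores.append(p[:, 1])
    return float(np.sum(losses) / len(y)), np.concatenate(scores)


def _maybe_snapshot(history: TrainHistory, model: Network, rule: str, losses: list[float]) -> None:
    # strict improvement only, so ties keep the earlier epoch
    epoch = len(losses) - 1
    best = history.snapshots.get(rule)
    if best is None or losses[epoch] < losses[best[0]]:
        history.snapshots[rule] = (epoch, model.state_dict())


def train_model(
    model: Network,
    train_x: np.ndarray,
    train_y: np.ndarray,
    cfg: TrainConfig,
    val_x: np.ndarray | None = None,
    val_y: np.ndarray | None = None,
) -> tuple[Network, TrainHistory]:
    """Train in place; returns the model and its per-epoch history.

    Flip augmentation redraws a mask per sample per epoch (applied jointly to
    all channels, so constant prior planes are unaffected).  Non-finite loss
    aborts with diagnostics.
    """
    train_x = np.asarray(train_x, dtype=np.float32)
    train_y = np.asarray(train_y)
    n = len(train_y)
    if n == 0:
        raise ValueError("training set is empty")
    batch = min(cfg.batch_size, n)
    rng = np.random.default_rng(cfg.seed)
    opt = nn.Adam(model.layers, lr=cfg.learning_rate, betas=cfg.betas)
    history = TrainHistory()

    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, batch):
            idx = order[start : start + batch]
            xb = train_x[idx]
            if cfg.augment:
                masks = rng.random((len(idx), 3)) < 0.5
                xb = np.stack([flip_tensor(x, m) for x, m in zip(xb, masks)])
            logits = model.forward(xb, training=True)
            loss, dlogits = _loss_and_grad(logits, train_y[idx], cfg.loss_weights)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}, batch start {start}: "
                    f"lr={cfg.learning_rate}, batch mean={float(xb.mean()):.4g}, "
                    f"logit range=({float(logits.min()):.4g}, {float(logits.max()):.4g})"
                )
            model.backward(dlogits)
            opt.step()
            epoch_loss += loss * len(idx)
        history.train_losses.append(epoch_loss / n)
        _maybe_snapshot(history, model, "min_train_loss", history.train_losses)
        if val_x is not None:
            vloss, vscores = _eval_loss(model, val_x, val_y, cfg.loss_weights, batch)
            history.val_losses.append(vloss)
            history.val_aucs.append(_auc(vscores, val_y))
            _maybe_snapshot(history, model, "min_val_loss", history.val_losses)
    return model, history


def _auc(scores: np.ndarray, labels: np.ndarray) -> float:
    from .evaluation import compute_roc_auc

    if len(np.unique(labels)) < 2:
        return float("nan")
    return compute_roc_auc(scores, labels).auc


def argmin_epoch(losses: Sequence[float]) -> int:
    """Index of the smallest loss; ties broken toward the earlier epoch."""
    if len(losses) == 0:
        raise ValueError("empty loss history")
    return int(np.argmin(losses))  # argmin returns the first minimum


def select_checkpoint(history: TrainHistory, rule: str = "min_train_loss") -> tuple[int, dict]:
    """Return (epoch, model state) selected by the checkpoint rule."""
    losses = history.train_losses if rule == "min_train_loss" else history.val_losses
    if not losses:
        raise ValueError(f"no recorded history for rule {rule!r}")
    epoch = argmin_epoch(losses)
    snap = history.snapshots.get(rule)
    if snap is None or snap[0] != epoch:  # pragma: no cover - defensive
        raise ValueError("no snapshot recorded for the selected epoch")
    return snap
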