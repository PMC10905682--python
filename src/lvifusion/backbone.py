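"""The prior-conditioned multimodal 3D classification network.

Architecture: a head block (conv in_channels->head_channels, BN3d, ReLU,
factor-2 max pooling), a stack of residual channel-attention blocks (RCABs)
at constant width, and a tail (1^3 conv head_channels->2, global average
pooling) whose two logits pass through a softmax to give the LVI risk
probability.  With 19 input channels (3 image patches + 16 prior planes)
this is the prior-conditioned network; with 3 input channels it is the
image-only ablation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import nn
from .nn import softmax

__all__ = ["NetConfig", "Network", "build_network", "predict_proba", "expected_n_params"]


@dataclass
class NetConfig:
    in_channels: int = 19
    head_channels: int = 64
    n_rcab: int = 4
    kernel: int = 3
    attention_reduction: int = 8
    pool: int = 2
    n_classes: int = 2

    def __post_init__(self) -> None:
        if self.head_channels % self.attention_reduction:
            raise ValueError("head_channels must be divisible by attention_reduction")
        if self.n_rcab < 1:
            raise ValueError("need at least one residual block")
        if self.in_channels < 1 or self.n_classes < 2:
            raise ValueError("invalid channel/class counts")


class Network:
    """Forward/backward container over the layer stack."""

    def __init__(self, cfg: NetConfig, seed: int = 0) -> None:
        self.cfg = cfg
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.head_conv = nn.Conv3d(
            cfg.in_channels, cfg.head_channels, cfg.kernel, rng=rng, input_grad=False
        )
        self.head_bn = nn.BatchNorm3d(cfg.head_channels)
        self.head_relu = nn.ReLU()
        self.head_pool = nn.MaxPool3d(cfg.pool)
        self.blocks = [
            nn.RCAB(cfg.head_channels, cfg.attention_reduction, cfg.kernel, rng=rng)
            for _ in range(cfg.n_rcab)
        ]
        self.tail_conv = nn.Conv3d(cfg.head_channels, cfg.n_classes, kernel=1, rng=rng)
        self.gap = nn.GlobalAvgPool()
        self.layers = [self.head_conv, self.head_bn, self.head_relu, self.head_pool,
                       *self.blocks, self.tail_conv, self.gap]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Logits of shape (N, n_classes)."""
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 4:
            x = x[None]
        if x.shape[1] != self.cfg.in_channels:
            raise ValueError(
                f"input has {x.shape[1]} channels; network expects {self.cfg.in_channels}"
            )
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, dlogits: np.ndarray) -> None:
        g = dlogits
        for layer in reversed(self.layers):
            g = layer.backward(g)

    def parameter_count(self) -> int:
        return sum(layer.n_params() for layer in self.layers)

    # -- state handling -------------------------------------------------
    def _stat_slots(self):
        for i, layer in enumerate(self.layers):
            if isinstance(layer, nn.BatchNorm3d):
                yield f"{i}.running_mean", layer, "running_mean"
                yield f"{i}.running_var", layer, "running_var"

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for i, layer in enumerate(self.layers):
            for j, (sub, key) in enumerate(nn._walk(layer)):
                state[f"{i}.{j}.{key}"] = sub.params[key].copy()
        for name, layer, attr in self._stat_slots():
            state[name] = getattr(layer, attr).copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            for j, (sub, key) in enumerate(nn._walk(layer)):
                sub.params[key] = state[f"{i}.{j}.{key}"].copy()
        for name, layer, attr in self._stat_slots():
            setattr(layer, attr, state[name].copy())

    def summary(self) -> dict:
        return {"config": asdict(self.cfg), "seed": self.seed,
                "n_params": self.parameter_count()}

    def save(self, path: str | Path) -> None:
        """Checkpoint: parameter arrays (npz) plus a JSON config echo."""
        path = Path(path)
        flat = {}
        for i, layer in enumerate(self.layers):
            for j, (sub, key) in enumerate(nn._walk(layer)):
                flat[f"p{i}_{j}_{key}"] = sub.params[key]
        for name, layer, attr in self._stat_slots():
            flat["s_" + name.replace(".", "_")] = getattr(layer, attr)
        np.savez(path.with_suffix(".npz"), **flat)
        path.with_suffix(".json").write_text(json.dumps(self.summary(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "Network":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        model = cls(NetConfig(**meta["config"]), seed=meta["seed"])
        data = np.load(path.with_suffix(".npz"))
        for i, layer in enumerate(model.layers):
            for j, (sub, key) in enumerate(nn._walk(layer)):
                sub.params[key] = data[f"p{i}_{j}_{key}"].copy()
        for name, layer, attr in model._stat_slots():
            setattr(layer, attr, data["s_" + name.replace(".", "_")].copy())
        return model


def build_network(cfg: NetConfig, seed: int = 0) -> Network:
    """Build the network; ``cfg.in_channels=19`` gives the prior-conditioned
    model, ``cfg.in_channels=3`` the image-only ablation."""
    return Network(cfg, seed=seed)


def predict_proba(model: Network, x: np.ndarray) -> np.ndarray:
    """Class probabilities (N, 2) in inference mode (frozen BN statistics)."""
    logits = model.forward(np.asarray(x, dtype=np.float32), training=False)
    return softmax(logits)


def expected_n_params(cfg: NetConfig) -> int:
    """Closed-form parameter count implied by the declared layer stack."""
    k3 = cfg.kernel**3
    c = cfg.head_channels
    head = cfg.in_channels * c * k3 + c + 2 * c  # conv + BN affine
    hidden = c // cfg.attention_reduction
    ca = c * hidden + hidden + hidden * c + c
    rcab = 2 * (c * c * k3 + c) + ca
    tail = c * cfg.n_classes + cfg.n_classes
    return head + cfg.n_rcab * rcab + tail
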