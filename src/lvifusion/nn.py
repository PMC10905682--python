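"""Minimal 3D neural-network layers in numpy (float32, NCDHW layout).

3^3 convolutions run in the frequency domain (real FFT per spatial axis,
channel contraction as a batched matrix product over frequency bins), which
on a single CPU is substantially faster than im2col gathering for the
volume sizes this package trains on; 1^3 convolutions are plain channel
matrix products.  Every layer stores what its backward pass needs during a
training forward pass and releases it afterwards; inference
(``training=False``) stores nothing and uses batch-norm running statistics.

Only stride 1 with same-padding (kernel 3) or no padding (kernel 1) is
supported — exactly what the backbone uses.
"""

from __future__ import annotations

import numpy as np
from scipy import fft as sfft

__all__ = [
    "Layer",
    "Conv3d",
    "BatchNorm3d",
    "ReLU",
    "MaxPool3d",
    "GlobalAvgPool",
    "ChannelAttention",
    "RCAB",
    "Adam",
    "softmax",
]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class Layer:
    """Base layer: dict-of-array parameters and matching gradients."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def n_params(self) -> int:
        return int(sum(p.size for p in self.params.values()))


def _freq_matmul(af: np.ndarray, bf: np.ndarray) -> np.ndarray:
    """Contract (A, C, *freq) with (B, C, *freq) over C -> (A, B, *freq)."""
    a, c = af.shape[:2]
    b = bf.shape[0]
    freq = af.shape[2:]
    am = af.reshape(a, c, -1).transpose(2, 0, 1)  # (F, A, C)
    bm = bf.reshape(b, c, -1).transpose(2, 1, 0)  # (F, C, B)
    return np.matmul(am, bm).transpose(1, 2, 0).reshape(a, b, *freq)


class Conv3d(Layer):
    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: int = 3,
        rng: np.random.Generator | None = None,
        zero_init: bool = False,
        input_grad: bool = True,
    ) -> None:
        super().__init__()
        if kernel not in (1, 3):
            raise ValueError("only 1^3 and 3^3 kernels are supported")
        self.kernel = kernel
        self.pad = kernel // 2
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.input_grad = input_grad  # first layer skips dX
        fan_in = in_channels * kernel**3
        if zero_init:
            w = np.zeros((out_channels, in_channels) + (kernel,) * 3, dtype=np.float32)
        else:
            rng = rng or np.random.default_rng()
            w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (out_channels, in_channels) + (kernel,) * 3)
        self.params = {"w": w.astype(np.float32), "b": np.zeros(out_channels, dtype=np.float32)}
        self._cache = None

    # ---- 1^3 kernel: plain channel matmul --------------------------------
    def _forward1(self, x: np.ndarray, training: bool) -> np.ndarray:
        wmat = self.params["w"].reshape(self.out_channels, self.in_channels)
        y = np.tensordot(x, wmat, axes=([1], [1]))  # (N, D, H, W, out)
        y += self.params["b"]
        if training:
            self._cache = x
        return np.ascontiguousarray(y.transpose(0, 4, 1, 2, 3))

    def _backward1(self, grad: np.ndarray) -> np.ndarray:
        x = self._cache
        self._cache = None
        wmat = self.params["w"].reshape(self.out_channels, self.in_channels)
        self.grads["w"] = np.einsum("nodhw,ncdhw->oc", grad, x).reshape(self.params["w"].shape)
        self.grads["b"] = grad.sum(axis=(0, 2, 3, 4))
        if not self.input_grad:
            return np.zeros_like(x)
        dx = np.tensordot(grad, wmat, axes=([1], [0]))  # (N, D, H, W, in)
        return np.ascontiguousarray(dx.transpose(0, 4, 1, 2, 3))

    # ---- 3^3 kernel: frequency domain ------------------------------------
    def _fft_sizes(self, spatial: tuple[int, ...]) -> tuple[int, ...]:
        return tuple(sfft.next_fast_len(s + self.kernel - 1) for s in spatial)

    def _forward3(self, x: np.ndarray, training: bool) -> np.ndarray:
        spatial = x.shape[2:]
        sizes = self._fft_sizes(spatial)
        xf = sfft.rfftn(x, s=sizes, axes=(2, 3, 4))
        wflip = self.params["w"][:, :, ::-1, ::-1, ::-1]
        wf = sfft.rfftn(wflip.astype(np.float32), s=sizes, axes=(2, 3, 4))
        yf = _freq_matmul(xf, wf)
        y = sfft.irfftn(yf, s=sizes, axes=(2, 3, 4))
        p = self.pad
        sl = tuple(slice(p, p + s) for s in spatial)
        y = np.ascontiguousarray(y[(slice(None), slice(None)) + sl])
        y += self.params["b"][None, :, None, None, None]
        if training:
            self._cache = (xf, x.shape, sizes)
        return y.astype(np.float32)

    def _backward3(self, grad: np.ndarray) -> np.ndarray:
        xf, x_shape, sizes = self._cache
        self._cache = None
        spatial = x_shape[2:]
        p = self.pad
        gf = sfft.rfftn(grad, s=sizes, axes=(2, 3, 4))
        # dW[o,c,q] = sum_p g[p] x[p+q-pad]: circular cross-correlation of x
        # with g, sampled at the kernel lags.
        cf = _freq_matmul(
            np.conj(gf).transpose(1, 0, 2, 3, 4), xf.transpose(1, 0, 2, 3, 4)
        )  # (out, in, *freq)
        cc = sfft.irfftn(cf, s=sizes, axes=(2, 3, 4))
        lag = [np.asarray([(q - p) % L for q in range(self.kernel)]) for L in sizes]
        self.grads["w"] = cc[np.ix_(np.arange(cc.shape[0]), np.arange(cc.shape[1]), *lag)].astype(
            np.float32
        )
        self.grads["b"] = grad.sum(axis=(0, 2, 3, 4)).astype(np.float32)
        if not self.input_grad:
            return np.zeros(x_shape, dtype=np.float32)
        wfu = sfft.rfftn(self.params["w"], s=sizes, axes=(2, 3, 4))  # unflipped
        df = _freq_matmul(gf, wfu.transpose(1, 0, 2, 3, 4))  # (N, in, *f)
        dx = sfft.irfftn(df, s=sizes, axes=(2, 3, 4))
        sl = tuple(slice(p, p + s) for s in spatial)
        return np.ascontiguousarray(dx[(slice(None), slice(None)) + sl]).astype(np.float32)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if x.shape[1] != self.in_channels:
            raise ValueError(f"expected {self.in_channels} input channels, got {x.shape[1]}")
        if self.kernel == 1:
            return self._forward1(x, training)
        return self._forward3(x, training)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self.kernel == 1:
            return self._backward1(grad)
        return self._backward3(grad)


class BatchNorm3d(Layer):
    """Channel-wise batch normalization over (N, D, H, W); running averages
    are frozen and used at inference."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5) -> None:
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.params = {
            "gamma": np.ones(channels, dtype=np.float32),
            "beta": np.zeros(channels, dtype=np.float32),
        }
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self._cache = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        axes = (0, 2, 3, 4)
        shape = (1, -1, 1, 1, 1)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = ((1 - self.momentum) * self.running_mean + self.momentum * mean).astype(np.float32)
            self.running_var = ((1 - self.momentum) * self.running_var + self.momentum * var).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(shape)) * invstd.reshape(shape)
        if training:
            self._cache = (xhat, invstd)
        return (self.params["gamma"].reshape(shape) * xhat + self.params["beta"].reshape(shape)).astype(np.float32)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, invstd = self._cache
        self._cache = None
        axes = (0, 2, 3, 4)
        shape = (1, -1, 1, 1, 1)
        m = grad.shape[0] * grad.shape[2] * grad.shape[3] * grad.shape[4]
        dbeta = grad.sum(axis=axes)
        dgamma = (grad * xhat).sum(axis=axes)
        self.grads["gamma"] = dgamma
        self.grads["beta"] = dbeta
        coef = (self.params["gamma"] * invstd / m).reshape(shape)
        dx = coef * (m * grad - dbeta.reshape(shape) - xhat * dgamma.reshape(shape))
        return dx.astype(np.float32)


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        y = np.maximum(x, 0.0)
        if training:
            self._mask = x > 0
        return y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = grad * self._mask
        self._mask = None
        return g


class MaxPool3d(Layer):
    def __init__(self, factor: int = 2) -> None:
        super().__init__()
        self.factor = factor

    def _blocks(self, x: np.ndarray) -> np.ndarray:
        f = self.factor
        n, c, d, h, w = x.shape
        if d % f or h % f or w % f:
            raise ValueError("spatial dims must be divisible by the pooling factor")
        v = x.reshape(n, c, d // f, f, h // f, f, w // f, f)
        return np.ascontiguousarray(v.transpose(0, 1, 2, 4, 6, 3, 5, 7)).reshape(
            n, c, d // f, h // f, w // f, f**3
        )

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        blocks = self._blocks(x)
        idx = blocks.argmax(axis=-1)
        y = np.take_along_axis(blocks, idx[..., None], axis=-1)[..., 0]
        if training:
            self._idx = idx
            self._in_shape = x.shape
        return y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        f = self.factor
        n, c, d, h, w = self._in_shape
        z = np.zeros((n, c, d // f, h // f, w // f, f**3), dtype=grad.dtype)
        np.put_along_axis(z, self._idx[..., None], grad[..., None], axis=-1)
        self._idx = None
        z = z.reshape(n, c, d // f, h // f, w // f, f, f, f).transpose(0, 1, 2, 5, 3, 6, 4, 7)
        return np.ascontiguousarray(z).reshape(n, c, d, h, w)


class GlobalAvgPool(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            self._shape = x.shape
        return x.mean(axis=(2, 3, 4))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, d, h, w = self._shape
        return np.broadcast_to(grad[:, :, None, None, None] / (d * h * w), self._shape).astype(
            np.float32
        )


class ChannelAttention(Layer):
    """Squeeze-and-excitation gate: sigmoid(MLP(global-average descriptor))
    rescales each channel; weights lie strictly in (0, 1)."""

    def __init__(self, channels: int, reduction: int, rng: np.random.Generator | None = None) -> None:
        super().__init__()
        if channels % reduction:
            raise ValueError("attention reduction must divide the channel count")
        hidden = channels // reduction
        rng = rng or np.random.default_rng()
        self.params = {
            "w1": rng.normal(0.0, np.sqrt(2.0 / channels), (channels, hidden)).astype(np.float32),
            "b1": np.zeros(hidden, dtype=np.float32),
            "w2": rng.normal(0.0, np.sqrt(2.0 / hidden), (hidden, channels)).astype(np.float32),
            "b2": np.zeros(channels, dtype=np.float32),
        }

    def gate(self, x: np.ndarray) -> np.ndarray:
        """Per-channel attention weights in (0, 1) for a batch."""
        z = x.mean(axis=(2, 3, 4))
        h = np.maximum(z @ self.params["w1"] + self.params["b1"], 0.0)
        return 1.0 / (1.0 + np.exp(-(h @ self.params["w2"] + self.params["b2"])))

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        z = x.mean(axis=(2, 3, 4))
        hpre = z @ self.params["w1"] + self.params["b1"]
        h = np.maximum(hpre, 0.0)
        s = 1.0 / (1.0 + np.exp(-(h @ self.params["w2"] + self.params["b2"])))
        if training:
            self._cache = (x, z, hpre, h, s)
        return (x * s[:, :, None, None, None]).astype(np.float32)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x, z, hpre, h, s = self._cache
        self._cache = None
        p = x.shape[2] * x.shape[3] * x.shape[4]
        ds = (grad * x).sum(axis=(2, 3, 4))
        dx = grad * s[:, :, None, None, None]
        dpre2 = ds * s * (1.0 - s)
        self.grads["w2"] = h.T @ dpre2
        self.grads["b2"] = dpre2.sum(axis=0)
        dh = dpre2 @ self.params["w2"].T
        dpre1 = dh * (hpre > 0)
        self.grads["w1"] = z.T @ dpre1
        self.grads["b1"] = dpre1.sum(axis=0)
        dz = dpre1 @ self.params["w1"].T
        return (dx + dz[:, :, None, None, None] / p).astype(np.float32)


class RCAB(Layer):
    """Residual channel-attention block: x + CA(conv(ReLU(conv(x)))).

    The second convolution is zero-initialized so an untrained block starts
    as the identity map.
    """

    def __init__(self, channels: int, reduction: int, kernel: int = 3,
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        self.conv1 = Conv3d(channels, channels, kernel, rng=rng)
        self.relu = ReLU()
        self.conv2 = Conv3d(channels, channels, kernel, zero_init=True)
        self.ca = ChannelAttention(channels, reduction, rng=rng)
        self.children = [self.conv1, self.relu, self.conv2, self.ca]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        y = self.conv1.forward(x, training)
        y = self.relu.forward(y, training)
        y = self.conv2.forward(y, training)
        y = self.ca.forward(y, training)
        return x + y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = self.ca.backward(grad)
        g = self.conv2.backward(g)
        g = self.relu.backward(g)
        g = self.conv1.backward(g)
        return grad + g

    def n_params(self) -> int:
        return sum(c.n_params() for c in self.children)


def _walk(layer: Layer):
    """Yield (layer, key) pairs for every parameter array, depth-first."""
    children = getattr(layer, "children", None)
    if children:
        for c in children:
            yield from _walk(c)
    else:
        for k in layer.params:
            yield layer, k


class Adam:
    """Adam over the parameters of a list of layers; deterministic given the
    layer order and gradients."""

    def __init__(self, layers, lr: float = 1e-4, betas=(0.9, 0.999), eps: float = 1e-8) -> None:
        self.slots = [lk for layer in layers for lk in _walk(layer)]
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(layer.params[k]) for layer, k in self.slots]
        self.v = [np.zeros_like(layer.params[k]) for layer, k in self.slots]

    def step(self) -> None:
        self.t += 1
        for i, (layer, k) in enumerate(self.slots):
            g = layer.grads[k].astype(np.float32)
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            layer.params[k] -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(np.float32)
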