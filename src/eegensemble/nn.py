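"""Minimal NumPy neural-network core for the seizure detector.

Implements exactly the pieces the detector architecture needs — 1-D
convolution (valid, stride 1), batch normalization, ReLU, max pooling,
global average pooling, a linear layer, additive channel attention, and a
softmax cross-entropy head — each with a hand-derived backward pass, plus
the Adam optimizer.  Everything is deterministic given a seed: weights are
initialized with fan-in-scaled uniform draws from a caller-supplied
generator, and no operation introduces hidden randomness.

Tensors follow the (batch, channels, length) convention.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Conv1d",
    "BatchNorm1d",
    "ReLU",
    "MaxPool1d",
    "GlobalAvgPool",
    "Linear",
    "ChannelAttention",
    "Sequential",
    "Adam",
    "softmax",
    "cross_entropy_with_grad",
]


def _uniform_init(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape)


class Layer:
    """Base class: trainable arrays live in ``params``, gradients in ``grads``."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.buffers: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def n_params(self) -> int:
        return sum(int(p.size) for p in self.params.values())


class Conv1d(Layer):
    """Valid cross-correlation, stride 1: (B, Cin, L) → (B, Cout, L−K+1)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        fan_in = c_in * kernel
        self.params["W"] = _uniform_init(rng, (c_out, c_in, kernel), fan_in)
        self.params["b"] = _uniform_init(rng, (c_out,), fan_in)
        self.kernel = kernel

    def forward(self, x, train):
        self._x = x
        v = sliding_window_view(x, self.kernel, axis=2)  # (B, Cin, Lo, K)
        y = np.einsum("bilk,oik->bol", v, self.params["W"], optimize=True)
        return y + self.params["b"][None, :, None]

    def backward(self, gy):
        x, W, K = self._x, self.params["W"], self.kernel
        v = sliding_window_view(x, K, axis=2)
        self.grads["W"] = np.einsum("bilk,bol->oik", v, gy, optimize=True)
        self.grads["b"] = gy.sum(axis=(0, 2))
        gp = np.pad(gy, ((0, 0), (0, 0), (K - 1, K - 1)))
        win = sliding_window_view(gp, K, axis=2)  # (B, Cout, L, K)
        return np.einsum("bolk,oik->bil", win, W[:, :, ::-1], optimize=True)


class BatchNorm1d(Layer):
    """Per-feature-map normalization over (batch, length)."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.params["gamma"] = np.ones(c)
        self.params["beta"] = np.zeros(c)
        self.buffers["running_mean"] = np.zeros(c)
        self.buffers["running_var"] = np.ones(c)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x, train):
        if train:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            m = self.momentum
            self.buffers["running_mean"] = (1 - m) * self.buffers["running_mean"] + m * mean
            self.buffers["running_var"] = (1 - m) * self.buffers["running_var"] + m * var
        else:
            mean = self.buffers["running_mean"]
            var = self.buffers["running_var"]
        self._train = train
        self._inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean[None, :, None]) * self._inv[None, :, None]
        return self.params["gamma"][None, :, None] * self._xhat + self.params["beta"][None, :, None]

    def backward(self, gy):
        xhat = self._xhat
        self.grads["gamma"] = (gy * xhat).sum(axis=(0, 2))
        self.grads["beta"] = gy.sum(axis=(0, 2))
        coeff = (self.params["gamma"] * self._inv)[None, :, None]
        if not self._train:
            # eval mode: the normalization constants are fixed buffers
            return coeff * gy
        g_mean = gy.mean(axis=(0, 2))
        gx_mean = (gy * xhat).mean(axis=(0, 2))
        return coeff * (gy - g_mean[None, :, None] - xhat * gx_mean[None, :, None])


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, gy):
        return gy * self._mask


class MaxPool1d(Layer):
    """Non-overlapping max pooling; trailing remainder samples are dropped."""

    def __init__(self, pool: int = 2):
        super().__init__()
        self.pool = pool

    def forward(self, x, train):
        b, c, l = x.shape
        lo = l // self.pool
        self._in_len = l
        xr = x[:, :, : lo * self.pool].reshape(b, c, lo, self.pool)
        self._arg = xr.argmax(axis=3)
        return xr.max(axis=3)

    def backward(self, gy):
        b, c, lo = gy.shape
        gx = np.zeros((b, c, lo, self.pool))
        bi, ci, li = np.ogrid[:b, :c, :lo]
        gx[bi, ci, li, self._arg] = gy
        gx = gx.reshape(b, c, lo * self.pool)
        if lo * self.pool < self._in_len:
            gx = np.pad(gx, ((0, 0), (0, 0), (0, self._in_len - lo * self.pool)))
        return gx


class GlobalAvgPool(Layer):
    """(B, C, L) → (B, C)."""

    def forward(self, x, train):
        self._l = x.shape[2]
        return x.mean(axis=2)

    def backward(self, gy):
        return np.repeat(gy[:, :, None], self._l, axis=2) / self._l


class Linear(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        super().__init__()
        self.params["W"] = _uniform_init(rng, (d_in, d_out), d_in)
        self.params["b"] = _uniform_init(rng, (d_out,), d_in)

    def forward(self, x, train):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, gy):
        self.grads["W"] = self._x.T @ gy
        self.grads["b"] = gy.sum(axis=0)
        return gy @ self.params["W"].T


class ChannelAttention(Layer):
    """Additive attention collapsing C per-channel feature vectors into one.

    Scores ``e_c = v · tanh(W f_c + b)`` are softmax-normalized over the
    channel axis and used as weights for the sum ``Σ_c α_c f_c``.  The
    parameter count depends only on the feature dimension, never on the
    number of channels, and the output is invariant to channel permutation.
    """

    def __init__(self, d: int, hidden: int, rng: np.random.Generator):
        super().__init__()
        self.params["W"] = _uniform_init(rng, (d, hidden), d)
        self.params["b"] = _uniform_init(rng, (hidden,), d)
        self.params["v"] = _uniform_init(rng, (hidden,), hidden)

    def forward(self, f, train):
        # f: (N, C, d)
        self._f = f
        self._h = np.tanh(f @ self.params["W"] + self.params["b"])  # (N, C, H)
        e = self._h @ self.params["v"]  # (N, C)
        e = e - e.max(axis=1, keepdims=True)
        ex = np.exp(e)
        self._alpha = ex / ex.sum(axis=1, keepdims=True)
        return np.einsum("nc,ncd->nd", self._alpha, f, optimize=True)

    def backward(self, go):
        f, h, alpha = self._f, self._h, self._alpha
        # value path
        gf = alpha[:, :, None] * go[:, None, :]
        # score path
        g_alpha = np.einsum("nd,ncd->nc", go, f, optimize=True)
        ge = alpha * (g_alpha - (alpha * g_alpha).sum(axis=1, keepdims=True))
        self.grads["v"] = np.einsum("nch,nc->h", h, ge, optimize=True)
        gh = ge[:, :, None] * self.params["v"][None, None, :]
        gpre = gh * (1.0 - h * h)
        self.grads["W"] = np.einsum("ncd,nch->dh", f, gpre, optimize=True)
        self.grads["b"] = gpre.sum(axis=(0, 1))
        gf += gpre @ self.params["W"].T
        return gf


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x, train):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, gy):
        for layer in reversed(self.layers):
            gy = layer.backward(gy)
        return gy

    def n_params(self) -> int:
        return sum(l.n_params() for l in self.layers)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=1, keepdims=True)


def cross_entropy_with_grad(logits: np.ndarray, targets: np.ndarray):
    """Mean cross entropy over the batch and its gradient wrt the logits."""
    n = logits.shape[0]
    p = softmax(logits)
    eps = 1e-12
    loss = -float(np.mean(np.log(p[np.arange(n), targets] + eps)))
    grad = p.copy()
    grad[np.arange(n), targets] -= 1.0
    return loss, grad / n


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, layers: list[Layer], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.layers = [l for l in layers if l.params]
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]
        self.v = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]

    def step(self) -> None:
        self.t += 1
        bc1 = 1 - self.b1**self.t
        bc2 = 1 - self.b2**self.t
        for layer, m, v in zip(self.layers, self.m, self.v):
            for k, p in layer.params.items():
                g = layer.grads[k]
                m[k] = self.b1 * m[k] + (1 - self.b1) * g
                v[k] = self.b2 * v[k] + (1 - self.b2) * g * g
                p -= self.lr * (m[k] / bc1) / (np.sqrt(v[k] / bc2) + self.eps)
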