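"""A small, fully deterministic conv-net engine on numpy.

This backs the adversarial translation networks.  It provides exactly the
pieces those networks need — strided convolution (via im2col), batch
normalization with running statistics, ReLU/tanh, nearest-neighbour
upsampling, a residual block and Adam — with explicit layer-wise
backpropagation.  Forward caches are kept on a stack, so a module can be run
several times per iteration (as both generators are in a cycle-consistent
step) and backpropagated in reverse order of the forward calls.

All state is plain float64 numpy; given a seeded initialization the whole
training loop is bit-reproducible.
"""

from __future__ import annotations

from typing import Dict, List

import numpy as np
from numpy.lib.stride_tricks import as_strided

__all__ = ["Param", "Layer", "Conv2d", "BatchNorm2d", "ReLU", "Tanh",
           "Upsample2x", "Sequential", "Residual", "Adam"]


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = np.zeros_like(self.data)


class Layer:
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> List[Param]:
        return []

    def state(self) -> Dict[str, np.ndarray]:
        """Non-trainable buffers (e.g. batchnorm running stats)."""
        return {}

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    def clear_cache(self) -> None:
        if hasattr(self, "_cache"):
            self._cache.clear()


def _im2col(x: np.ndarray, k: int, stride: int) -> np.ndarray:
    N, C, H, W = x.shape
    Ho = (H - k) // stride + 1
    Wo = (W - k) // stride + 1
    s = x.strides
    cols = as_strided(x, (N, C, k, k, Ho, Wo),
                      (s[0], s[1], s[2], s[3], s[2] * stride, s[3] * stride))
    return np.ascontiguousarray(cols).reshape(N, C * k * k, Ho * Wo), Ho, Wo


class Conv2d(Layer):
    """2-D convolution, square kernel, symmetric zero padding."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int = 3,
                 stride: int = 1, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        fan_in = in_ch * kernel * kernel
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (out_ch, in_ch, kernel, kernel))
        self.weight = Param(w)
        self.bias = Param(np.zeros(out_ch))
        self.kernel = kernel
        self.stride = stride
        self.pad = kernel // 2
        self._cache: list = []

    def forward(self, x, train=True):
        k, s, p = self.kernel, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        cols, Ho, Wo = _im2col(xp, k, s)
        Wm = self.weight.data.reshape(self.weight.data.shape[0], -1)
        y = np.einsum("fk,nkl->nfl", Wm, cols) + self.bias.data[None, :, None]
        if train:
            self._cache.append((cols, x.shape))
        return y.reshape(x.shape[0], -1, Ho, Wo)

    def backward(self, dy):
        cols, x_shape = self._cache.pop()
        N, C, H, W = x_shape
        k, s, p = self.kernel, self.stride, self.pad
        F = dy.shape[1]
        Ho, Wo = dy.shape[2], dy.shape[3]
        dyf = dy.reshape(N, F, Ho * Wo)
        Wm = self.weight.data.reshape(F, -1)
        self.weight.grad += np.einsum("nfl,nkl->fk", dyf, cols).reshape(
            self.weight.data.shape)
        self.bias.grad += dyf.sum(axis=(0, 2))
        dcols = np.einsum("fk,nfl->nkl", Wm, dyf).reshape(N, C, k, k, Ho, Wo)
        dxp = np.zeros((N, C, H + 2 * p, W + 2 * p))
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + s * Ho:s, j:j + s * Wo:s] += dcols[:, :, i, j]
        return dxp[:, :, p:p + H, p:p + W]

    def params(self):
        return [self.weight, self.bias]


class BatchNorm2d(Layer):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps
        self._cache: list = []

    def forward(self, x, train=True):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        if train:
            self._cache.append((xhat, inv))
        return self.gamma.data[None, :, None, None] * xhat \
            + self.beta.data[None, :, None, None]

    def backward(self, dy):
        xhat, inv = self._cache.pop()
        m = dy.shape[0] * dy.shape[2] * dy.shape[3]
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        g = self.gamma.data[None, :, None, None]
        dxhat = dy * g
        term1 = dxhat
        term2 = dxhat.mean(axis=(0, 2, 3), keepdims=True)
        term3 = xhat * (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
        return inv[None, :, None, None] * (term1 - term2 - term3)

    def params(self):
        return [self.gamma, self.beta]

    def state(self):
        return {"running_mean": self.running_mean, "running_var": self.running_var}


class ReLU(Layer):
    def __init__(self):
        self._cache: list = []

    def forward(self, x, train=True):
        mask = x > 0
        if train:
            self._cache.append(mask)
        return x * mask

    def backward(self, dy):
        return dy * self._cache.pop()


class Tanh(Layer):
    def __init__(self):
        self._cache: list = []

    def forward(self, x, train=True):
        y = np.tanh(x)
        if train:
            self._cache.append(y)
        return y

    def backward(self, dy):
        y = self._cache.pop()
        return dy * (1.0 - y ** 2)


class Upsample2x(Layer):
    """Nearest-neighbour 2x upsampling."""

    def forward(self, x, train=True):
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dy):
        N, C, H, W = dy.shape
        return dy.reshape(N, C, H // 2, 2, W // 2, 2).sum(axis=(3, 5))


class Sequential(Layer):
    def __init__(self, layers: List[Layer]):
        self.layers = layers

    def forward(self, x, train=True):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def state(self):
        out = {}
        for i, layer in enumerate(self.layers):
            for k, v in layer.state().items():
                out[f"{i}.{k}"] = v
        return out

    def zero_grad(self):
        for layer in self.layers:
            layer.zero_grad()

    def clear_cache(self):
        for layer in self.layers:
            layer.clear_cache()


class Residual(Layer):
    """y = x + inner(x); inner must preserve shape."""

    def __init__(self, inner: Layer):
        self.inner = inner

    def forward(self, x, train=True):
        return x + self.inner.forward(x, train)

    def backward(self, dy):
        return dy + self.inner.backward(dy)

    def params(self):
        return self.inner.params()

    def state(self):
        return {f"inner.{k}": v for k, v in self.inner.state().items()}

    def zero_grad(self):
        self.inner.zero_grad()

    def clear_cache(self):
        self.inner.clear_cache()


class Adam:
    """Adam with the standard bias correction.

    The defaults (beta1=0.5, beta2=0.9) favour the short, small-batch
    adversarial runs this engine is built for over the asymptotic regime.
    """

    def __init__(self, params: List[Param], lr: float = 2e-4,
                 beta1: float = 0.5, beta2: float = 0.9, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * p.grad
            v[...] = b2 * v + (1 - b2) * p.grad ** 2
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0
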