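"""Minimal CNN building blocks on NumPy with hand-written backprop.

No deep-learning framework is available in this environment, so the few layer
types the surrogate architectures need are implemented directly: 2-D
convolution (im2col + GEMM), batch normalisation, max pooling, nearest
upsampling, inverted dropout, dense layers and the usual activations.  Every
layer caches what its backward pass needs; correctness is pinned by
finite-difference gradient checks in the test suite.

Layers default to float32 arithmetic (``DTYPE``); gradient-check tests build
them in float64.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DTYPE = np.float32


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


class Layer:
    """Base class: ``forward`` caches, ``backward`` consumes the cache."""

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[Param]:
        return []

    def set_rng(self, rng: np.random.Generator) -> None:
        pass


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def set_rng(self, rng):
        for layer in self.layers:
            layer.set_rng(rng)


class Conv2d(Layer):
    """2-D convolution, stride 1, zero padding ``pad``."""

    def __init__(self, c_in: int, c_out: int, k: int, pad: int = 0,
                 rng: np.random.Generator | None = None, dtype=DTYPE):
        rng = rng or np.random.default_rng()
        fan_in = c_in * k * k
        scale = np.sqrt(2.0 / fan_in)  # He init (ReLU follows in all uses)
        self.w = Param(rng.normal(0.0, scale, (c_out, fan_in)).astype(dtype))
        self.b = Param(np.zeros(c_out, dtype=dtype))
        self.c_in, self.c_out, self.k, self.pad = c_in, c_out, k, pad

    def forward(self, x, training=False):
        if self.pad:
            x = np.pad(x, ((0, 0), (0, 0), (self.pad,) * 2, (self.pad,) * 2))
        B, C, H, W = x.shape
        k = self.k
        Ho, Wo = H - k + 1, W - k + 1
        win = sliding_window_view(x, (k, k), axis=(2, 3))  # (B,C,Ho,Wo,k,k)
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            B * Ho * Wo, C * k * k
        )
        y = cols @ self.w.value.T + self.b.value
        self._cache = (cols, (B, C, H, W), (Ho, Wo))
        return y.reshape(B, Ho, Wo, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, grad):
        cols, (B, C, H, W), (Ho, Wo) = self._cache
        k = self.k
        g2 = np.ascontiguousarray(grad.transpose(0, 2, 3, 1)).reshape(-1, self.c_out)
        self.w.grad += g2.T @ cols
        self.b.grad += g2.sum(axis=0)
        dcols = (g2 @ self.w.value).reshape(B, Ho, Wo, C, k, k)
        dx = np.zeros((B, C, H, W), dtype=grad.dtype)
        for i in range(k):
            for j in range(k):
                dx[:, :, i : i + Ho, j : j + Wo] += dcols[:, :, :, :, i, j].transpose(
                    0, 3, 1, 2
                )
        if self.pad:
            dx = dx[:, :, self.pad : -self.pad, self.pad : -self.pad]
        self._cache = None
        return dx

    def params(self):
        return [self.w, self.b]


class Dense(Layer):
    def __init__(self, f_in: int, f_out: int, rng=None, scale: str = "he", dtype=DTYPE):
        rng = rng or np.random.default_rng()
        s = np.sqrt(2.0 / f_in) if scale == "he" else np.sqrt(1.0 / f_in)
        self.w = Param(rng.normal(0.0, s, (f_out, f_in)).astype(dtype))
        self.b = Param(np.zeros(f_out, dtype=dtype))

    def forward(self, x, training=False):
        self._x = x
        return x @ self.w.value.T + self.b.value

    def backward(self, grad):
        self.w.grad += grad.T @ self._x
        self.b.grad += grad.sum(axis=0)
        dx = grad @ self.w.value
        self._x = None
        return dx

    def params(self):
        return [self.w, self.b]


class ReLU(Layer):
    def forward(self, x, training=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        g = grad * self._mask
        self._mask = None
        return g


class Tanh(Layer):
    def forward(self, x, training=False):
        self._y = np.tanh(x)
        return self._y

    def backward(self, grad):
        g = grad * (1.0 - self._y**2)
        self._y = None
        return g


class Sigmoid(Layer):
    def forward(self, x, training=False):
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, grad):
        g = grad * self._y * (1.0 - self._y)
        self._y = None
        return g


class Flatten(Layer):
    def forward(self, x, training=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class MaxPool2(Layer):
    """2x2 max pooling; odd trailing rows/columns are dropped (floor)."""

    def forward(self, x, training=False):
        B, C, H, W = x.shape
        H2, W2 = H // 2, W // 2
        self._in_shape = x.shape
        xr = x[:, :, : 2 * H2, : 2 * W2].reshape(B, C, H2, 2, W2, 2)
        xr = xr.transpose(0, 1, 2, 4, 3, 5).reshape(B, C, H2, W2, 4)
        self._idx = xr.argmax(axis=-1)
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, grad):
        B, C, H, W = self._in_shape
        H2, W2 = H // 2, W // 2
        dxr = np.zeros((B, C, H2, W2, 4), dtype=grad.dtype)
        np.put_along_axis(dxr, self._idx[..., None], grad[..., None], axis=-1)
        dx = np.zeros((B, C, H, W), dtype=grad.dtype)
        dx[:, :, : 2 * H2, : 2 * W2] = (
            dxr.reshape(B, C, H2, W2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
                B, C, 2 * H2, 2 * W2
            )
        )
        self._idx = None
        return dx


class UpsampleNearest2(Layer):
    def forward(self, x, training=False):
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, grad):
        B, C, H, W = grad.shape
        return grad.reshape(B, C, H // 2, 2, W // 2, 2).sum(axis=(3, 5))


class Dropout(Layer):
    """Inverted dropout; active in training and in MC-dropout inference."""

    def __init__(self, p: float, rng: np.random.Generator | None = None):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must lie in [0, 1)")
        self.p = p
        self.rng = rng or np.random.default_rng()
        self.mc_active = False  # force dropout during inference (MC dropout)

    def set_rng(self, rng):
        self.rng = rng

    def forward(self, x, training=False):
        if (training or self.mc_active) and self.p > 0.0:
            self._mask = (self.rng.random(x.shape) >= self.p).astype(x.dtype) / (
                1.0 - self.p
            )
            return x * self._mask
        self._mask = None
        return x

    def backward(self, grad):
        if self._mask is None:
            return grad
        g = grad * self._mask
        self._mask = None
        return g


class BatchNorm(Layer):
    """Batch normalisation over axis 0 (+ spatial axes for 4-D input)."""

    def __init__(self, n_channels: int, momentum: float = 0.1, eps: float = 1e-5,
                 dtype=DTYPE):
        self.gamma = Param(np.ones(n_channels, dtype=dtype))
        self.beta = Param(np.zeros(n_channels, dtype=dtype))
        self.running_mean = np.zeros(n_channels, dtype=np.float64)
        self.running_var = np.ones(n_channels, dtype=np.float64)
        self.momentum = momentum
        self.eps = eps

    def _axes_shape(self, x):
        if x.ndim == 4:
            return (0, 2, 3), (1, -1, 1, 1)
        return (0,), (1, -1)

    def forward(self, x, training=False):
        axes, shape = self._axes_shape(x)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean += self.momentum * (mean.astype(np.float64) - self.running_mean)
            self.running_var += self.momentum * (var.astype(np.float64) - self.running_var)
        else:
            mean = self.running_mean.astype(x.dtype)
            var = self.running_var.astype(x.dtype)
        std = np.sqrt(var + self.eps).astype(x.dtype)
        xhat = (x - mean.astype(x.dtype).reshape(shape)) / std.reshape(shape)
        self._cache = (xhat, std, axes, shape, training)
        return self.gamma.value.reshape(shape) * xhat + self.beta.value.reshape(shape)

    def backward(self, grad):
        xhat, std, axes, shape, training = self._cache
        self.gamma.grad += (grad * xhat).sum(axis=axes)
        self.beta.grad += grad.sum(axis=axes)
        dxhat = grad * self.gamma.value.reshape(shape)
        if not training:
            dx = dxhat / std.reshape(shape)
        else:
            dx = (
                dxhat
                - dxhat.mean(axis=axes, keepdims=True)
                - xhat * (dxhat * xhat).mean(axis=axes, keepdims=True)
            ) / std.reshape(shape)
        self._cache = None
        return dx

    def params(self):
        return [self.gamma, self.beta]
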