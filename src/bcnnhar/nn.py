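"""Minimal NumPy neural-network layers with manual reverse-mode gradients.

Implements exactly the pieces a VGG-style 1D branch CNN needs: 1D
convolution with length-preserving padding, ReLU, max pooling, global
average pooling over time, and a fully connected layer, plus an Adam
optimizer.  Layers cache their forward inputs and expose ``backward`` which
returns the gradient w.r.t. their input while accumulating parameter
gradients in place.  Everything is float32 and fully deterministic given
the initialization RNG and the input stream.

Array convention: convolutional layers operate on (batch, channels, time);
dense layers on (batch, features).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Param", "Conv1d", "ReLU", "MaxPool1d", "GlobalAvgPool1d", "Dense", "Adam"]


class Param:
    """A trainable tensor and its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)

    @property
    def size(self) -> int:
        return self.value.size


class Conv1d:
    """1D convolution with 'same' zero padding (odd kernel), stride 1."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int, rng: np.random.Generator):
        if kernel % 2 != 1:
            raise ValueError("kernel length must be odd for symmetric padding")
        scale = np.sqrt(2.0 / (in_channels * kernel))  # He fan-in
        self.weight = Param(rng.normal(0.0, scale, size=(out_channels, in_channels * kernel)))
        self.bias = Param(np.zeros(out_channels))
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        self._cache = None

    @property
    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        b, c, t = x.shape
        pad = self.kernel // 2
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
        # (b, c, t, k) -> (b*t, c*k) columns; convolution becomes one matmul
        cols = sliding_window_view(xp, self.kernel, axis=2)
        cols2 = np.ascontiguousarray(cols.transpose(0, 2, 1, 3)).reshape(b * t, c * self.kernel)
        y = cols2 @ self.weight.value.T + self.bias.value
        if train:
            self._cache = (cols2, (b, c, t))
        return np.ascontiguousarray(y.reshape(b, t, self.out_channels).transpose(0, 2, 1))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols2, (b, c, t) = self._cache
        dy2 = np.ascontiguousarray(dy.transpose(0, 2, 1)).reshape(b * t, self.out_channels)
        self.weight.grad += dy2.T @ cols2
        self.bias.grad += dy2.sum(axis=0)
        dcols = (dy2 @ self.weight.value).reshape(b, t, c, self.kernel)
        pad = self.kernel // 2
        dxp = np.zeros((b, c, t + 2 * pad), dtype=np.float32)
        for j in range(self.kernel):
            dxp[:, :, j : j + t] += dcols[:, :, :, j].transpose(0, 2, 1)
        return dxp[:, :, pad : pad + t]


class ReLU:
    params: list[Param] = []

    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        mask = x > 0
        if train:
            self._mask = mask
        return np.where(mask, x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class MaxPool1d:
    """Non-overlapping max pooling; odd remainders at the end are dropped."""

    params: list[Param] = []

    def __init__(self, factor: int = 2):
        if factor < 2:
            raise ValueError("pool factor must be >= 2")
        self.factor = factor
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        b, c, t = x.shape
        t2 = (t // self.factor) * self.factor
        if t2 == 0:
            raise ValueError(f"sequence length {t} shorter than pool factor {self.factor}")
        xr = x[:, :, :t2].reshape(b, c, t2 // self.factor, self.factor)
        idx = xr.argmax(axis=3)
        if train:
            self._cache = (idx, (b, c, t, t2))
        return np.take_along_axis(xr, idx[..., None], axis=3)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        idx, (b, c, t, t2) = self._cache
        dxr = np.zeros((b, c, t2 // self.factor, self.factor), dtype=np.float32)
        np.put_along_axis(dxr, idx[..., None], dy[..., None], axis=3)
        dx = np.zeros((b, c, t), dtype=np.float32)
        dx[:, :, :t2] = dxr.reshape(b, c, t2)
        return dx


class GlobalAvgPool1d:
    """Mean over the time axis: (b, c, t) -> (b, c)."""

    params: list[Param] = []

    def __init__(self):
        self._t = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._t = x.shape[2]
        return x.mean(axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.repeat(dy[:, :, None], self._t, axis=2) / self._t


class Dense:
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / in_features)
        self.weight = Param(rng.normal(0.0, scale, size=(in_features, out_features)))
        self.bias = Param(np.zeros(out_features))
        self._x = None

    @property
    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.weight.value + self.bias.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.weight.grad += self._x.T @ dy
        self.bias.grad += dy.sum(axis=0)
        return dy @ self.weight.value.T


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(
        self,
        params: list[Param],
        lr: float = 0.001,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in params]
        self._v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad.fill(0.0)

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, m, v in zip(self.params, self._m, self._v):
            m += (1.0 - self.beta1) * (p.grad - m)
            v += (1.0 - self.beta2) * (p.grad**2 - v)
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
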