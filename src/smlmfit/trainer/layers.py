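"""Minimal neural-network layers with hand-written backward passes.

Convolutions use im2col (strided sliding windows + matmul); the backward
input gradient is scattered back with nine shifted slice-adds, which keeps
everything vectorised.  Gradients are verified against finite differences
in the test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Adam", "Conv2d", "Flatten", "LeakyReLU", "Linear", "Param"]


class Param:
    """A trainable array with its accumulated gradient."""

    def __init__(self, value: np.ndarray) -> None:
        self.value = value
        self.grad = np.zeros_like(value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Conv2d:
    """3x3 convolution, padding 1, configurable stride."""

    def __init__(self, cin: int, cout: int, stride: int, rng: np.random.Generator,
                 dtype=np.float64) -> None:
        self.cin, self.cout, self.stride = cin, cout, stride
        std = np.sqrt(2.0 / (cin * 9))
        self.w = Param(rng.normal(scale=std, size=(cout, cin, 3, 3)).astype(dtype))
        self.b = Param(np.zeros(cout, dtype=dtype))
        self._cache = None

    @property
    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, C, H, W = x.shape
        s = self.stride
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        win = sliding_window_view(xp, (3, 3), axis=(2, 3))[:, :, ::s, ::s]
        Ho, Wo = win.shape[2], win.shape[3]
        # (B, Ho, Wo, C*9)
        col = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(B, Ho * Wo, C * 9)
        wm = self.w.value.reshape(self.cout, C * 9)
        y = col @ wm.T + self.b.value
        self._cache = (col, (B, C, H, W), (Ho, Wo))
        return y.reshape(B, Ho, Wo, self.cout).transpose(0, 3, 1, 2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        col, (B, C, H, W), (Ho, Wo) = self._cache
        s = self.stride
        dym = np.ascontiguousarray(dy.transpose(0, 2, 3, 1)).reshape(B * Ho * Wo, self.cout)
        flat_col = col.reshape(B * Ho * Wo, C * 9)
        self.w.grad += (dym.T @ flat_col).reshape(self.w.value.shape)
        self.b.grad += dym.sum(axis=0)
        wm = self.w.value.reshape(self.cout, C * 9)
        dcol = (dym @ wm).reshape(B, Ho, Wo, C, 3, 3).transpose(0, 3, 1, 2, 4, 5)
        dxp = np.zeros((B, C, H + 2, W + 2), dtype=dy.dtype)
        for ki in range(3):
            for kj in range(3):
                dxp[:, :, ki : ki + s * Ho : s, kj : kj + s * Wo : s] += dcol[..., ki, kj]
        return dxp[:, :, 1 : H + 1, 1 : W + 1]


class Linear:
    def __init__(self, nin: int, nout: int, rng: np.random.Generator, dtype=np.float64) -> None:
        std = np.sqrt(2.0 / nin)
        self.w = Param(rng.normal(scale=std, size=(nout, nin)).astype(dtype))
        self.b = Param(np.zeros(nout, dtype=dtype))
        self._x = None

    @property
    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w.value.T + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.w.grad += dy.T @ self._x
        self.b.grad += dy.sum(axis=0)
        return dy @ self.w.value


class LeakyReLU:
    def __init__(self, slope: float = 0.1) -> None:
        self.slope = slope
        self._mask = None

    params: list[Param] = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x >= 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, self.slope * dy)


class Flatten:
    params: list[Param] = []

    def __init__(self) -> None:
        self._shape = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)


class Adam:
    """Adaptive-moment gradient descent with bias correction."""

    def __init__(self, params: list[Param], lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        c1 = 1.0 - b1**self.t
        c2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1.0 - b1) * p.grad
            v *= b2
            v += (1.0 - b2) * p.grad**2
            p.value -= self.lr * (m / c1) / (np.sqrt(v / c2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
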