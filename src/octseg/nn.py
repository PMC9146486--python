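"""Minimal CPU conv-net engine (numpy + BLAS) used by the segmentation networks.

Implements exactly the layer set the segmentation architectures need:
same-padded 2-D convolution, 2x2 max pooling, 2x2 stride-2 transposed
convolution, ReLU, dropout and a softmax head — each with a hand-written
backward pass — plus an Adam optimizer. Layout is NCHW, float32.

Convolutions are evaluated as im2col + GEMM so the heavy lifting stays in
BLAS; the backward pass reuses the cached column matrix.
"""
from __future__ import annotations

import math
from typing import Iterable, Optional

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Conv2d",
    "ConvTranspose2x2",
    "MaxPool2x2",
    "ReLU",
    "Dropout",
    "Adam",
    "softmax",
]


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)
        self.name = name

    @property
    def size(self) -> int:
        return self.value.size


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    std = math.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(np.float32)


class Conv2d(Layer):
    """k x k convolution with 'same' zero padding, stride 1."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator, name: str = "conv"):
        if k % 2 != 1:
            raise ValueError("kernel size must be odd for same padding")
        self.cin, self.cout, self.k = cin, cout, k
        self.W = Param(_he_init(rng, (cout, cin, k, k), cin * k * k), f"{name}.W")
        self.b = Param(np.zeros(cout, dtype=np.float32), f"{name}.b")
        self._cols: Optional[np.ndarray] = None
        self._xshape: Optional[tuple[int, ...]] = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, cin, h, w = x.shape
        assert cin == self.cin, (cin, self.cin)
        k, p = self.k, self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        # (n, cin, h, w, k, k) strided view over the padded image
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, cin * k * k)
        cols = np.ascontiguousarray(cols, dtype=np.float32)
        wmat = self.W.value.reshape(self.cout, -1)
        y = cols @ wmat.T
        y += self.b.value
        if train:
            self._cols = cols
            self._xshape = x.shape
        return y.reshape(n, h, w, self.cout).transpose(0, 3, 1, 2)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        assert self._cols is not None, "forward(train=True) required before backward"
        n, cout, h, w = gy.shape
        k, p = self.k, self.k // 2
        g = np.ascontiguousarray(gy.transpose(0, 2, 3, 1).reshape(n * h * w, cout))
        self.W.grad += (g.T @ self._cols).reshape(self.W.value.shape)
        self.b.grad += g.sum(axis=0)
        gcols = g @ self.W.value.reshape(cout, -1)  # (n*h*w, cin*k*k)
        gcols = gcols.reshape(n, h, w, self.cin, k, k)
        gxp = np.zeros((n, self.cin, h + 2 * p, w + 2 * p), dtype=np.float32)
        for di in range(k):
            for dj in range(k):
                gxp[:, :, di : di + h, dj : dj + w] += gcols[:, :, :, :, di, dj].transpose(0, 3, 1, 2)
        self._cols = None
        return gxp[:, :, p : p + h, p : p + w]


class ConvTranspose2x2(Layer):
    """2x2 transposed convolution with stride 2 (doubles H and W)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator, name: str = "upconv"):
        self.cin, self.cout = cin, cout
        self.W = Param(_he_init(rng, (cin, cout, 2, 2), cin * 4), f"{name}.W")
        self.b = Param(np.zeros(cout, dtype=np.float32), f"{name}.b")
        self._x: Optional[np.ndarray] = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, cin, h, w = x.shape
        y = np.empty((n, self.cout, 2 * h, 2 * w), dtype=np.float32)
        for di in range(2):
            for dj in range(2):
                # (n,cin,h,w) x (cin,cout) -> (n,h,w,cout)
                part = np.tensordot(x, self.W.value[:, :, di, dj], axes=([1], [0]))
                y[:, :, di::2, dj::2] = part.transpose(0, 3, 1, 2)
        y += self.b.value[None, :, None, None]
        if train:
            self._x = x
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        assert self._x is not None
        x = self._x
        gx = np.zeros_like(x)
        for di in range(2):
            for dj in range(2):
                gpart = gy[:, :, di::2, dj::2]  # (n,cout,h,w)
                self.W.grad[:, :, di, dj] += np.tensordot(x, gpart, axes=([0, 2, 3], [0, 2, 3]))
                gx += np.tensordot(gpart, self.W.value[:, :, di, dj], axes=([1], [1])).transpose(
                    0, 3, 1, 2
                )
        self.b.grad += gy.sum(axis=(0, 2, 3))
        self._x = None
        return gx


class MaxPool2x2(Layer):
    def __init__(self) -> None:
        self._mask: Optional[np.ndarray] = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError("max pooling requires even spatial dims")
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        y = xr.max(axis=(3, 5))
        if train:
            self._mask = (xr == y[:, :, :, None, :, None]).astype(np.float32)
            self._shape = x.shape
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        assert self._mask is not None
        n, c, h, w = self._shape
        g = self._mask * gy[:, :, :, None, :, None]
        self._mask = None
        return g.reshape(n, c, h, w)


class ReLU(Layer):
    def __init__(self) -> None:
        self._pos: Optional[np.ndarray] = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        y = np.maximum(x, 0.0)
        if train:
            self._pos = x > 0
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        assert self._pos is not None
        g = gy * self._pos
        self._pos = None
        return g


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator) -> None:
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng
        self._mask: Optional[np.ndarray] = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, gy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return gy
        g = gy * self._mask
        self._mask = None
        return g


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z, dtype=np.float32 if logits.dtype == np.float32 else np.float64)
    return e / e.sum(axis=axis, keepdims=True)


class Adam:
    """Adam optimizer over a list of :class:`Param`."""

    def __init__(
        self,
        params: Iterable[Param],
        lr: float = 0.001,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-7,
    ) -> None:
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in self.params]
        self._v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self._m, self._v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * np.square(p.grad)
            p.value -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
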