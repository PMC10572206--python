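"""Minimal CPU neural-network engine for the detector.

Implements exactly what the two-stage detector needs — 2-D convolutions
(stride 1, same padding, kernel 1 or 3), ReLU, 2x2 max pooling, an Adam
optimizer, and the detection losses (binary/softmax cross-entropy, smooth-L1)
— with explicit forward/backward passes on ``float32`` arrays of layout
``(channels, height, width)`` for a single image. Convolutions run as
im2col + matmul so the heavy lifting stays inside BLAS.
"""

from __future__ import annotations

import math
from typing import Iterable

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param",
    "Conv2d",
    "ReLU",
    "MaxPool2",
    "Sequential",
    "Adam",
    "sigmoid",
    "sigmoid_bce_with_logits",
    "softmax_cross_entropy",
    "smooth_l1",
]


class Param:
    """A trainable tensor with an accumulated gradient."""

    __slots__ = ("name", "value", "grad")

    def __init__(self, name: str, value: np.ndarray):
        self.name = name
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Conv2d:
    """Stride-1 convolution with 'same' zero padding; kernel size 1 or 3."""

    def __init__(self, cin: int, cout: int, ksize: int, rng: np.random.Generator, name: str):
        if ksize not in (1, 3):
            raise ValueError("only 1x1 and 3x3 kernels are supported")
        self.cin, self.cout, self.ksize = cin, cout, ksize
        fan_in = cin * ksize * ksize
        w = rng.normal(0.0, math.sqrt(2.0 / fan_in), size=(cout, fan_in))
        self.weight = Param(f"{name}.weight", w)
        self.bias = Param(f"{name}.bias", np.zeros(cout))
        self._cols: np.ndarray | None = None
        self._shape: tuple[int, int] | None = None

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        c, h, w = x.shape
        if self.ksize == 1:
            cols = x.reshape(c, h * w).T  # (HW, C)
        else:
            xp = np.pad(x, ((0, 0), (1, 1), (1, 1)))
            cols = sliding_window_view(xp, (3, 3), axis=(1, 2))  # (C, H, W, 3, 3)
            cols = np.ascontiguousarray(cols.transpose(1, 2, 0, 3, 4)).reshape(h * w, c * 9)
        out = cols @ self.weight.value.T + self.bias.value
        if train:
            self._cols = cols
            self._shape = (h, w)
        return np.ascontiguousarray(out.T.reshape(self.cout, h, w))

    def backward(self, gout: np.ndarray) -> np.ndarray:
        if self._cols is None or self._shape is None:
            raise RuntimeError("backward before forward")
        h, w = self._shape
        g = np.ascontiguousarray(gout.reshape(self.cout, h * w).T)  # (HW, Cout)
        self.weight.grad += g.T @ self._cols
        self.bias.grad += g.sum(axis=0)
        gcols = g @ self.weight.value  # (HW, cin*ks*ks)
        if self.ksize == 1:
            gin = gcols.T.reshape(self.cin, h, w)
        else:
            gcols = gcols.reshape(h, w, self.cin, 3, 3)
            gxp = np.zeros((self.cin, h + 2, w + 2), dtype=np.float32)
            for dy in range(3):
                for dx in range(3):
                    gxp[:, dy : dy + h, dx : dx + w] += gcols[:, :, :, dy, dx].transpose(2, 0, 1)
            gin = gxp[:, 1 : h + 1, 1 : w + 1]
        self._cols = None
        return np.ascontiguousarray(gin)


class ReLU:
    def __init__(self):
        self._mask: np.ndarray | None = None

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0.0
        return out

    def backward(self, gout: np.ndarray) -> np.ndarray:
        return gout * self._mask


class MaxPool2:
    """2x2 max pooling, stride 2. Input height/width must be even."""

    def __init__(self):
        self._argmax: np.ndarray | None = None
        self._shape: tuple[int, int, int] | None = None

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"MaxPool2 needs even spatial dims, got {h}x{w}")
        windows = x.reshape(c, h // 2, 2, w // 2, 2).transpose(0, 1, 3, 2, 4).reshape(
            c, h // 2, w // 2, 4
        )
        idx = windows.argmax(axis=-1)
        out = np.take_along_axis(windows, idx[..., None], axis=-1)[..., 0]
        if train:
            self._argmax = idx
            self._shape = (c, h, w)
        return np.ascontiguousarray(out)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        c, h, w = self._shape
        gwin = np.zeros((c, h // 2, w // 2, 4), dtype=np.float32)
        np.put_along_axis(gwin, self._argmax[..., None], gout[..., None], axis=-1)
        gin = gwin.reshape(c, h // 2, w // 2, 2, 2).transpose(0, 1, 3, 2, 4).reshape(c, h, w)
        return np.ascontiguousarray(gin)


class Sequential:
    def __init__(self, *layers):
        self.layers = list(layers)

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, gout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            gout = layer.backward(gout)
        return gout


class Adam:
    """Adam with first-moment coefficient ``beta1`` and L2 weight decay."""

    def __init__(
        self,
        params: Iterable[Param],
        lr: float = 5e-4,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
        weight_decay: float = 5e-4,
    ):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.weight_decay = weight_decay
        self._m = [np.zeros_like(p.value) for p in self.params]
        self._v = [np.zeros_like(p.value) for p in self.params]
        self._t = 0

    def step(self) -> None:
        self._t += 1
        b1t = 1.0 - self.beta1**self._t
        b2t = 1.0 - self.beta2**self._t
        for p, m, v in zip(self.params, self._m, self._v):
            g = p.grad + self.weight_decay * p.value
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


# ---------------------------------------------------------------------------
# losses (each returns (scalar loss, gradient wrt the logits/predictions))
# ---------------------------------------------------------------------------

def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def sigmoid_bce_with_logits(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy over all elements."""
    logits = np.asarray(logits, dtype=np.float64)
    targets = np.asarray(targets, dtype=np.float64)
    n = logits.size
    if n == 0:
        raise ValueError("binary cross-entropy over an empty sample set is undefined")
    # stable: log(1+exp(-|x|)) + max(x,0) - x*t
    loss = np.maximum(logits, 0.0) - logits * targets + np.log1p(np.exp(-np.abs(logits)))
    grad = (sigmoid(logits) - targets) / n
    return float(loss.mean()), grad


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy for ``(N, C)`` logits and integer labels ``(N,)``."""
    logits = np.asarray(logits, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    n = len(logits)
    if n == 0:
        raise ValueError("cross-entropy over an empty sample set is undefined")
    z = logits - logits.max(axis=1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    loss = -logp[np.arange(n), labels].mean()
    grad = np.exp(logp)
    grad[np.arange(n), labels] -= 1.0
    return float(loss), grad / n


def smooth_l1(pred: np.ndarray, target: np.ndarray, beta: float = 1.0) -> tuple[float, np.ndarray]:
    """Smooth-L1 (Huber) loss, mean over rows, summed over the 4 components."""
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.size == 0:
        return 0.0, np.zeros_like(pred)
    n = pred.shape[0] if pred.ndim > 1 else 1
    d = pred - target
    ad = np.abs(d)
    quad = ad < beta
    loss = np.where(quad, 0.5 * d * d / beta, ad - 0.5 * beta).sum() / n
    grad = np.where(quad, d / beta, np.sign(d)) / n
    return float(loss), grad
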