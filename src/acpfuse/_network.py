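"""Minimal NumPy feedforward stack used by the peptide classifier.

Implements exactly the layers the dual-channel architecture needs —
trainable embedding, valid-mode 1-D convolution, non-overlapping max
pooling, dense layers, inverted dropout — plus Adam and a numerically
stable sigmoid/binary-cross-entropy head. Forward passes cache what the
matching backward pass needs; parameters are float32.
"""

from __future__ import annotations

import numpy as np


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class Embedding:
    """Lookup table mapping integer codes (0 = padding) to learned vectors."""

    def __init__(self, rng: np.random.Generator, vocab_size: int, dim: int):
        self.table = Param(rng.normal(0.0, 0.05, size=(vocab_size, dim)))
        self._x: np.ndarray | None = None

    @property
    def params(self) -> list[Param]:
        return [self.table]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        return self.table.value[x]

    def backward(self, dy: np.ndarray) -> None:
        np.add.at(self.table.grad, self._x, dy)


class Conv1D:
    """Valid-mode 1-D convolution with ReLU, via an im2col matmul."""

    def __init__(self, rng: np.random.Generator, in_channels: int, filters: int, kernel: int):
        self.kernel = kernel
        self.in_channels = in_channels
        self.W = Param(_he_init(rng, (kernel * in_channels, filters), kernel * in_channels))
        self.b = Param(np.zeros(filters))
        self._cols: np.ndarray | None = None
        self._mask: np.ndarray | None = None
        self._in_len: int = 0

    @property
    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        B, L, C = x.shape
        self._in_len = L
        # (B, P, C, K) windows -> (B, P, K*C) patches
        win = np.lib.stride_tricks.sliding_window_view(x, self.kernel, axis=1)
        cols = np.ascontiguousarray(win.transpose(0, 1, 3, 2)).reshape(B, -1, self.kernel * C)
        self._cols = cols
        z = cols @ self.W.value + self.b.value
        self._mask = z > 0
        return np.where(self._mask, z, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy = np.where(self._mask, dy, 0.0)
        B, P, F = dy.shape
        KC = self.kernel * self.in_channels
        self.W.grad += self._cols.reshape(-1, KC).T @ dy.reshape(-1, F)
        self.b.grad += dy.sum(axis=(0, 1))
        dcols = (dy @ self.W.value.T).reshape(B, P, self.kernel, self.in_channels)
        dx = np.zeros((B, self._in_len, self.in_channels), dtype=np.float32)
        for j in range(self.kernel):
            dx[:, j : j + P] += dcols[:, :, j]
        return dx


class MaxPool1D:
    """Non-overlapping max pooling (stride = pool size; remainder dropped)."""

    def __init__(self, size: int):
        self.size = size
        self._argmax: np.ndarray | None = None
        self._in_shape: tuple[int, ...] = ()

    @property
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        B, L, C = x.shape
        P = L // self.size
        self._in_shape = x.shape
        xw = x[:, : P * self.size].reshape(B, P, self.size, C)
        self._argmax = xw.argmax(axis=2)
        return xw.max(axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, P, C = dy.shape
        dxw = np.zeros((B, P, self.size, C), dtype=np.float32)
        b, p, c = np.ogrid[:B, :P, :C]
        dxw[b, p, self._argmax, c] = dy
        dx = np.zeros(self._in_shape, dtype=np.float32)
        dx[:, : P * self.size] = dxw.reshape(B, P * self.size, C)
        return dx


class Dense:
    """Fully connected layer, optionally with ReLU."""

    def __init__(self, rng: np.random.Generator, n_in: int, n_out: int, relu: bool = True):
        self.relu = relu
        self.W = Param(_he_init(rng, (n_in, n_out), n_in))
        self.b = Param(np.zeros(n_out))
        self._x: np.ndarray | None = None
        self._mask: np.ndarray | None = None

    @property
    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        z = x @ self.W.value + self.b.value
        if self.relu:
            self._mask = z > 0
            return np.where(self._mask, z, 0.0)
        return z

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self.relu:
            dy = np.where(self._mask, dy, 0.0)
        self.W.grad += self._x.T @ dy
        self.b.grad += dy.sum(axis=0)
        return dy @ self.W.value.T


class Dropout:
    """Inverted dropout; identity at evaluation time."""

    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate = rate
        self.rng = rng
        self._mask: np.ndarray | None = None

    @property
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.rate <= 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy if self._mask is None else dy * self._mask


class Adam:
    """Adam optimizer over a list of :class:`Param`."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1 ** self.t
        b2c = 1.0 - self.beta2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * p.grad
            v *= self.beta2
            v += (1.0 - self.beta2) * p.grad ** 2
            p.value -= self.lr * (m / b1c) / (np.sqrt(v / b2c) + self.eps)


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy and its gradient w.r.t. the logits."""
    z = logits.astype(np.float64)
    loss = float(np.mean(np.maximum(z, 0.0) - z * y + np.log1p(np.exp(-np.abs(z)))))
    grad = ((sigmoid(z) - y) / z.size).astype(np.float32)
    return loss, grad
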