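"""Minimal NumPy neural-network plumbing: parameters, conv/dense ops, Adam.

Feature maps use NHWC layout. The 3x3 same-padding convolution is an im2col
GEMM with persistent scratch buffers: for the tiny images this package works
with (at most 8 x 24 pixels) the whole batch's patch matrix fits comfortably
in memory and one large matrix product beats nine small ones. Everything is
deterministic given the seeds handed in by callers.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Param", "Conv3x3", "Conv1x1", "Dense", "Adam", "relu", "log_softmax"]


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0)


def log_softmax(x: np.ndarray) -> np.ndarray:
    m = x.max(axis=1, keepdims=True)
    s = x - m
    return s - np.log(np.exp(s).sum(axis=1, keepdims=True))


class Conv3x3:
    """3x3 same-padding convolution, stride 1, NHWC."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, dtype=np.float32):
        std = np.sqrt(2.0 / (9 * c_in))
        self.w = Param((rng.standard_normal((3, 3, c_in, c_out)) * std).astype(dtype))
        self.b = Param(np.zeros(c_out, dtype=dtype))
        self.c_in = c_in
        self.c_out = c_out
        self._patches = None  # (n*h*w, 9*c_in) im2col scratch, reused across steps
        self._shape = None

    @property
    def params(self):
        return [self.w, self.b]

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        n, h, w_, c = x.shape
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        if self._patches is None or self._patches.shape[0] != n * h * w_:
            self._patches = np.empty((n * h * w_, 9 * c), dtype=x.dtype)
        view = self._patches.reshape(n, h, w_, 9, c)
        k = 0
        for i in range(3):
            for j in range(3):
                view[:, :, :, k, :] = xp[:, i : i + h, j : j + w_, :]
                k += 1
        return self._patches

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w_, _ = x.shape
        self._shape = (n, h, w_)
        patches = self._im2col(x)
        y = patches @ self.w.value.reshape(9 * self.c_in, self.c_out)
        y += self.b.value
        return y.reshape(n, h, w_, self.c_out)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w_ = self._shape
        dy_mat = np.ascontiguousarray(dy, dtype=self.w.value.dtype).reshape(n * h * w_, self.c_out)
        self.b.grad += dy_mat.sum(axis=0)
        self.w.grad += (self._patches.T @ dy_mat).reshape(3, 3, self.c_in, self.c_out)
        dpatches = dy_mat @ self.w.value.reshape(9 * self.c_in, self.c_out).T
        dview = dpatches.reshape(n, h, w_, 9, self.c_in)
        dxp = np.zeros((n, h + 2, w_ + 2, self.c_in), dtype=dy_mat.dtype)
        k = 0
        for i in range(3):
            for j in range(3):
                dxp[:, i : i + h, j : j + w_, :] += dview[:, :, :, k, :]
                k += 1
        return dxp[:, 1:-1, 1:-1, :]


class Conv1x1:
    """1x1 convolution (pointwise channel projection), NHWC."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, dtype=np.float32):
        std = np.sqrt(2.0 / c_in)
        self.w = Param((rng.standard_normal((c_in, c_out)) * std).astype(dtype))
        self.b = Param(np.zeros(c_out, dtype=dtype))
        self._cache = None

    @property
    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._cache = x
        return x @ self.w.value + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._cache
        c_in, c_out = self.w.value.shape
        x_mat = x.reshape(-1, c_in)
        dy_mat = np.ascontiguousarray(dy).reshape(-1, c_out)
        self.b.grad += dy_mat.sum(axis=0)
        self.w.grad += x_mat.T @ dy_mat
        return (dy_mat @ self.w.value.T).reshape(x.shape)


class Dense:
    """Fully connected layer on (batch, features)."""

    def __init__(
        self,
        n_in: int,
        n_out: int,
        rng: np.random.Generator,
        dtype=np.float32,
        gain: float = 2.0,
    ):
        std = np.sqrt(gain / n_in)
        self.w = Param((rng.standard_normal((n_in, n_out)) * std).astype(dtype))
        self.b = Param(np.zeros(n_out, dtype=dtype))
        self._cache = None

    @property
    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._cache = x
        return x @ self.w.value + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._cache
        self.b.grad += dy.sum(axis=0)
        self.w.grad += x.T @ dy
        return dy @ self.w.value.T


class Adam:
    """Adam optimizer over a flat parameter list.

    Updates are fused in-place with persistent scratch buffers; the bias
    corrections are folded into an effective step size, the standard
    reformulation ``lr_t = lr * sqrt(1 - b2^t) / (1 - b1^t)`` with
    ``eps`` rescaled accordingly.
    """

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self._scratch = [np.empty_like(p.value) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0

    def step(self) -> None:
        self.t += 1
        b2t = 1.0 - self.beta2**self.t
        lr_t = self.lr * np.sqrt(b2t) / (1.0 - self.beta1**self.t)
        eps_t = self.eps * np.sqrt(b2t)
        for p, m, v, s in zip(self.params, self.m, self.v, self._scratch):
            g = p.grad
            m *= self.beta1
            np.multiply(g, 1.0 - self.beta1, out=s)
            m += s
            v *= self.beta2
            np.multiply(g, g, out=s)
            s *= 1.0 - self.beta2
            v += s
            np.sqrt(v, out=s)
            s += eps_t
            np.divide(m, s, out=s)
            s *= lr_t
            p.value -= s
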