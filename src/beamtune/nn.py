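"""Minimal feed-forward neural-network layers in numpy.

Implements exactly the pieces the multi-encoder 1D-CNN regressor needs —
same-padding 1D convolutions (via im2col matrix multiplication), ReLU,
max-pooling with window 2, dense layers, mean-squared-error loss and the
Adam optimizer — with explicit, hand-derived backward passes.  Everything
is float32 (ample precision for profile regression, and twice the matmul
throughput of float64) and seeded, so training is bit-reproducible on a
single thread.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv1D", "ReLU", "MaxPool1D", "Flatten", "Dense", "Adam", "mse_loss"]


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


class Conv1D(Layer):
    """Length-preserving 1D convolution; input (B, N, C_in) -> (B, N, C_out)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        self.c_in, self.c_out, self.kernel = c_in, c_out, kernel
        fan_in = kernel * c_in
        self.W = Param(
            rng.standard_normal((fan_in, c_out), dtype=np.float32)
            * np.float32(np.sqrt(2.0 / fan_in))
        )
        self.b = Param(np.zeros(c_out, dtype=np.float32))
        self._col: np.ndarray | None = None
        self._shape: tuple | None = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        B, N, C = x.shape
        pad = self.kernel // 2
        if pad:
            xp = np.zeros((B, N + 2 * pad, C), dtype=x.dtype)
            xp[:, pad:-pad, :] = x
        else:
            xp = x
        cols = np.stack([xp[:, i : i + N, :] for i in range(self.kernel)], axis=2)
        return cols.reshape(B * N, self.kernel * C)

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, N, _ = x.shape
        col = self._im2col(x)
        self._col, self._shape = col, x.shape
        return (col @ self.W.value + self.b.value).reshape(B, N, self.c_out)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, N, C = self._shape
        dy2 = dy.reshape(B * N, self.c_out)
        self.W.grad += self._col.T @ dy2
        self.b.grad += dy2.sum(axis=0)
        dcol = (dy2 @ self.W.value.T).reshape(B, N, self.kernel, C)
        pad = self.kernel // 2
        dxp = np.zeros((B, N + 2 * pad, C), dtype=dy.dtype)
        for i in range(self.kernel):
            dxp[:, i : i + N, :] += dcol[:, :, i, :]
        return dxp[:, pad : pad + N, :] if pad else dxp


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class MaxPool1D(Layer):
    """Window-2 max pooling; output length N // 2 (a trailing odd sample is dropped)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, N, C = x.shape
        n_out = N // 2
        xw = x[:, : 2 * n_out, :].reshape(B, n_out, 2, C)
        self._argmax = xw.argmax(axis=2)
        self._shape = x.shape
        return xw.max(axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, N, C = self._shape
        n_out = N // 2
        dx = np.zeros((B, n_out, 2, C), dtype=dy.dtype)
        b_idx, n_idx, c_idx = np.ogrid[:B, :n_out, :C]
        dx[b_idx, n_idx, self._argmax, c_idx] = dy
        out = np.zeros((B, N, C), dtype=dy.dtype)
        out[:, : 2 * n_out, :] = dx.reshape(B, 2 * n_out, C)
        return out


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = Param(
            rng.standard_normal((n_in, n_out), dtype=np.float32)
            * np.float32(np.sqrt(2.0 / n_in))
        )
        self.b = Param(np.zeros(n_out, dtype=np.float32))

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.W.grad += self._x.T @ dy
        self.b.grad += dy.sum(axis=0)
        return dy @ self.W.value.T


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error over all entries and its gradient w.r.t. pred."""
    diff = pred - target
    loss = float(np.mean(diff**2))
    return loss, (2.0 / diff.size) * diff


class Adam:
    """Adam optimizer with the standard (keras-default) moment constants."""

    def __init__(
        self,
        params: list[Param],
        lr: float = 1e-4,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in params]
        self._v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, m, v in zip(self.params, self._m, self._v):
            m *= self.beta1
            m += (1.0 - self.beta1) * p.grad
            v *= self.beta2
            v += (1.0 - self.beta2) * p.grad**2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
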