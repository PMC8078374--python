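"""Minimal numpy 1D convolutional network with manual backpropagation.

Small stacks of strided 1D convolutions with ReLU, global average
pooling and a linear head — a few thousand parameters — are entirely
tractable on a CPU with plain numpy, so the package carries its own
compact layer/optimizer implementation rather than a deep-learning
framework.  Determinism is exact: all initialization and batching flows
from explicit generators, and the arithmetic is ordinary dense numpy.

Layers implement ``forward(x)`` caching what ``backward(grad)`` needs;
``params()`` / ``grads()`` expose flat lists consumed by the Adam
optimizer.  Input convention: (batch, channels, length).
"""

from __future__ import annotations

import numpy as np


class Layer:
    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


class Conv1d(Layer):
    """Valid (no padding) strided 1D convolution via im2col."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int, stride: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (in_channels * kernel))  # He init for ReLU stacks
        self.w = rng.normal(0.0, scale, size=(out_channels, in_channels, kernel))
        self.b = np.zeros(out_channels)
        self.stride = stride
        self.kernel = kernel
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._cols: np.ndarray | None = None
        self._in_shape: tuple | None = None

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, L = x.shape
        k, s = self.kernel, self.stride
        if L < k:
            raise ValueError(f"input length {L} shorter than kernel {k}")
        windows = np.lib.stride_tricks.sliding_window_view(x, k, axis=2)[:, :, ::s]  # (n, c, Lo, k)
        cols = windows.transpose(0, 2, 1, 3).reshape(n, -1, c * k)  # (n, Lo, c*k)
        self._cols = cols
        self._in_shape = (n, c, L)
        out = cols @ self.w.reshape(len(self.w), -1).T + self.b  # (n, Lo, out)
        return out.transpose(0, 2, 1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, L = self._in_shape
        k, s = self.kernel, self.stride
        g = grad.transpose(0, 2, 1)  # (n, Lo, out)
        cols = self._cols
        self.dw[...] = np.einsum("nlo,nlj->oj", g, cols).reshape(self.w.shape) / n
        self.db[...] = g.sum(axis=(0, 1)) / n
        dcols = g @ self.w.reshape(len(self.w), -1)  # (n, Lo, c*k)
        dcols = dcols.reshape(n, -1, c, k).transpose(0, 2, 1, 3)  # (n, c, Lo, k)
        dx = np.zeros((n, c, L))
        Lo = dcols.shape[2]
        for j in range(k):
            dx[:, :, j : j + Lo * s : s] += dcols[:, :, :, j]
        return dx


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class GlobalAvgPool(Layer):
    def forward(self, x):
        self._length = x.shape[2]
        return x.mean(axis=2)

    def backward(self, grad):
        return np.repeat(grad[:, :, None], self._length, axis=2) / self._length


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        scale = np.sqrt(1.0 / in_features)
        self.w = rng.normal(0.0, scale, size=(out_features, in_features))
        self.b = np.zeros(out_features)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]

    def forward(self, x):
        self._x = x
        return x @ self.w.T + self.b

    def backward(self, grad):
        n = len(grad)
        self.dw[...] = grad.T @ self._x / n
        self.db[...] = grad.sum(axis=0) / n
        return grad @ self.w


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def grads(self):
        return [g for layer in self.layers for g in layer.grads()]

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def param_count(self) -> int:
        return int(sum(p.size for p in self.params()))

    def state(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params()]

    def load_state(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.params(), state, strict=True):
            p[...] = np.asarray(s, dtype=float).reshape(p.shape)


class Adam:
    def __init__(self, params: list[np.ndarray], lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v, strict=True):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error and its gradient wrt pred."""
    diff = pred - target
    return float(np.mean(diff**2)), 2.0 * diff / diff.size * len(diff)


def bce_with_logits(logits: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Binary cross-entropy on logits; numerically stable."""
    z, y = logits, target
    loss = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
    p = 1.0 / (1.0 + np.exp(-z))
    return float(np.mean(loss)), (p - y) / z.size * len(z)


def sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))


def fit(
    net: Sequential,
    x: np.ndarray,
    y: np.ndarray,
    *,
    loss: str = "mse",
    x_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
    epochs: int = 30,
    batch_size: int = 128,
    lr: float = 1e-3,
    patience: int = 8,
    seed: int = 0,
) -> dict:
    """Mini-batch Adam training with early stopping on validation loss.

    Returns a history dict with per-epoch train/val losses; the network
    is left at the best-validation-loss weights (or final weights when no
    validation set is given).  Raises if the loss diverges to non-finite.
    """
    loss_fn = {"mse": mse_loss, "bce": bce_with_logits}[loss]
    rng = np.random.default_rng(seed)
    opt = Adam(net.params(), lr=lr)
    history: dict = {"train_loss": [], "val_loss": []}
    best_val = np.inf
    best_state = net.state()
    stale = 0
    n = len(x)
    for _epoch in range(epochs):
        order = rng.permutation(n)
        total = 0.0
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            pred = net.forward(x[idx])
            L, dgrad = loss_fn(pred, y[idx])
            if not np.isfinite(L):
                raise RuntimeError("training diverged: non-finite loss")
            net.backward(dgrad)
            opt.step(net.grads())
            total += L * len(idx)
        history["train_loss"].append(total / n)
        if x_val is not None and len(x_val):
            vl = loss_fn(net.forward(x_val), y_val)[0]
            history["val_loss"].append(vl)
            if vl < best_val - 1e-6:
                best_val, best_state, stale = vl, net.state(), 0
            else:
                stale += 1
                if stale >= patience:
                    break
    if x_val is not None and len(x_val):
        net.load_state(best_state)
    return history
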