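"""A compact NumPy layer stack for 1-D convolutional networks.

Implements exactly the pieces the insertion-site classifier needs —
1-D convolution (via im2col GEMM), batch normalization, ReLU, dropout,
dense layers — each with a hand-derived backward pass, plus plain
stochastic gradient descent.  Everything is float32; forward passes in
inference mode are deterministic and batch-size independent (dropout off,
batch-norm running statistics).

Array convention: activations are ``(batch, length, channels)``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    """Base layer: ``params()`` yields (name, value, grad) triples."""

    trainable: bool = True

    def params(self):
        return []

    def forward(self, x: np.ndarray, training: bool, rng: "np.random.Generator | None" = None):
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv1D(Layer):
    """1-D convolution, stride 1, optional asymmetric zero padding.

    ``padding=(left, right)``; ``(0, 0)`` is a valid convolution shrinking
    the length by ``kernel − 1``, ``(1, 2)`` preserves length for kernel 4.
    """

    def __init__(self, in_channels: int, filters: int, kernel: int,
                 padding: tuple[int, int] = (0, 0), rng: "np.random.Generator | None" = None):
        self.in_channels = in_channels
        self.filters = filters
        self.kernel = kernel
        self.padding = padding
        rng = rng or np.random.default_rng()
        fan_in = kernel * in_channels
        # He initialization, appropriate for the ReLU nonlinearity that follows
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, filters)).astype(np.float32)
        self.b = np.zeros(filters, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._cols = None
        self._in_shape = None

    def params(self):
        return [("w", self.w, self.dw), ("b", self.b, self.db)]

    def _im2col(self, xp: np.ndarray) -> np.ndarray:
        # xp: (B, Lp, C) -> (B, Lout, k, C) -> (B*Lout, k*C)
        view = sliding_window_view(xp, self.kernel, axis=1)  # (B, Lout, C, k)
        cols = np.ascontiguousarray(view.transpose(0, 1, 3, 2))
        return cols.reshape(-1, self.kernel * xp.shape[2])

    def forward(self, x, training, rng=None):
        pl, pr = self.padding
        xp = np.pad(x, ((0, 0), (pl, pr), (0, 0))) if (pl or pr) else x
        b, lp, _ = xp.shape
        lout = lp - self.kernel + 1
        cols = self._im2col(xp)
        y = cols @ self.w + self.b
        if training:
            self._cols = cols
            self._in_shape = x.shape
        return y.reshape(b, lout, self.filters)

    def backward(self, grad):
        b, lout, f = grad.shape
        gflat = grad.reshape(-1, f).astype(np.float32)
        self.dw = self._cols.T @ gflat
        self.db = gflat.sum(axis=0)
        dcols = (gflat @ self.w.T).reshape(b, lout, self.kernel, self.in_channels)
        pl, pr = self.padding
        _, l_in, c = self._in_shape
        dxp = np.zeros((b, l_in + pl + pr, c), dtype=np.float32)
        for k in range(self.kernel):
            dxp[:, k : k + lout, :] += dcols[:, :, k, :]
        self._cols = None
        return dxp[:, pl : pl + l_in, :] if (pl or pr) else dxp


class BatchNorm(Layer):
    """Per-channel batch normalization over (batch, length).

    Trainable scale/offset only; running mean/variance (exponential moving
    average) are used in inference mode.
    """

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-3):
        self.gamma = np.ones(channels, dtype=np.float32)
        self.beta = np.zeros(channels, dtype=np.float32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def params(self):
        return [("gamma", self.gamma, self.dgamma), ("beta", self.beta, self.dbeta)]

    def forward(self, x, training, rng=None):
        if training:
            mean = x.mean(axis=(0, 1))
            var = x.var(axis=(0, 1))
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mean).astype(np.float32)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        if training:
            self._cache = (xhat, inv.astype(np.float32), x.shape[0] * x.shape[1])
        return (self.gamma * xhat + self.beta).astype(np.float32)

    def backward(self, grad):
        xhat, inv, m = self._cache
        self.dgamma = (grad * xhat).sum(axis=(0, 1))
        self.dbeta = grad.sum(axis=(0, 1))
        # standard batch-norm gradient w.r.t. the input
        dxhat = grad * self.gamma
        dx = (inv / m) * (m * dxhat - dxhat.sum(axis=(0, 1))
                          - xhat * (dxhat * xhat).sum(axis=(0, 1)))
        self._cache = None
        return dx.astype(np.float32)


class ReLU(Layer):
    def __init__(self):
        self._mask = None

    def forward(self, x, training, rng=None):
        y = np.maximum(x, 0)
        if training:
            self._mask = x > 0
        return y

    def backward(self, grad):
        out = grad * self._mask
        self._mask = None
        return out


class Dropout(Layer):
    """Inverted dropout; identity in inference mode."""

    def __init__(self, rate: float):
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate
        self._mask = None

    def forward(self, x, training, rng=None):
        if not training or self.rate == 0:
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape, dtype=np.float32) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, grad):
        if self._mask is None:
            return grad
        out = grad * self._mask
        self._mask = None
        return out


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int,
                 rng: "np.random.Generator | None" = None, init: str = "he"):
        rng = rng or np.random.default_rng()
        if init == "he":
            std = np.sqrt(2.0 / in_features)
        else:  # glorot, for the sigmoid head
            std = np.sqrt(2.0 / (in_features + out_features))
        self.w = rng.normal(0.0, std, size=(in_features, out_features)).astype(np.float32)
        self.b = np.zeros(out_features, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._x = None

    def params(self):
        return [("w", self.w, self.dw), ("b", self.b, self.db)]

    def forward(self, x, training, rng=None):
        if training:
            self._x = x
        return x @ self.w + self.b

    def backward(self, grad):
        self.dw = self._x.T @ grad
        self.db = grad.sum(axis=0)
        dx = grad @ self.w.T
        self._x = None
        return dx


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(z: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy of sigmoid(z) against labels y, and dL/dz."""
    z = z.astype(np.float64).ravel()
    y = y.astype(np.float64).ravel()
    # log(1 + e^z) computed stably
    loss = float(np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))))
    dz = ((sigmoid(z) - y) / z.size).astype(np.float32).reshape(-1, 1)
    return loss, dz


class SGD:
    """Plain stochastic gradient descent."""

    def __init__(self, layers, learning_rate: float):
        self.layers = layers
        self.lr = learning_rate

    def step(self) -> None:
        for layer in self.layers:
            for _, value, grad in layer.params():
                value -= self.lr * grad
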