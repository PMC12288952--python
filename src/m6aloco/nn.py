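"""Self-contained NumPy neural-network core.

Implements exactly the layer vocabulary the m6A model family needs —
length-preserving 1-D convolution, non-overlapping max pooling, dense
layers, inverted dropout, batch normalization — plus the Adam optimizer and
the binary cross-entropy loss, all with explicit reverse-mode gradients.
Everything is seeded and single-threaded-deterministic: two training runs
with the same seed produce bit-identical parameter trajectories.

Array convention: sequence activations are ``(batch, length, channels)``;
flat activations are ``(batch, features)``.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class ArchitectureError(ValueError):
    pass


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(DTYPE)
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool, rng: np.random.Generator) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def out_shape(self, in_shape: tuple[int, ...]) -> tuple[int, ...]:
        raise NotImplementedError


class Conv1D(Layer):
    """Length-preserving ("same" padded) 1-D convolution, stride 1, ReLU."""

    def __init__(self, in_channels: int, filters: int, kernel: int, rng: np.random.Generator):
        self.in_channels = in_channels
        self.filters = filters
        self.kernel = kernel
        fan_in = kernel * in_channels
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, filters))
        self.W = Param(w)
        self.b = Param(np.zeros(filters))
        self._cache = None

    def params(self):
        return [self.W, self.b]

    def out_shape(self, in_shape):
        L, C = in_shape
        if C != self.in_channels:
            raise ArchitectureError(f"Conv1D expected {self.in_channels} channels, got {C}")
        if L < self.kernel:
            raise ArchitectureError(f"input length {L} < kernel {self.kernel}")
        return (L, self.filters)

    def forward(self, x, training, rng):
        B, L, C = x.shape
        k = self.kernel
        pl = (k - 1) // 2
        xp = np.pad(x, ((0, 0), (pl, k - 1 - pl), (0, 0)))
        # (B, L, C, k) -> (B, L, k, C) -> (B*L, k*C)
        cols = np.lib.stride_tricks.sliding_window_view(xp, k, axis=1)
        cols = np.ascontiguousarray(cols.transpose(0, 1, 3, 2)).reshape(B * L, k * C)
        z = cols @ self.W.value + self.b.value
        y = np.maximum(z, 0.0)
        self._cache = (cols, z > 0, (B, L, C, pl))
        return y.reshape(B, L, self.filters)

    def backward(self, dy):
        cols, mask, (B, L, C, pl) = self._cache
        k = self.kernel
        dz = dy.reshape(B * L, self.filters) * mask
        self.W.grad = cols.T @ dz
        self.b.grad = dz.sum(axis=0)
        dcols = (dz @ self.W.value.T).reshape(B, L, k, C)
        dxp = np.zeros((B, L + k - 1, C), dtype=DTYPE)
        for i in range(k):
            dxp[:, i : i + L, :] += dcols[:, :, i, :]
        return dxp[:, pl : pl + L, :]


class MaxPool1D(Layer):
    """Non-overlapping max pooling (stride = pool size, floor truncation)."""

    def __init__(self, pool: int):
        self.pool = pool
        self._cache = None

    def out_shape(self, in_shape):
        L, C = in_shape
        Lp = L // self.pool
        if Lp == 0:
            raise ArchitectureError(f"pooling size {self.pool} collapses length {L} to 0")
        return (Lp, C)

    def forward(self, x, training, rng):
        B, L, C = x.shape
        p = self.pool
        Lp = L // p
        xr = x[:, : Lp * p, :].reshape(B, Lp, p, C)
        idx = xr.argmax(axis=2)
        y = np.take_along_axis(xr, idx[:, :, None, :], axis=2)[:, :, 0, :]
        self._cache = (idx, (B, L, C))
        return y

    def backward(self, dy):
        idx, (B, L, C) = self._cache
        p = self.pool
        Lp = L // p
        dxr = np.zeros((B, Lp, p, C), dtype=DTYPE)
        np.put_along_axis(dxr, idx[:, :, None, :], dy[:, :, None, :], axis=2)
        dx = np.zeros((B, L, C), dtype=DTYPE)
        dx[:, : Lp * p, :] = dxr.reshape(B, Lp * p, C)
        return dx


class Dropout(Layer):
    """Inverted dropout; identity at inference time."""

    def __init__(self, rate: float):
        if not 0 <= rate < 1:
            raise ArchitectureError(f"dropout rate must be in [0,1), got {rate}")
        self.rate = rate
        self._mask = None

    def out_shape(self, in_shape):
        return in_shape

    def forward(self, x, training, rng):
        if not training or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(DTYPE) / keep
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Flatten(Layer):
    def out_shape(self, in_shape):
        return (int(np.prod(in_shape)),)

    def forward(self, x, training, rng):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Dense(Layer):
    """Fully connected layer; activation in {'relu', None} (the output
    sigmoid is fused with the loss for numerical stability)."""

    def __init__(self, in_dim: int, units: int, activation: str | None, rng: np.random.Generator):
        self.in_dim, self.units, self.activation = in_dim, units, activation
        if activation == "relu":
            w = rng.normal(0.0, np.sqrt(2.0 / in_dim), size=(in_dim, units))
        else:
            limit = np.sqrt(6.0 / (in_dim + units))
            w = rng.uniform(-limit, limit, size=(in_dim, units))
        self.W = Param(w)
        self.b = Param(np.zeros(units))

    def params(self):
        return [self.W, self.b]

    def out_shape(self, in_shape):
        if in_shape != (self.in_dim,):
            raise ArchitectureError(f"Dense expected ({self.in_dim},), got {in_shape}")
        return (self.units,)

    def forward(self, x, training, rng):
        z = x @ self.W.value + self.b.value
        if self.activation == "relu":
            self._cache = (x, z > 0)
            return np.maximum(z, 0.0)
        self._cache = (x, None)
        return z

    def backward(self, dy):
        x, mask = self._cache
        dz = dy if mask is None else dy * mask
        self.W.grad = x.T @ dz
        self.b.grad = dz.sum(axis=0)
        return dz @ self.W.value.T


class BatchNorm(Layer):
    """Batch normalization over flat features, Keras-style defaults
    (momentum 0.99, epsilon 1e-3); running statistics used at inference."""

    def __init__(self, dim: int, momentum: float = 0.99, eps: float = 1e-3):
        self.dim, self.momentum, self.eps = dim, momentum, eps
        self.gamma = Param(np.ones(dim))
        self.beta = Param(np.zeros(dim))
        self.run_mean = np.zeros(dim, dtype=DTYPE)
        self.run_var = np.ones(dim, dtype=DTYPE)

    def params(self):
        return [self.gamma, self.beta]

    def out_shape(self, in_shape):
        return in_shape

    def forward(self, x, training, rng):
        if training:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            m = self.momentum
            self.run_mean = m * self.run_mean + (1 - m) * mu
            self.run_var = m * self.run_var + (1 - m) * var
        else:
            mu, var = self.run_mean, self.run_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        self._cache = (xhat, inv, training, x.shape[0])
        return self.gamma.value * xhat + self.beta.value

    def backward(self, dy):
        xhat, inv, training, B = self._cache
        self.gamma.grad = (dy * xhat).sum(axis=0)
        self.beta.grad = dy.sum(axis=0)
        dxhat = dy * self.gamma.value
        if not training:
            return dxhat * inv
        return (inv / B) * (B * dxhat - dxhat.sum(axis=0) - xhat * (dxhat * xhat).sum(axis=0))


class Adam:
    """Adam optimizer with bias correction (beta1=0.9, beta2=0.999)."""

    def __init__(self, params: list[Param], lr: float = 1e-3, beta1=0.9, beta2=0.999, eps=1e-7):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self):
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.b2**self.t) / (1 - self.b1**self.t)
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad**2
            p.value -= lr_t * m / (np.sqrt(v) + self.eps)


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(z: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy computed from logits; returns (loss, dz)."""
    z = z.astype(np.float64)
    p = sigmoid(z)
    loss = np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z))))
    dz = ((p - y) / z.shape[0]).astype(DTYPE)
    return float(loss), dz
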