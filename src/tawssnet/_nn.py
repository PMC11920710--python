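"""Minimal NumPy layer stack with hand-written backpropagation.

Implements exactly the pieces the point-cloud U-Net needs: dense (shared
per-point) layers, 3x3 same-padding convolutions via im2col, batch
normalization (pre-activation), ReLU, 2x2 max pooling, 2x2 stride-2
transposed convolutions, and Adam with a staircase exponential
learning-rate decay.  All tensors are channels-last: (B, H, W, C) for
spatial layers, (M, C) for dense layers.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Dense",
    "Conv3x3",
    "ConvTranspose2x2",
    "BatchNorm",
    "ReLU",
    "MaxPool2x2",
    "Adam",
]


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)

    @property
    def size(self) -> int:
        return self.value.size


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


DTYPE = np.float32  # network compute precision


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(DTYPE)


class Dense(Layer):
    """Shared per-point affine transform on (M, c_in) tensors."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.w = Param(_he_init(rng, (c_in, c_out), c_in))
        self.b = Param(np.zeros(c_out, dtype=DTYPE))
        self._x: np.ndarray | None = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train):
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, dout):
        self.w.grad += self._x.T @ dout
        self.b.grad += dout.sum(axis=0)
        return dout @ self.w.value.T


def _im2col(x: np.ndarray) -> np.ndarray:
    """3x3 same-padding patches of (B,H,W,C) -> (B*H*W, 9*C), (ki,kj,c) order."""
    b, h, w, c = x.shape
    xp = np.zeros((b, h + 2, w + 2, c), dtype=x.dtype)
    xp[:, 1:-1, 1:-1] = x
    win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(1, 2))
    # win: (B, H, W, C, 3, 3) -> (B, H, W, 3, 3, C)
    cols = np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3))
    return cols.reshape(b * h * w, 9 * c)


class Conv3x3(Layer):
    """3x3 convolution, stride 1, same padding."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.c_in, self.c_out = c_in, c_out
        self.w = Param(_he_init(rng, (3, 3, c_in, c_out), 9 * c_in))
        self.b = Param(np.zeros(c_out, dtype=DTYPE))
        self._cols: np.ndarray | None = None
        self._shape: tuple[int, ...] | None = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train):
        b, h, w, _ = x.shape
        self._shape = x.shape
        self._cols = _im2col(x)
        y = self._cols @ self.w.value.reshape(9 * self.c_in, self.c_out) + self.b.value
        return y.reshape(b, h, w, self.c_out)

    def backward(self, dout):
        b, h, w, _ = self._shape
        dflat = dout.reshape(b * h * w, self.c_out)
        self.w.grad += (self._cols.T @ dflat).reshape(self.w.value.shape)
        self.b.grad += dflat.sum(axis=0)
        # dx = correlation of dout with the 180-deg-rotated, channel-swapped kernel
        w_rot = self.w.value[::-1, ::-1].transpose(0, 1, 3, 2)  # (3,3,c_out,c_in)
        cols_d = _im2col(dout)
        dx = cols_d @ w_rot.reshape(9 * self.c_out, self.c_in)
        return dx.reshape(b, h, w, self.c_in)


class ConvTranspose2x2(Layer):
    """2x2 stride-2 transposed convolution: exact spatial doubling."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.c_in, self.c_out = c_in, c_out
        self.w = Param(_he_init(rng, (2, 2, c_in, c_out), c_in))
        self.b = Param(np.zeros(c_out, dtype=DTYPE))
        self._x: np.ndarray | None = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train):
        self._x = x
        b, h, w, _ = x.shape
        y6 = np.einsum("bijc,pqcf->bipjqf", x, self.w.value)
        return y6.reshape(b, 2 * h, 2 * w, self.c_out) + self.b.value

    def backward(self, dout):
        b, h2, w2, _ = dout.shape
        d6 = dout.reshape(b, h2 // 2, 2, w2 // 2, 2, self.c_out)
        self.w.grad += np.einsum("bijc,bipjqf->pqcf", self._x, d6)
        self.b.grad += dout.sum(axis=(0, 1, 2))
        return np.einsum("bipjqf,pqcf->bijc", d6, self.w.value)


class BatchNorm(Layer):
    """Batch normalization over all axes but the channel axis (last)."""

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(np.ones(c, dtype=DTYPE))
        self.beta = Param(np.zeros(c, dtype=DTYPE))
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(c, dtype=DTYPE)
        self.running_var = np.ones(c, dtype=DTYPE)
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train):
        shape = x.shape
        x2 = x.reshape(-1, shape[-1])
        m = x2.shape[0]
        if train:
            mean = x2.sum(axis=0) / m
            d = x2 - mean
            var = np.einsum("nc,nc->c", d, d) / m
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean = self.running_mean
            d = x2 - mean
            var = self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = d * inv
        self._cache = (xhat, inv, shape)
        return (self.gamma.value * xhat + self.beta.value).reshape(shape)

    def backward(self, dout):
        xhat, inv, shape = self._cache
        d2 = dout.reshape(-1, shape[-1])
        m = d2.shape[0]
        self.gamma.grad += np.einsum("nc,nc->c", d2, xhat)
        self.beta.grad += d2.sum(axis=0)
        dxhat = d2 * self.gamma.value
        dx = inv * (
            dxhat
            - dxhat.sum(axis=0) / m
            - xhat * (np.einsum("nc,nc->c", dxhat, xhat) / m)
        )
        return dx.reshape(shape)


class ReLU(Layer):
    def __init__(self):
        self._mask = None

    def forward(self, x, train):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout):
        return np.where(self._mask, dout, 0.0)


class MaxPool2x2(Layer):
    def __init__(self):
        self._idx = None
        self._shape = None

    def forward(self, x, train):
        b, h, w, c = x.shape
        self._shape = x.shape
        xr = x.reshape(b, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 5, 2, 4)
        xr = np.ascontiguousarray(xr).reshape(b, h // 2, w // 2, c, 4)
        self._idx = xr.argmax(axis=-1)
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dout):
        b, h, w, c = self._shape
        dr = np.zeros((b, h // 2, w // 2, c, 4), dtype=dout.dtype)
        np.put_along_axis(dr, self._idx[..., None], dout[..., None], axis=-1)
        dr = dr.reshape(b, h // 2, w // 2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        return np.ascontiguousarray(dr).reshape(b, h, w, c)


class Adam:
    """Adam with staircase exponential learning-rate decay."""

    def __init__(
        self,
        params: list[Param],
        lr0: float = 1e-3,
        decay_rate: float = 0.9,
        decay_every: int = 2000,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr0, self.decay_rate, self.decay_every = lr0, decay_rate, decay_every
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.step_count = 0

    @property
    def lr(self) -> float:
        return self.lr0 * self.decay_rate ** (self.step_count // self.decay_every)

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.step_count += 1
        lr = self.lr
        b1c = 1.0 - self.beta1**self.step_count
        b2c = 1.0 - self.beta2**self.step_count
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * p.grad
            v *= self.beta2
            v += (1 - self.beta2) * p.grad**2
            p.value -= lr * (m / b1c) / (np.sqrt(v / b2c) + self.eps)
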