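"""Minimal NumPy neural-network layers with exact backpropagation.

Just the pieces the parallel cross network needs: a full-sequence LSTM
(BPTT), 3x3 same-padding convolution, 2x2 ceiling max-pooling,
batch normalization, dropout, dense layers, and Adam.  All tensors are
channels-last (NHWC / NTC) float64.  Every layer caches what its
backward pass needs during a training forward pass; gradients are
verified against finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import expit as sigmoid

__all__ = [
    "Param",
    "Layer",
    "Dense",
    "ReLU",
    "Conv2D",
    "MaxPool2x2Ceil",
    "BatchNorm",
    "Dropout",
    "LSTM",
    "Adam",
    "softmax",
    "glorot_uniform",
]


def glorot_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class Param:
    """A trainable tensor; ``grad`` is allocated lazily on backward."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.asarray(value, dtype=float)
        self.grad: np.ndarray | None = None
        self.name = name

    @property
    def size(self) -> int:
        return self.value.size

    def zero_grad(self) -> None:
        self.grad = np.zeros_like(self.value)

    def add_grad(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.value)
        self.grad += g


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 name: str = "dense"):
        self.w = Param(glorot_uniform(rng, (in_dim, out_dim), in_dim, out_dim),
                       f"{name}.w")
        self.b = Param(np.zeros(out_dim), f"{name}.b")

    def params(self):
        return [self.w, self.b]

    def forward(self, x, training=False):
        self._x = x if training else None
        return x @ self.w.value + self.b.value

    def backward(self, dy):
        self.w.add_grad(self._x.T @ dy)
        self.b.add_grad(dy.sum(axis=0))
        return dy @ self.w.value.T


class ReLU(Layer):
    def forward(self, x, training=False):
        mask = x > 0
        self._mask = mask if training else None
        return x * mask

    def backward(self, dy):
        return dy * self._mask


class Conv2D(Layer):
    """3x3 (or k x k) stride-1 convolution with size-preserving padding."""

    def __init__(self, in_ch: int, filters: int, rng: np.random.Generator,
                 kernel: tuple[int, int] = (3, 3), name: str = "conv"):
        if filters <= 0:
            raise ValueError("filters must be positive")
        kh, kw = kernel
        if kh % 2 == 0 or kw % 2 == 0:
            raise ValueError("kernel dims must be odd for same padding")
        fan_in, fan_out = kh * kw * in_ch, kh * kw * filters
        self.kernel = kernel
        self.in_ch, self.filters = in_ch, filters
        # weight layout (kh, kw, C_in, F)
        self.w = Param(glorot_uniform(rng, (kh, kw, in_ch, filters), fan_in, fan_out),
                       f"{name}.w")
        self.b = Param(np.zeros(filters), f"{name}.b")

    def params(self):
        return [self.w, self.b]

    def _pad(self, x):
        ph, pw = self.kernel[0] // 2, self.kernel[1] // 2
        return np.pad(x, ((0, 0), (ph, ph), (pw, pw), (0, 0)))

    def forward(self, x, training=False):
        kh, kw = self.kernel
        b, h, w, c = x.shape
        xp = self._pad(x)
        # (B, H, W, C, kh, kw) -> flatten patch dims in (kh, kw, C) order
        cols = sliding_window_view(xp, (kh, kw), axis=(1, 2))
        cols = cols.transpose(0, 1, 2, 4, 5, 3).reshape(b * h * w, kh * kw * c)
        wmat = self.w.value.reshape(kh * kw * c, self.filters)
        y = cols @ wmat + self.b.value
        if training:
            self._cols, self._xshape = cols, x.shape
        return y.reshape(b, h, w, self.filters)

    def backward(self, dy):
        kh, kw = self.kernel
        b, h, w, c = self._xshape
        dyf = dy.reshape(b * h * w, self.filters)
        dwmat = self._cols.T @ dyf
        self.w.add_grad(dwmat.reshape(kh, kw, c, self.filters))
        self.b.add_grad(dyf.sum(axis=0))
        ph, pw = kh // 2, kw // 2
        dxp = np.zeros((b, h + 2 * ph, w + 2 * pw, c))
        for i in range(kh):
            for j in range(kw):
                # dy (B,H,W,F) @ w[i,j] (C,F)^T  -> contribution at offset (i, j)
                dxp[:, i : i + h, j : j + w, :] += dy @ self.w.value[i, j].T
        return dxp[:, ph : ph + h, pw : pw + w, :]


class MaxPool2x2Ceil(Layer):
    """2x2 stride-2 max pooling with ceiling semantics (output ceil(d/2)).

    Odd edges are padded with -inf so the partial window's max is still a
    real sample; gradients flow only to each window's argmax.
    """

    def forward(self, x, training=False):
        b, h, w, c = x.shape
        h2, w2 = -(-h // 2), -(-w // 2)
        xp = np.pad(x, ((0, 0), (0, 2 * h2 - h), (0, 2 * w2 - w), (0, 0)),
                    constant_values=-np.inf)
        win = xp.reshape(b, h2, 2, w2, 2, c).transpose(0, 1, 3, 2, 4, 5)
        win = win.reshape(b, h2, w2, 4, c)
        idx = win.argmax(axis=3)
        out = np.take_along_axis(win, idx[:, :, :, None, :], axis=3)[:, :, :, 0, :]
        if training:
            self._idx, self._inshape = idx, (b, h, w, c)
        return out

    def backward(self, dy):
        b, h, w, c = self._inshape
        h2, w2 = -(-h // 2), -(-w // 2)
        dwin = np.zeros((b, h2, w2, 4, c))
        np.put_along_axis(dwin, self._idx[:, :, :, None, :], dy[:, :, :, None, :],
                          axis=3)
        dxp = dwin.reshape(b, h2, w2, 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
        dxp = dxp.reshape(b, 2 * h2, 2 * w2, c)
        return dxp[:, :h, :w, :]


class BatchNorm(Layer):
    """Per-channel batch normalization over (B, H, W) for NHWC input."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5,
                 name: str = "bn"):
        self.gamma = Param(np.ones(channels), f"{name}.gamma")
        self.beta = Param(np.zeros(channels), f"{name}.beta")
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, training=False):
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mean
            self.running_var = m * self.running_var + (1 - m) * var
            inv_std = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mean) * inv_std
            self._xhat, self._inv_std, self._axes = xhat, inv_std, axes
            self._n = x.size // x.shape[-1]
        else:
            xhat = (x - self.running_mean) / np.sqrt(self.running_var + self.eps)
        return self.gamma.value * xhat + self.beta.value

    def backward(self, dy):
        axes, n = self._axes, self._n
        xhat, inv_std = self._xhat, self._inv_std
        self.gamma.add_grad((dy * xhat).sum(axis=axes))
        self.beta.add_grad(dy.sum(axis=axes))
        dxhat = dy * self.gamma.value
        return (inv_std / n) * (
            n * dxhat
            - dxhat.sum(axis=axes, keepdims=True)
            - xhat * (dxhat * xhat).sum(axis=axes, keepdims=True)
        )


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate, self.rng = rate, rng

    def forward(self, x, training=False):
        if not training or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class LSTM(Layer):
    """Full-sequence LSTM: (B, T, I) -> (B, T, H).

    Single fused weight matrix over [x_t, h_{t-1}] with gate order
    (input, forget, cell, output); forget-gate bias initialized to 1.
    Backward is standard truncated-nowhere BPTT over the whole sequence.
    """

    def __init__(self, input_size: int, units: int, rng: np.random.Generator,
                 name: str = "lstm"):
        self.input_size, self.units = input_size, units
        fan_in = input_size + units
        self.w = Param(glorot_uniform(rng, (fan_in, 4 * units), fan_in, 4 * units),
                       f"{name}.w")
        b = np.zeros(4 * units)
        b[units : 2 * units] = 1.0  # forget gate bias
        self.b = Param(b, f"{name}.b")

    def params(self):
        return [self.w, self.b]

    def forward(self, x, training=False):
        b_, t_, _ = x.shape
        h_dim = self.units
        h = np.zeros((b_, h_dim))
        c = np.zeros((b_, h_dim))
        out = np.empty((b_, t_, h_dim))
        cache = [] if training else None
        for t in range(t_):
            xt = x[:, t, :]
            zin = np.concatenate([xt, h], axis=1)
            z = zin @ self.w.value + self.b.value
            i = sigmoid(z[:, :h_dim])
            f = sigmoid(z[:, h_dim : 2 * h_dim])
            g = np.tanh(z[:, 2 * h_dim : 3 * h_dim])
            o = sigmoid(z[:, 3 * h_dim :])
            c_prev = c
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h = o * tc
            out[:, t, :] = h
            if training:
                cache.append((zin, i, f, g, o, c_prev, tc))
        self._cache = cache
        self._in_shape = x.shape
        return out

    def backward(self, dy):
        b_, t_, _ = self._in_shape
        h_dim = self.units
        dx = np.empty((b_, t_, self.input_size))
        dh_next = np.zeros((b_, h_dim))
        dc_next = np.zeros((b_, h_dim))
        dw = np.zeros_like(self.w.value)
        db = np.zeros_like(self.b.value)
        wT = self.w.value.T
        for t in range(t_ - 1, -1, -1):
            zin, i, f, g, o, c_prev, tc = self._cache[t]
            dh = dy[:, t, :] + dh_next
            do = dh * tc
            dc = dc_next + dh * o * (1.0 - tc * tc)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g * g),
                 do * o * (1 - o)], axis=1)
            dw += zin.T @ dz
            db += dz.sum(axis=0)
            dzin = dz @ wT
            dx[:, t, :] = dzin[:, : self.input_size]
            dh_next = dzin[:, self.input_size :]
            dc_next = dc * f
        self.w.add_grad(dw)
        self.b.add_grad(db)
        return dx


class Adam:
    """Adam optimizer with the standard bias-corrected moments."""

    def __init__(self, params: list[Param], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._m = [None] * len(params)
        self._v = [None] * len(params)

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1 - b1**self.t
        bc2 = 1 - b2**self.t
        for k, p in enumerate(self.params):
            if p.grad is None:
                continue
            if self._m[k] is None:
                self._m[k] = np.zeros_like(p.value)
                self._v[k] = np.zeros_like(p.value)
            self._m[k] = b1 * self._m[k] + (1 - b1) * p.grad
            self._v[k] = b2 * self._v[k] + (1 - b2) * p.grad**2
            mhat = self._m[k] / bc1
            vhat = self._v[k] / bc2
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
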