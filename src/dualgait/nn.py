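"""Minimal numpy neural-network core for the dual-branch CNN-LSTM.

Layers keep explicit caches and implement exact analytic backward passes
(validated against finite differences in the test suite).  Everything runs
in float64 on a single CPU; the model sizes used here (a few tens of
thousands of parameters, windows of 300 samples) train in seconds to
minutes, which is the intended desk scale.

Conventions: convolutional activations are ``(N, C, L)``; the LSTM consumes
``(N, T, F)`` and returns its final hidden state.
"""

from __future__ import annotations

from typing import List, Sequence

import numpy as np

__all__ = [
    "Conv1d",
    "BatchNorm1d",
    "ReLU",
    "MaxPool1d",
    "Dropout",
    "LSTM",
    "Dense",
    "Sequential",
    "softmax",
    "softmax_cross_entropy",
    "Adam",
]


class Layer:
    """Base class: layers expose aligned ``params`` and ``grads`` lists."""

    def params(self) -> List[np.ndarray]:
        return []

    def grads(self) -> List[np.ndarray]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv1d(Layer):
    """Same-padded 1-D convolution (odd kernel)."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator):
        if kernel % 2 == 0:
            raise ValueError("kernel size must be odd")
        scale = np.sqrt(2.0 / (in_ch * kernel))
        self.W = rng.normal(0.0, scale, size=(out_ch, in_ch, kernel))
        self.b = np.zeros(out_ch)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.kernel = kernel

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x, train=False):
        p = self.kernel // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p)))
        self._windows = np.lib.stride_tricks.sliding_window_view(xp, self.kernel, axis=2)
        # windows: (N, C, L, k)
        out = np.einsum("nclk,ock->nol", self._windows, self.W, optimize=True)
        return out + self.b[None, :, None]

    def backward(self, dout):
        N, C, L, k = self._windows.shape
        self.dW[...] = np.einsum("nclk,nol->ock", self._windows, dout, optimize=True)
        self.db[...] = dout.sum(axis=(0, 2))
        p = k // 2
        dxp = np.zeros((N, C, L + 2 * p))
        tmp = np.einsum("nol,ock->nclk", dout, self.W, optimize=True)
        for j in range(k):
            dxp[:, :, j : j + L] += tmp[:, :, :, j]
        return dxp[:, :, p : p + L]


class BatchNorm1d(Layer):
    """Per-channel batch normalization over the (N, L) axes."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(channels)
        self.beta = np.zeros(channels)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.dgamma, self.dbeta]

    def forward(self, x, train=False):
        if train:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean[None, :, None]) / self._std[None, :, None]
        self._train = train
        return self.gamma[None, :, None] * self._xhat + self.beta[None, :, None]

    def backward(self, dout):
        self.dgamma[...] = (dout * self._xhat).sum(axis=(0, 2))
        self.dbeta[...] = dout.sum(axis=(0, 2))
        dxhat = dout * self.gamma[None, :, None]
        if not self._train:
            return dxhat / self._std[None, :, None]
        m = dout.shape[0] * dout.shape[2]
        # standard batch-norm backward, reduced over (N, L)
        sum_dxhat = dxhat.sum(axis=(0, 2), keepdims=True)
        sum_dxhat_xhat = (dxhat * self._xhat).sum(axis=(0, 2), keepdims=True)
        return (
            dxhat - sum_dxhat / m - self._xhat * sum_dxhat_xhat / m
        ) / self._std[None, :, None]


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class MaxPool1d(Layer):
    """Non-overlapping max pooling (window = stride = ``size``)."""

    def __init__(self, size: int = 2):
        self.size = size

    def forward(self, x, train=False):
        N, C, L = x.shape
        Lp = L // self.size
        xr = x[:, :, : Lp * self.size].reshape(N, C, Lp, self.size)
        self._argmax = xr.argmax(axis=3)
        self._in_shape = x.shape
        return xr.max(axis=3)

    def backward(self, dout):
        N, C, Lp = dout.shape
        dx = np.zeros(self._in_shape)
        dxr = dx[:, :, : Lp * self.size].reshape(N, C, Lp, self.size)
        n, c, l = np.ogrid[:N, :C, :Lp]
        dxr[n, c, l, self._argmax] = dout
        return dx


class Dropout(Layer):
    def __init__(self, rate: float, rng: np.random.Generator):
        if not (0 <= rate < 1):
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x, train=False):
        if train and self.rate > 0:
            self._mask = (self.rng.random(x.shape) >= self.rate) / (1 - self.rate)
        else:
            self._mask = np.ones_like(x)
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class LSTM(Layer):
    """Single-layer LSTM returning the final hidden state.

    Gate order in the stacked weight matrices is (input, forget, cell, output).
    Backward is full BPTT from the final-state gradient.
    """

    def __init__(self, input_size: int, hidden: int, rng: np.random.Generator):
        s = np.sqrt(1.0 / hidden)
        self.Wx = rng.uniform(-s, s, size=(input_size, 4 * hidden))
        self.Wh = rng.uniform(-s, s, size=(hidden, 4 * hidden))
        self.b = np.zeros(4 * hidden)
        self.b[hidden : 2 * hidden] = 1.0  # forget-gate bias init
        self.dWx = np.zeros_like(self.Wx)
        self.dWh = np.zeros_like(self.Wh)
        self.db = np.zeros_like(self.b)
        self.hidden = hidden

    def params(self):
        return [self.Wx, self.Wh, self.b]

    def grads(self):
        return [self.dWx, self.dWh, self.db]

    @staticmethod
    def _sigmoid(z):
        return 1.0 / (1.0 + np.exp(-np.clip(z, -50, 50)))

    def forward(self, x, train=False):
        N, T, F = x.shape
        H = self.hidden
        h = np.zeros((N, H))
        c = np.zeros((N, H))
        self._x = x
        self._cache = []
        for t in range(T):
            z = x[:, t, :] @ self.Wx + h @ self.Wh + self.b
            i = self._sigmoid(z[:, :H])
            f = self._sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = self._sigmoid(z[:, 3 * H :])
            c_prev = c
            c = f * c_prev + i * g
            tanh_c = np.tanh(c)
            h_prev_cache = h
            h = o * tanh_c
            self._cache.append((i, f, g, o, c_prev, tanh_c, h_prev_cache))
        return h

    def backward(self, dh_last):
        x = self._x
        N, T, F = x.shape
        H = self.hidden
        self.dWx[...] = 0
        self.dWh[...] = 0
        self.db[...] = 0
        dx = np.zeros_like(x)
        dh = dh_last.copy()
        dc = np.zeros((N, H))
        for t in range(T - 1, -1, -1):
            i, f, g, o, c_prev, tanh_c, h_prev = self._cache[t]
            do = dh * tanh_c
            dc = dc + dh * o * (1 - tanh_c**2)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [
                    di * i * (1 - i),
                    df * f * (1 - f),
                    dg * (1 - g**2),
                    do * o * (1 - o),
                ],
                axis=1,
            )
            self.dWx += x[:, t, :].T @ dz
            self.dWh += h_prev.T @ dz
            self.db += dz.sum(axis=0)
            dx[:, t, :] = dz @ self.Wx.T
            dh = dz @ self.Wh.T
            dc = dc * f
        return dx


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        s = np.sqrt(2.0 / in_dim)
        self.W = rng.normal(0.0, s, size=(in_dim, out_dim))
        self.b = np.zeros(out_dim)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x, train=False):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout):
        self.dW[...] = self._x.T @ dout
        self.db[...] = dout.sum(axis=0)
        return dout @ self.W.T


class Sequential(Layer):
    def __init__(self, layers: Sequence[Layer]):
        self.layers = list(layers)

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def grads(self):
        return [g for layer in self.layers for g in layer.grads()]

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, y: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and the gradient w.r.t. the logits."""
    n = logits.shape[0]
    p = softmax(logits)
    loss = -np.log(np.maximum(p[np.arange(n), y], 1e-300)).mean()
    dlogits = p.copy()
    dlogits[np.arange(n), y] -= 1.0
    return float(loss), dlogits / n


class Adam:
    """Adam with L2 weight decay and stepwise learning-rate halving."""

    def __init__(
        self,
        params: List[np.ndarray],
        grads: List[np.ndarray],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ):
        self.params = params
        self.grads = grads
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            if self.weight_decay and p.ndim > 1:  # decay weights, not biases
                g = g + self.weight_decay * p
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g**2
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
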