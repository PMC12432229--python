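"""Minimal CPU convolutional-network toolkit (numpy forward/backward).

Implements exactly the pieces the segmentation model needs — 3x3 (optionally
dilated) convolutions, batch normalization, ReLU, 2x2 max pooling, nearest
upsampling, 1x1 heads and the Adam optimizer — with explicit, hand-derived
backward passes.  Arrays are NCHW float32 except where float64 improves
gradient stability.  Desk-scale by design: the intended workloads are
64–128 px patches and a handful of filters per layer.
"""

from __future__ import annotations

import numpy as np


class Layer:
    """Base: layers expose params/grads pairs and forward/backward."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params, self.grads = [], []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2d(Layer):
    """3x3 'same' convolution with configurable dilation (or 1x1 head).

    Dilation inserts gaps between kernel taps, enlarging the receptive
    field at constant parameter count.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int = 3, dilation: int = 1,
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng()
        fan_in = c_in * kernel * kernel
        self.w = (rng.standard_normal((c_out, c_in, kernel, kernel)) * np.sqrt(2.0 / fan_in)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.kernel, self.dilation = kernel, dilation
        self.pad = dilation * (kernel // 2)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        p, d, k = self.pad, self.dilation, self.kernel
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        self._xp_shape, self._xp = xp.shape, xp
        n, _, hp, wp = xp.shape
        h, w = x.shape[2], x.shape[3]
        y = np.zeros((n, self.w.shape[0], h, w), dtype=np.float32)
        for ky in range(k):
            for kx in range(k):
                patch = xp[:, :, ky * d: ky * d + h, kx * d: kx * d + w]
                y += np.einsum("oi,nihw->nohw", self.w[:, :, ky, kx], patch, optimize=True)
        return y + self.b[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        p, d, k = self.pad, self.dilation, self.kernel
        xp = self._xp
        h, w = dy.shape[2], dy.shape[3]
        dxp = np.zeros_like(xp)
        dw, db = self.grads
        db += dy.sum(axis=(0, 2, 3))
        for ky in range(k):
            for kx in range(k):
                patch = xp[:, :, ky * d: ky * d + h, kx * d: kx * d + w]
                dw[:, :, ky, kx] += np.einsum("nohw,nihw->oi", dy, patch, optimize=True)
                dxp[:, :, ky * d: ky * d + h, kx * d: kx * d + w] += np.einsum(
                    "oi,nohw->nihw", self.w[:, :, ky, kx], dy, optimize=True
                )
        self._xp = None
        return dxp[:, :, p: p + h, p: p + w] if p else dxp


class BatchNorm2d(Layer):
    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5) -> None:
        super().__init__()
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.running_mean = np.zeros(c, dtype=np.float64)
        self.running_var = np.ones(c, dtype=np.float64)
        self.momentum, self.eps = momentum, eps
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3), dtype=np.float64)
            var = x.var(axis=(0, 2, 3), dtype=np.float64)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat.astype(np.float32), inv)
        return (self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]).astype(np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        m = dy.shape[0] * dy.shape[2] * dy.shape[3]
        dgamma = (dy * xhat).sum(axis=(0, 2, 3))
        dbeta = dy.sum(axis=(0, 2, 3))
        self.grads[0] += dgamma
        self.grads[1] += dbeta
        gi = (self.gamma * inv).astype(np.float32)[None, :, None, None]
        dx = gi * (dy - dbeta[None, :, None, None] / m - xhat * dgamma[None, :, None, None] / m)
        self._cache = None
        return dx


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0.0)


class MaxPool2d(Layer):
    """2x2 max pooling; spatial dims must be even."""

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        y = xr.max(axis=(3, 5))
        self._mask = xr == y[:, :, :, None, :, None]
        self._shape = x.shape
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        dxr = self._mask * dy[:, :, :, None, :, None]
        return dxr.reshape(n, c, h, w)


class UpsampleNearest2(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = dy.shape
        return dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class Sigmoid(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._y = 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))
        return self._y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._y * (1.0 - self._y)


class Sequential(Layer):
    def __init__(self, *layers: Layer) -> None:
        super().__init__()
        self.layers = list(layers)
        for lay in self.layers:
            self.params += lay.params
            self.grads += lay.grads

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        for lay in self.layers:
            x = lay.forward(x, train)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for lay in reversed(self.layers):
            dy = lay.backward(dy)
        return dy


class Adam:
    def __init__(self, params: list[np.ndarray], grads: list[np.ndarray],
                 lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.params, self.grads = params, grads
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p, dtype=np.float64) for p in params]
        self.v = [np.zeros_like(p, dtype=np.float64) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)

    def zero_grad(self) -> None:
        for g in self.grads:
            g[...] = 0.0


def parameter_count(layer: Layer) -> int:
    return int(sum(p.size for p in layer.params))
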