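"""Minimal NumPy neural-network primitives for small 3-D volumes.

No deep-learning framework is assumed: 3-D (optionally grouped/depthwise)
convolutions are implemented via ``sliding_window_view`` patch extraction
and einsum contractions, with explicit backward passes and an Adam
optimizer.  All initialization is driven by a ``numpy.random.Generator``,
so training is bit-reproducible on a fixed seed (single-threaded BLAS
nondeterminism aside).

Tensor layout: ``(N, C, D, H, W)``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Conv3d", "ReLU", "Dense", "GlobalAvgPool3d", "Sequential", "Adam", "sigmoid"]


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class Layer:
    def parameters(self) -> list[np.ndarray]:
        return []

    def gradients(self) -> list[np.ndarray]:
        return []


class Conv3d(Layer):
    """Grouped 3-D convolution, stride ``s``, symmetric zero padding ``p``.

    ``groups=in_channels`` with ``out_channels=in_channels`` gives a
    depthwise convolution; ``kernel=1`` gives a pointwise (channel-mixing)
    convolution.  Together they form the separable blocks used by the
    parameter-efficient image branches.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel: int = 3,
                 stride: int = 1, padding: int = 0, groups: int = 1,
                 rng: np.random.Generator | None = None):
        if in_channels % groups or out_channels % groups:
            raise ValueError("channels must be divisible by groups")
        rng = rng or np.random.default_rng(0)
        self.cin, self.cout, self.k = in_channels, out_channels, kernel
        self.s, self.p, self.g = stride, padding, groups
        fan_in = (in_channels // groups) * kernel**3
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            size=(groups, out_channels // groups,
                                  in_channels // groups, kernel, kernel, kernel))
        self.b = np.zeros(out_channels)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n = x.shape[0]
        if self.p:
            x = np.pad(x, ((0, 0), (0, 0)) + ((self.p, self.p),) * 3)
        view = sliding_window_view(x, (self.k, self.k, self.k), axis=(2, 3, 4))
        view = view[:, :, ::self.s, ::self.s, ::self.s]
        do, ho, wo = view.shape[2:5]
        viewg = view.reshape(n, self.g, self.cin // self.g, do, ho, wo,
                             self.k, self.k, self.k)
        out = np.einsum("ngcdhwijk,gocijk->ngodhw", viewg, self.W, optimize=True)
        out = out.reshape(n, self.cout, do, ho, wo) + self.b[None, :, None, None, None]
        if train:
            self._cache = (viewg, x.shape)
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        viewg, xp_shape = self._cache
        n, _, do, ho, wo = dy.shape
        dyg = dy.reshape(n, self.g, self.cout // self.g, do, ho, wo)
        self.dW += np.einsum("ngcdhwijk,ngodhw->gocijk", viewg, dyg, optimize=True)
        self.db += dy.sum(axis=(0, 2, 3, 4)).ravel()
        dxp = np.zeros((n, self.cin) + xp_shape[2:])
        dxg = dxp.reshape(n, self.g, self.cin // self.g, *xp_shape[2:])
        for i in range(self.k):
            for j in range(self.k):
                for k in range(self.k):
                    contrib = np.einsum("ngodhw,goc->ngcdhw", dyg,
                                        self.W[:, :, :, i, j, k], optimize=True)
                    dxg[:, :, :,
                        i:i + self.s * do:self.s,
                        j:j + self.s * ho:self.s,
                        k:k + self.s * wo:self.s] += contrib
        if self.p:
            dxp = dxp[:, :, self.p:-self.p, self.p:-self.p, self.p:-self.p]
        return dxp

    def parameters(self):
        return [self.W, self.b]

    def gradients(self):
        return [self.dW, self.db]


class ReLU(Layer):
    def forward(self, x, train: bool = True):
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, dy):
        return dy * self._mask


class GlobalAvgPool3d(Layer):
    def forward(self, x, train: bool = True):
        self._shape = x.shape
        return x.mean(axis=(2, 3, 4))

    def backward(self, dy):
        n, c, d, h, w = self._shape
        return np.broadcast_to(dy[:, :, None, None, None], self._shape) / (d * h * w)


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.W = rng.normal(0.0, np.sqrt(2.0 / in_features), size=(in_features, out_features))
        self.b = np.zeros(out_features)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x, train: bool = True):
        if train:
            self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        self.dW += self._x.T @ dy
        self.db += dy.sum(axis=0)
        return dy @ self.W.T


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def forward(self, x, train: bool = True):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def parameters(self):
        return [p for l in self.layers for p in l.parameters()]

    def gradients(self):
        return [g for l in self.layers for g in l.gradients()]


class Adam:
    """Adam optimizer over a flat list of parameter/gradient array pairs."""

    def __init__(self, params: list[np.ndarray], grads: list[np.ndarray],
                 lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.params, self.grads = params, grads
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for g in self.grads:
            g[...] = 0.0
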