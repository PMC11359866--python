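"""Minimal NumPy neural-network layers with manual backpropagation.

Supports exactly what the SE-RCNet architecture needs: 3×3 same-padding
convolutions (im2col + BLAS matmul), batch normalization, ReLU, 2×2
max-pooling with floor semantics, squeeze-and-excite channel gating,
dense layers, softmax cross-entropy and Adam.  All tensors are float32
NCHW.  Every source of randomness is a caller-supplied Generator, so
training is bit-reproducible on a given seed.
"""

from __future__ import annotations

from typing import List, Optional

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

F32 = np.float32


def _conv3x3(x: np.ndarray, w: np.ndarray, b: Optional[np.ndarray]):
    """3×3 stride-1 same-padding convolution.

    x: (N, Cin, H, W); w: (Cout, Cin, 3, 3).  Returns (y, cols) where
    cols is the (N*H*W, Cin*9) patch matrix reused by the backward pass.
    """
    n, c, h, wd = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    # (N, C, H, W, 3, 3) -> (N, H, W, C, 3, 3) -> (N*H*W, C*9)
    patches = sliding_window_view(xp, (3, 3), axis=(2, 3))
    cols = np.ascontiguousarray(patches.transpose(0, 2, 3, 1, 4, 5)).reshape(
        n * h * wd, c * 9
    )
    y = cols @ w.reshape(w.shape[0], -1).T
    if b is not None:
        y += b
    return y.reshape(n, h, wd, w.shape[0]).transpose(0, 3, 1, 2), cols


class Layer:
    def params(self) -> List[np.ndarray]:
        return []

    def grads(self) -> List[np.ndarray]:
        return []


class Conv3x3(Layer):
    """3×3 convolution, stride 1, same padding, He-initialized."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * 9))
        self.w = (rng.standard_normal((c_out, c_in, 3, 3)) * scale).astype(F32)
        self.b = np.zeros(c_out, dtype=F32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        y, self._cols = _conv3x3(x, self.w, self.b)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c_out, h, w = dy.shape
        dyf = dy.transpose(0, 2, 3, 1).reshape(-1, c_out)
        self.dw[...] = (dyf.T @ self._cols).reshape(self.w.shape)
        self.db[...] = dyf.sum(axis=0)
        # dx = full correlation of dy with spatially-flipped kernels
        w_flip = self.w[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
        dx, _ = _conv3x3(dy, np.ascontiguousarray(w_flip), None)
        self._cols = None
        return dx

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]


class BatchNorm(Layer):
    """Per-channel batch normalization with running statistics."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(c, dtype=F32)
        self.beta = np.zeros(c, dtype=F32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(c, dtype=F32)
        self.running_var = np.ones(c, dtype=F32)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        axes = (0, 2, 3)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mean
            ).astype(F32)
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var
            ).astype(F32)
        else:
            mean, var = self.running_mean, self.running_var
        self._istd = (1.0 / np.sqrt(var + self.eps)).astype(F32)
        self._xhat = (x - mean[None, :, None, None]) * self._istd[
            None, :, None, None
        ]
        return self.gamma[None, :, None, None] * self._xhat + self.beta[
            None, :, None, None
        ]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        axes = (0, 2, 3)
        m = dy.shape[0] * dy.shape[2] * dy.shape[3]
        self.dgamma[...] = (dy * self._xhat).sum(axis=axes)
        self.dbeta[...] = dy.sum(axis=axes)
        g = self.gamma[None, :, None, None]
        istd = self._istd[None, :, None, None]
        dxhat = dy * g
        dx = (
            dxhat
            - dxhat.mean(axis=axes, keepdims=True)
            - self._xhat * (dxhat * self._xhat).mean(axis=axes, keepdims=True)
        ) * istd
        self._xhat = None
        return dx.astype(F32)

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.dgamma, self.dbeta]


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = dy * self._mask
        self._mask = None
        return dx


class MaxPool2(Layer):
    """2×2 max pooling, stride 2, valid windows (odd trailing row/col dropped)."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        h2, w2 = h // 2, w // 2
        if h2 < 1 or w2 < 1:
            raise ValueError(f"spatial size {h}x{w} too small to pool")
        self._in_shape = x.shape
        xt = x[:, :, : 2 * h2, : 2 * w2].reshape(n, c, h2, 2, w2, 2)
        flat = xt.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h2, w2, 4)
        self._arg = flat.argmax(axis=-1)  # first max on ties
        return flat.max(axis=-1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h2, w2 = dy.shape
        dflat = np.zeros((n, c, h2, w2, 4), dtype=F32)
        np.put_along_axis(dflat, self._arg[..., None], dy[..., None], axis=-1)
        dxt = dflat.reshape(n, c, h2, w2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        dx = np.zeros(self._in_shape, dtype=F32)
        dx[:, :, : 2 * h2, : 2 * w2] = dxt.reshape(n, c, 2 * h2, 2 * w2)
        self._arg = None
        return dx


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


class SqueezeExcite(Layer):
    """Channel attention: global average pool → bottleneck → sigmoid gates.

    The bottleneck width is max(1, C // reduction).  Setting ``enabled``
    to False makes the module an identity (gates pinned to 1), which is
    useful for ablation against the plain residual block.
    """

    def __init__(self, c: int, reduction: int, rng: np.random.Generator):
        cr = max(1, c // reduction)
        self.w1 = (rng.standard_normal((cr, c)) * np.sqrt(2.0 / c)).astype(F32)
        self.b1 = np.zeros(cr, dtype=F32)
        self.w2 = (rng.standard_normal((c, cr)) * np.sqrt(1.0 / cr)).astype(F32)
        self.b2 = np.zeros(c, dtype=F32)
        self.dw1 = np.zeros_like(self.w1)
        self.db1 = np.zeros_like(self.b1)
        self.dw2 = np.zeros_like(self.w2)
        self.db2 = np.zeros_like(self.b2)
        self.enabled = True

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not self.enabled:
            return x
        self._x = x
        self._z = x.mean(axis=(2, 3))  # squeeze: (N, C)
        self._h = np.maximum(self._z @ self.w1.T + self.b1, 0.0)
        self._g = _sigmoid(self._h @ self.w2.T + self.b2)
        return x * self._g[:, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if not self.enabled:
            return dy
        x, g, h, z = self._x, self._g, self._h, self._z
        hw = x.shape[2] * x.shape[3]
        dg = (dy * x).sum(axis=(2, 3))
        da = dg * g * (1.0 - g)  # through sigmoid
        self.dw2[...] = da.T @ h
        self.db2[...] = da.sum(axis=0)
        dh = (da @ self.w2) * (h > 0)
        self.dw1[...] = dh.T @ z
        self.db1[...] = dh.sum(axis=0)
        dz = dh @ self.w1
        dx = dy * g[:, :, None, None] + dz[:, :, None, None] / hw
        self._x = self._g = self._h = self._z = None
        return dx.astype(F32)

    def params(self):
        return [self.w1, self.b1, self.w2, self.b2]

    def grads(self):
        return [self.dw1, self.db1, self.dw2, self.db2]


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = (rng.standard_normal((n_out, n_in)) * np.sqrt(2.0 / n_in)).astype(F32)
        self.b = np.zeros(n_out, dtype=F32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        return x @ self.w.T + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.dw[...] = dy.T @ self._x
        self.db[...] = dy.sum(axis=0)
        dx = dy @ self.w
        self._x = None
        return dx

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]


def softmax_xent(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy and its gradient w.r.t. logits."""
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=1, keepdims=True)
    n = logits.shape[0]
    loss = -np.log(np.maximum(p[np.arange(n), labels], 1e-30)).mean()
    dz = p.copy()
    dz[np.arange(n), labels] -= 1.0
    return float(loss), (dz / n).astype(F32)


class Adam:
    def __init__(self, params: List[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: List[np.ndarray]) -> None:
        if self.lr == 0.0:
            return
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)
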