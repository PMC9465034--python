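"""Layers with explicit forward/backward passes.

Tensor layout is NCHW. Each layer caches what its backward pass needs during
forward; one forward/backward pair may be in flight at a time, which is all a
plain training loop requires.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Param", "Conv2d", "BatchNorm2d", "ReLU", "Dense", "GlobalAvgPool"]


class Param:
    """A trainable array and its gradient accumulator."""

    __slots__ = ("v", "g")

    def __init__(self, value: np.ndarray):
        self.v = value
        self.g = np.zeros_like(value)

    def zero_grad(self) -> None:
        self.g[...] = 0


class Conv2d:
    """3x3/1x1 convolution via im2col + BLAS matmul. He-normal init, no bias
    (a BatchNorm always follows in the networks built here; the classifier
    head uses :class:`Dense`, which does carry a bias)."""

    def __init__(self, in_ch: int, out_ch: int, ksize: int = 3,
                 stride: int = 1, pad: int | None = None,
                 rng: np.random.Generator | None = None,
                 dtype=np.float32):
        if pad is None:
            pad = ksize // 2
        rng = rng or np.random.default_rng()
        std = np.sqrt(2.0 / (ksize * ksize * in_ch))
        self.W = Param(rng.normal(0, std, (out_ch, in_ch, ksize, ksize))
                       .astype(dtype))
        self.stride, self.pad, self.ksize = stride, pad, ksize
        self.in_ch, self.out_ch = in_ch, out_ch

    def params(self) -> list[Param]:
        return [self.W]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        k, s, p = self.ksize, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        # (N, C, Ho, Wo, k, k) -> (N, Ho, Wo, C*k*k)
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5))
        n, ho, wo = cols.shape[:3]
        cols = cols.reshape(n, ho, wo, c * k * k)
        y = cols @ self.W.v.reshape(self.out_ch, -1).T
        self._cache = (cols, x.shape)
        return np.ascontiguousarray(y.transpose(0, 3, 1, 2))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, xshape = self._cache
        n, c, h, w = xshape
        k, s, p = self.ksize, self.stride, self.pad
        dyt = dy.transpose(0, 2, 3, 1)  # (N, Ho, Wo, F)
        ho, wo = dyt.shape[1:3]
        self.W.g += np.tensordot(dyt, cols, axes=([0, 1, 2], [0, 1, 2])) \
            .reshape(self.W.v.shape)
        dcols = (dyt @ self.W.v.reshape(self.out_ch, -1)) \
            .reshape(n, ho, wo, c, k, k)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=dy.dtype)
        dct = dcols.transpose(0, 3, 1, 2, 4, 5)  # (N, C, Ho, Wo, k, k)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + s * ho:s, j:j + s * wo:s] += dct[..., i, j]
        return dxp[:, :, p:p + h, p:p + w] if p else dxp


class BatchNorm2d:
    """Per-channel batch normalization with running statistics for inference."""

    def __init__(self, ch: int, momentum: float = 0.9, eps: float = 1e-5,
                 dtype=np.float32):
        self.gamma = Param(np.ones(ch, dtype=dtype))
        self.beta = Param(np.zeros(ch, dtype=dtype))
        self.running_mean = np.zeros(ch, dtype=dtype)
        self.running_var = np.ones(ch, dtype=dtype)
        self.momentum, self.eps = momentum, eps

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mean
            self.running_var = m * self.running_var + (1 - m) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        if train:
            self._cache = (xhat, inv, x.shape)
        return self.gamma.v[None, :, None, None] * xhat \
            + self.beta.v[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv, xshape = self._cache
        n, c, h, w = xshape
        m = n * h * w
        self.gamma.g += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.g += dy.sum(axis=(0, 2, 3))
        dxhat = dy * self.gamma.v[None, :, None, None]
        dx = (inv[None, :, None, None] / m) * (
            m * dxhat
            - dxhat.sum(axis=(0, 2, 3), keepdims=True)
            - xhat * (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True))
        return dx.astype(dy.dtype)


class ReLU:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class GlobalAvgPool:
    """Spatial mean over H, W: (N, C, H, W) -> (N, C)."""

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return np.broadcast_to(dy[:, :, None, None] / (h * w),
                               self._shape).astype(dy.dtype)


class Dense:
    def __init__(self, n_in: int, n_out: int,
                 rng: np.random.Generator | None = None, dtype=np.float32,
                 init_std: float | None = None):
        rng = rng or np.random.default_rng()
        std = init_std if init_std is not None else np.sqrt(2.0 / n_in)
        self.W = Param(rng.normal(0, std, (n_in, n_out)).astype(dtype))
        self.b = Param(np.zeros(n_out, dtype=dtype))

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.v + self.b.v

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.W.g += self._x.T @ dy
        self.b.g += dy.sum(axis=0)
        return dy @ self.W.v.T
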