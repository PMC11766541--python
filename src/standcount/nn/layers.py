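"""Minimal trainable layer zoo for the segmentation network.

All layers operate on float32 arrays in NCHW layout and implement explicit
forward/backward passes.  Convolution uses im2col + BLAS matmul, which is the
fastest pure-numpy route on a single CPU.  Each layer caches what its backward
pass needs; calling ``backward`` before ``forward`` is a programming error.
"""

from __future__ import annotations

import numpy as np


class Param:
    """A trainable tensor together with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    """Base class: layers expose their Params and a forward/backward pair."""

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _out_dim(n: int, k: int, s: int, p: int) -> int:
    return (n + 2 * p - k) // s + 1


def _im2col(x: np.ndarray, kh: int, kw: int, s: int, p: int):
    """Unfold ``x`` (N,C,H,W) into (N, C*kh*kw, oh*ow) patches."""
    n, c, h, w = x.shape
    oh, ow = _out_dim(h, kh, s, p), _out_dim(w, kw, s, p)
    if p:
        x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    col = np.empty((n, c, kh, kw, oh, ow), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            col[:, :, i, j] = x[:, :, i : i + s * oh : s, j : j + s * ow : s]
    return col.reshape(n, c * kh * kw, oh * ow), oh, ow


def _col2im(col: np.ndarray, x_shape, kh: int, kw: int, s: int, p: int) -> np.ndarray:
    """Adjoint of :func:`_im2col`: scatter-add patches back onto the image."""
    n, c, h, w = x_shape
    oh, ow = _out_dim(h, kh, s, p), _out_dim(w, kw, s, p)
    col6 = col.reshape(n, c, kh, kw, oh, ow)
    xp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=col.dtype)
    for i in range(kh):
        for j in range(kw):
            xp[:, :, i : i + s * oh : s, j : j + s * ow : s] += col6[:, :, i, j]
    return xp[:, :, p : p + h, p : p + w] if p else xp


class Conv2d(Layer):
    def __init__(self, c_in: int, c_out: int, k: int, stride: int = 1,
                 pad: int | None = None, bias: bool = True, *, rng: np.random.Generator):
        self.c_in, self.c_out, self.k = c_in, c_out, k
        self.stride = stride
        self.pad = k // 2 if pad is None else pad
        # He-normal fan-in init, appropriate for ReLU networks
        std = np.sqrt(2.0 / (c_in * k * k))
        self.weight = Param(rng.normal(0.0, std, (c_out, c_in, k, k)))
        self.bias = Param(np.zeros(c_out)) if bias else None
        self._cache = None

    def params(self) -> list[Param]:
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        col, oh, ow = _im2col(x, self.k, self.k, self.stride, self.pad)
        w2 = self.weight.value.reshape(self.c_out, -1)
        y = np.matmul(w2, col)  # (N, c_out, oh*ow)
        if self.bias is not None:
            y += self.bias.value[:, None]
        self._cache = (x.shape, col) if train else None
        return y.reshape(x.shape[0], self.c_out, oh, ow)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x_shape, col = self._cache
        n = dy.shape[0]
        dy2 = dy.reshape(n, self.c_out, -1)
        self.weight.grad += np.matmul(dy2, col.transpose(0, 2, 1)).sum(axis=0).reshape(
            self.weight.value.shape
        )
        if self.bias is not None:
            self.bias.grad += dy.sum(axis=(0, 2, 3))
        w2 = self.weight.value.reshape(self.c_out, -1)
        dcol = np.matmul(w2.T, dy2)
        self._cache = None
        return _col2im(dcol, x_shape, self.k, self.k, self.stride, self.pad)


class BatchNorm2d(Layer):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        g = self.gamma.value[:, None, None]
        b = self.beta.value[:, None, None]
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            inv_std = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mean[:, None, None]) * inv_std[:, None, None]
            m = self.momentum
            self.running_mean += m * (mean - self.running_mean)
            self.running_var += m * (var - self.running_var)
            self._cache = (xhat, inv_std)
            return (g * xhat + b).astype(np.float32)
        inv_std = 1.0 / np.sqrt(self.running_var + self.eps)
        xhat = (x - self.running_mean[:, None, None]) * inv_std[:, None, None]
        return (g * xhat + b).astype(np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        self._cache = None
        n = dy.shape[0] * dy.shape[2] * dy.shape[3]
        dxhat = dy * self.gamma.value[:, None, None]
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        s1 = dxhat.sum(axis=(0, 2, 3), keepdims=True)
        s2 = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        dx = (inv_std.reshape(1, -1, 1, 1) / n) * (n * dxhat - s1 - xhat * s2)
        return dx.astype(np.float32)


class ReLU(Layer):
    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._mask = x > 0
            return np.where(self._mask, x, 0.0).astype(np.float32)
        return np.maximum(x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = np.where(self._mask, dy, 0.0)
        self._mask = None
        return dx


class MaxPool2d(Layer):
    """3x3/stride-2 pool (the residual-stem variant) or any odd kernel."""

    def __init__(self, k: int = 3, stride: int = 2, pad: int = 1):
        self.k, self.stride, self.pad = k, stride, pad
        self._cache = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        kk = self.k * self.k
        xneg = x if not self.pad else np.pad(
            x, ((0, 0), (0, 0), (self.pad,) * 2, (self.pad,) * 2),
            constant_values=-np.inf,
        )
        oh = _out_dim(h, self.k, self.stride, self.pad)
        ow = _out_dim(w, self.k, self.stride, self.pad)
        col = np.empty((n, c, kk, oh, ow), dtype=x.dtype)
        for i in range(self.k):
            for j in range(self.k):
                col[:, :, i * self.k + j] = xneg[
                    :, :, i : i + self.stride * oh : self.stride,
                    j : j + self.stride * ow : self.stride,
                ]
        arg = col.argmax(axis=2)
        y = np.take_along_axis(col, arg[:, :, None], axis=2)[:, :, 0]
        if train:
            self._cache = (x.shape, arg, kk)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x_shape, arg, kk = self._cache
        self._cache = None
        n, c, oh, ow = dy.shape
        dcol = np.zeros((n, c, kk, oh, ow), dtype=dy.dtype)
        np.put_along_axis(dcol, arg[:, :, None], dy[:, :, None], axis=2)
        return _col2im(
            dcol.reshape(n, c * kk, oh * ow), x_shape, self.k, self.k, self.stride, self.pad
        )


class Upsample2x(Layer):
    """Nearest-neighbour x2 upsampling."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = dy.shape
        return dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy
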