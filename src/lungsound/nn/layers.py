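"""Minimal feed-forward layers with explicit backward passes.

All layers work on float32 arrays in NCHW layout and follow one contract:
``forward(x, train)`` caches whatever ``backward(dy)`` needs, ``backward``
returns the gradient w.r.t. the layer input and accumulates parameter
gradients into :class:`Param.grad`. Convolutions use im2col so the inner
loop is a single BLAS matmul; the backward image reconstruction iterates
over the (at most 7 x 7) kernel offsets only.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "MaxPool2d",
    "RowMeanPool",
    "Flatten",
    "Dropout",
    "Linear",
]


class Param:
    """A trainable tensor and its accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)
        self.name = name

    @property
    def size(self) -> int:
        return self.value.size


class Layer:
    def forward(self, x, train: bool = False):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - interface
        raise NotImplementedError

    def params(self) -> list[Param]:
        return []


def _pair(v):
    return (v, v) if np.isscalar(v) else tuple(v)


class Conv2d(Layer):
    def __init__(self, c_in, c_out, kernel, stride=1, pad=0, bias=False, *, rng):
        self.kh, self.kw = _pair(kernel)
        self.sh, self.sw = _pair(stride)
        self.ph, self.pw = _pair(pad)
        fan_in = c_in * self.kh * self.kw
        w = rng.standard_normal((c_out, c_in, self.kh, self.kw)) * np.sqrt(2.0 / fan_in)
        self.w = Param(w, "conv.w")
        self.b = Param(np.zeros(c_out), "conv.b") if bias else None
        self._cache = None

    def _im2col(self, x):
        n, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (self.ph, self.ph), (self.pw, self.pw)))
        oh = (h + 2 * self.ph - self.kh) // self.sh + 1
        ow = (w + 2 * self.pw - self.kw) // self.sw + 1
        cols = np.empty((n, c, self.kh, self.kw, oh, ow), dtype=x.dtype)
        for i in range(self.kh):
            for j in range(self.kw):
                cols[:, :, i, j] = xp[
                    :, :, i : i + self.sh * oh : self.sh, j : j + self.sw * ow : self.sw
                ]
        return cols.reshape(n, c * self.kh * self.kw, oh * ow), (oh, ow, xp.shape)

    def forward(self, x, train=False):
        x = np.ascontiguousarray(x, dtype=np.float32)
        cols, (oh, ow, xp_shape) = self._im2col(x)
        c_out = self.w.value.shape[0]
        wm = self.w.value.reshape(c_out, -1)
        y = np.matmul(wm[None], cols)  # (n, c_out, oh*ow)
        if self.b is not None:
            y += self.b.value[None, :, None]
        self._cache = (cols, xp_shape, x.shape, oh, ow) if train else None
        if not train:
            return y.reshape(x.shape[0], c_out, oh, ow)
        return y.reshape(x.shape[0], c_out, oh, ow)

    def backward(self, dy):
        cols, xp_shape, x_shape, oh, ow = self._cache
        n, c, h, w = x_shape
        c_out = self.w.value.shape[0]
        dyf = np.ascontiguousarray(dy, dtype=np.float32).reshape(n, c_out, oh * ow)
        wm = self.w.value.reshape(c_out, -1)
        self.w.grad += (
            np.matmul(dyf, cols.transpose(0, 2, 1)).sum(axis=0).reshape(self.w.value.shape)
        )
        if self.b is not None:
            self.b.grad += dyf.sum(axis=(0, 2))
        dcols = np.matmul(wm.T[None], dyf)  # (n, c*kh*kw, oh*ow)
        dcols = dcols.reshape(n, c, self.kh, self.kw, oh, ow)
        dxp = np.zeros(xp_shape, dtype=np.float32)
        for i in range(self.kh):
            for j in range(self.kw):
                dxp[
                    :, :, i : i + self.sh * oh : self.sh, j : j + self.sw * ow : self.sw
                ] += dcols[:, :, i, j]
        self._cache = None
        if self.ph or self.pw:
            return dxp[:, :, self.ph : self.ph + h, self.pw : self.pw + w]
        return dxp

    def params(self):
        return [self.w] + ([self.b] if self.b is not None else [])


class BatchNorm2d(Layer):
    def __init__(self, c, momentum=0.1, eps=1e-5):
        self.gamma = Param(np.ones(c), "bn.gamma")
        self.beta = Param(np.zeros(c), "bn.beta")
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def forward(self, x, train=False):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mean
            ).astype(np.float32)
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var
            ).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * invstd[None, :, None, None]
        if train:
            self._cache = (xhat, invstd)
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]

    def backward(self, dy):
        xhat, invstd = self._cache
        self._cache = None
        m = dy.shape[0] * dy.shape[2] * dy.shape[3]
        dxhat = dy * self.gamma.value[None, :, None, None]
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        s1 = dxhat.sum(axis=(0, 2, 3), keepdims=True)
        s2 = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        return (invstd[None, :, None, None] / m) * (m * dxhat - s1 - xhat * s2)

    def params(self):
        return [self.gamma, self.beta]


class ReLU(Layer):
    def forward(self, x, train=False):
        mask = x > 0
        if train:
            self._mask = mask
        return x * mask

    def backward(self, dy):
        return dy * self._mask


class MaxPool2d(Layer):
    def __init__(self, kernel=3, stride=2, pad=1):
        self.k = kernel
        self.s = stride
        self.p = pad

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        xp = np.full(
            (n, c, h + 2 * self.p, w + 2 * self.p), -np.inf, dtype=np.float32
        )
        xp[:, :, self.p : self.p + h, self.p : self.p + w] = x
        oh = (h + 2 * self.p - self.k) // self.s + 1
        ow = (w + 2 * self.p - self.k) // self.s + 1
        stack = np.empty((self.k * self.k, n, c, oh, ow), dtype=np.float32)
        for i in range(self.k):
            for j in range(self.k):
                stack[i * self.k + j] = xp[
                    :, :, i : i + self.s * oh : self.s, j : j + self.s * ow : self.s
                ]
        arg = stack.argmax(axis=0)
        out = np.take_along_axis(stack, arg[None], axis=0)[0]
        if train:
            self._cache = (arg, x.shape, oh, ow)
        return out

    def backward(self, dy):
        arg, x_shape, oh, ow = self._cache
        self._cache = None
        n, c, h, w = x_shape
        dxp = np.zeros((n, c, h + 2 * self.p, w + 2 * self.p), dtype=np.float32)
        for i in range(self.k):
            for j in range(self.k):
                mask = arg == (i * self.k + j)
                dxp[
                    :, :, i : i + self.s * oh : self.s, j : j + self.s * ow : self.s
                ] += dy * mask
        return dxp[:, :, self.p : self.p + h, self.p : self.p + w]


class RowMeanPool(Layer):
    """Average over the frequency (row) axis, keeping the temporal axis.

    (N, C, H, W) -> (N, C, W): the column dimension survives as the sequence
    the recurrent head consumes.
    """

    def forward(self, x, train=False):
        self._h = x.shape[2]
        return x.mean(axis=2)

    def backward(self, dy):
        return np.repeat(dy[:, :, None, :], self._h, axis=2) / self._h


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Dropout(Layer):
    """Inverted dropout; identity in inference mode."""

    def __init__(self, p, *, rng):
        if not 0 <= p < 1:
            raise ValueError(f"dropout must be in [0, 1), got {p}")
        self.p = p
        self.rng = rng

    def forward(self, x, train=False):
        if not train or self.p == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p).astype(np.float32) / (1 - self.p)
        return x * self._mask

    def backward(self, dy):
        if self._mask is None:
            return dy
        return dy * self._mask


class Linear(Layer):
    def __init__(self, d_in, d_out, *, rng):
        w = rng.standard_normal((d_out, d_in)) * np.sqrt(2.0 / d_in)
        self.w = Param(w, "fc.w")
        self.b = Param(np.zeros(d_out), "fc.b")

    def forward(self, x, train=False):
        if train:
            self._x = x
        return x @ self.w.value.T + self.b.value

    def backward(self, dy):
        self.w.grad += dy.T @ self._x
        self.b.grad += dy.sum(axis=0)
        return dy @ self.w.value

    def params(self):
        return [self.w, self.b]
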