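"""Minimal convolutional network engine on numpy.

Implements exactly the layer set the GAN and the convolutional predictor need:
dense, strided ``same``-padded convolution and transposed convolution, batch
normalization, ReLU/LeakyReLU/Tanh/Sigmoid, 2x2 max pooling, and an Adam
optimizer.  Tensors are NCHW float32.  Every layer exposes ``forward`` /
``backward`` with explicit gradients; correctness is pinned down by numerical
gradient checks in the test suite.

``same`` padding follows the convention of padding more at the trailing edge
when the total padding is odd, so a stride-2 convolution maps side S to
ceil(S/2) and a stride-2 transposed convolution maps side S to 2S.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

DTYPE = np.float32
EPS_PROB = 1e-7  # probability clamp before logs


class Parameter:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.ascontiguousarray(data, dtype=DTYPE)
        self.grad = np.zeros_like(self.data)


class Layer:
    def params(self) -> list[Parameter]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


# ---------------------------------------------------------------------------
# convolution plumbing


def same_pad(in_size: int, k: int, s: int) -> tuple[int, int, int]:
    """Output size and (begin, end) padding for 'same' convolution."""
    out = math.ceil(in_size / s)
    total = max((out - 1) * s + k - in_size, 0)
    return out, total // 2, total - total // 2


def _im2col(xp: np.ndarray, k: int, s: int, oh: int, ow: int) -> np.ndarray:
    n, c, _, _ = xp.shape
    cols = np.empty((n, c, k, k, oh, ow), dtype=xp.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = xp[:, :, i : i + s * oh : s, j : j + s * ow : s]
    return cols.reshape(n, c * k * k, oh * ow)


def _col2im(dcols: np.ndarray, pshape: tuple, k: int, s: int, oh: int, ow: int) -> np.ndarray:
    n, c, hp, wp = pshape
    dxp = np.zeros((n, c, hp, wp), dtype=dcols.dtype)
    dc = dcols.reshape(n, c, k, k, oh, ow)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i : i + s * oh : s, j : j + s * ow : s] += dc[:, :, i, j]
    return dxp


class Conv2d(Layer):
    """Strided 'same' convolution, weights N(0, init_std)."""

    def __init__(self, c_in: int, c_out: int, k: int, stride: int, rng: np.random.Generator,
                 init_std: float = 0.02):
        self.c_in, self.c_out, self.k, self.s = c_in, c_out, k, stride
        self.W = Parameter(rng.normal(0.0, init_std, size=(c_out, c_in, k, k)))
        self.b = Parameter(np.zeros(c_out))
        self._cache = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=True):
        n, c, h, w = x.shape
        if c != self.c_in:
            raise ValueError(f"Conv2d expected {self.c_in} input channels, got {c}")
        oh, pt, pb = same_pad(h, self.k, self.s)
        ow, pl, pr = same_pad(w, self.k, self.s)
        xp = np.pad(x, ((0, 0), (0, 0), (pt, pb), (pl, pr)))
        cols = _im2col(xp, self.k, self.s, oh, ow)
        wm = self.W.data.reshape(self.c_out, -1)
        y = np.matmul(wm[None], cols) + self.b.data[None, :, None]
        self._cache = (cols, xp.shape, (pt, pl), (oh, ow), (h, w))
        return y.reshape(n, self.c_out, oh, ow)

    def backward(self, dout):
        cols, pshape, (pt, pl), (oh, ow), (h, w) = self._cache
        n = dout.shape[0]
        dr = dout.reshape(n, self.c_out, oh * ow)
        self.b.grad += dr.sum(axis=(0, 2))
        self.W.grad += np.matmul(dr, cols.transpose(0, 2, 1)).sum(axis=0).reshape(self.W.data.shape)
        wm = self.W.data.reshape(self.c_out, -1)
        dcols = np.matmul(wm.T[None], dr)
        dxp = _col2im(dcols, pshape, self.k, self.s, oh, ow)
        return dxp[:, :, pt : pt + h, pl : pl + w]


class ConvTranspose2d(Layer):
    """Stride-s 'same' transposed convolution: side S -> s*S.

    Implemented as the exact adjoint of :class:`Conv2d` with the same
    geometry, so Conv/ConvT gradients share one code path.
    """

    def __init__(self, c_in: int, c_out: int, k: int, stride: int, rng: np.random.Generator,
                 init_std: float = 0.02):
        self.c_in, self.c_out, self.k, self.s = c_in, c_out, k, stride
        # weight of the *virtual* forward conv mapping output-space -> input-space
        self.W = Parameter(rng.normal(0.0, init_std, size=(c_in, c_out, k, k)))
        self.b = Parameter(np.zeros(c_out))
        self._cache = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=True):
        n, c, h, w = x.shape
        if c != self.c_in:
            raise ValueError(f"ConvTranspose2d expected {self.c_in} input channels, got {c}")
        ho, wo = h * self.s, w * self.s
        oh, pt, pb = same_pad(ho, self.k, self.s)
        ow, pl, pr = same_pad(wo, self.k, self.s)
        assert (oh, ow) == (h, w)
        wm = self.W.data.reshape(self.c_in, -1)
        xr = x.reshape(n, self.c_in, h * w)
        dcols = np.matmul(wm.T[None], xr)
        pshape = (n, self.c_out, ho + pt + pb, wo + pl + pr)
        yp = _col2im(dcols, pshape, self.k, self.s, h, w)
        y = yp[:, :, pt : pt + ho, pl : pl + wo] + self.b.data[None, :, None, None]
        self._cache = (xr, (pt, pl), (ho, wo), (h, w))
        return y

    def backward(self, dout):
        xr, (pt, pl), (ho, wo), (h, w) = self._cache
        n = dout.shape[0]
        self.b.grad += dout.sum(axis=(0, 2, 3))
        _, pt2, pb2 = same_pad(ho, self.k, self.s)
        _, pl2, pr2 = same_pad(wo, self.k, self.s)
        dyp = np.pad(dout, ((0, 0), (0, 0), (pt2, pb2), (pl2, pr2)))
        cols = _im2col(dyp, self.k, self.s, h, w)
        self.W.grad += np.matmul(xr, cols.transpose(0, 2, 1)).sum(axis=0).reshape(self.W.data.shape)
        wm = self.W.data.reshape(self.c_in, -1)
        dx = np.matmul(wm[None], cols)
        return dx.reshape(n, self.c_in, h, w)


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, init_std: float = 0.02):
        self.W = Parameter(rng.normal(0.0, init_std, size=(d_in, d_out)))
        self.b = Parameter(np.zeros(d_out))
        self._x = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=True):
        self._x = x
        return x @ self.W.data + self.b.data

    def backward(self, dout):
        self.W.grad += self._x.T @ dout
        self.b.grad += dout.sum(axis=0)
        return dout @ self.W.data.T


class BatchNorm(Layer):
    """Batch normalization over the batch (and spatial axes for 4-D input)."""

    def __init__(self, n_features: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(n_features))
        self.beta = Parameter(np.zeros(n_features))
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(n_features, dtype=DTYPE)
        self.running_var = np.ones(n_features, dtype=DTYPE)
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    @staticmethod
    def _axes(x):
        return (0, 2, 3) if x.ndim == 4 else (0,)

    def _shape(self, x, v):
        return v.reshape(1, -1, 1, 1) if x.ndim == 4 else v.reshape(1, -1)

    def forward(self, x, train=True):
        axes = self._axes(x)
        if train:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mu
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - self._shape(x, mu)) * self._shape(x, inv)
        self._cache = (xhat, inv, axes)
        return self._shape(x, self.gamma.data) * xhat + self._shape(x, self.beta.data)

    def backward(self, dout):
        xhat, inv, axes = self._cache
        m = np.prod([dout.shape[a] for a in axes])
        self.gamma.grad += (dout * xhat).sum(axis=axes)
        self.beta.grad += dout.sum(axis=axes)
        g = self._shape(dout, self.gamma.data) * dout
        t1 = g - self._shape(dout, g.mean(axis=axes)) \
            - xhat * self._shape(dout, (g * xhat).sum(axis=axes) / m)
        return t1 * self._shape(dout, inv)


class ReLU(Layer):
    def forward(self, x, train=True):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class LeakyReLU(Layer):
    def __init__(self, alpha: float = 0.2):
        self.alpha = alpha

    def forward(self, x, train=True):
        self._mask = x > 0
        return np.where(self._mask, x, self.alpha * x)

    def backward(self, dout):
        return np.where(self._mask, dout, self.alpha * dout)


class Tanh(Layer):
    def forward(self, x, train=True):
        self._y = np.tanh(x)
        return self._y

    def backward(self, dout):
        return dout * (1.0 - self._y**2)


class Sigmoid(Layer):
    def forward(self, x, train=True):
        self._y = 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))
        return self._y

    def backward(self, dout):
        return dout * self._y * (1.0 - self._y)


class MaxPool2x2(Layer):
    def forward(self, x, train=True):
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"MaxPool2x2 needs even sides, got {h}x{w}")
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
            n, c, h // 2, w // 2, 4)
        self._idx = xr.argmax(axis=-1)
        self._shape = (n, c, h, w)
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dout):
        n, c, h, w = self._shape
        dxr = np.zeros((n, c, h // 2, w // 2, 4), dtype=dout.dtype)
        np.put_along_axis(dxr, self._idx[..., None], dout[..., None], axis=-1)
        return dxr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
            n, c, h, w)


class Reshape(Layer):
    def __init__(self, shape: Sequence[int]):
        self.shape = tuple(shape)

    def forward(self, x, train=True):
        self._in = x.shape
        return x.reshape((x.shape[0],) + self.shape)

    def backward(self, dout):
        return dout.reshape(self._in)


class Flatten(Layer):
    def forward(self, x, train=True):
        self._in = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._in)


class Sequential(Layer):
    def __init__(self, layers: Sequence[Layer]):
        self.layers = list(layers)

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def forward(self, x, train=True):
        for l in self.layers:
            x = l.forward(x, train=train)
        return x

    def backward(self, dout):
        for l in reversed(self.layers):
            dout = l.backward(dout)
        return dout

    def __call__(self, x, train=False):
        return self.forward(x, train=train)

    # -- persistence -------------------------------------------------------
    def get_weights(self) -> list[np.ndarray]:
        arrays = [p.data.copy() for p in self.params()]
        for l in self.layers:
            if isinstance(l, BatchNorm):
                arrays += [l.running_mean.copy(), l.running_var.copy()]
        return arrays

    def set_weights(self, arrays: Sequence[np.ndarray]) -> None:
        it = iter(arrays)
        for p in self.params():
            a = next(it)
            if a.shape != p.data.shape:
                raise ValueError(f"weight shape mismatch: {a.shape} vs {p.data.shape}")
            p.data = np.ascontiguousarray(a, dtype=DTYPE)
        for l in self.layers:
            if isinstance(l, BatchNorm):
                l.running_mean = np.ascontiguousarray(next(it), dtype=DTYPE)
                l.running_var = np.ascontiguousarray(next(it), dtype=DTYPE)


class Adam:
    def __init__(self, params: Sequence[Parameter], lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad**2
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def bce(p: np.ndarray, t: np.ndarray) -> float:
    """Binary cross-entropy on probabilities, mean over all elements."""
    pc = np.clip(p, EPS_PROB, 1.0 - EPS_PROB)
    return float(-np.mean(t * np.log(pc) + (1 - t) * np.log(1 - pc)))


def bce_grad(p: np.ndarray, t: np.ndarray) -> np.ndarray:
    """d(bce)/dp; composed with a sigmoid layer this yields the stable (p-t)/n."""
    pc = np.clip(p, EPS_PROB, 1.0 - EPS_PROB)
    return ((pc - t) / (pc * (1.0 - pc))) / p.size
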