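"""Minimal reverse-mode automatic differentiation on NumPy arrays.

This is the numerical substrate shared by the trainable parts of the
pipeline: the encoder--decoder FCN used for ROI localization, the reduced
Inception-style deep-feature network, and the four-branch hybrid
classifier.  Networks here are desk-scale (tens of thousands of
parameters), so a vectorized tape on float64 ndarrays is fast enough on a
single CPU and keeps every run bit-reproducible for a fixed seed.

Conventions
-----------
* Image tensors are NCHW.
* ``Tensor`` wraps an ``ndarray``; operations build a DAG; ``backward()``
  runs a topological sweep accumulating ``.grad``.
* Only parameters are created with ``requires_grad=True``; constants
  propagate no gradient.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "constant",
    "parameter",
    "concat",
    "conv2d",
    "max_pool2d",
    "avg_pool2d",
    "upsample_nearest",
    "softmax",
    "softmax_cross_entropy",
    "batchnorm2d",
    "Adam",
    "he_init",
    "glorot_init",
]


class Tensor:
    """A node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, parents=(), backward=None, requires_grad=False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # -- graph mechanics ------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self):
        return Tensor(self.data)

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = None
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def _accum(self, grad):
        grad = _unbroadcast(grad, self.data.shape)
        self.grad = grad if self.grad is None else self.grad + grad

    # -- arithmetic -----------------------------------------------------
    def __add__(self, other):
        other = _wrap(other)
        out = Tensor(self.data + other.data, (self, other))
        out._backward = lambda g: (self._accum(g), other._accum(g))
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, (self,))
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-_wrap(other))

    def __rsub__(self, other):
        return _wrap(other) + (-self)

    def __mul__(self, other):
        other = _wrap(other)
        out = Tensor(self.data * other.data, (self, other))
        out._backward = lambda g: (
            self._accum(g * other.data),
            other._accum(g * self.data),
        )
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * _wrap(other) ** -1.0

    def __rtruediv__(self, other):
        return _wrap(other) * self**-1.0

    def __pow__(self, p):
        out = Tensor(self.data**p, (self,))
        out._backward = lambda g: self._accum(g * p * self.data ** (p - 1))
        return out

    def __matmul__(self, other):
        other = _wrap(other)
        out = Tensor(np.matmul(self.data, other.data), (self, other))

        def bwd(g):
            self._accum(np.matmul(g, np.swapaxes(other.data, -1, -2)))
            other._accum(np.matmul(np.swapaxes(self.data, -1, -2), g))

        out._backward = bwd
        return out

    # -- elementwise nonlinearities --------------------------------------
    def exp(self):
        e = np.exp(self.data)
        out = Tensor(e, (self,))
        out._backward = lambda g: self._accum(g * e)
        return out

    def log(self):
        out = Tensor(np.log(self.data), (self,))
        out._backward = lambda g: self._accum(g / self.data)
        return out

    def tanh(self):
        t = np.tanh(self.data)
        out = Tensor(t, (self,))
        out._backward = lambda g: self._accum(g * (1 - t * t))
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, (self,))
        out._backward = lambda g: self._accum(g * s * (1 - s))
        return out

    def relu(self):
        m = self.data > 0
        out = Tensor(self.data * m, (self,))
        out._backward = lambda g: self._accum(g * m)
        return out

    # -- reductions / shape ----------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def bwd(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape))

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), (self,))
        out._backward = lambda g: self._accum(g.reshape(self.data.shape))
        return out

    def transpose(self, *axes):
        out = Tensor(self.data.transpose(*axes), (self,))
        inv = np.argsort(axes)
        out._backward = lambda g: self._accum(g.transpose(*inv))
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], (self,))

        def bwd(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)

        out._backward = bwd
        return out


def _wrap(x):
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(grad, shape):
    """Sum gradient over broadcast dimensions so it matches ``shape``."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and grad.shape[i] != 1:
            grad = grad.sum(axis=i, keepdims=True)
    return grad.reshape(shape)


def constant(x):
    return Tensor(x)


def parameter(x):
    return Tensor(x, requires_grad=True)


def concat(tensors, axis):
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accum(piece)

    out._backward = bwd
    return out


# ---------------------------------------------------------------------------
# Spatial operations (NCHW)
# ---------------------------------------------------------------------------


def conv2d(x, w, b=None, pad="same"):
    """2-D cross-correlation, stride 1.

    x: (N, C, H, W); w: (F, C, kh, kw); b: (F,) or None.
    ``pad='same'`` keeps the spatial size (odd kernels only).
    """
    kh, kw = w.data.shape[2:]
    p = (kh // 2, kw // 2) if pad == "same" else (0, 0)
    xp = np.pad(x.data, ((0, 0), (0, 0), (p[0], p[0]), (p[1], p[1])))
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))  # N,C,H,W,kh,kw
    y = np.einsum("nchwuv,fcuv->nfhw", win, w.data, optimize=True)
    if b is not None:
        y = y + b.data[None, :, None, None]
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(y, parents)

    def bwd(g):
        w._accum(np.einsum("nchwuv,nfhw->fcuv", win, g, optimize=True))
        if b is not None:
            b._accum(g.sum(axis=(0, 2, 3)))
        gp = np.pad(g, ((0, 0), (0, 0), (kh - 1, kh - 1), (kw - 1, kw - 1)))
        gwin = sliding_window_view(gp, (kh, kw), axis=(2, 3))
        wf = w.data[:, :, ::-1, ::-1]
        dxp = np.einsum("nfabuv,fcuv->ncab", gwin, wf, optimize=True)
        H, W = x.data.shape[2:]
        x._accum(dxp[:, :, p[0] : p[0] + H, p[1] : p[1] + W])

    out._backward = bwd
    return out


def max_pool2d(x, k=2):
    n, c, h, w = x.data.shape
    if h % k or w % k:
        raise ValueError("max_pool2d requires spatial size divisible by the window")
    r = x.data.reshape(n, c, h // k, k, w // k, k).transpose(0, 1, 2, 4, 3, 5)
    r = r.reshape(n, c, h // k, w // k, k * k)
    arg = r.argmax(axis=-1)
    y = np.take_along_axis(r, arg[..., None], axis=-1)[..., 0]
    out = Tensor(y, (x,))

    def bwd(g):
        gr = np.zeros_like(r)
        np.put_along_axis(gr, arg[..., None], g[..., None], axis=-1)
        gr = gr.reshape(n, c, h // k, w // k, k, k).transpose(0, 1, 2, 4, 3, 5)
        x._accum(gr.reshape(n, c, h, w))

    out._backward = bwd
    return out


def avg_pool2d(x, k=2):
    n, c, h, w = x.data.shape
    if h % k or w % k:
        raise ValueError("avg_pool2d requires spatial size divisible by the window")
    y = x.data.reshape(n, c, h // k, k, w // k, k).mean(axis=(3, 5))
    out = Tensor(y, (x,))

    def bwd(g):
        gx = np.repeat(np.repeat(g, k, axis=2), k, axis=3) / (k * k)
        x._accum(gx)

    out._backward = bwd
    return out


def upsample_nearest(x, k=2):
    y = np.repeat(np.repeat(x.data, k, axis=2), k, axis=3)
    out = Tensor(y, (x,))
    n, c, h, w = x.data.shape

    def bwd(g):
        x._accum(g.reshape(n, c, h, k, w, k).sum(axis=(3, 5)))

    out._backward = bwd
    return out


def softmax(x, axis=-1):
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(s, (x,))

    def bwd(g):
        x._accum(s * (g - (g * s).sum(axis=axis, keepdims=True)))

    out._backward = bwd
    return out


def softmax_cross_entropy(logits, labels, sample_weight=None):
    """Mean (weighted) cross-entropy of integer ``labels`` under softmax logits.

    logits: (N, K); labels: (N,) ints; sample_weight: (N,) or None.
    """
    labels = np.asarray(labels)
    n = logits.data.shape[0]
    w = np.ones(n) if sample_weight is None else np.asarray(sample_weight, float)
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=1))
    nll = lse - z[np.arange(n), labels]
    out = Tensor((w * nll).sum() / w.sum(), (logits,))

    def bwd(g):
        p = np.exp(z) / np.exp(z).sum(axis=1, keepdims=True)
        p[np.arange(n), labels] -= 1.0
        logits._accum(g * p * (w / w.sum())[:, None])

    out._backward = bwd
    return out


def batchnorm2d(x, scale, offset, gate=None, eps=1e-5):
    """Per-channel batch normalization on NCHW with optional constant gate.

    Statistics are taken over (N, H, W) per feature map.  ``gate`` is a
    per-channel multiplier treated as a constant in the backward pass
    (used by the entropy-regularized variant).
    """
    mu = x.data.mean(axis=(0, 2, 3), keepdims=True)
    var = x.data.var(axis=(0, 2, 3), keepdims=True)
    sd = np.sqrt(var + eps)
    xhat = (x.data - mu) / sd
    gmul = 1.0 if gate is None else np.asarray(gate)[None, :, None, None]
    a = scale.data[None, :, None, None]
    y = (xhat * a + offset.data[None, :, None, None]) * gmul
    out = Tensor(y, (x, scale, offset))
    m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]

    def bwd(g):
        g = g * gmul
        scale._accum((g * xhat).sum(axis=(0, 2, 3)))
        offset._accum(g.sum(axis=(0, 2, 3)))
        gxh = g * a
        x._accum(
            (gxh - gxh.mean(axis=(0, 2, 3), keepdims=True)
             - xhat * (gxh * xhat).mean(axis=(0, 2, 3), keepdims=True)) / sd
        )
        _ = m  # statistics count, kept for clarity

    out._backward = bwd
    return out


# ---------------------------------------------------------------------------
# Initialization and optimization
# ---------------------------------------------------------------------------


def he_init(rng, shape, fan_in):
    return parameter(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape))


def glorot_init(rng, shape, fan_in, fan_out):
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return parameter(rng.uniform(-lim, lim, size=shape))


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mh = self.m[i] / (1 - self.b1**self.t)
            vh = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mh / (np.sqrt(vh) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
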