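"""Minimal reverse-mode automatic differentiation with convolutional layers.

A small numpy-only tensor/autodiff backend sized for desk-scale CPU training
of the compact U-Net family used by :mod:`hfsnet.networks`.  It supports
exactly the operations those networks and the segmentation losses need:
same-padding stride-1 convolutions (2D and 3D), factor-2 max pooling and
nearest-neighbour upsampling, channel concatenation, ReLU, a numerically
stable softmax, elementwise arithmetic/log/pow, reductions, and an Adam
optimizer.  Gradient tracking can be switched off for inference with
:func:`no_grad`.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np

_GRAD_ENABLED = True


@contextmanager
def no_grad():
    """Disable graph construction (inference mode) within the block."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """N-dimensional array node in a dynamically built computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple = ()
        self._backward = None

    # -- graph plumbing ---------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self) -> None:
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # -- convenience ------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- elementwise arithmetic -------------------------------------------
    @staticmethod
    def _coerce(x):
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = Tensor._coerce(other)
        out_data = self.data + other.data

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return Tensor._make(out_data, (self, other), bw)

    __radd__ = __add__

    def __mul__(self, other):
        other = Tensor._coerce(other)
        out_data = self.data * other.data

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(out_data, (self, other), bw)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-Tensor._coerce(other))

    def __rsub__(self, other):
        return Tensor._coerce(other) + (-self)

    def __truediv__(self, other):
        return self * Tensor._coerce(other) ** (-1.0)

    def __rtruediv__(self, other):
        return Tensor._coerce(other) * self ** (-1.0)

    def __pow__(self, p: float):
        out_data = self.data ** p

        def bw(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1.0))

        return Tensor._make(out_data, (self,), bw)

    def log(self):
        out_data = np.log(self.data)

        def bw(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return Tensor._make(out_data, (self,), bw)

    def exp(self):
        out_data = np.exp(self.data)

        def bw(g):
            if self.requires_grad:
                self._accum(g * out_data)

        return Tensor._make(out_data, (self,), bw)

    def clip(self, lo: float, hi: float):
        mask = (self.data > lo) & (self.data < hi)
        out_data = np.clip(self.data, lo, hi)

        def bw(g):
            if self.requires_grad:
                self._accum(g * mask)

        return Tensor._make(out_data, (self,), bw)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def bw(g):
            if self.requires_grad:
                d = np.zeros_like(self.data)
                np.add.at(d, idx, g)
                self._accum(d)

        return Tensor._make(out_data, (self,), bw)

    # -- reductions -------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            if self.requires_grad:
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.data.shape).copy())

        return Tensor._make(out_data, (self,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- nonlinearities ---------------------------------------------------
    def relu(self):
        mask = self.data > 0
        out_data = self.data * mask

        def bw(g):
            if self.requires_grad:
                self._accum(g * mask)

        return Tensor._make(out_data, (self,), bw)

    def softmax(self, axis: int = 1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)

        def bw(g):
            if self.requires_grad:
                self._accum(s * (g - (g * s).sum(axis=axis, keepdims=True)))

        return Tensor._make(s, (self,), bw)


# -- structural ops --------------------------------------------------------

def concat(tensors: list, axis: int = 1) -> Tensor:
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor._make(out_data, tuple(tensors), bw)


# -- convolution (stride 1, same padding, odd kernels) ----------------------

def _conv_nd(x: Tensor, w: Tensor, b: Tensor | None, nsp: int) -> Tensor:
    """Correlation over the last `nsp` spatial axes with same padding."""
    xd, wd = x.data, w.data
    k = wd.shape[2:]
    pad = [(0, 0), (0, 0)] + [(ki // 2, ki // 2) for ki in k]
    xp = np.pad(xd, pad)
    view = np.lib.stride_tricks.sliding_window_view(
        xp, k, axis=tuple(range(2, 2 + nsp))
    )
    # view: (N, C, *spatial, *k); w: (O, C, *k)
    ax_v = [1] + list(range(2 + nsp, 2 + 2 * nsp))
    ax_w = [1] + list(range(2, 2 + nsp))
    out = np.tensordot(view, wd, axes=(ax_v, ax_w))  # (N, *spatial, O)
    out = np.moveaxis(out, -1, 1)
    if b is not None:
        out = out + b.data.reshape((1, -1) + (1,) * nsp)

    parents = (x, w) if b is None else (x, w, b)

    def bw(g):
        if w.requires_grad:
            # contract over batch + spatial axes
            ax_g = [0] + list(range(2, 2 + nsp))
            ax_v2 = [0] + list(range(2, 2 + nsp))
            dw = np.tensordot(g, view, axes=(ax_g, ax_v2))  # (O, C, *k)
            w._accum(dw)
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=tuple([0] + list(range(2, 2 + nsp)))))
        if x.requires_grad:
            # full correlation of g with spatially flipped, transposed kernel
            flip = tuple(slice(None, None, -1) for _ in range(nsp))
            wf = wd[(slice(None), slice(None)) + flip].swapaxes(0, 1)  # (C, O, *k)
            gp = np.pad(g, pad)
            gview = np.lib.stride_tricks.sliding_window_view(
                gp, k, axis=tuple(range(2, 2 + nsp))
            )
            dx = np.tensordot(gview, wf, axes=(ax_v, ax_w))
            x._accum(np.moveaxis(dx, -1, 1))

    return Tensor._make(out, parents, bw)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    return _conv_nd(x, w, b, 2)


def conv3d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    return _conv_nd(x, w, b, 3)


# -- pooling / upsampling ---------------------------------------------------

def _pool_reshape(shape, factors):
    out = list(shape[:2])
    for s, f in zip(shape[2:], factors):
        if s % f:
            raise ValueError(f"spatial size {s} not divisible by pool factor {f}")
        out += [s // f, f]
    return out


def maxpool(x: Tensor, factors: tuple) -> Tensor:
    """Max pooling by integer factors over the trailing spatial axes."""
    rs = _pool_reshape(x.data.shape, factors)
    r = x.data.reshape(rs)
    red = tuple(range(3, r.ndim, 2))
    m = r.max(axis=red, keepdims=True)
    mask = (r == m)
    mask = mask / mask.sum(axis=red, keepdims=True)  # split gradient on ties
    out_data = m.reshape([rs[0], rs[1]] + rs[2::2])

    def bw(g):
        if x.requires_grad:
            gshape = [g.shape[0], g.shape[1]]
            for s in g.shape[2:]:
                gshape += [s, 1]
            x._accum((mask * g.reshape(gshape)).reshape(x.data.shape))

    return Tensor._make(out_data, (x,), bw)


def upsample_nearest(x: Tensor, factors: tuple) -> Tensor:
    out_data = x.data
    for ax, f in enumerate(factors):
        if f > 1:
            out_data = np.repeat(out_data, f, axis=2 + ax)

    def bw(g):
        if x.requires_grad:
            gshape = [g.shape[0], g.shape[1]]
            for s, f in zip(x.data.shape[2:], factors):
                gshape += [s, f]
            red = tuple(range(3, len(gshape), 2))
            x._accum(g.reshape(gshape).sum(axis=red))

    return Tensor._make(out_data, (x,), bw)


# -- layers -----------------------------------------------------------------

class ConvNd:
    """Convolution layer with He-initialized weights (stride 1, same pad)."""

    def __init__(self, cin: int, cout: int, k: int, nsp: int, rng: np.random.Generator):
        fan_in = cin * k ** nsp
        std = np.sqrt(2.0 / fan_in)
        self.w = Tensor(rng.normal(0.0, std, size=(cout, cin) + (k,) * nsp),
                        requires_grad=True)
        self.b = Tensor(np.zeros(cout), requires_grad=True)
        self._nsp = nsp

    def __call__(self, x: Tensor) -> Tensor:
        return _conv_nd(x, self.w, self.b, self._nsp)

    @property
    def params(self):
        return [self.w, self.b]


class Conv2d(ConvNd):
    def __init__(self, cin, cout, k=3, rng=None):
        super().__init__(cin, cout, k, 2, rng)


class Conv3d(ConvNd):
    def __init__(self, cin, cout, k=3, rng=None):
        super().__init__(cin, cout, k, 3, rng)


class Adam:
    """Adam optimizer over an explicit parameter list."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
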