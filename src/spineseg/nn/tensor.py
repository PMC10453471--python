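"""Minimal reverse-mode automatic differentiation on numpy arrays.

The engine supports exactly the operator set the spine models need:
broadcast arithmetic, matmul, the sigmoid/rectifier nonlinearities,
reductions, shape ops, 2D/3D convolution (with stride, dilation and
depthwise grouping), 2x2 max-pooling, nearest upsampling, linear axis
resampling, dropout and fused softmax cross-entropy.  Gradients of every
operator are verified against central finite differences in the test
suite; training code should rely on those semantics rather than on any
resemblance to other frameworks.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_grad_enabled = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction (inference mode)."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


def _as_array(x) -> np.ndarray:
    a = np.asarray(x, dtype=np.float32)
    return a


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndim_extra = grad.ndim - len(shape)
    if ndim_extra > 0:
        grad = grad.sum(axis=tuple(range(ndim_extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph bookkeeping -------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        # iterative topological order
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float32)}
        for node in reversed(order):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad:
                node.grad = g if node.grad is None else node.grad + g
            if node._backward is None:
                continue
            for parent, pg in node._backward(g):
                if pg is None:
                    continue
                key = id(parent)
                if key in grads:
                    grads[key] = grads[key] + pg
                else:
                    grads[key] = pg

    # -- operator sugar ----------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __truediv__(self, other):
        return div(self, other)

    def __neg__(self):
        return mul(self, -1.0)

    def __matmul__(self, other):
        return matmul(self, other)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    def transpose(self, axes: Sequence[int]):
        return transpose(self, axes)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data: np.ndarray, parents: Iterable[Tensor], backward) -> Tensor:
    parents = tuple(p for p in parents if isinstance(p, Tensor))
    if _grad_enabled and any(p.requires_grad or p._parents for p in parents):
        out = Tensor(data)
        out._parents = parents
        out._backward = backward
        # mark as needing graph so descendants keep building
        out.requires_grad = False
        return out
    return Tensor(data)


# -- elementwise & arithmetic ---------------------------------------------

def add(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    data = a.data + b.data

    def backward(g):
        return ((a, _unbroadcast(g, a.data.shape)), (b, _unbroadcast(g, b.data.shape)))

    return _make(data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    data = a.data * b.data

    def backward(g):
        return (
            (a, _unbroadcast(g * b.data, a.data.shape)),
            (b, _unbroadcast(g * a.data, b.data.shape)),
        )

    return _make(data, (a, b), backward)


def div(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    data = a.data / b.data

    def backward(g):
        return (
            (a, _unbroadcast(g / b.data, a.data.shape)),
            (b, _unbroadcast(-g * a.data / (b.data * b.data), b.data.shape)),
        )

    return _make(data, (a, b), backward)


def matmul(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    data = a.data @ b.data

    def backward(g):
        return ((a, g @ b.data.T), (b, a.data.T @ g))

    return _make(data, (a, b), backward)


def relu(a) -> Tensor:
    a = _wrap(a)
    mask = a.data > 0
    data = np.where(mask, a.data, 0.0)

    def backward(g):
        return ((a, g * mask),)

    return _make(data, (a,), backward)


def sigmoid(a) -> Tensor:
    a = _wrap(a)
    # clip: beyond +-60 the logistic saturates in float32 anyway, and the
    # clipped form avoids overflow warnings and subnormal intermediates
    data = 1.0 / (1.0 + np.exp(-np.clip(a.data, -60.0, 60.0)))

    def backward(g):
        return ((a, g * data * (1.0 - data)),)

    return _make(data, (a,), backward)


def exp(a) -> Tensor:
    a = _wrap(a)
    data = np.exp(a.data)

    def backward(g):
        return ((a, g * data),)

    return _make(data, (a,), backward)


def log(a) -> Tensor:
    a = _wrap(a)
    data = np.log(a.data)

    def backward(g):
        return ((a, g / a.data),)

    return _make(data, (a,), backward)


def sqrt(a) -> Tensor:
    a = _wrap(a)
    data = np.sqrt(a.data)

    def backward(g):
        return ((a, g * 0.5 / data),)

    return _make(data, (a,), backward)


# -- reductions & shape ----------------------------------------------------

def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = _wrap(a)
    data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        g = np.asarray(g)
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis if isinstance(axis, int) else tuple(sorted(axis)))
        return ((a, np.broadcast_to(g, a.data.shape).astype(np.float32)),)

    return _make(data, (a,), backward)


def tmean(a, axis=None, keepdims=False) -> Tensor:
    a = _wrap(a)
    n = a.data.size if axis is None else np.prod(
        [a.data.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
    )
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / float(n))


def reshape(a, shape) -> Tensor:
    a = _wrap(a)
    data = a.data.reshape(shape)

    def backward(g):
        return ((a, g.reshape(a.data.shape)),)

    return _make(data, (a,), backward)


def transpose(a, axes: Sequence[int]) -> Tensor:
    a = _wrap(a)
    axes = tuple(axes)
    data = a.data.transpose(axes)
    inv = tuple(np.argsort(axes))

    def backward(g):
        return ((a, g.transpose(inv)),)

    return _make(data, (a,), backward)


def concat(tensors: Sequence[Tensor], axis: int) -> Tensor:
    tensors = [_wrap(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        parts = np.split(g, splits, axis=axis)
        return tuple(zip(tensors, parts))

    return _make(data, tensors, backward)


def pad2d(a, p: int) -> Tensor:
    """Zero-pad the last two axes symmetrically by p."""
    a = _wrap(a)
    if p == 0:
        return a
    width = [(0, 0)] * (a.ndim - 2) + [(p, p), (p, p)]
    data = np.pad(a.data, width)
    sl = tuple([slice(None)] * (a.ndim - 2) + [slice(p, -p), slice(p, -p)])

    def backward(g):
        return ((a, g[sl]),)

    return _make(data, (a,), backward)


# -- convolution -----------------------------------------------------------

def conv2d(x, w, b=None, stride: int = 1, dilation: int = 1, padding: int = 0,
           groups: int = 1) -> Tensor:
    """2D cross-correlation.  groups must be 1 or C_in (depthwise)."""
    x, w = _wrap(x), _wrap(w)
    N, C, H, W = x.data.shape
    Cout, Cin_g, kh, kw = w.data.shape
    if groups not in (1, C):
        raise ValueError("conv2d supports groups of 1 or C_in only")
    depthwise = groups > 1
    if depthwise and (Cin_g != 1 or Cout != C):
        raise ValueError("depthwise conv2d requires weight shape (C, 1, kh, kw)")
    if not depthwise and Cin_g != C:
        raise ValueError(f"weight expects {Cin_g} input channels, got {C}")
    p, s, d = padding, stride, dilation
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
    eh, ew = (kh - 1) * d + 1, (kw - 1) * d + 1
    win = sliding_window_view(xp, (eh, ew), axis=(2, 3))
    cols = win[:, :, ::s, ::s, ::d, ::d]  # (N, C, Ho, Wo, kh, kw)
    Ho, Wo = cols.shape[2], cols.shape[3]

    if groups == 1:
        colm = np.ascontiguousarray(cols.transpose(0, 2, 3, 1, 4, 5)).reshape(
            N * Ho * Wo, C * kh * kw)
        Wm = w.data.reshape(Cout, C * kh * kw)
        out = (colm @ Wm.T).reshape(N, Ho, Wo, Cout).transpose(0, 3, 1, 2)
    else:
        wd = w.data[:, 0]  # (C, kh, kw)
        out = np.einsum("nchwij,cij->nchw", cols, wd, optimize=True)
        colm = None
    out = np.ascontiguousarray(out)
    if b is not None:
        b = _wrap(b)
        out = out + b.data.reshape(1, -1, 1, 1)

    def backward(g):
        grads = []
        g = np.ascontiguousarray(g)
        if groups == 1:
            gm = g.transpose(0, 2, 3, 1).reshape(N * Ho * Wo, Cout)
            Wm_ = w.data.reshape(Cout, C * kh * kw)
            gw = (gm.T @ colm).reshape(w.data.shape)
            gcols = (gm @ Wm_).reshape(N, Ho, Wo, C, kh, kw).transpose(0, 3, 1, 2, 4, 5)
        else:
            gw = np.einsum("nchwij,nchw->cij", cols, g, optimize=True)[:, None]
            gcols = None
        # scatter-add back to the padded input
        gxp = np.zeros((N, C, H + 2 * p, W + 2 * p), dtype=np.float32)
        for i in range(kh):
            for j in range(kw):
                sl = (slice(None), slice(None),
                      slice(i * d, i * d + Ho * s, s),
                      slice(j * d, j * d + Wo * s, s))
                if groups == 1:
                    gxp[sl] += gcols[:, :, :, :, i, j]
                else:
                    gxp[sl] += g * w.data[:, 0, i, j][None, :, None, None]
        gx = gxp[:, :, p:p + H, p:p + W] if p else gxp
        grads.append((x, gx))
        grads.append((w, gw))
        if b is not None:
            grads.append((b, g.sum(axis=(0, 2, 3))))
        return tuple(grads)

    parents = (x, w) if b is None else (x, w, b)
    return _make(out, parents, backward)


def conv3d(x, w, b=None, padding: int = 0) -> Tensor:
    """3D cross-correlation, stride 1, groups 1."""
    x, w = _wrap(x), _wrap(w)
    N, C, D, H, W = x.data.shape
    Cout, Cin, kd, kh, kw = w.data.shape
    if Cin != C:
        raise ValueError(f"weight expects {Cin} input channels, got {C}")
    p = padding
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p), (p, p))) if p else x.data
    win = sliding_window_view(xp, (kd, kh, kw), axis=(2, 3, 4))
    Do, Ho, Wo = win.shape[2:5]
    colm = np.ascontiguousarray(win.transpose(0, 2, 3, 4, 1, 5, 6, 7)).reshape(
        N * Do * Ho * Wo, C * kd * kh * kw)
    Wm = w.data.reshape(Cout, -1)
    out = (colm @ Wm.T).reshape(N, Do, Ho, Wo, Cout).transpose(0, 4, 1, 2, 3)
    out = np.ascontiguousarray(out)
    if b is not None:
        b = _wrap(b)
        out = out + b.data.reshape(1, -1, 1, 1, 1)

    def backward(g):
        g = np.ascontiguousarray(g)
        gm = g.transpose(0, 2, 3, 4, 1).reshape(N * Do * Ho * Wo, Cout)
        gw = (gm.T @ colm).reshape(w.data.shape)
        gcols = (gm @ Wm).reshape(N, Do, Ho, Wo, C, kd, kh, kw)
        gcols = gcols.transpose(0, 4, 1, 2, 3, 5, 6, 7)
        gxp = np.zeros((N, C, D + 2 * p, H + 2 * p, W + 2 * p), dtype=np.float32)
        for i in range(kd):
            for j in range(kh):
                for k in range(kw):
                    gxp[:, :, i:i + Do, j:j + Ho, k:k + Wo] += gcols[..., i, j, k]
        gx = gxp[:, :, p:p + D, p:p + H, p:p + W] if p else gxp
        grads = [(x, gx), (w, gw)]
        if b is not None:
            grads.append((b, g.sum(axis=(0, 2, 3, 4))))
        return tuple(grads)

    parents = (x, w) if b is None else (x, w, b)
    return _make(out, parents, backward)


# -- pooling / resampling --------------------------------------------------

def maxpool2d(x) -> Tensor:
    """2x2 max-pooling with stride 2; ties resolve to the first position."""
    x = _wrap(x)
    N, C, H, W = x.data.shape
    if H % 2 or W % 2:
        raise ValueError("maxpool2d requires even spatial extents")
    x4 = x.data.reshape(N, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    x4 = np.ascontiguousarray(x4).reshape(N, C, H // 2, W // 2, 4)
    idx = x4.argmax(axis=-1)
    out = np.take_along_axis(x4, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        g4 = np.zeros_like(x4)
        np.put_along_axis(g4, idx[..., None], g[..., None], axis=-1)
        gx = g4.reshape(N, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return ((x, np.ascontiguousarray(gx).reshape(N, C, H, W)),)

    return _make(np.ascontiguousarray(out), (x,), backward)


def upsample2d(x, factor: int = 2) -> Tensor:
    """Nearest-neighbour upsampling of the last two axes."""
    x = _wrap(x)
    f = factor
    data = np.repeat(np.repeat(x.data, f, axis=-2), f, axis=-1)

    def backward(g):
        s = g.shape
        g6 = g.reshape(*s[:-2], s[-2] // f, f, s[-1] // f, f)
        return ((x, g6.sum(axis=(-3, -1))),)

    return _make(data, (x,), backward)


def _interp_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Linear-interpolation matrix mapping length n_in to n_out (edge-aligned centers)."""
    pos = (np.arange(n_out) + 0.5) * n_in / n_out - 0.5
    pos = np.clip(pos, 0, n_in - 1)
    lo = np.floor(pos).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    t = (pos - lo).astype(np.float32)
    M = np.zeros((n_out, n_in), dtype=np.float32)
    M[np.arange(n_out), lo] += 1 - t
    M[np.arange(n_out), hi] += t
    return M


def axis_resample(x, axis: int, n_out: int) -> Tensor:
    """Differentiable linear resampling of one axis to length n_out."""
    x = _wrap(x)
    n_in = x.data.shape[axis]
    if n_in == n_out:
        return x
    M = _interp_matrix(n_out, n_in)
    moved = np.moveaxis(x.data, axis, -1)
    out = np.moveaxis(moved @ M.T, -1, axis)

    def backward(g):
        gm = np.moveaxis(g, axis, -1)
        return ((x, np.ascontiguousarray(np.moveaxis(gm @ M, -1, axis))),)

    return _make(np.ascontiguousarray(out), (x,), backward)


def dropout(x, p: float, rng: np.random.Generator) -> Tensor:
    """Inverted dropout; call only in training mode."""
    x = _wrap(x)
    if p <= 0:
        return x
    mask = (rng.random(x.data.shape) >= p).astype(np.float32) / (1.0 - p)
    data = x.data * mask

    def backward(g):
        return ((x, g * mask),)

    return _make(data, (x,), backward)


# -- losses ----------------------------------------------------------------

def softmax(x, axis: int = 1) -> Tensor:
    x = _wrap(x)
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * y).sum(axis=axis, keepdims=True)
        return ((x, y * (g - dot)),)

    return _make(y, (x,), backward)


def cross_entropy(logits, target: np.ndarray, axis: int = 1) -> Tensor:
    """Mean cross-entropy of integer class targets against raw logits."""
    logits = _wrap(logits)
    z = logits.data - logits.data.max(axis=axis, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
    logp = z - lse
    tgt = np.asarray(target)
    picked = np.take_along_axis(logp, np.expand_dims(tgt, axis), axis=axis)
    n = picked.size
    data = np.asarray(-picked.sum() / n, dtype=np.float32)

    def backward(g):
        p = np.exp(logp)
        onehot = np.zeros_like(p)
        np.put_along_axis(onehot, np.expand_dims(tgt, axis), 1.0, axis=axis)
        return ((logits, (p - onehot) * (float(g) / n)),)

    return _make(data, (logits,), backward)
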