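"""Reverse-mode automatic differentiation on numpy arrays.

A small tape-based autograd sufficient for volumetric segmentation
networks: elementwise arithmetic with broadcasting, reductions, the usual
activations, 3D convolution (stride 1, "same" padding), strided transposed
convolution, 2x max pooling and instance normalization.  Everything is
float64; volumes carry no batch axis (channels-first ``(C, D, H, W)``),
which matches a training batch size of one.
"""

from __future__ import annotations

from contextlib import contextmanager
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "no_grad",
    "as_tensor",
    "concat",
    "narrow",
    "conv3d",
    "conv_transpose3d",
    "max_pool3d",
    "instance_norm",
    "relu",
    "sigmoid",
    "tanh",
]

_GRAD_ENABLED = True


@contextmanager
def no_grad():
    """Disable graph construction (inference / memory detachment)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    # Make numpy defer to the reflected operators instead of broadcasting
    # a Tensor operand elementwise.
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph ----------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = grad if self.grad is None else self.grad + grad
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    # -- operators ------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, -as_tensor(other))

    def __rsub__(self, other):
        return add(as_tensor(other), -self)

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(as_tensor(other), self)

    def sum(self, axis=None):
        return tsum(self, axis=axis)

    def mean(self, axis=None):
        return tmean(self, axis=axis)

    def log(self):
        return tlog(self)

    def clip(self, lo, hi):
        return tclip(self, lo, hi)

    def reshape(self, *shape):
        return treshape(self, shape)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _result(data, parents: Sequence[Tensor], backward: Callable[[np.ndarray], None]) -> Tensor:
    out = Tensor(data)
    if _GRAD_ENABLED and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


# -- elementwise --------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.data.shape))

    return _result(out_data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _result(out_data, (a, b), backward)


def div(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data / b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g / b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(-g * a.data / (b.data ** 2), b.data.shape))

    return _result(out_data, (a, b), backward)


def tsum(a: Tensor, axis=None) -> Tensor:
    out_data = a.data.sum(axis=axis)

    def backward(g):
        if not a.requires_grad:
            return
        if axis is None:
            a._accumulate(np.broadcast_to(g, a.data.shape).copy())
        else:
            a._accumulate(np.broadcast_to(np.expand_dims(g, axis), a.data.shape).copy())

    return _result(out_data, (a,), backward)


def tmean(a: Tensor, axis=None) -> Tensor:
    n = a.data.size if axis is None else a.data.shape[axis]
    return mul(tsum(a, axis=axis), 1.0 / n)


def tlog(a: Tensor) -> Tensor:
    out_data = np.log(a.data)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g / a.data)

    return _result(out_data, (a,), backward)


def tclip(a: Tensor, lo: float, hi: float) -> Tensor:
    out_data = np.clip(a.data, lo, hi)
    inside = (a.data >= lo) & (a.data <= hi)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * inside)

    return _result(out_data, (a,), backward)


def treshape(a: Tensor, shape) -> Tensor:
    out_data = a.data.reshape(shape)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g.reshape(a.data.shape))

    return _result(out_data, (a,), backward)


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0
    out_data = a.data * mask

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * mask)

    return _result(out_data, (a,), backward)


def sigmoid(a: Tensor) -> Tensor:
    out_data = 1.0 / (1.0 + np.exp(-a.data))

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * out_data * (1.0 - out_data))

    return _result(out_data, (a,), backward)


def tanh(a: Tensor) -> Tensor:
    out_data = np.tanh(a.data)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * (1.0 - out_data ** 2))

    return _result(out_data, (a,), backward)


def concat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    ts = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.data.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accumulate(g[tuple(idx)])

    return _result(out_data, ts, backward)


# -- spatial ops --------------------------------------------------------

def _offsets(k: int):
    for iz in range(k):
        for iy in range(k):
            for ix in range(k):
                yield iz, iy, ix


def narrow(a: Tensor, axis: int, start: int, length: int) -> Tensor:
    """Contiguous slice along one axis (differentiable)."""
    idx = [slice(None)] * a.data.ndim
    idx[axis] = slice(start, start + length)
    idx = tuple(idx)
    out_data = a.data[idx]

    def backward(g):
        if a.requires_grad:
            ga = np.zeros_like(a.data)
            ga[idx] = g
            a._accumulate(ga)

    return _result(out_data, (a,), backward)


def _im2col(xp: np.ndarray, k: int, spatial) -> np.ndarray:
    """(Cin, D+2p, ...) padded volume -> (Cin*k^3, D*H*W) patch matrix."""
    D, H, W = spatial
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k, k), axis=(1, 2, 3))
    return win.transpose(0, 4, 5, 6, 1, 2, 3).reshape(xp.shape[0] * k ** 3, D * H * W)


def conv3d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """3D convolution, stride 1, zero 'same' padding, via im2col + GEMM.

    ``x``: (Cin, D, H, W); ``w``: (Cout, Cin, k, k, k) with odd k;
    ``b``: (Cout,) or None.  (Cross-correlation, as in every DL framework.)
    """
    xd, wd = x.data, w.data
    cout, cin, k = wd.shape[0], wd.shape[1], wd.shape[2]
    if xd.ndim != 4 or xd.shape[0] != cin:
        raise ValueError(f"conv3d: input shape {xd.shape} incompatible with kernel {wd.shape}")
    p = k // 2
    D, H, W = xd.shape[1:]
    spatial = (D, H, W)
    cols = None
    if k == 1:
        out = (wd.reshape(cout, cin) @ xd.reshape(cin, -1)).reshape(cout, D, H, W)
    else:
        xp = np.pad(xd, ((0, 0), (p, p), (p, p), (p, p)))
        cols = _im2col(xp, k, spatial)
        out = (wd.reshape(cout, -1) @ cols).reshape(cout, D, H, W)
    if b is not None:
        out += b.data.reshape(-1, 1, 1, 1)
    if not (_GRAD_ENABLED and (x.requires_grad or w.requires_grad
                               or (b is not None and b.requires_grad))):
        cols = None  # inference: drop the patch matrix immediately

    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        gmat = g.reshape(cout, -1)
        if k == 1:
            if x.requires_grad:
                x._accumulate((wd.reshape(cout, cin).T @ gmat).reshape(xd.shape))
            if w.requires_grad:
                w._accumulate((gmat @ xd.reshape(cin, -1).T).reshape(wd.shape))
        else:
            if w.requires_grad:
                w._accumulate((gmat @ cols.T).reshape(wd.shape))
            if x.requires_grad:
                gcols = (wd.reshape(cout, -1).T @ gmat).reshape(cin, k, k, k, D, H, W)
                gxp = np.zeros((cin, D + 2 * p, H + 2 * p, W + 2 * p))
                for iz, iy, ix in _offsets(k):
                    gxp[:, iz:iz + D, iy:iy + H, ix:ix + W] += gcols[:, iz, iy, ix]
                x._accumulate(gxp[:, p:p + D, p:p + H, p:p + W])
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(1, 2, 3)))

    return _result(out, parents, backward)


def conv_transpose3d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Transposed 3D convolution with kernel 2, stride 2 (exact x2 upsampling).

    ``x``: (Cin, D, H, W); ``w``: (Cout, Cin, 2, 2, 2); output (Cout, 2D, 2H, 2W).
    """
    xd, wd = x.data, w.data
    cout, cin = wd.shape[0], wd.shape[1]
    if xd.shape[0] != cin:
        raise ValueError(f"conv_transpose3d: input shape {xd.shape} incompatible with kernel {wd.shape}")
    D, H, W = xd.shape[1:]
    out = np.empty((cout, 2 * D, 2 * H, 2 * W))
    for iz, iy, ix in _offsets(2):
        out[:, iz::2, iy::2, ix::2] = np.tensordot(wd[:, :, iz, iy, ix], xd, axes=(1, 0))
    if b is not None:
        out += b.data.reshape(-1, 1, 1, 1)

    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        if x.requires_grad:
            gx = np.zeros_like(xd)
            for iz, iy, ix in _offsets(2):
                gx += np.tensordot(wd[:, :, iz, iy, ix].T, g[:, iz::2, iy::2, ix::2], axes=(1, 0))
            x._accumulate(gx)
        if w.requires_grad:
            gw = np.empty_like(wd)
            for iz, iy, ix in _offsets(2):
                gw[:, :, iz, iy, ix] = np.tensordot(
                    g[:, iz::2, iy::2, ix::2], xd, axes=([1, 2, 3], [1, 2, 3]))
            w._accumulate(gw)
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(1, 2, 3)))

    return _result(out, parents, backward)


def max_pool3d(x: Tensor) -> Tensor:
    """2x2x2 max pooling, stride 2.  Ties share the gradient equally."""
    xd = x.data
    C, D, H, W = xd.shape
    if D % 2 or H % 2 or W % 2:
        raise ValueError(f"max_pool3d: spatial dims {xd.shape[1:]} not divisible by 2")
    xr = xd.reshape(C, D // 2, 2, H // 2, 2, W // 2, 2)
    out = xr.max(axis=(2, 4, 6))

    def backward(g):
        if not x.requires_grad:
            return
        m = out[:, :, None, :, None, :, None]
        mask = (xr == m)
        cnt = mask.sum(axis=(2, 4, 6), keepdims=True)
        gx = mask * (g[:, :, None, :, None, :, None] / cnt)
        x._accumulate(gx.reshape(C, D, H, W))

    return _result(out, (x,), backward)


def instance_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Per-channel normalization over the spatial axes with affine parameters.

    Appropriate for batch size 1, where batch statistics are meaningless.
    """
    xd = x.data
    mu = xd.mean(axis=(1, 2, 3), keepdims=True)
    var = xd.var(axis=(1, 2, 3), keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (xd - mu) * inv
    gb = gamma.data.reshape(-1, 1, 1, 1)
    out = gb * xhat + beta.data.reshape(-1, 1, 1, 1)

    def backward(g):
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=(1, 2, 3)))
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=(1, 2, 3)))
        if x.requires_grad:
            gh = g * gb
            m1 = gh.mean(axis=(1, 2, 3), keepdims=True)
            m2 = (gh * xhat).mean(axis=(1, 2, 3), keepdims=True)
            x._accumulate(inv * (gh - m1 - xhat * m2))

    return _result(out, (x, gamma, beta), backward)
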