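"""Reverse-mode automatic differentiation on numpy arrays.

A deliberately small tape-based engine: each operation returns a new
:class:`Tensor` holding the forward value and a closure that propagates
gradients to its parents.  Only the primitives the translation and
segmentation networks need are provided (elementwise arithmetic with
broadcasting, reductions, activations, 2-D padding/convolution and
friends).  Gradients are checked against central finite differences in
the test suite.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Tensor", "concat", "conv2d", "depthwise_conv2d", "pad2d",
           "zero_dilate2d", "interp2d"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """An n-d array with an optional gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64) if not isinstance(
            data, np.ndarray) else data
        if self.data.dtype not in (np.float32, np.float64):
            self.data = self.data.astype(np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # ------------------------------------------------------------------ infra
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(np.asarray(other))

    def _make(self, data: np.ndarray, parents: Sequence["Tensor"], backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def _accumulate(self, grad: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad = self.grad + grad

    def zero_grad(self) -> None:
        self.grad = None

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = self._wrap(other)
        a, b = self, other

        def backward(g):
            a._accumulate(_unbroadcast(g, a.shape))
            b._accumulate(_unbroadcast(g, b.shape))

        return self._make(a.data + b.data, (a, b), backward)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def backward(g):
            a._accumulate(-g)

        return self._make(-a.data, (a,), backward)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        a, b = self, other

        def backward(g):
            a._accumulate(_unbroadcast(g * b.data, a.shape))
            b._accumulate(_unbroadcast(g * a.data, b.shape))

        return self._make(a.data * b.data, (a, b), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        a, b = self, other

        def backward(g):
            a._accumulate(_unbroadcast(g / b.data, a.shape))
            b._accumulate(_unbroadcast(-g * a.data / (b.data ** 2), b.shape))

        return self._make(a.data / b.data, (a, b), backward)

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, p: float):
        a = self

        def backward(g):
            a._accumulate(g * p * a.data ** (p - 1))

        return self._make(a.data ** p, (a,), backward)

    def sqrt(self):
        a = self
        y = np.sqrt(a.data)

        def backward(g):
            a._accumulate(g * 0.5 / np.maximum(np.sqrt(a.data), 1e-300))

        return self._make(y, (a,), backward)

    # -------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        a = self
        y = a.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            a._accumulate(np.broadcast_to(g, a.shape).copy())

        return self._make(y, (a,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.shape[ax] for ax in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ------------------------------------------------------------- activations
    def relu(self):
        a = self
        mask = a.data > 0

        def backward(g):
            a._accumulate(g * mask)

        return self._make(a.data * mask, (a,), backward)

    def leaky_relu(self, slope: float = 0.2):
        a = self
        mask = a.data > 0
        factor = np.where(mask, 1.0, slope)

        def backward(g):
            a._accumulate(g * factor)

        return self._make(a.data * factor, (a,), backward)

    def tanh(self):
        a = self
        y = np.tanh(a.data)

        def backward(g):
            a._accumulate(g * (1.0 - y ** 2))

        return self._make(y, (a,), backward)

    def sigmoid(self):
        a = self
        y = 1.0 / (1.0 + np.exp(-a.data))

        def backward(g):
            a._accumulate(g * y * (1.0 - y))

        return self._make(y, (a,), backward)

    def exp(self):
        a = self
        y = np.exp(a.data)

        def backward(g):
            a._accumulate(g * y)

        return self._make(y, (a,), backward)

    def log(self):
        a = self

        def backward(g):
            a._accumulate(g / a.data)

        return self._make(np.log(a.data), (a,), backward)

    def abs(self):
        a = self
        sign = np.sign(a.data)

        def backward(g):
            a._accumulate(g * sign)

        return self._make(np.abs(a.data), (a,), backward)

    def clip(self, lo: float, hi: float):
        a = self
        mask = (a.data > lo) & (a.data < hi)

        def backward(g):
            a._accumulate(g * mask)

        return self._make(np.clip(a.data, lo, hi), (a,), backward)

    # ------------------------------------------------------------------ shape
    def reshape(self, *shape):
        a = self
        old = a.shape

        def backward(g):
            a._accumulate(g.reshape(old))

        return self._make(a.data.reshape(*shape), (a,), backward)

    def __getitem__(self, idx):
        a = self

        def backward(g):
            buf = np.zeros_like(a.data)
            buf[idx] = g
            a._accumulate(buf)

        return self._make(a.data[idx], (a,), backward)


def concat(tensors: Iterable[Tensor], axis: int = 1) -> Tensor:
    tensors = list(tensors)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)
    out_data = np.concatenate([t.data for t in tensors], axis=axis)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            t._accumulate(g[tuple(idx)])

    return tensors[0]._make(out_data, tensors, backward)


def pad2d(x: Tensor, pad: int, mode: str = "constant") -> Tensor:
    """Pad the two trailing spatial axes of an NCHW tensor."""
    if pad == 0:
        return x
    n, c, h, w = x.shape
    if mode == "constant":
        data = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))

        def backward(g):
            x._accumulate(g[:, :, pad:-pad, pad:-pad])

        return x._make(data, (x,), backward)
    if mode == "reflect":
        idx_h = np.r_[pad:0:-1, 0:h, h - 2:h - 2 - pad:-1]
        idx_w = np.r_[pad:0:-1, 0:w, w - 2:w - 2 - pad:-1]
        data = x.data[:, :, idx_h][:, :, :, idx_w]

        def backward(g):
            tmp = np.zeros((n, c, h, w + 2 * pad), dtype=g.dtype)
            np.add.at(tmp, (slice(None), slice(None), idx_h), g)
            gx = np.zeros((n, c, h, w), dtype=g.dtype)
            np.add.at(gx, (slice(None), slice(None), slice(None), idx_w), tmp)
            x._accumulate(gx)

        return x._make(data, (x,), backward)
    raise ValueError(f"unknown padding mode {mode!r}")


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, dilation: int = 1) -> Tensor:
    """2-D cross-correlation on NCHW input with OIHW weights (no padding)."""
    xd, wd = x.data, w.data
    n, cin, h, ww_ = xd.shape
    cout, cin_w, kh, kw = wd.shape
    if cin != cin_w:
        raise ValueError("channel mismatch in conv2d")
    eh = (kh - 1) * dilation + 1
    ew = (kw - 1) * dilation + 1
    if h < eh or ww_ < ew:
        raise ValueError("input smaller than (dilated) kernel")
    win = sliding_window_view(xd, (eh, ew), axis=(2, 3))
    win = win[:, :, ::stride, ::stride, ::dilation, ::dilation]
    ho, wo = win.shape[2], win.shape[3]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, cin * kh * kw)
    wmat = wd.reshape(cout, cin * kh * kw)
    y = (cols @ wmat.T).reshape(n, ho, wo, cout).transpose(0, 3, 1, 2)
    if b is not None:
        y = y + b.data.reshape(1, cout, 1, 1)

    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        gmat = g.transpose(0, 2, 3, 1).reshape(n * ho * wo, cout)
        if w.requires_grad:
            gw = (gmat.T @ cols).reshape(cout, cin, kh, kw)
            w._accumulate(gw)
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gx = np.zeros_like(xd)
            for p in range(kh):
                for q in range(kw):
                    # grad wrt x[n, c, i*s + p*d, j*s + q*d]
                    contrib = np.tensordot(g, wd[:, :, p, q], axes=([1], [0]))
                    # contrib: (n, ho, wo, cin) -> scatter into strided view
                    gx[:, :,
                       p * dilation:p * dilation + ho * stride:stride,
                       q * dilation:q * dilation + wo * stride:stride] += \
                        contrib.transpose(0, 3, 1, 2)
            x._accumulate(gx)

    return x._make(y, parents, backward)


def depthwise_conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
                     stride: int = 1, dilation: int = 1) -> Tensor:
    """Per-channel 2-D convolution; weights shaped (C, kh, kw)."""
    xd, wd = x.data, w.data
    n, c, h, ww_ = xd.shape
    cw, kh, kw = wd.shape
    if c != cw:
        raise ValueError("channel mismatch in depthwise_conv2d")
    eh = (kh - 1) * dilation + 1
    ew = (kw - 1) * dilation + 1
    if h < eh or ww_ < ew:
        raise ValueError("input smaller than (dilated) kernel")
    win = sliding_window_view(xd, (eh, ew), axis=(2, 3))
    win = win[:, :, ::stride, ::stride, ::dilation, ::dilation]
    ho, wo = win.shape[2], win.shape[3]
    y = np.einsum("nchwpq,cpq->nchw", win, wd, optimize=True)
    if b is not None:
        y = y + b.data.reshape(1, c, 1, 1)

    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        if w.requires_grad:
            gw = np.einsum("nchwpq,nchw->cpq", win, g, optimize=True)
            w._accumulate(gw)
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gx = np.zeros_like(xd)
            for p in range(kh):
                for q in range(kw):
                    gx[:, :,
                       p * dilation:p * dilation + ho * stride:stride,
                       q * dilation:q * dilation + wo * stride:stride] += \
                        g * wd[:, p, q][None, :, None, None]
            x._accumulate(gx)

    return x._make(y, parents, backward)


def zero_dilate2d(x: Tensor, stride: int, extra: int = 0) -> Tensor:
    """Insert ``stride - 1`` zeros between pixels (plus trailing zeros)."""
    n, c, h, w = x.shape
    ho = (h - 1) * stride + 1 + extra
    wo = (w - 1) * stride + 1 + extra
    data = np.zeros((n, c, ho, wo), dtype=x.data.dtype)
    data[:, :, ::stride, ::stride][:, :, :h, :w] = x.data

    def backward(g):
        x._accumulate(g[:, :, ::stride, ::stride][:, :, :h, :w])

    return x._make(data, (x,), backward)


def interp2d(x: Tensor, mat_h: np.ndarray, mat_w: np.ndarray) -> Tensor:
    """Apply fixed interpolation matrices along H and W: ``A_h x A_w^T``."""
    t = np.matmul(mat_h, x.data)          # (n, c, H2, W)
    y = np.matmul(t, mat_w.T)             # (n, c, H2, W2)

    def backward(g):
        gt = np.matmul(g, mat_w)
        x._accumulate(np.matmul(mat_h.T, gt))

    return x._make(y, (x,), backward)
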