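"""Minimal reverse-mode automatic differentiation over numpy arrays.

The networks in this package (the attention-gated U-Net and the ConvNeXt-V2
application backbone) are trained through this engine.  It implements exactly
the operator set those architectures need — elementwise arithmetic with
broadcasting, matmul, reductions, activations, 2-D convolution with stride /
dilation / groups, max pooling, and bilinear resampling — with gradients
validated against finite differences in the test suite.

Tensors carry float data of whatever precision they were built with; training
uses float32, gradient-check tests use float64.
"""

from __future__ import annotations

import math
from contextlib import contextmanager
from typing import Callable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import special as _special

__all__ = ["Tensor", "no_grad", "concat", "is_grad_enabled"]

_GRAD_ENABLED = True


@contextmanager
def no_grad():
    """Disable graph construction (inference / weight updates)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward_fn")

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, Tensor):
            data = data.data
        arr = np.asarray(data)
        if not np.issubdtype(arr.dtype, np.floating):
            arr = arr.astype(np.float32)
        self.data = arr
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward_fn: Callable[[np.ndarray], None] | None = None

    # -- graph plumbing ----------------------------------------------------

    @staticmethod
    def _result(data: np.ndarray, parents: Sequence["Tensor"],
                backward: Callable[[np.ndarray], None]) -> "Tensor":
        req = _GRAD_ENABLED and any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=req)
        if req:
            out._parents = tuple(parents)
            out._backward_fn = backward
        return out

    def _accum(self, g: np.ndarray) -> None:
        if not self.requires_grad:
            return
        g = _unbroadcast(np.asarray(g, dtype=self.data.dtype), self.data.shape)
        self.grad = g if self.grad is None else self.grad + g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar tensor")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or node._backward_fn is None:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self._accum(grad)
        for node in reversed(topo):
            if node.grad is not None:
                node._backward_fn(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- convenience -------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    # -- elementwise arithmetic --------------------------------------------

    def __add__(self, other):
        other = self._wrap(other)
        a, b = self, other

        def bw(g):
            a._accum(g)
            b._accum(g)

        return self._result(a.data + b.data, (a, b), bw)

    __radd__ = __add__

    def __neg__(self):
        a = self
        return self._result(-a.data, (a,), lambda g: a._accum(-g))

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        a, b = self, other

        def bw(g):
            a._accum(g * b.data)
            b._accum(g * a.data)

        return self._result(a.data * b.data, (a, b), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        a, b = self, other

        def bw(g):
            a._accum(g / b.data)
            b._accum(-g * a.data / (b.data * b.data))

        return self._result(a.data / b.data, (a, b), bw)

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, p: float):
        a = self
        out = a.data ** p
        return self._result(out, (a,), lambda g: a._accum(g * p * a.data ** (p - 1)))

    def exp(self):
        a = self
        out = np.exp(a.data)
        return self._result(out, (a,), lambda g: a._accum(g * out))

    def log(self):
        a = self
        return self._result(np.log(a.data), (a,), lambda g: a._accum(g / a.data))

    def sqrt(self):
        a = self
        out = np.sqrt(a.data)
        return self._result(out, (a,), lambda g: a._accum(g / (2.0 * out)))

    # -- activations --------------------------------------------------------

    def relu(self):
        a = self
        mask = a.data > 0
        return self._result(a.data * mask, (a,), lambda g: a._accum(g * mask))

    def sigmoid(self):
        a = self
        out = _special.expit(a.data)
        return self._result(out, (a,), lambda g: a._accum(g * out * (1.0 - out)))

    def gelu(self):
        """Exact Gaussian-error-linear unit, 0.5 x (1 + erf(x / sqrt(2)))."""
        a = self
        cdf = 0.5 * (1.0 + _special.erf(a.data / math.sqrt(2.0)))
        out = a.data * cdf

        def bw(g):
            pdf = np.exp(-0.5 * a.data * a.data) / math.sqrt(2.0 * math.pi)
            a._accum(g * (cdf + a.data * pdf))

        return self._result(out, (a,), bw)

    # -- reductions / shape ------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        a = self
        out = a.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            a._accum(np.broadcast_to(g, a.data.shape))

        return self._result(out, (a,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[i] for i in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        return self._result(a.data.reshape(shape), (a,),
                            lambda g: a._accum(g.reshape(a.data.shape)))

    def transpose(self, axes):
        a = self
        inv = np.argsort(axes)
        return self._result(a.data.transpose(axes), (a,),
                            lambda g: a._accum(g.transpose(inv)))

    def __getitem__(self, idx):
        a = self

        def bw(g):
            full = np.zeros_like(a.data)
            np.add.at(full, idx, g)
            a._accum(full)

        return self._result(a.data[idx], (a,), bw)

    def __matmul__(self, other):
        other = self._wrap(other)
        a, b = self, other

        def bw(g):
            a._accum(g @ b.data.swapaxes(-1, -2))
            b._accum(a.data.swapaxes(-1, -2) @ g)

        return self._result(a.data @ b.data, (a, b), bw)

    # -- spatial ops ---------------------------------------------------------

    def conv2d(self, weight: "Tensor", bias: "Tensor | None" = None,
               stride: int = 1, padding: int = 0, dilation: int = 1,
               groups: int = 1):
        return _conv2d(self, weight, bias, stride, padding, dilation, groups)

    def maxpool2x2(self):
        return _maxpool2x2(self)

    def resize_bilinear(self, out_h: int, out_w: int):
        return _resize_bilinear(self, out_h, out_w)


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accum(piece)

    return Tensor._result(np.concatenate([t.data for t in tensors], axis=axis),
                          tensors, bw)


# ---------------------------------------------------------------------------
# convolution


def _dilated_windows(x: np.ndarray, kh: int, kw: int, stride: int,
                     padding: int, dilation: int) -> np.ndarray:
    """Return view (N, C, Ho, Wo, kh, kw) of sliding windows of ``x``."""
    if padding:
        x = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    kh_eff = (kh - 1) * dilation + 1
    kw_eff = (kw - 1) * dilation + 1
    win = sliding_window_view(x, (kh_eff, kw_eff), axis=(2, 3))
    win = win[:, :, ::stride, ::stride, ::dilation, ::dilation]
    return win


def conv_out_size(size: int, k: int, stride: int, padding: int, dilation: int) -> int:
    return (size + 2 * padding - dilation * (k - 1) - 1) // stride + 1


def _conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int, padding: int,
            dilation: int, groups: int) -> Tensor:
    xd, wd = x.data, w.data
    n, cin, h, ww_ = xd.shape
    cout, cin_g, kh, kw = wd.shape
    if cin != cin_g * groups or cout % groups:
        raise ValueError(
            f"conv2d channel mismatch: input {cin}, weight {wd.shape}, groups {groups}")
    win = _dilated_windows(xd, kh, kw, stride, padding, dilation)
    ho, wo = win.shape[2], win.shape[3]
    win_g = win.reshape(n, groups, cin_g, ho, wo, kh, kw)
    w_g = wd.reshape(groups, cout // groups, cin_g, kh, kw)
    out = np.einsum("ngchwij,gocij->ngohw", win_g, w_g, optimize=True)
    out = np.ascontiguousarray(out.reshape(n, cout, ho, wo))
    if b is not None:
        out += b.data.reshape(1, cout, 1, 1)
    parents = [x, w] if b is None else [x, w, b]

    def bw(g):
        g_g = g.reshape(n, groups, cout // groups, ho, wo)
        if w.requires_grad:
            gw = np.einsum("ngchwij,ngohw->gocij", win_g, g_g, optimize=True)
            w._accum(gw.reshape(wd.shape))
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            # scatter g*w back onto the padded input, then strip the padding
            hp, wp = h + 2 * padding, ww_ + 2 * padding
            gx_pad = np.zeros((n, cin, hp, wp), dtype=xd.dtype)
            # contribution of every (output position, kernel tap)
            contrib = np.einsum("ngohw,gocij->ngchwij", g_g, w_g, optimize=True)
            contrib = contrib.reshape(n, cin, ho, wo, kh, kw)
            for i in range(kh):
                hi = i * dilation
                rows = slice(hi, hi + stride * ho, stride)
                for j in range(kw):
                    wj = j * dilation
                    cols = slice(wj, wj + stride * wo, stride)
                    gx_pad[:, :, rows, cols] += contrib[:, :, :, :, i, j]
            if padding:
                gx_pad = gx_pad[:, :, padding:hp - padding, padding:wp - padding]
            x._accum(gx_pad)

    return Tensor._result(out, parents, bw)


def _maxpool2x2(x: Tensor) -> Tensor:
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError(f"maxpool2x2 requires even spatial dims, got {h}x{w}")
    win = x.data.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    win = win.reshape(n, c, h // 2, w // 2, 4)
    idx = win.argmax(axis=-1)
    out = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]

    def bw(g):
        gwin = np.zeros_like(win)
        np.put_along_axis(gwin, idx[..., None], g[..., None], axis=-1)
        gx = gwin.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        x._accum(gx.reshape(n, c, h, w))

    return Tensor._result(np.ascontiguousarray(out), (x,), bw)


def conv_transpose2x2(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Transposed convolution, kernel 2x2 stride 2 (exact 2x upsampling).

    ``w`` has shape (C_in, C_out, 2, 2); output is (N, C_out, 2H, 2W) with
    out[n, o, 2i+di, 2j+dj] = sum_c x[n, c, i, j] * w[c, o, di, dj].
    """
    xd, wd = x.data, w.data
    n, cin, h, ww_ = xd.shape
    cin_w, cout = wd.shape[:2]
    if cin != cin_w:
        raise ValueError(f"conv_transpose channel mismatch: {cin} vs {cin_w}")
    out = np.zeros((n, cout, 2 * h, 2 * ww_), dtype=xd.dtype)
    for di in range(2):
        for dj in range(2):
            out[:, :, di::2, dj::2] = np.einsum(
                "nchw,co->nohw", xd, wd[:, :, di, dj], optimize=True)
    if b is not None:
        out += b.data.reshape(1, cout, 1, 1)
    parents = [x, w] if b is None else [x, w, b]

    def bw(g):
        if x.requires_grad:
            gx = np.zeros_like(xd)
            for di in range(2):
                for dj in range(2):
                    gx += np.einsum("nohw,co->nchw", g[:, :, di::2, dj::2],
                                    wd[:, :, di, dj], optimize=True)
            x._accum(gx)
        if w.requires_grad:
            gw = np.empty_like(wd)
            for di in range(2):
                for dj in range(2):
                    gw[:, :, di, dj] = np.einsum(
                        "nchw,nohw->co", xd, g[:, :, di::2, dj::2], optimize=True)
            w._accum(gw)
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))

    return Tensor._result(out, parents, bw)


def interp_matrix(n_in: int, n_out: int, dtype=np.float64) -> np.ndarray:
    """1-D bilinear interpolation matrix, align_corners=False, edges clamped."""
    a = np.zeros((n_out, n_in), dtype=dtype)
    scale = n_in / n_out
    for i in range(n_out):
        src = (i + 0.5) * scale - 0.5
        src = min(max(src, 0.0), n_in - 1.0)
        lo = int(math.floor(src))
        hi = min(lo + 1, n_in - 1)
        frac = src - lo
        a[i, lo] += 1.0 - frac
        a[i, hi] += frac
    return a


def _resize_bilinear(x: Tensor, out_h: int, out_w: int) -> Tensor:
    n, c, h, w = x.data.shape
    ah = interp_matrix(h, out_h, dtype=x.data.dtype)
    aw = interp_matrix(w, out_w, dtype=x.data.dtype)
    out = np.einsum("oh,nchw,pw->ncop", ah, x.data, aw, optimize=True)

    def bw(g):
        x._accum(np.einsum("oh,ncop,pw->nchw", ah, g, aw, optimize=True))

    return Tensor._result(np.ascontiguousarray(out), (x,), bw)
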