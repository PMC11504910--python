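"""Minimal reverse-mode automatic differentiation over numpy arrays.

This is the numerical substrate for the classifier: a :class:`Tensor` wrapping
an ``ndarray`` plus the handful of differentiable operations the network needs
(elementwise arithmetic, batched matmul, convolution via im2col, pooling,
softmax/log-softmax, reductions, reshapes). Gradients are accumulated by a
topological backward sweep, micrograd-style, generalised to broadcasting
ndarrays.

Only the operations used by the model are implemented; this is not a general
deep-learning framework.
"""

from __future__ import annotations

import contextlib
from typing import Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

# ---------------------------------------------------------------------------
# global configuration
# ---------------------------------------------------------------------------

_DEFAULT_DTYPE = np.float32
_GRAD_ENABLED = True


def set_default_dtype(dtype) -> None:
    """Set the floating dtype new tensors are cast to (float32 by default).

    float64 is useful for finite-difference gradient checks in tests.
    """
    global _DEFAULT_DTYPE
    if dtype not in (np.float32, np.float64):
        raise ValueError("dtype must be np.float32 or np.float64")
    _DEFAULT_DTYPE = dtype


def default_dtype():
    return _DEFAULT_DTYPE


@contextlib.contextmanager
def no_grad():
    """Context manager disabling graph construction (inference passes)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An ndarray with an optional gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev",
                 "_grad_owned")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=_DEFAULT_DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self._backward = None
        self._prev: tuple = ()
        self._grad_owned = False

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data, parents: Sequence["Tensor"], backward) -> "Tensor":
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._prev = tuple(p for p in parents if p.requires_grad)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def _accum(self, g: np.ndarray) -> None:
        # First contribution is stored by reference (copy-on-write): incoming
        # buffers may be shared with other nodes, so in-place += only happens
        # once this tensor owns its grad buffer.
        if g.dtype != self.data.dtype:
            g = g.astype(self.data.dtype)
        if self.grad is None:
            self.grad = g
            self._grad_owned = False
        elif self._grad_owned:
            self.grad += g
        else:
            self.grad = self.grad + g
            self._grad_owned = True

    def zero_grad(self) -> None:
        self.grad = None
        self._grad_owned = False

    # -- autodiff -------------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accum(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)
        out_data = self.data + other.data

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return Tensor._make(out_data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            self._accum(-g)

        return Tensor._make(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        out_data = self.data * other.data

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(out_data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)
        out_data = self.data / other.data

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / (other.data**2), other.data.shape)
                )

        return Tensor._make(out_data, (self, other), bw)

    def __rtruediv__(self, other):
        return _as_tensor(other) / self

    def __pow__(self, p: float):
        out_data = self.data**p

        def bw(g):
            self._accum(g * p * self.data ** (p - 1))

        return Tensor._make(out_data, (self,), bw)

    def __matmul__(self, other):
        other = _as_tensor(other)
        out_data = np.matmul(self.data, other.data)

        def bw(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accum(_unbroadcast(gb, other.data.shape))

        return Tensor._make(out_data, (self, other), bw)

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape
        out_data = self.data.reshape(shape)

        def bw(g):
            self._accum(g.reshape(orig))

        return Tensor._make(out_data, (self,), bw)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out_data = np.transpose(self.data, axes)

        def bw(g):
            self._accum(np.transpose(g, inv))

        return Tensor._make(out_data, (self,), bw)

    def narrow(self, axis: int, start: int, length: int):
        """Contiguous slice along one axis (differentiable)."""
        idx = [slice(None)] * self.data.ndim
        idx[axis] = slice(start, start + length)
        idx = tuple(idx)
        out_data = self.data[idx].copy()

        def bw(g):
            full = np.zeros_like(self.data)
            full[idx] = g
            self._accum(full)

        return Tensor._make(out_data, (self,), bw)

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        return Tensor._make(out_data, (self,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False):
        out_data = self.data.max(axis=axis, keepdims=True)
        mask = (self.data == out_data).astype(self.data.dtype)
        mask /= mask.sum(axis=axis, keepdims=True)  # split ties evenly
        res = out_data if keepdims else np.squeeze(out_data, axis=axis)

        def bw(g):
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(mask * g)

        return Tensor._make(res, (self,), bw)

    # -- elementwise nonlinearities -------------------------------------------
    def relu(self):
        mask = self.data > 0
        out_data = self.data * mask

        def bw(g):
            self._accum(g * mask)

        return Tensor._make(out_data, (self,), bw)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def bw(g):
            self._accum(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (self,), bw)

    def exp(self):
        out_data = np.exp(self.data)

        def bw(g):
            self._accum(g * out_data)

        return Tensor._make(out_data, (self,), bw)

    def log(self):
        out_data = np.log(self.data)

        def bw(g):
            self._accum(g / self.data)

        return Tensor._make(out_data, (self,), bw)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ---------------------------------------------------------------------------
# composite / structured operations
# ---------------------------------------------------------------------------


def concat(tensors: Iterable[Tensor], axis: int) -> Tensor:
    tensors = list(tensors)
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(a, b)
                t._accum(g[tuple(idx)])

    return Tensor._make(out_data, tensors, bw)


def softmax(x: Tensor, axis: int) -> Tensor:
    y = x.data - x.data.max(axis=axis, keepdims=True)
    np.exp(y, out=y)
    y /= y.sum(axis=axis, keepdims=True)

    def bw(g):
        dot = (g * y).sum(axis=axis, keepdims=True)
        dx = g - dot
        dx *= y
        x._accum(dx)

    return Tensor._make(y, (x,), bw)


def log_softmax(x: Tensor, axis: int) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
    out_data = z - lse
    y = np.exp(out_data)

    def bw(g):
        x._accum(g - y * g.sum(axis=axis, keepdims=True))

    return Tensor._make(out_data, (x,), bw)


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of integer `labels` under softmax(`logits`)."""
    labels = np.asarray(labels)
    n = logits.data.shape[0]
    ls = log_softmax(logits, axis=1)
    picked = ls.data[np.arange(n), labels]
    out_data = np.array(-picked.mean(), dtype=logits.data.dtype)

    def bw(g):
        gi = np.zeros_like(ls.data)
        gi[np.arange(n), labels] = -float(g) / n
        ls._accum(gi)

    return Tensor._make(out_data, (ls,), bw)


def _pad_hw(x: np.ndarray, pad: int) -> np.ndarray:
    if pad == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))


def _windows(xp: np.ndarray, k: int, stride: int):
    """Strided (N, C, Ho, Wo, k, k) view of padded input."""
    w = sliding_window_view(xp, (k, k), axis=(2, 3))
    if stride > 1:
        w = w[:, :, ::stride, ::stride]
    return w


def _col2im(dwin: np.ndarray, xp_shape: tuple, k: int, stride: int) -> np.ndarray:
    """Scatter window gradients back to the padded input (inverse of _windows)."""
    dxp = np.zeros(xp_shape, dtype=dwin.dtype)
    Ho, Wo = dwin.shape[2], dwin.shape[3]
    for ki in range(k):
        for kj in range(k):
            dxp[
                :, :, ki : ki + stride * Ho : stride, kj : kj + stride * Wo : stride
            ] += dwin[:, :, :, :, ki, kj]
    return dxp


def conv2d(
    x: Tensor,
    weight: Tensor,
    bias: Tensor | None,
    stride: int = 1,
    padding: int = 0,
) -> Tensor:
    """Standard 2-D convolution (cross-correlation), NCHW layout."""
    N, C, H, W = x.data.shape
    O, Cw, k, _ = weight.data.shape
    if Cw != C:
        raise ValueError(f"conv2d: weight expects {Cw} input channels, got {C}")
    xp = _pad_hw(x.data, padding)
    Ho = (xp.shape[2] - k) // stride + 1
    Wo = (xp.shape[3] - k) // stride + 1
    win = _windows(xp, k, stride)[:, :, :Ho, :Wo]
    # (N, Ho, Wo, C*k*k) @ (C*k*k, O)
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        N, Ho * Wo, C * k * k
    )
    w2 = weight.data.reshape(O, C * k * k)
    out = cols @ w2.T
    if bias is not None:
        out += bias.data
    out_data = out.reshape(N, Ho, Wo, O).transpose(0, 3, 1, 2)
    parents = [x, weight] + ([bias] if bias is not None else [])

    def bw(g):
        g2 = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(N, Ho * Wo, O)
        if weight.requires_grad:
            dw = np.tensordot(g2, cols, axes=([0, 1], [0, 1]))  # (O, C*k*k)
            weight._accum(dw.reshape(weight.data.shape))
        if bias is not None and bias.requires_grad:
            bias._accum(g2.sum(axis=(0, 1)))
        if x.requires_grad:
            dcols = g2 @ w2  # (N, Ho*Wo, C*k*k)
            dwin = dcols.reshape(N, Ho, Wo, C, k, k).transpose(0, 3, 1, 2, 4, 5)
            dxp = _col2im(dwin, xp.shape, k, stride)
            if padding:
                dxp = dxp[:, :, padding:-padding, padding:-padding]
            x._accum(dxp)

    return Tensor._make(out_data, parents, bw)


def depthwise_conv2d(
    x: Tensor,
    weight: Tensor,
    bias: Tensor | None,
    stride: int = 1,
    padding: int = 0,
) -> Tensor:
    """Depthwise convolution: one k x k filter per input channel.

    `weight` has shape (C, k, k); output has C channels.
    """
    N, C, H, W = x.data.shape
    Cw, k, _ = weight.data.shape
    if Cw != C:
        raise ValueError(f"depthwise_conv2d: {Cw} filters for {C} channels")
    xp = _pad_hw(x.data, padding)
    Ho = (xp.shape[2] - k) // stride + 1
    Wo = (xp.shape[3] - k) // stride + 1
    win = _windows(xp, k, stride)[:, :, :Ho, :Wo]
    out_data = np.einsum("nchwij,cij->nchw", win, weight.data)
    if bias is not None:
        out_data = out_data + bias.data[None, :, None, None]
    parents = [x, weight] + ([bias] if bias is not None else [])

    def bw(g):
        if weight.requires_grad:
            weight._accum(np.einsum("nchw,nchwij->cij", g, win))
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dwin = np.einsum("nchw,cij->nchwij", g, weight.data)
            dxp = _col2im(dwin, xp.shape, k, stride)
            if padding:
                dxp = dxp[:, :, padding:-padding, padding:-padding]
            x._accum(dxp)

    return Tensor._make(out_data, parents, bw)


def max_pool2d(x: Tensor, kernel: int, stride: int, padding: int = 0) -> Tensor:
    N, C, H, W = x.data.shape
    fill = np.finfo(x.data.dtype).min
    if padding:
        xp = np.full(
            (N, C, H + 2 * padding, W + 2 * padding), fill, dtype=x.data.dtype
        )
        xp[:, :, padding : padding + H, padding : padding + W] = x.data
    else:
        xp = x.data
    Ho = (xp.shape[2] - kernel) // stride + 1
    Wo = (xp.shape[3] - kernel) // stride + 1
    win = _windows(xp, kernel, stride)[:, :, :Ho, :Wo]
    flat = win.reshape(N, C, Ho, Wo, kernel * kernel)
    arg = flat.argmax(axis=-1)
    out_data = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]

    # map window-local argmax to padded coordinates
    ki, kj = np.divmod(arg, kernel)
    oh = np.arange(Ho)[None, None, :, None]
    ow = np.arange(Wo)[None, None, None, :]
    ph = oh * stride + ki
    pw = ow * stride + kj
    nn = np.arange(N)[:, None, None, None]
    cc = np.arange(C)[None, :, None, None]
    lin = ((nn * C + cc) * xp.shape[2] + ph) * xp.shape[3] + pw

    def bw(g):
        dxp = np.bincount(
            lin.ravel(), weights=g.ravel().astype(np.float64), minlength=xp.size
        ).reshape(xp.shape)
        if padding:
            dxp = dxp[:, :, padding : padding + H, padding : padding + W]
        x._accum(dxp.astype(x.data.dtype))

    return Tensor._make(out_data, (x,), bw)


def adaptive_avg_pool2d(x: Tensor, out_hw: int) -> Tensor:
    """Average-pool an NCHW map to an out_hw x out_hw grid.

    Fast reshape path when both spatial dims divide evenly, otherwise generic
    per-bin slicing (still differentiable).
    """
    N, C, H, W = x.data.shape
    g = out_hw
    if H == g and W == g:
        return x
    if H % g == 0 and W % g == 0:
        return (
            x.reshape(N, C, g, H // g, g, W // g).mean(axis=(3, 5))
        )
    rows = [(int(np.floor(i * H / g)), int(np.ceil((i + 1) * H / g))) for i in range(g)]
    cols = [(int(np.floor(j * W / g)), int(np.ceil((j + 1) * W / g))) for j in range(g)]
    cells = []
    for r0, r1 in rows:
        for c0, c1 in cols:
            cell = x.narrow(2, r0, r1 - r0).narrow(3, c0, c1 - c0)
            cells.append(cell.mean(axis=(2, 3), keepdims=True))
    grid = concat(cells, axis=2)  # (N, C, g*g, 1)
    return grid.reshape(N, C, g, g)


def global_avg_pool(x: Tensor) -> Tensor:
    """GAP: NCHW -> NC."""
    return x.mean(axis=(2, 3))


def global_max_pool(x: Tensor) -> Tensor:
    """GMP: NCHW -> NC."""
    return x.max(axis=3).max(axis=2)
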