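"""Reverse-mode automatic differentiation on NumPy arrays.

A deliberately small tape-based engine: every operation builds a node holding
references to its parent tensors and a closure that maps the output gradient
to parent gradients.  ``Tensor.backward()`` topologically sorts the tape and
accumulates gradients.  Only the operations the segmentation network needs are
implemented (elementwise arithmetic, matmul, 2-D convolution at stride 1,
softmax, reductions, reshaping).  Gradients are validated against central
finite differences in the test suite.

Float32 is the working precision throughout the network; float64 inputs are
left untouched so that finite-difference checks can run at full precision.
"""

from __future__ import annotations

import contextlib
from typing import Iterable, Sequence

import numpy as np
from scipy.special import erf

_GRAD_ENABLED = True

_INV_SQRT2 = 1.0 / np.sqrt(2.0)
_INV_SQRT2PI = 1.0 / np.sqrt(2.0 * np.pi)


@contextlib.contextmanager
def no_grad():
    """Disable graph construction inside the block (inference / metrics)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def grad_enabled() -> bool:
    return _GRAD_ENABLED


def _as_array(x, like: np.ndarray | None = None) -> np.ndarray:
    a = np.asarray(x)
    if a.dtype.kind != "f":
        dtype = like.dtype if like is not None else np.float32
        a = a.astype(dtype)
    return a


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = _as_array(data)
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _op(data, parents: Sequence["Tensor"], backward):
        req = _GRAD_ENABLED and any(p.requires_grad for p in parents)
        out = Tensor.__new__(Tensor)
        out.data = data
        out.requires_grad = req
        out.grad = None
        out._parents = tuple(parents) if req else ()
        out._backward = backward if req else None
        return out

    # -- basic info -----------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    @property
    def dtype(self):
        return self.data.dtype

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- autograd -------------------------------------------------------------
    def backward(self, grad=None):
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that does not require grad")
        if grad is None:
            if self.data.size != 1:
                raise RuntimeError("grad must be supplied for non-scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs are deep (24-block encoders)
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            for parent, pgrad in node._backward(node.grad):
                if not parent.requires_grad:
                    continue
                if parent.grad is None:
                    parent.grad = pgrad.astype(parent.data.dtype, copy=False)
                else:
                    parent.grad = parent.grad + pgrad
            if node is not self:
                node._backward = None  # free closures/saved activations early

    def zero_grad(self):
        self.grad = None

    # -- operators ------------------------------------------------------------
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
        if isinstance(other, Tensor):
            return mul(self, power(other, -1.0))
        return mul(self, 1.0 / other)

    def __rtruediv__(self, other):
        return mul(power(self, -1.0), other)

    def __neg__(self):
        return mul(self, -1.0)

    def __matmul__(self, other):
        return matmul(self, other)

    def __pow__(self, p):
        return power(self, p)

    def __getitem__(self, idx):
        return getitem(self, idx)

    # method aliases
    def reshape(self, *shape):
        return reshape(self, *shape)

    def transpose(self, *axes):
        return transpose(self, axes)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis, keepdims)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ---------------------------------------------------------------------------
# elementwise / arithmetic
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data + b.data

    def backward(g):
        return ((a, _unbroadcast(g, a.data.shape)), (b, _unbroadcast(g, b.data.shape)))

    return Tensor._op(out_data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data * b.data

    def backward(g):
        return (
            (a, _unbroadcast(g * b.data, a.data.shape)),
            (b, _unbroadcast(g * a.data, b.data.shape)),
        )

    return Tensor._op(out_data, (a, b), backward)


def power(a, p: float) -> Tensor:
    a = as_tensor(a)
    out_data = a.data ** p

    def backward(g):
        return ((a, g * p * a.data ** (p - 1.0)),)

    return Tensor._op(out_data, (a,), backward)


def texp(a) -> Tensor:
    a = as_tensor(a)
    out_data = np.exp(a.data)

    def backward(g):
        return ((a, g * out_data),)

    return Tensor._op(out_data, (a,), backward)


def tlog(a) -> Tensor:
    a = as_tensor(a)
    out_data = np.log(a.data)

    def backward(g):
        return ((a, g / a.data),)

    return Tensor._op(out_data, (a,), backward)


def relu(a) -> Tensor:
    a = as_tensor(a)
    out_data = np.maximum(a.data, 0.0)

    def backward(g):
        return ((a, g * (a.data > 0)),)

    return Tensor._op(out_data, (a,), backward)


def sigmoid(a) -> Tensor:
    a = as_tensor(a)
    out_data = 1.0 / (1.0 + np.exp(-a.data))

    def backward(g):
        return ((a, g * out_data * (1.0 - out_data)),)

    return Tensor._op(out_data, (a,), backward)


def gelu(a) -> Tensor:
    """Exact (erf-based) Gaussian error linear unit."""
    a = as_tensor(a)
    x = a.data
    cdf = 0.5 * (1.0 + erf(x * _INV_SQRT2))
    out_data = (x * cdf).astype(x.dtype, copy=False)

    def backward(g):
        pdf = np.exp(-0.5 * x * x) * _INV_SQRT2PI
        return ((a, g * (cdf + x * pdf)),)

    return Tensor._op(out_data, (a,), backward)


# ---------------------------------------------------------------------------
# reductions
# ---------------------------------------------------------------------------

def _norm_axis(axis, ndim):
    if axis is None:
        return tuple(range(ndim))
    if isinstance(axis, int):
        axis = (axis,)
    return tuple(a % ndim for a in axis)


def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    axes = _norm_axis(axis, a.ndim)
    out_data = a.data.sum(axis=axes, keepdims=keepdims)

    def backward(g):
        if not keepdims:
            g = np.expand_dims(g, axes)
        return ((a, np.broadcast_to(g, a.data.shape)),)

    return Tensor._op(out_data, (a,), backward)


def tmean(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    axes = _norm_axis(axis, a.ndim)
    n = int(np.prod([a.data.shape[i] for i in axes]))
    return mul(tsum(a, axes, keepdims), 1.0 / n)


def tmax(a, axis, keepdims=False) -> Tensor:
    """Max over an axis; ties share the gradient equally."""
    a = as_tensor(a)
    axes = _norm_axis(axis, a.ndim)
    out_data = a.data.max(axis=axes, keepdims=True)
    mask = (a.data == out_data).astype(a.data.dtype)
    mask /= mask.sum(axis=axes, keepdims=True)
    result = out_data if keepdims else out_data.squeeze(axes)

    def backward(g):
        if not keepdims:
            g = np.expand_dims(g, axes)
        return ((a, g * mask),)

    return Tensor._op(result, (a,), backward)


def softmax(a, axis=-1) -> Tensor:
    a = as_tensor(a)
    shifted = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    out_data = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * out_data).sum(axis=axis, keepdims=True)
        return ((a, out_data * (g - dot)),)

    return Tensor._op(out_data, (a,), backward)


# ---------------------------------------------------------------------------
# fused channel normalization (batch / group) with analytic backward
# ---------------------------------------------------------------------------

def batchnorm2d(x, weight, bias, eps: float = 1e-5):
    """Training-mode batch norm over (B,H,W) per channel; returns
    (output, batch_mean, batch_var) with the stats as plain arrays."""
    x, weight, bias = as_tensor(x), as_tensor(weight), as_tensor(bias)
    xd = x.data
    c = xd.shape[1]
    axes = (0, 2, 3)
    mu = xd.mean(axis=axes, keepdims=True)
    var = xd.var(axis=axes, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (xd - mu) * inv
    out_data = xhat * weight.data.reshape(1, c, 1, 1) + bias.data.reshape(1, c, 1, 1)
    m = xd.size // c

    def backward(g):
        grads = []
        gxh_sum = (g * xhat).sum(axis=axes, keepdims=True)
        g_sum = g.sum(axis=axes, keepdims=True)
        if x.requires_grad:
            gy = g * weight.data.reshape(1, c, 1, 1)
            gy_sum = g_sum * weight.data.reshape(1, c, 1, 1)
            gyxh_sum = gxh_sum * weight.data.reshape(1, c, 1, 1)
            gx = inv * (gy - gy_sum / m - xhat * (gyxh_sum / m))
            grads.append((x, gx))
        if weight.requires_grad:
            grads.append((weight, gxh_sum.reshape(c)))
        if bias.requires_grad:
            grads.append((bias, g_sum.reshape(c)))
        return tuple(grads)

    out = Tensor._op(out_data, (x, weight, bias), backward)
    return out, mu.reshape(c), var.reshape(c)


def groupnorm2d(x, weight, bias, groups: int, eps: float = 1e-5):
    """Group norm: stats per (sample, group), affine per channel."""
    x, weight, bias = as_tensor(x), as_tensor(weight), as_tensor(bias)
    xd = x.data
    b, c, h, w = xd.shape
    cg = c // groups
    xg = xd.reshape(b, groups, cg, h, w)
    axes = (2, 3, 4)
    mu = xg.mean(axis=axes, keepdims=True)
    var = xg.var(axis=axes, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = ((xg - mu) * inv).reshape(b, c, h, w)
    out_data = xhat * weight.data.reshape(1, c, 1, 1) + bias.data.reshape(1, c, 1, 1)
    m = cg * h * w

    def backward(g):
        grads = []
        if x.requires_grad:
            gy = (g * weight.data.reshape(1, c, 1, 1)).reshape(b, groups, cg, h, w)
            xhg = xhat.reshape(b, groups, cg, h, w)
            gy_sum = gy.sum(axis=axes, keepdims=True)
            gyxh_sum = (gy * xhg).sum(axis=axes, keepdims=True)
            gx = inv * (gy - gy_sum / m - xhg * (gyxh_sum / m))
            grads.append((x, gx.reshape(b, c, h, w)))
        if weight.requires_grad:
            grads.append((weight, (g * xhat).sum(axis=(0, 2, 3))))
        if bias.requires_grad:
            grads.append((bias, g.sum(axis=(0, 2, 3))))
        return tuple(grads)

    return Tensor._op(out_data, (x, weight, bias), backward)


def batchnorm2d_eval(x, weight, bias, running_mean, running_var, eps: float = 1e-5):
    """Inference-mode batch norm using running statistics."""
    x, weight, bias = as_tensor(x), as_tensor(weight), as_tensor(bias)
    c = x.data.shape[1]
    inv = (1.0 / np.sqrt(running_var + eps)).astype(x.data.dtype)
    scale = (weight.data * inv).reshape(1, c, 1, 1)
    shift = (bias.data - weight.data * inv * running_mean).reshape(1, c, 1, 1)
    out_data = x.data * scale + shift
    xd = x.data
    xhat = (xd - running_mean.reshape(1, c, 1, 1)) * inv.reshape(1, c, 1, 1)

    def backward(g):
        grads = []
        if x.requires_grad:
            grads.append((x, g * scale))
        if weight.requires_grad:
            grads.append((weight, (g * xhat).sum(axis=(0, 2, 3))))
        if bias.requires_grad:
            grads.append((bias, g.sum(axis=(0, 2, 3))))
        return tuple(grads)

    return Tensor._op(out_data, (x, weight, bias), backward)


# ---------------------------------------------------------------------------
# shape manipulation
# ---------------------------------------------------------------------------

def reshape(a, *shape) -> Tensor:
    a = as_tensor(a)
    if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
        shape = tuple(shape[0])
    out_data = a.data.reshape(shape)
    in_shape = a.data.shape

    def backward(g):
        return ((a, g.reshape(in_shape)),)

    return Tensor._op(out_data, (a,), backward)


def transpose(a, axes) -> Tensor:
    a = as_tensor(a)
    axes = tuple(axes)
    out_data = a.data.transpose(axes)
    inv = tuple(np.argsort(axes))

    def backward(g):
        return ((a, g.transpose(inv)),)

    return Tensor._op(out_data, (a,), backward)


def swap_last2(a) -> Tensor:
    axes = tuple(range(a.ndim - 2)) + (a.ndim - 1, a.ndim - 2)
    return transpose(a, axes)


def getitem(a, idx) -> Tensor:
    a = as_tensor(a)
    out_data = a.data[idx]
    in_shape = a.data.shape

    def backward(g):
        full = np.zeros(in_shape, dtype=g.dtype)
        full[idx] = g  # basic (slice) indexing only: destinations are unique
        return ((a, full),)

    return Tensor._op(out_data, (a,), backward)


def concat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        grads = []
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            grads.append((t, g[tuple(sl)]))
        return tuple(grads)

    return Tensor._op(out_data, tuple(tensors), backward)


# ---------------------------------------------------------------------------
# linear algebra
# ---------------------------------------------------------------------------

def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data @ b.data

    def backward(g):
        grads = []
        if a.requires_grad:
            ga = g @ np.swapaxes(b.data, -1, -2)
            if ga.shape != a.data.shape:
                ga = _unbroadcast(ga, a.data.shape)
            grads.append((a, ga))
        if b.requires_grad:
            gb = np.swapaxes(a.data, -1, -2) @ g
            if gb.shape != b.data.shape:
                gb = _unbroadcast(gb, b.data.shape)
            grads.append((b, gb))
        return tuple(grads)

    return Tensor._op(out_data, (a, b), backward)


# ---------------------------------------------------------------------------
# 2-D convolution (stride 1).  The inner loops live in numba kernels
# (shift-multiply-accumulate): far more cache-friendly on one CPU core than
# im2col + GEMM for the small kernels this network uses.
# ---------------------------------------------------------------------------

def _pad_hw(x: np.ndarray, p: int) -> np.ndarray:
    if not p:
        return np.ascontiguousarray(x)
    b, c, h, w = x.shape
    out = np.zeros((b, c, h + 2 * p, w + 2 * p), dtype=x.dtype)
    out[:, :, p:p + h, p:p + w] = x
    return out


def conv2d(x, w, b=None, padding: int = 0) -> Tensor:
    """Cross-correlation at stride 1 with symmetric zero padding."""
    from . import _conv_kernels as _ck

    x, w = as_tensor(x), as_tensor(w)
    cout, cin, kh, kw = w.data.shape
    if x.data.shape[1] != cin:
        raise ValueError(
            f"conv2d: input has {x.data.shape[1]} channels, weight expects {cin}"
        )
    bsz, _, h, ww = x.data.shape
    oh, ow = h + 2 * padding - kh + 1, ww + 2 * padding - kw + 1
    xp = _pad_hw(x.data, padding)
    wdat = np.ascontiguousarray(w.data, dtype=xp.dtype)
    out_data = np.empty((bsz, cout, oh, ow), dtype=xp.dtype)
    _ck.conv_fwd(xp, wdat, out_data)
    if b is not None:
        b = as_tensor(b)
        out_data += b.data.reshape(1, cout, 1, 1)
    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        g = np.ascontiguousarray(g)
        grads = []
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            _ck.conv_bwd_x(g, wdat, gxp)
            gx = gxp[:, :, padding:padding + h, padding:padding + ww] if padding else gxp
            grads.append((x, gx))
        if w.requires_grad:
            gw = np.empty_like(wdat)
            _ck.conv_bwd_w(g, xp, gw)
            grads.append((w, gw))
        if b is not None and b.requires_grad:
            grads.append((b, g.sum(axis=(0, 2, 3))))
        return tuple(grads)

    return Tensor._op(out_data, parents, backward)
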