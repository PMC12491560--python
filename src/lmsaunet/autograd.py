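"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Provides exactly the operations the segmentation network needs: broadcast
arithmetic, pointwise/grouped/depthwise/dense 2-D convolution (stride 1,
same padding), 1-D same-length convolution, 2x2 pooling, a fixed linear
up-sampling operator, channel concatenation/slicing, and the elementwise
nonlinearities.  Gradients propagate through a topologically sorted tape.

Arrays are batched NCHW throughout.  float32 is used for model state;
float64 inputs stay float64 so finite-difference checks are meaningful.
"""

from __future__ import annotations

import numpy as np

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling tape construction (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
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

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph bookkeeping -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    def backward(self, grad: np.ndarray | None = None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def _accum(self, grad):
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    # -- operators ---------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(other, -1.0) if isinstance(other, Tensor) else -np.asarray(other))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            return mul(self, power(other, -1.0))
        return mul(self, 1.0 / np.asarray(other))

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _coerce(other, like: np.ndarray) -> Tensor:
    """Wrap `other`, demoting stray float64 scalars so float32 graphs stay float32."""
    if isinstance(other, Tensor):
        return other
    arr = np.asarray(other)
    if arr.dtype == np.float64 and like.dtype == np.float32:
        arr = arr.astype(np.float32)
    return Tensor(arr)


def _make(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if _GRAD_ENABLED and any(p.requires_grad or p._parents for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    return out


# -- arithmetic -----------------------------------------------------------

def add(a, b):
    a = _wrap(a)
    b = _coerce(b, a.data)

    def backward(g):
        a._accum(_unbroadcast(g, a.data.shape))
        b._accum(_unbroadcast(g, b.data.shape))

    return _make(a.data + b.data, (a, b), backward)


def mul(a, b):
    a = _wrap(a)
    b = _coerce(b, a.data)

    def backward(g):
        a._accum(_unbroadcast(g * b.data, a.data.shape))
        b._accum(_unbroadcast(g * a.data, b.data.shape))

    return _make(a.data * b.data, (a, b), backward)


def power(a, exponent: float):
    a = _wrap(a)

    def backward(g):
        a._accum(g * exponent * np.power(a.data, exponent - 1.0))

    return _make(np.power(a.data, exponent), (a,), backward)


def log(a):
    a = _wrap(a)

    def backward(g):
        a._accum(g / a.data)

    return _make(np.log(a.data), (a,), backward)


def relu(a):
    a = _wrap(a)
    mask = a.data > 0

    def backward(g):
        a._accum(g * mask)

    return _make(a.data * mask, (a,), backward)


def sigmoid(a):
    a = _wrap(a)
    s = 1.0 / (1.0 + np.exp(-a.data))

    def backward(g):
        a._accum(g * s * (1.0 - s))

    return _make(s, (a,), backward)


def clip(a, lo: float, hi: float):
    a = _wrap(a)
    mask = (a.data > lo) & (a.data < hi)

    def backward(g):
        a._accum(g * mask)

    return _make(np.clip(a.data, lo, hi), (a,), backward)


def tsum(a, axis=None, keepdims=False):
    a = _wrap(a)

    def backward(g):
        gg = g
        if axis is not None and not keepdims:
            gg = np.expand_dims(gg, axis)
        a._accum(np.broadcast_to(gg, a.data.shape).astype(a.data.dtype))

    return _make(a.data.sum(axis=axis, keepdims=keepdims), (a,), backward)


def tmean(a, axis=None, keepdims=False):
    a = _wrap(a)
    if axis is None:
        denom = a.data.size
    else:
        ax = axis if isinstance(axis, tuple) else (axis,)
        denom = int(np.prod([a.data.shape[i] for i in ax]))

    def backward(g):
        gg = g
        if axis is not None and not keepdims:
            gg = np.expand_dims(gg, axis)
        a._accum(np.broadcast_to(gg, a.data.shape).astype(a.data.dtype) / denom)

    return _make(a.data.mean(axis=axis, keepdims=keepdims), (a,), backward)


def channel_max(a):
    """Max over the channel axis of an NCHW tensor, keepdims.

    Gradient flows to the first maximal channel at each position.
    """
    a = _wrap(a)
    idx = a.data.argmax(axis=1, keepdims=True)
    out = np.take_along_axis(a.data, idx, axis=1)

    def backward(g):
        ga = np.zeros_like(a.data)
        np.put_along_axis(ga, idx, g, axis=1)
        a._accum(ga)

    return _make(out, (a,), backward)


def batchnorm2d_train(x, gamma, beta, eps: float):
    """Fused training-mode batch normalization over axes (0,2,3).

    Returns (out, batch_mean, batch_var) — the statistics as plain arrays
    so the caller can maintain running estimates.
    """
    x, gamma, beta = _wrap(x), _wrap(gamma), _wrap(beta)
    c = x.data.shape[1]
    axes = (0, 2, 3)
    mu = x.data.mean(axis=axes, keepdims=True)
    var = x.data.var(axis=axes, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out = gamma.data.reshape(1, c, 1, 1) * xhat + beta.data.reshape(1, c, 1, 1)

    def backward(g):
        beta._accum(g.sum(axis=axes))
        gamma._accum((g * xhat).sum(axis=axes))
        dxhat = g * gamma.data.reshape(1, c, 1, 1)
        m1 = dxhat.mean(axis=axes, keepdims=True)
        m2 = (dxhat * xhat).mean(axis=axes, keepdims=True)
        x._accum((inv * (dxhat - m1 - xhat * m2)).astype(x.data.dtype, copy=False))

    return _make(out.astype(x.data.dtype, copy=False), (x, gamma, beta), backward), \
        mu.reshape(-1), var.reshape(-1)


# -- shape ops ------------------------------------------------------------

def concat_channels(tensors):
    tensors = [_wrap(t) for t in tensors]
    sizes = [t.data.shape[1] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            t._accum(g[:, lo:hi])

    return _make(np.concatenate([t.data for t in tensors], axis=1), tensors, backward)


def narrow_channels(a, start: int, length: int):
    a = _wrap(a)

    def backward(g):
        ga = np.zeros_like(a.data)
        ga[:, start:start + length] = g
        a._accum(ga)

    return _make(a.data[:, start:start + length], (a,), backward)


def reshape(a, shape):
    a = _wrap(a)
    orig = a.data.shape

    def backward(g):
        a._accum(g.reshape(orig))

    return _make(a.data.reshape(shape), (a,), backward)


# -- convolutions (stride 1, zero same-padding) ---------------------------

def pointwise_conv2d(x, w, groups: int = 1):
    """1x1 convolution. x: (B,Cin,H,W), w: (Cout, Cin//groups)."""
    x, w = _wrap(x), _wrap(w)
    cout, cing = w.data.shape
    b, cin, h, wd = x.data.shape
    if cin != cing * groups:
        raise ValueError(f"channel mismatch: input has {cin}, weight expects {cing * groups}")
    hw = h * wd
    if groups == 1:
        xf = np.ascontiguousarray(x.data).reshape(b, cin, hw)
        out = np.matmul(w.data, xf).reshape(b, cout, h, wd)
    else:
        og = cout // groups
        xf = np.ascontiguousarray(x.data).reshape(b, groups, cing, hw)
        wg = w.data.reshape(groups, og, cing)
        out = np.matmul(wg, xf).reshape(b, cout, h, wd)

    def backward(g):
        if groups == 1:
            gf = np.ascontiguousarray(g).reshape(b, cout, hw)
            x._accum(np.matmul(w.data.T, gf).reshape(b, cin, h, wd))
            w._accum(np.tensordot(g, x.data, axes=([0, 2, 3], [0, 2, 3])))
        else:
            og = cout // groups
            gf = np.ascontiguousarray(g).reshape(b, groups, og, hw)
            wg = w.data.reshape(groups, og, cing)
            gx = np.matmul(wg.transpose(0, 2, 1), gf)
            x._accum(gx.reshape(b, cin, h, wd))
            gw = np.matmul(gf, xf.transpose(0, 1, 3, 2)).sum(axis=0)
            w._accum(gw.reshape(cout, cing))

    return _make(out, (x, w), backward)


def depthwise_conv2d(x, w, padding: int | None = None):
    """Per-channel KxK correlation, stride 1. x: (B,C,H,W), w: (C,K,K).

    ``padding`` defaults to K//2 (same-size output); smaller values shrink
    the output to H + 2*padding - K + 1.
    """
    x, w = _wrap(x), _wrap(w)
    b, c, h, wd = x.data.shape
    k = w.data.shape[1]
    p = k // 2 if padding is None else int(padding)
    oh, ow = h + 2 * p - k + 1, wd + 2 * p - k + 1
    if oh < 1 or ow < 1:
        raise ValueError(
            f"kernel {k} larger than padded input {h + 2 * p}x{wd + 2 * p}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)))
    out = np.zeros((b, c, oh, ow), dtype=x.data.dtype)
    for i in range(k):
        for j in range(k):
            out += w.data[None, :, i, j, None, None] * xp[:, :, i:i + oh, j:j + ow]

    def backward(g):
        gxp = np.zeros_like(xp)
        gw = np.zeros_like(w.data)
        for i in range(k):
            for j in range(k):
                gxp[:, :, i:i + oh, j:j + ow] += w.data[None, :, i, j, None, None] * g
                gw[:, i, j] += (g * xp[:, :, i:i + oh, j:j + ow]).sum(axis=(0, 2, 3))
        x._accum(gxp[:, :, p:p + h, p:p + wd] if p else gxp)
        w._accum(gw)

    return _make(out, (x, w), backward)


def dense_conv2d(x, w):
    """Full KxK convolution, same padding. x: (B,Cin,H,W), w: (Cout,Cin,K,K)."""
    x, w = _wrap(x), _wrap(w)
    b, c, h, wd = x.data.shape
    k = w.data.shape[2]
    p = k // 2
    co = w.data.shape[0]
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)))
    out = np.zeros((b, co, h, wd), dtype=x.data.dtype)
    for i in range(k):
        for j in range(k):
            win = xp[:, :, i:i + h, j:j + wd]
            for o in range(co):
                for ci in range(c):
                    out[:, o] += w.data[o, ci, i, j] * win[:, ci]

    def backward(g):
        gxp = np.zeros_like(xp)
        gw = np.zeros_like(w.data)
        for i in range(k):
            for j in range(k):
                win = xp[:, :, i:i + h, j:j + wd]
                gwin = gxp[:, :, i:i + h, j:j + wd]
                for o in range(co):
                    for ci in range(c):
                        gwin[:, ci] += w.data[o, ci, i, j] * g[:, o]
                        gw[o, ci, i, j] += float((g[:, o] * win[:, ci]).sum())
        x._accum(gxp[:, :, p:p + h, p:p + wd] if p else gxp)
        w._accum(gw)

    return _make(out, (x, w), backward)


def conv1d_same(s, w):
    """Zero-padded same-length 1-D correlation. s: (B,C), w: (k,)."""
    s, w = _wrap(s), _wrap(w)
    b, c = s.data.shape
    k = w.data.shape[0]
    p = k // 2
    sp = np.pad(s.data, ((0, 0), (p, p)))
    out = np.zeros((b, c), dtype=s.data.dtype)
    for i in range(k):
        out += w.data[i] * sp[:, i:i + c]

    def backward(g):
        gsp = np.zeros_like(sp)
        gw = np.zeros_like(w.data)
        for i in range(k):
            gsp[:, i:i + c] += w.data[i] * g
            gw[i] = (g * sp[:, i:i + c]).sum()
        s._accum(gsp[:, p:p + c] if p else gsp)
        w._accum(gw)

    return _make(out, (s, w), backward)


# -- pooling and resampling ----------------------------------------------

def pool2x2(x, mode: str = "max"):
    x = _wrap(x)
    b, c, h, wd = x.data.shape
    if h % 2 or wd % 2:
        raise ValueError(f"2x2 pooling requires even spatial size, got {h}x{wd}")
    win = x.data.reshape(b, c, h // 2, 2, wd // 2, 2)
    if mode == "max":
        flat = win.transpose(0, 1, 2, 4, 3, 5).reshape(b, c, h // 2, wd // 2, 4)
        idx = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

        def backward(g):
            gflat = np.zeros_like(flat)
            np.put_along_axis(gflat, idx[..., None], g[..., None], axis=-1)
            gx = gflat.reshape(b, c, h // 2, wd // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
            x._accum(gx.reshape(b, c, h, wd))
    elif mode == "average":
        out = win.mean(axis=(3, 5))

        def backward(g):
            gx = np.repeat(np.repeat(g, 2, axis=2), 2, axis=3) / 4.0
            x._accum(gx)
    else:
        raise ValueError(f"unknown pooling mode {mode!r}")
    return _make(out, (x,), backward)


def linear_resample(x, row_op: np.ndarray, col_op: np.ndarray):
    """Apply a fixed separable linear operator: out[b,c] = R @ x[b,c] @ C^T."""
    x = _wrap(x)
    out = np.matmul(np.matmul(row_op, x.data), col_op.T)

    def backward(g):
        x._accum(np.matmul(np.matmul(row_op.T, g), col_op).astype(x.data.dtype, copy=False))

    return _make(out.astype(x.data.dtype, copy=False), (x,), backward)
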