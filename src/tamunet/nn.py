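"""Minimal reverse-mode autodiff engine and neural-network layers on numpy.

Everything the segmentation networks need — batched 2D convolution (strided,
dilated, grouped), transposed convolution, pooling, normalization layers,
linear layers, bilinear resizing and the usual pointwise nonlinearities — is
implemented here on float32 numpy arrays.  Convolutions are lowered to matrix
multiplication (im2col) so the heavy lifting runs in BLAS.  Gradients for the
composite operations (normalizations, softmax, attention) are obtained by
composing primitive ops; conv / pool / resize have hand-written adjoints that
are checked against central finite differences in the test-suite.
"""

from __future__ import annotations

import math
from contextlib import contextmanager

import numpy as np

_DTYPE = np.float32

# ---------------------------------------------------------------------------
# global state: construction-time RNG and gradient switch
# ---------------------------------------------------------------------------

_rng = np.random.default_rng(0)
_grad_enabled = True


def manual_seed(seed: int) -> None:
    """Seed the generator used for parameter initialization."""
    global _rng
    _rng = np.random.default_rng(seed)


def get_rng() -> np.random.Generator:
    return _rng


@contextmanager
def no_grad():
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


# ---------------------------------------------------------------------------
# Tensor
# ---------------------------------------------------------------------------


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad=False, _prev=()):
        if not isinstance(data, np.ndarray):
            data = np.asarray(data, dtype=_DTYPE)
        if data.dtype != _DTYPE:
            data = data.astype(_DTYPE)
        self.data = data
        self.grad = None
        self.requires_grad = requires_grad and _grad_enabled
        self._backward = None
        self._prev = _prev

    # -- basic introspection ------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- autograd -----------------------------------------------------------
    def _accum(self, g):
        if self.grad is None:
            self.grad = g.astype(_DTYPE, copy=False)
        else:
            self.grad = self.grad + g

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.asarray(grad, dtype=_DTYPE)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)
            if t is not self:
                # graph nodes are transient; parameters keep their grads
                t._prev = ()
                t._backward = None

    # -- operators ----------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, -_as_tensor(other))

    def __rsub__(self, other):
        return add(_as_tensor(other), -self)

    def __truediv__(self, other):
        if isinstance(other, (int, float)):
            return mul(self, 1.0 / other)
        return mul(self, pow_(other, -1.0))

    def __rtruediv__(self, other):
        return mul(_as_tensor(other), pow_(self, -1.0))

    def __pow__(self, p):
        return pow_(self, p)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return getitem(self, idx)

    def sum(self, axis=None, keepdims=False):
        return sum_(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return mean(self, axis, keepdims)

    def reshape(self, *shape):
        return reshape(self, shape)

    def transpose(self, *axes):
        return transpose(self, axes)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce gradient ``g`` back to ``shape`` after numpy broadcasting."""
    if g.shape == shape:
        return g
    nd = g.ndim - len(shape)
    if nd > 0:
        g = g.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g.reshape(shape)


def _make(data, parents, backward):
    req = _grad_enabled and any(p.requires_grad for p in parents)
    out = Tensor(data, requires_grad=req, _prev=tuple(parents) if req else ())
    if req:
        out._backward = backward
    return out


# ---------------------------------------------------------------------------
# primitive ops
# ---------------------------------------------------------------------------


def add(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data + b.data

    def bw(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g, b.data.shape))

    return _make(out_data, (a, b), bw)


def mul(a, b):
    a = _as_tensor(a)
    if isinstance(b, (int, float)):
        s = float(b)

        def bw_s(g):
            if a.requires_grad:
                a._accum(g * s)

        return _make(a.data * s, (a,), bw_s)
    b = _as_tensor(b)

    def bw(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * a.data, b.data.shape))

    return _make(a.data * b.data, (a, b), bw)


def pow_(a, p):
    a = _as_tensor(a)
    out_data = a.data**p

    def bw(g):
        if a.requires_grad:
            a._accum(g * p * a.data ** (p - 1))

    return _make(out_data, (a,), bw)


def matmul(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data @ b.data

    def bw(g):
        if a.requires_grad:
            ga = g @ np.swapaxes(b.data, -1, -2)
            a._accum(_unbroadcast(ga, a.data.shape))
        if b.requires_grad:
            gb = np.swapaxes(a.data, -1, -2) @ g
            b._accum(_unbroadcast(gb, b.data.shape))

    return _make(out_data, (a, b), bw)


def exp(a):
    a = _as_tensor(a)
    out_data = np.exp(a.data)

    def bw(g):
        if a.requires_grad:
            a._accum(g * out_data)

    return _make(out_data, (a,), bw)


def log(a):
    a = _as_tensor(a)

    def bw(g):
        if a.requires_grad:
            a._accum(g / a.data)

    return _make(np.log(a.data), (a,), bw)


def sqrt(a):
    a = _as_tensor(a)
    out_data = np.sqrt(a.data)

    def bw(g):
        if a.requires_grad:
            a._accum(g * 0.5 / out_data)

    return _make(out_data, (a,), bw)


def sigmoid(a):
    a = _as_tensor(a)
    with np.errstate(over="ignore"):  # exp overflow saturates cleanly to 0/1
        out_data = 1.0 / (1.0 + np.exp(-a.data))

    def bw(g):
        if a.requires_grad:
            a._accum(g * out_data * (1.0 - out_data))

    return _make(out_data, (a,), bw)


def tanh(a):
    a = _as_tensor(a)
    out_data = np.tanh(a.data)

    def bw(g):
        if a.requires_grad:
            a._accum(g * (1.0 - out_data**2))

    return _make(out_data, (a,), bw)


def relu(a):
    a = _as_tensor(a)
    mask = a.data > 0

    def bw(g):
        if a.requires_grad:
            a._accum(g * mask)

    return _make(a.data * mask, (a,), bw)


def gelu(a):
    """GELU, tanh approximation."""
    a = _as_tensor(a)
    c = math.sqrt(2.0 / math.pi)
    x = a.data
    inner = c * (x + 0.044715 * x**3)
    t = np.tanh(inner)
    out_data = 0.5 * x * (1.0 + t)

    def bw(g):
        if a.requires_grad:
            dinner = c * (1.0 + 3 * 0.044715 * x**2)
            da = 0.5 * (1.0 + t) + 0.5 * x * (1.0 - t**2) * dinner
            a._accum(g * da)

    return _make(out_data, (a,), bw)


def clamp(a, lo, hi):
    a = _as_tensor(a)
    out_data = np.clip(a.data, lo, hi)
    mask = (a.data > lo) & (a.data < hi)

    def bw(g):
        if a.requires_grad:
            a._accum(g * mask)

    return _make(out_data, (a,), bw)


def sum_(a, axis=None, keepdims=False):
    a = _as_tensor(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def bw(g):
        if not a.requires_grad:
            return
        if axis is None:
            a._accum(np.broadcast_to(g, a.data.shape))
            return
        if not keepdims:
            axes = axis if isinstance(axis, tuple) else (axis,)
            axes = tuple(ax % a.data.ndim for ax in axes)
            shp = [1 if i in axes else s for i, s in enumerate(a.data.shape)]
            g = g.reshape(shp)
        a._accum(np.broadcast_to(g, a.data.shape))

    return _make(out_data, (a,), bw)


def mean(a, axis=None, keepdims=False):
    a = _as_tensor(a)
    if axis is None:
        n = a.data.size
    else:
        axes = axis if isinstance(axis, tuple) else (axis,)
        n = int(np.prod([a.data.shape[ax] for ax in axes]))
    return sum_(a, axis, keepdims) * (1.0 / n)


def reshape(a, shape):
    a = _as_tensor(a)
    if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
        shape = tuple(shape[0])

    def bw(g):
        if a.requires_grad:
            a._accum(g.reshape(a.data.shape))

    return _make(a.data.reshape(shape), (a,), bw)


def transpose(a, axes):
    a = _as_tensor(a)
    if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
        axes = tuple(axes[0])
    inv = np.argsort(axes)

    def bw(g):
        if a.requires_grad:
            a._accum(g.transpose(inv))

    return _make(a.data.transpose(axes), (a,), bw)


def concat(tensors, axis=0):
    tensors = [_as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accum(g[tuple(idx)])

    return _make(out_data, tensors, bw)


def _is_basic_index(idx):
    items = idx if isinstance(idx, tuple) else (idx,)
    return all(isinstance(i, (int, slice, type(Ellipsis), type(None))) for i in items)


def getitem(a, idx):
    a = _as_tensor(a)
    basic = _is_basic_index(idx)

    def bw(g):
        if a.requires_grad:
            full = np.zeros_like(a.data)
            if basic:  # view assignment; no repeated positions possible
                full[idx] += g
            else:
                np.add.at(full, idx, g)
            a._accum(full)

    return _make(a.data[idx], (a,), bw)


def softmax(a, axis=-1):
    a = _as_tensor(a)
    z = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)

    def bw(g):
        if a.requires_grad:
            a._accum(y * (g - (g * y).sum(axis=axis, keepdims=True)))

    return _make(y, (a,), bw)


def batch_norm(x, gamma, beta, eps=1e-5):
    """Fused training-mode batch normalization over axes (0, 2, 3) of an
    (N, C, H, W) tensor, with a hand-written backward.  Returns
    (out, batch_mean, batch_var) where the statistics are plain arrays
    (biased variance, as used for normalization)."""
    x, gamma, beta = _as_tensor(x), _as_tensor(gamma), _as_tensor(beta)
    N, C, H, W = x.data.shape
    axes = (0, 2, 3)
    m = N * H * W
    mu = x.data.mean(axis=axes, keepdims=True)
    xc = x.data - mu
    var = np.mean(xc * xc, axis=axes, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    gr = gamma.data.reshape(1, C, 1, 1)
    out_data = xhat * gr + beta.data.reshape(1, C, 1, 1)

    def bw(g):
        if beta.requires_grad:
            beta._accum(g.sum(axis=axes))
        if gamma.requires_grad:
            gamma._accum((g * xhat).sum(axis=axes))
        if x.requires_grad:
            dxhat = g * gr
            t1 = dxhat.mean(axis=axes, keepdims=True)
            t2 = (dxhat * xhat).mean(axis=axes, keepdims=True)
            x._accum(inv * (dxhat - t1 - xhat * t2))

    out = _make(out_data, (x, gamma, beta), bw)
    return out, mu.reshape(C), var.reshape(C)


def instance_norm(a, axes, eps=1e-5):
    """Normalize to zero mean / unit variance over ``axes`` (no affine)."""
    a = _as_tensor(a)
    mu = a.data.mean(axis=axes, keepdims=True)
    xc = a.data - mu
    inv = 1.0 / np.sqrt((xc * xc).mean(axis=axes, keepdims=True) + eps)
    xhat = xc * inv

    def bw(g):
        if a.requires_grad:
            gm = g.mean(axis=axes, keepdims=True)
            gx = (g * xhat).mean(axis=axes, keepdims=True)
            a._accum(inv * (g - gm - xhat * gx))

    return _make(xhat, (a,), bw)


# ---------------------------------------------------------------------------
# spatial ops (hand-written adjoints)
# ---------------------------------------------------------------------------


def _im2col(x: np.ndarray, kh, kw, sh, sw, ph, pw, dh, dw):
    """(N,C,H,W) -> (N, C, kh, kw, OH, OW) patch tensor."""
    N, C, H, W = x.shape
    if ph or pw:
        xp = np.zeros((N, C, H + 2 * ph, W + 2 * pw), dtype=x.dtype)
        xp[:, :, ph : ph + H, pw : pw + W] = x
        x = xp
    Hp, Wp = x.shape[2], x.shape[3]
    OH = (Hp - dh * (kh - 1) - 1) // sh + 1
    OW = (Wp - dw * (kw - 1) - 1) // sw + 1
    view = np.lib.stride_tricks.sliding_window_view(
        x, (dh * (kh - 1) + 1, dw * (kw - 1) + 1), axis=(2, 3)
    )[:, :, ::sh, ::sw, ::dh, ::dw]  # (N, C, OH, OW, kh, kw)
    cols = np.ascontiguousarray(view.transpose(0, 1, 4, 5, 2, 3))
    return cols, OH, OW


def _col2im(gcols: np.ndarray, xshape, sh, sw, ph, pw, dh, dw):
    """Adjoint of _im2col: scatter-add patches back to the input layout."""
    N, C, H, W = xshape
    kh, kw, OH, OW = gcols.shape[2], gcols.shape[3], gcols.shape[4], gcols.shape[5]
    gx = np.zeros((N, C, H + 2 * ph, W + 2 * pw), dtype=gcols.dtype)
    for i in range(kh):
        hi = i * dh
        for j in range(kw):
            wj = j * dw
            gx[:, :, hi : hi + sh * OH : sh, wj : wj + sw * OW : sw] += gcols[:, :, i, j]
    if ph or pw:
        gx = gx[:, :, ph : ph + H, pw : pw + W]
    return gx


def conv2d(x, w, b=None, stride=1, padding=0, dilation=1, groups=1):
    """Batched 2D convolution (cross-correlation, as is conventional).

    x: (N, Cin, H, W); w: (Cout, Cin/groups, kh, kw); b: (Cout,) or None.
    ``padding`` may be an int pair or "same" (odd kernels, stride 1).
    """
    x, w = _as_tensor(x), _as_tensor(w)
    N, Cin, H, W = x.data.shape
    Cout, Cg, kh, kw = w.data.shape
    sh = sw = stride
    dh = dw = dilation
    if padding == "same":
        ph, pw = dh * (kh - 1) // 2, dw * (kw - 1) // 2
    elif isinstance(padding, int):
        ph = pw = padding
    else:
        ph, pw = padding
    if Cin != Cg * groups:
        raise ValueError("channel/group mismatch")

    if kh == kw == 1 and stride == 1 and groups == 1 and not (ph or pw):
        # pointwise fast path: channel-mixing matmul, no patch extraction
        x2 = x.data.reshape(N, Cin, H * W)
        w2 = w.data.reshape(Cout, Cin)
        out_data = np.matmul(w2[None], x2).reshape(N, Cout, H, W)
        if b is not None:
            out_data = out_data + b.data.reshape(1, Cout, 1, 1)
        parents = (x, w) if b is None else (x, w, b)

        def bw_1x1(g):
            g2 = g.reshape(N, Cout, H * W)
            if b is not None and b.requires_grad:
                b._accum(g.sum(axis=(0, 2, 3)))
            if w.requires_grad:
                gw = np.matmul(g2, np.swapaxes(x2, -1, -2)).sum(axis=0)
                w._accum(gw.reshape(w.data.shape))
            if x.requires_grad:
                gx = np.matmul(w2.T[None], g2)
                x._accum(gx.reshape(x.data.shape))

        return _make(out_data, parents, bw_1x1)

    cols, OH, OW = _im2col(x.data, kh, kw, sh, sw, ph, pw, dh, dw)
    L = OH * OW
    Og = Cout // groups
    parents = (x, w) if b is None else (x, w, b)

    if groups == Cin and Og == 1:
        # depthwise fast path: one kernel per channel, einsum instead of
        # a batch of degenerate 1-row GEMMs
        wd = w.data.reshape(Cin, kh * kw)
        c2 = cols.reshape(N, Cin, kh * kw, L)
        out_data = np.matmul(wd[None, :, None, :], c2).reshape(N, Cin, OH, OW)
        if b is not None:
            out_data = out_data + b.data.reshape(1, Cout, 1, 1)

        def bw_dw(g):
            gl = g.reshape(N, Cin, 1, L)
            if b is not None and b.requires_grad:
                b._accum(g.sum(axis=(0, 2, 3)))
            if w.requires_grad:
                gw = np.matmul(gl, np.swapaxes(c2, -1, -2)).sum(axis=0)
                w._accum(gw.reshape(w.data.shape))
            if x.requires_grad:
                gcols = wd[None, :, :, None] * gl
                gcols = gcols.reshape(N, Cin, kh, kw, OH, OW)
                x._accum(_col2im(gcols, x.data.shape, sh, sw, ph, pw, dh, dw))

        return _make(out_data, parents, bw_dw)

    # (N, G, Cg*kh*kw, L) x (G, Og, Cg*kh*kw) -> (N, G, Og, L)
    cols_g = cols.reshape(N, groups, Cg * kh * kw, L)
    w_g = w.data.reshape(groups, Og, Cg * kh * kw)
    out = np.matmul(w_g[None], cols_g)
    out_data = out.reshape(N, Cout, OH, OW)
    if b is not None:
        out_data = out_data + b.data.reshape(1, Cout, 1, 1)

    def bw(g):
        gl = g.reshape(N, groups, Og, L)
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            gw = np.matmul(gl, np.swapaxes(cols_g, -1, -2)).sum(axis=0)
            w._accum(gw.reshape(w.data.shape))
        if x.requires_grad:
            gc = np.matmul(np.swapaxes(w_g, -1, -2)[None], gl)
            gcols = gc.reshape(N, Cin, kh, kw, OH, OW)
            x._accum(_col2im(gcols, x.data.shape, sh, sw, ph, pw, dh, dw))

    return _make(out_data, parents, bw)


def conv_transpose2d_2x(x, w, b=None):
    """Transposed convolution, kernel 2, stride 2 (the U-Net up-sampler).

    x: (N, Cin, H, W); w: (Cin, Cout, 2, 2) -> (N, Cout, 2H, 2W).
    """
    x, w = _as_tensor(x), _as_tensor(w)
    N, Cin, H, W = x.data.shape
    _, Cout, _, _ = w.data.shape
    # out[n,o,2i+u,2j+v] = sum_c x[n,c,i,j] * w[c,o,u,v]
    out = np.einsum("ncij,couv->noiujv", x.data, w.data, optimize=True)
    out_data = out.reshape(N, Cout, 2 * H, 2 * W)
    if b is not None:
        out_data = out_data + b.data.reshape(1, Cout, 1, 1)
    parents = (x, w) if b is None else (x, w, b)

    def bw(g):
        g6 = g.reshape(N, Cout, H, 2, W, 2)
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            w._accum(np.einsum("ncij,noiujv->couv", x.data, g6, optimize=True))
        if x.requires_grad:
            x._accum(np.einsum("noiujv,couv->ncij", g6, w.data, optimize=True))

    return _make(out_data, parents, bw)


def max_pool2d(x, k=2):
    x = _as_tensor(x)
    N, C, H, W = x.data.shape
    if H % k or W % k:
        raise ValueError(f"spatial dims {(H, W)} not divisible by pool size {k}")
    xr = x.data.reshape(N, C, H // k, k, W // k, k).transpose(0, 1, 2, 4, 3, 5)
    xr = xr.reshape(N, C, H // k, W // k, k * k)
    amax = xr.argmax(axis=-1)
    out_data = np.take_along_axis(xr, amax[..., None], axis=-1)[..., 0]

    def bw(g):
        if not x.requires_grad:
            return
        gr = np.zeros((N, C, H // k, W // k, k * k), dtype=g.dtype)
        np.put_along_axis(gr, amax[..., None], g[..., None], axis=-1)
        gr = gr.reshape(N, C, H // k, W // k, k, k).transpose(0, 1, 2, 4, 3, 5)
        x._accum(gr.reshape(N, C, H, W))

    return _make(out_data, (x,), bw)


def avg_pool2d(x, k):
    """Non-overlapping average pooling (used for parameter-free patch embedding)."""
    x = _as_tensor(x)
    N, C, H, W = x.data.shape
    if H % k or W % k:
        raise ValueError(f"spatial dims {(H, W)} not divisible by patch size {k}")
    xr = reshape(x, (N, C, H // k, k, W // k, k))
    return mean(xr, axis=(3, 5))


def _interp_matrix(n_in: int, n_out: int) -> np.ndarray:
    """1-D bilinear interpolation matrix (align_corners=False convention)."""
    A = np.zeros((n_out, n_in), dtype=_DTYPE)
    for o in range(n_out):
        src = (o + 0.5) * n_in / n_out - 0.5
        src = min(max(src, 0.0), n_in - 1.0)
        lo = int(math.floor(src))
        hi = min(lo + 1, n_in - 1)
        t = src - lo
        A[o, lo] += 1.0 - t
        A[o, hi] += t
    return A


def interpolate_bilinear(x, out_h, out_w):
    """Bilinear resize of (N,C,H,W) to (N,C,out_h,out_w); linear, so the
    adjoint is the transposed interpolation."""
    x = _as_tensor(x)
    N, C, H, W = x.data.shape
    Ah = _interp_matrix(H, out_h)
    Aw = _interp_matrix(W, out_w)
    out_data = np.matmul(np.matmul(Ah, x.data), Aw.T)

    def bw(g):
        if x.requires_grad:
            x._accum(np.matmul(np.matmul(Ah.T, g), Aw))

    return _make(out_data, (x,), bw)


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    def __init__(self):
        self.training = True

    def modules(self):
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield v
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for it in v:
                    if isinstance(it, Module):
                        yield it
                        yield from it.modules()

    def named_parameters(self, prefix=""):
        for k, v in self.__dict__.items():
            name = f"{prefix}{k}"
            if isinstance(v, Parameter):
                yield name, v
            elif isinstance(v, Module):
                yield from v.named_parameters(f"{name}.")
            elif isinstance(v, (list, tuple)):
                for i, it in enumerate(v):
                    if isinstance(it, Parameter):
                        yield f"{name}.{i}", it
                    elif isinstance(it, Module):
                        yield from it.named_parameters(f"{name}.{i}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def buffers(self):
        """Non-trainable state (running statistics)."""
        out = {}
        for name, m in self.named_modules():
            if isinstance(m, BatchNorm2d):
                out[f"{name}.running_mean"] = m.running_mean
                out[f"{name}.running_var"] = m.running_var
        return out

    def named_modules(self, prefix=""):
        yield prefix.rstrip("."), self
        for k, v in self.__dict__.items():
            name = f"{prefix}{k}"
            if isinstance(v, Module):
                yield from v.named_modules(f"{name}.")
            elif isinstance(v, (list, tuple)):
                for i, it in enumerate(v):
                    if isinstance(it, Module):
                        yield from it.named_modules(f"{name}.{i}.")

    def train(self):
        for m in [self, *self.modules()]:
            m.training = True
        return self

    def eval(self):
        for m in [self, *self.modules()]:
            m.training = False
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self):
        d = {k: v.data.copy() for k, v in self.named_parameters()}
        d.update({k: v.copy() for k, v in self.buffers().items()})
        return d

    def load_state_dict(self, d):
        params = dict(self.named_parameters())
        for k, v in d.items():
            if k in params:
                params[k].data = np.asarray(v, dtype=_DTYPE)
        for name, m in self.named_modules():
            if isinstance(m, BatchNorm2d):
                if f"{name}.running_mean" in d:
                    m.running_mean = np.asarray(d[f"{name}.running_mean"], dtype=_DTYPE)
                if f"{name}.running_var" in d:
                    m.running_var = np.asarray(d[f"{name}.running_var"], dtype=_DTYPE)


class ModuleList(Module):
    def __init__(self, mods=()):
        super().__init__()
        self.items = list(mods)

    def __iter__(self):
        return iter(self.items)

    def __len__(self):
        return len(self.items)

    def __getitem__(self, i):
        return self.items[i]

    def append(self, m):
        self.items.append(m)


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self.items = list(mods)

    def __call__(self, x):
        for m in self.items:
            x = m(x)
        return x


def _kaiming(shape, fan_in, rng):
    std = math.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(_DTYPE)


class Conv2d(Module):
    def __init__(self, in_ch, out_ch, kernel_size, stride=1, padding="same",
                 dilation=1, groups=1, bias=True):
        super().__init__()
        if isinstance(kernel_size, int):
            kernel_size = (kernel_size, kernel_size)
        kh, kw = kernel_size
        self.stride, self.padding, self.dilation, self.groups = stride, padding, dilation, groups
        fan_in = (in_ch // groups) * kh * kw
        self.weight = Parameter(_kaiming((out_ch, in_ch // groups, kh, kw), fan_in, _rng))
        self.bias = Parameter(np.zeros(out_ch, dtype=_DTYPE)) if bias else None

    def __call__(self, x):
        return conv2d(x, self.weight, self.bias, self.stride, self.padding,
                      self.dilation, self.groups)


class ConvTranspose2d2x(Module):
    """Kernel-2 stride-2 transposed convolution."""

    def __init__(self, in_ch, out_ch, bias=True):
        super().__init__()
        self.weight = Parameter(_kaiming((in_ch, out_ch, 2, 2), in_ch * 4, _rng))
        self.bias = Parameter(np.zeros(out_ch, dtype=_DTYPE)) if bias else None

    def __call__(self, x):
        return conv_transpose2d_2x(x, self.weight, self.bias)


class Linear(Module):
    def __init__(self, in_f, out_f, bias=True):
        super().__init__()
        bound = 1.0 / math.sqrt(in_f)
        self.weight = Parameter(_rng.uniform(-bound, bound, size=(out_f, in_f)).astype(_DTYPE))
        self.bias = Parameter(np.zeros(out_f, dtype=_DTYPE)) if bias else None

    def __call__(self, x):
        out = matmul(x, transpose(self.weight, (1, 0)))
        if self.bias is not None:
            out = out + self.bias
        return out


class BatchNorm2d(Module):
    def __init__(self, num_features, eps=1e-5, momentum=0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.weight = Parameter(np.ones(num_features, dtype=_DTYPE))
        self.bias = Parameter(np.zeros(num_features, dtype=_DTYPE))
        self.running_mean = np.zeros(num_features, dtype=_DTYPE)
        self.running_var = np.ones(num_features, dtype=_DTYPE)

    def __call__(self, x):
        C = x.data.shape[1]
        if self.training:
            out, mu, var = batch_norm(x, self.weight, self.bias, self.eps)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
            return out
        m = self.running_mean.reshape(1, C, 1, 1)
        v = self.running_var.reshape(1, C, 1, 1)
        xhat = (x - Tensor(m)) * Tensor(1.0 / np.sqrt(v + self.eps))
        w = reshape(self.weight, (1, C, 1, 1))
        b = reshape(self.bias, (1, C, 1, 1))
        return xhat * w + b


class LayerNorm(Module):
    """Normalization over the last axis with affine parameters."""

    def __init__(self, dim, eps=1e-6):
        super().__init__()
        self.eps = eps
        self.weight = Parameter(np.ones(dim, dtype=_DTYPE))
        self.bias = Parameter(np.zeros(dim, dtype=_DTYPE))

    def __call__(self, x):
        m = mean(x, axis=-1, keepdims=True)
        d = x - m
        v = mean(d * d, axis=-1, keepdims=True)
        return d / sqrt(v + self.eps) * self.weight + self.bias


class ReLU(Module):
    def __call__(self, x):
        return relu(x)


class Sigmoid(Module):
    def __call__(self, x):
        return sigmoid(x)


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------


class Adam:
    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        scale = self.lr / b1t
        sq = math.sqrt(b2t)
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            np.multiply(m, self.b1, out=m)
            m += (1 - self.b1) * g
            np.multiply(v, self.b2, out=v)
            np.multiply(g, g, out=g)  # grads are consumed by the update
            v += (1 - self.b2) * g
            np.sqrt(v, out=g)
            g /= sq
            g += self.eps
            np.divide(m, g, out=g)
            g *= scale
            p.data -= g
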