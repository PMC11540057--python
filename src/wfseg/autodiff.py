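"""Minimal reverse-mode automatic differentiation on numpy arrays.

Provides exactly the operations the segmentation network needs: 3D
convolution (stride 1/2, cubic kernels), group/layer normalization, ReLU,
sigmoid, softmax, matmul, trilinear 2x upsampling, concatenation, the
elementwise arithmetic used by the BCE+Dice objective, and a linear
wavelet-fusion op whose backward pass is the transform adjoint.  Gradients
are accumulated by topological-order backpropagation from a scalar loss.

Every non-obvious backward pass (convolution, normalization, upsampling,
wavelet fusion) is covered by finite-difference or adjoint dot-product
tests in the suite.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DTYPE = np.float32


class Tensor:
    """Array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "name")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None, name=""):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents: tuple[Tensor, ...] = tuple(parents)
        self._backward: Callable[[np.ndarray], None] | None = backward
        self.name = name

    @property
    def shape(self):
        return self.data.shape

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.asarray(grad, dtype=DTYPE).copy()
        else:
            self.grad += grad

    def backward(self) -> None:
        """Backpropagate from this scalar."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # sugar
    def __add__(self, other):
        return add(self, _wrap(other))

    def __radd__(self, other):
        return add(_wrap(other), self)

    def __sub__(self, other):
        return sub(self, _wrap(other))

    def __rsub__(self, other):
        return sub(_wrap(other), self)

    def __mul__(self, other):
        return mul(self, _wrap(other))

    def __rmul__(self, other):
        return mul(_wrap(other), self)

    def __neg__(self):
        return mul(self, _wrap(-1.0))


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


# ---------------------------------------------------------------------------
# elementwise / reduction ops


def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def bwd(g):
        a._accumulate(_unbroadcast(g, a.data.shape))
        b._accumulate(_unbroadcast(g, b.data.shape))

    return Tensor(out_data, parents=(a, b), backward=bwd)


def sub(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data - b.data

    def bwd(g):
        a._accumulate(_unbroadcast(g, a.data.shape))
        b._accumulate(_unbroadcast(-g, b.data.shape))

    return Tensor(out_data, parents=(a, b), backward=bwd)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data * b.data

    def bwd(g):
        a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return Tensor(out_data, parents=(a, b), backward=bwd)


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0

    def bwd(g):
        a._accumulate(g * mask)

    return Tensor(a.data * mask, parents=(a,), backward=bwd)


def sigmoid(a: Tensor) -> Tensor:
    x = a.data
    s = np.empty_like(x)
    pos = x >= 0
    s[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    s[~pos] = ex / (1.0 + ex)

    def bwd(g):
        a._accumulate(g * s * (1.0 - s))

    return Tensor(s, parents=(a,), backward=bwd)


def softplus(a: Tensor) -> Tensor:
    """log(1 + e^x), evaluated stably; gradient is sigmoid(x)."""
    x = a.data
    out_data = np.maximum(x, 0) + np.log1p(np.exp(-np.abs(x)))
    sig = np.empty_like(x)
    pos = x >= 0
    sig[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    sig[~pos] = ex / (1.0 + ex)

    def bwd(g):
        a._accumulate(g * sig)

    return Tensor(out_data, parents=(a,), backward=bwd)


def log(a: Tensor) -> Tensor:
    def bwd(g):
        a._accumulate(g / a.data)

    return Tensor(np.log(a.data), parents=(a,), backward=bwd)


def clip(a: Tensor, lo: float, hi: float) -> Tensor:
    """Clamp with pass-through gradient strictly inside the bounds."""
    mask = (a.data > lo) & (a.data < hi)

    def bwd(g):
        a._accumulate(g * mask)

    return Tensor(np.clip(a.data, lo, hi), parents=(a,), backward=bwd)


def tsum(a: Tensor, axis=None) -> Tensor:
    out_data = a.data.sum(axis=axis)

    def bwd(g):
        if axis is None:
            a._accumulate(np.broadcast_to(g, a.data.shape))
        else:
            a._accumulate(np.broadcast_to(np.expand_dims(g, axis), a.data.shape))

    return Tensor(out_data, parents=(a,), backward=bwd)


def tmean(a: Tensor, axis=None) -> Tensor:
    n = a.data.size if axis is None else a.data.shape[axis]
    return mul(tsum(a, axis=axis), _wrap(1.0 / n))


def reshape(a: Tensor, shape) -> Tensor:
    def bwd(g):
        a._accumulate(g.reshape(a.data.shape))

    return Tensor(a.data.reshape(shape), parents=(a,), backward=bwd)


def concat(parts: Sequence[Tensor], axis: int = 0) -> Tensor:
    sizes = [p.data.shape[axis] for p in parts]
    out_data = np.concatenate([p.data for p in parts], axis=axis)
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for p, lo, hi in zip(parts, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            p._accumulate(g[tuple(sl)])

    return Tensor(out_data, parents=tuple(parts), backward=bwd)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data @ b.data

    def bwd(g):
        a._accumulate(g @ b.data.T if b.data.ndim == 2 else np.outer(g, b.data))
        b._accumulate(a.data.T @ g)

    return Tensor(out_data, parents=(a, b), backward=bwd)


def softmax(a: Tensor) -> Tensor:
    """Softmax over a 1-D tensor."""
    z = a.data - a.data.max()
    e = np.exp(z)
    s = e / e.sum()

    def bwd(g):
        a._accumulate(s * (g - float(g @ s)))

    return Tensor(s, parents=(a,), backward=bwd)


# ---------------------------------------------------------------------------
# convolution


def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    """(C, D, H, W) -> (N_out, C*k^3) patch matrix."""
    if pad:
        x = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (pad, pad)))
    win = sliding_window_view(x, (k, k, k), axis=(1, 2, 3))
    win = win[:, ::stride, ::stride, ::stride]
    c, do, ho, wo = win.shape[:4]
    cols = win.transpose(1, 2, 3, 0, 4, 5, 6).reshape(do * ho * wo, c * k * k * k)
    return np.ascontiguousarray(cols), (do, ho, wo)


def _dilate(g: np.ndarray, stride: int, extra: tuple[int, int, int]) -> np.ndarray:
    """Insert stride-1 zeros between gradient entries; append ``extra`` zeros."""
    if stride == 1 and not any(extra):
        return g
    c, d, h, w = g.shape
    out = np.zeros(
        (c, (d - 1) * stride + 1 + extra[0], (h - 1) * stride + 1 + extra[1], (w - 1) * stride + 1 + extra[2]),
        dtype=g.dtype,
    )
    out[
        :,
        0 : (d - 1) * stride + 1 : stride,
        0 : (h - 1) * stride + 1 : stride,
        0 : (w - 1) * stride + 1 : stride,
    ] = g
    return out


def conv3d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1, padding: int = 1) -> Tensor:
    """3D convolution: x (Cin, D, H, W), w (Cout, Cin, k, k, k), b (Cout,)."""
    cout, cin, k = w.data.shape[0], w.data.shape[1], w.data.shape[2]
    assert x.data.shape[0] == cin, (x.data.shape, w.data.shape)
    cols, out_sp = _im2col(x.data, k, stride, padding)
    wmat = w.data.reshape(cout, -1)
    y = cols @ wmat.T  # (N, Cout)
    if b is not None:
        y = y + b.data
    out_data = y.T.reshape(cout, *out_sp)
    in_shape = x.data.shape

    def bwd(g):
        g_mat = g.reshape(cout, -1).T  # (N, Cout)
        # weights
        w._accumulate((g_mat.T @ cols).reshape(w.data.shape))
        if b is not None:
            b._accumulate(g_mat.sum(axis=0))
        if not x.requires_grad:
            return
        # input gradient = full conv of (dilated) g with spatially flipped,
        # channel-transposed kernels
        extra = tuple((in_shape[i + 1] + 2 * padding - k) % stride for i in range(3))
        gd = _dilate(g, stride, extra)
        wt = np.ascontiguousarray(
            w.data.transpose(1, 0, 2, 3, 4)[:, :, ::-1, ::-1, ::-1]
        ).reshape(cin, -1)
        gcols, gsp = _im2col(gd, k, 1, k - 1 - padding)
        gx = (gcols @ wt.T).T.reshape(cin, *gsp)
        x._accumulate(gx[:, : in_shape[1], : in_shape[2], : in_shape[3]])

    return Tensor(out_data, parents=(x, w) if b is None else (x, w, b), backward=bwd)


# ---------------------------------------------------------------------------
# normalization


def group_norm(x: Tensor, gamma: Tensor, beta: Tensor, groups: int, eps: float = 1e-5) -> Tensor:
    """Group normalization over (channels-in-group, spatial) of (C, D, H, W)."""
    c = x.data.shape[0]
    assert c % groups == 0, (c, groups)
    xg = x.data.reshape(groups, -1).astype(np.float64)
    mu = xg.mean(axis=1, keepdims=True)
    var = xg.var(axis=1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = ((xg - mu) * inv).reshape(x.data.shape).astype(DTYPE)
    out_data = xhat * gamma.data[:, None, None, None] + beta.data[:, None, None, None]

    def bwd(g):
        gamma._accumulate((g * xhat).sum(axis=(1, 2, 3)))
        beta._accumulate(g.sum(axis=(1, 2, 3)))
        gxhat = (g * gamma.data[:, None, None, None]).reshape(groups, -1).astype(np.float64)
        xh = xhat.reshape(groups, -1).astype(np.float64)
        m = gxhat.shape[1]
        gx = inv * (gxhat - gxhat.mean(axis=1, keepdims=True) - xh * (gxhat * xh).sum(axis=1, keepdims=True) / m)
        x._accumulate(gx.reshape(x.data.shape).astype(DTYPE))

    return Tensor(out_data, parents=(x, gamma, beta), backward=bwd)


def layer_norm_vec(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Layer normalization of a 1-D vector with per-element scale/shift."""
    xd = x.data.astype(np.float64)
    mu, var = xd.mean(), xd.var()
    inv = 1.0 / np.sqrt(var + eps)
    xhat = ((xd - mu) * inv).astype(DTYPE)
    out_data = xhat * gamma.data + beta.data

    def bwd(g):
        gamma._accumulate(g * xhat)
        beta._accumulate(g.copy())
        gxhat = (g * gamma.data).astype(np.float64)
        n = xd.size
        gx = inv * (gxhat - gxhat.mean() - xhat.astype(np.float64) * (gxhat * xhat).sum() / n)
        x._accumulate(gx.astype(DTYPE))

    return Tensor(out_data, parents=(x, gamma, beta), backward=bwd)


# ---------------------------------------------------------------------------
# trilinear upsampling


def _up1(x: np.ndarray, axis: int) -> np.ndarray:
    """Linear 2x upsampling along one axis (half-voxel aligned, edge clamp)."""
    x = np.moveaxis(x, axis, -1)
    prev = np.concatenate([x[..., :1], x[..., :-1]], axis=-1)
    nxt = np.concatenate([x[..., 1:], x[..., -1:]], axis=-1)
    even = 0.75 * x + 0.25 * prev
    odd = 0.75 * x + 0.25 * nxt
    out = np.stack([even, odd], axis=-1).reshape(*x.shape[:-1], 2 * x.shape[-1])
    return np.moveaxis(out, -1, axis)


def _up1_adjoint(g: np.ndarray, axis: int) -> np.ndarray:
    g = np.moveaxis(g, axis, -1)
    n2 = g.shape[-1]
    even, odd = g[..., 0:n2:2], g[..., 1:n2:2]
    gx = 0.75 * (even + odd)
    # even[i] pulls 0.25 from x[i-1]  ->  x[i] receives 0.25 * even[i+1]
    gx[..., :-1] += 0.25 * even[..., 1:]
    gx[..., 0] += 0.25 * even[..., 0]  # clamped edge
    # odd[i] pulls 0.25 from x[i+1]  ->  x[i] receives 0.25 * odd[i-1]
    gx[..., 1:] += 0.25 * odd[..., :-1]
    gx[..., -1] += 0.25 * odd[..., -1]  # clamped edge
    return np.moveaxis(gx, -1, axis)


def upsample2x(x: Tensor) -> Tensor:
    """Trilinear 2x upsampling of (C, D, H, W) along the spatial axes."""
    y = x.data
    for axis in (1, 2, 3):
        y = _up1(y, axis)

    def bwd(g):
        for axis in (3, 2, 1):
            g = _up1_adjoint(g, axis)
        x._accumulate(g.astype(DTYPE))

    return Tensor(y, parents=(x,), backward=bwd)


# ---------------------------------------------------------------------------
# wavelet fusion (linear op with analytic adjoint)


def wavelet_fusion(xs: Sequence[Tensor], wavelet: str = "haar", high_freq_rule: str = "sum") -> Tensor:
    """Fused map F from four (C, D, H, W) tensors (see :mod:`wfseg.fusion`).

    The op is linear; for an orthonormal wavelet with periodic boundaries
    the DWT matrix is orthogonal, so the adjoint of IDWT is DWT and the
    gradient to every modality is IDWT of the rule-adjoint of DWT(gF).
    """
    from . import fusion as _fusion
    from .wavelet import HIGH_NAMES, SubbandSet, dwt3, idwt3

    if len(xs) != 4:
        raise ValueError("wavelet_fusion expects 4 tensors")
    if high_freq_rule not in ("sum", "mean"):
        raise ValueError("autodiff wavelet fusion supports high_freq_rule sum|mean")
    stack = np.stack([t.data for t in xs])
    f = _fusion.wavelet_fuse(stack, wavelet, high_freq_rule).astype(DTYPE)
    high_scale = 1.0 if high_freq_rule == "sum" else 0.25

    def bwd(g):
        grads = []
        for c in range(g.shape[0]):
            sb = dwt3(g[c], wavelet)
            adj = SubbandSet(
                lll=sb.lll * 0.25,
                **{name: getattr(sb, name) * high_scale for name in HIGH_NAMES},
                wavelet_name=sb.wavelet_name,
                original_shape=sb.original_shape,
            )
            grads.append(idwt3(adj))
        gx = np.stack(grads).astype(DTYPE)
        for t in xs:
            t._accumulate(gx)

    return Tensor(f, parents=tuple(xs), backward=bwd)
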