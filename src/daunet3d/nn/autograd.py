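"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The toolkit trains a single-volume (batch size 1) 3D segmentation network on
CPU, so the engine is deliberately small: rank-4 feature maps ``(C, D, H, W)``,
float32 throughout, and only the operations the network needs.  Convolutions
are lowered to a single BLAS GEMM through an im2col patch matrix, which is
the fastest pure-NumPy formulation at these sizes.

Gradient correctness of every primitive is pinned by finite-difference tests.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable, Sequence

import numpy as np

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction (inference / metric evaluation)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _as_float(x) -> np.ndarray:
    """float32 by default; float64 *arrays* keep their precision (for
    metric-style computations needing double-precision identities), while
    Python/NumPy scalars become float32 so literals in expressions never
    promote a float32 graph to float64."""
    if type(x) in (bool, int, float):  # Python literals only: NumPy
        return np.asarray(x, dtype=np.float32)  # scalars keep their dtype
    a = np.asarray(x)
    if a.dtype not in (np.float32, np.float64):
        a = a.astype(np.float32)
    return a


class Tensor:
    """An ndarray plus an entry on the backward tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    # make NumPy defer to the reflected operators instead of applying its
    # ufunc machinery elementwise over a wrapped object
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple = (), backward_fn: Callable | None = None):
        self.data = _as_float(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self._parents = parents if self.requires_grad else ()
        self._backward = backward_fn if self.requires_grad else None

    # -- bookkeeping ------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accumulate(self, g: np.ndarray, fresh: bool = False) -> None:
        # ``fresh`` marks a newly allocated array the caller will not reuse,
        # letting us take ownership without a defensive copy
        if self.grad is None:
            self.grad = g if fresh else g.copy()
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Reverse sweep from this tensor (scalar unless ``grad`` given)."""
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that requires no grad")
        if grad is None:
            if self.data.size != 1:
                raise RuntimeError("backward() without grad needs a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs are deep for a 4-level U-Net
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
        self._accumulate(_as_float(grad))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                node.grad = None  # non-leaf: free as the sweep proceeds

    # -- operator sugar ---------------------------------------------------
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

    def __rtruediv__(self, other):
        return div(other, self)

    def __neg__(self):
        return mul(self, -1.0)

    def __matmul__(self, other):
        return matmul(self, other)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # method forms used throughout the model code
    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    def transpose(self, *axes):
        return transpose(self, axes if axes else None)

    def sum(self, axis=None, keepdims=False):
        return reduce_sum(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return reduce_mean(self, axis, keepdims)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``g`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if g.shape == shape:
        return g
    nextra = g.ndim - len(shape)
    if nextra:
        g = g.sum(axis=tuple(range(nextra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


# -- elementwise arithmetic ------------------------------------------------

def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data + b.data
    req = a.requires_grad or b.requires_grad
    if not (req and _GRAD_ENABLED):
        return Tensor(out_data)

    def bw(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.data.shape))

    return Tensor(out_data, True, (a, b), bw)


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data * b.data
    req = a.requires_grad or b.requires_grad
    if not (req and _GRAD_ENABLED):
        return Tensor(out_data)

    def bw(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.data.shape), fresh=True)
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.data.shape), fresh=True)

    return Tensor(out_data, True, (a, b), bw)


def div(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data / b.data
    req = a.requires_grad or b.requires_grad
    if not (req and _GRAD_ENABLED):
        return Tensor(out_data)

    def bw(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g / b.data, a.data.shape), fresh=True)
        if b.requires_grad:
            b._accumulate(_unbroadcast(-g * out_data / b.data, b.data.shape),
                          fresh=True)

    return Tensor(out_data, True, (a, b), bw)


def power(a, exponent: float) -> Tensor:
    a = as_tensor(a)
    out_data = a.data ** exponent
    if not (a.requires_grad and _GRAD_ENABLED):
        return Tensor(out_data)

    def bw(g):
        a._accumulate(g * exponent * a.data ** (exponent - 1.0), fresh=True)

    return Tensor(out_data, True, (a,), bw)


# -- shape manipulation ----------------------------------------------------

def reshape(a, shape) -> Tensor:
    a = as_tensor(a)
    out_data = a.data.reshape(shape)
    if not (a.requires_grad and _GRAD_ENABLED):
        return Tensor(out_data)

    def bw(g):
        a._accumulate(g.reshape(a.data.shape))

    return Tensor(out_data, True, (a,), bw)


def transpose(a, axes=None) -> Tensor:
    a = as_tensor(a)
    out_data = a.data.transpose(axes)
    if not (a.requires_grad and _GRAD_ENABLED):
        return Tensor(out_data)
    inv = None if axes is None else np.argsort(axes)

    def bw(g):
        a._accumulate(g.transpose(inv))

    return Tensor(out_data, True, (a,), bw)


def concat(tensors: Sequence, axis: int = 0) -> Tensor:
    ts = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in ts], axis=axis)
    if not (_GRAD_ENABLED and any(t.requires_grad for t in ts)):
        return Tensor(out_data)
    sizes = [t.data.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accumulate(g[tuple(idx)])

    return Tensor(out_data, True, tuple(ts), bw)


# -- reductions ------------------------------------------------------------

def reduce_sum(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    out_data = np.asarray(a.data.sum(axis=axis, keepdims=keepdims))
    if not (a.requires_grad and _GRAD_ENABLED):
        return Tensor(out_data)

    def bw(g):
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        a._accumulate(np.broadcast_to(g, a.data.shape))

    return Tensor(out_data, True, (a,), bw)


def reduce_mean(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    n = a.data.size if axis is None else np.prod(
        [a.data.shape[i] for i in np.atleast_1d(axis)])
    return mul(reduce_sum(a, axis, keepdims), 1.0 / float(n))


def reduce_max(a, axis, keepdims=False) -> Tensor:
    """Max-reduce; ties share the incoming gradient equally."""
    a = as_tensor(a)
    out_data = a.data.max(axis=axis, keepdims=True)
    if not (a.requires_grad and _GRAD_ENABLED):
        return Tensor(out_data if keepdims else np.squeeze(out_data, axis))

    mask = (a.data == out_data).astype(np.float32)
    mask /= mask.sum(axis=axis, keepdims=True)

    def bw(g):
        if not keepdims:
            g = np.expand_dims(g, axis)
        a._accumulate(mask * g, fresh=True)

    data = out_data if keepdims else np.squeeze(out_data, axis)
    return Tensor(data, True, (a,), bw)


# -- nonlinearities --------------------------------------------------------

def relu(a) -> Tensor:
    a = as_tensor(a)
    out_data = np.maximum(a.data, 0.0)
    if not (a.requires_grad and _GRAD_ENABLED):
        return Tensor(out_data)

    def bw(g):
        a._accumulate(np.where(a.data > 0, g, np.float32(0.0)), fresh=True)

    return Tensor(out_data, True, (a,), bw)


def sigmoid(a) -> Tensor:
    a = as_tensor(a)
    with np.errstate(over="ignore"):
        out_data = 1.0 / (1.0 + np.exp(-a.data))
    if not (a.requires_grad and _GRAD_ENABLED):
        return Tensor(out_data)

    def bw(g):
        a._accumulate(g * out_data * (1.0 - out_data), fresh=True)

    return Tensor(out_data, True, (a,), bw)


def softmax(a, axis: int = -1) -> Tensor:
    """Numerically stable softmax (max-subtraction before exponentiation)."""
    a = as_tensor(a)
    if not np.all(np.isfinite(a.data)):
        raise ValueError("softmax input must be finite")
    shifted = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    out_data = e / e.sum(axis=axis, keepdims=True)
    if not (a.requires_grad and _GRAD_ENABLED):
        return Tensor(out_data)

    def bw(g):
        dot = (g * out_data).sum(axis=axis, keepdims=True)
        a._accumulate(out_data * (g - dot), fresh=True)

    return Tensor(out_data, True, (a,), bw)


# -- linear algebra --------------------------------------------------------

def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data @ b.data
    req = a.requires_grad or b.requires_grad
    if not (req and _GRAD_ENABLED):
        return Tensor(out_data)

    def bw(g):
        if a.requires_grad:
            a._accumulate(g @ b.data.T, fresh=True)
        if b.requires_grad:
            b._accumulate(a.data.T @ g, fresh=True)

    return Tensor(out_data, True, (a, b), bw)


# -- spatial primitives ----------------------------------------------------

def _workspace_buffer(workspace: dict | None, key, shape, dtype) -> np.ndarray:
    """Persistent scratch array (page-fault churn on 100 MB+ im2col buffers
    dominates conv cost otherwise); falls back to a fresh array."""
    if workspace is None:
        return np.empty(shape, dtype=dtype)
    buf = workspace.get(key)
    if buf is None or buf.shape != shape or buf.dtype != dtype:
        buf = np.empty(shape, dtype=dtype)
        workspace[key] = buf
    return buf


def _im2col(xp: np.ndarray, spatial: tuple[int, int, int],
            kernel: tuple[int, int, int], out: np.ndarray) -> np.ndarray:
    """Fill ``out`` (K, C_in, d, h, w) with shifted copies; return (K*C_in, N)."""
    d, h, w = spatial
    kd, kh, kw = kernel
    o = 0
    for a_ in range(kd):
        for b_ in range(kh):
            for c_ in range(kw):
                out[o] = xp[:, a_:a_ + d, b_:b_ + h, c_:c_ + w]
                o += 1
    cin = xp.shape[0]
    return out.reshape(kd * kh * kw * cin, d * h * w)


def conv3d(x, w, b=None, padding: int | None = None,
           workspace: dict | None = None) -> Tensor:
    """'Same'-padded stride-1 3D convolution on a (C, D, H, W) map.

    ``w`` has shape (C_out, C_in, k, k, k) with odd cubic k; ``padding``
    defaults to k // 2.  Lowered to a single BLAS GEMM through an im2col
    patch matrix; 1x1x1 kernels skip the patch construction entirely.
    ``workspace`` (owned by the calling layer) recycles the large patch
    buffers between calls.
    """
    x, w = as_tensor(x), as_tensor(w)
    cout, cin, kd, kh, kw = w.data.shape
    c, d, h, wd = x.data.shape
    if c != cin:
        raise ValueError(f"conv3d: input has {c} channels, weight expects {cin}")
    p = kd // 2 if padding is None else padding
    if not (kd == kh == kw and kd % 2 == 1 and p == kd // 2):
        raise ValueError("conv3d supports odd cubic kernels with 'same' "
                         f"padding only (k={kd}x{kh}x{kw}, p={p})")
    n = d * h * wd
    k3 = kd * kh * kw
    spatial, kernel = (d, h, wd), (kd, kh, kw)
    pointwise = k3 == 1

    if pointwise:
        wf = w.data.reshape(cout, cin)
        col = x.data.reshape(cin, n)  # a view; no copy
    else:
        # weight flattened to match the (offset, channel) patch-row order
        wf = w.data.transpose(0, 2, 3, 4, 1).reshape(cout, k3 * cin)
        xp = np.pad(x.data, ((0, 0), (p, p), (p, p), (p, p)))
        col = _im2col(xp, spatial, kernel,
                      _workspace_buffer(workspace, ("fwd", cin, k3, n),
                                        (k3, cin, d, h, wd), xp.dtype))
    y = wf @ col
    if b is not None:
        b = as_tensor(b)
        y = y + b.data[:, None]
    out_data = y.reshape(cout, d, h, wd)
    req = x.requires_grad or w.requires_grad or (b is not None and b.requires_grad)
    if not (req and _GRAD_ENABLED):
        return Tensor(out_data)

    parents = (x, w) if b is None else (x, w, b)

    def bw(g):
        gf = np.ascontiguousarray(g.reshape(cout, n))
        if b is not None and b.requires_grad:
            b._accumulate(gf.sum(axis=1), fresh=True)
        if w.requires_grad:
            gw = gf @ col.T  # (cout, k3 * cin) or (cout, cin) when pointwise
            if not pointwise:
                gw = np.ascontiguousarray(
                    gw.reshape(cout, kd, kh, kw, cin).transpose(0, 4, 1, 2, 3))
            w._accumulate(gw.reshape(w.data.shape), fresh=True)
        if x.requires_grad:
            if pointwise:
                x._accumulate((wf.T @ gf).reshape(cin, d, h, wd), fresh=True)
            else:
                # input gradient = correlation of g with the channel-transposed,
                # spatially flipped kernel (valid for odd k, 'same' padding)
                wt = w.data[:, :, ::-1, ::-1, ::-1].transpose(
                    1, 2, 3, 4, 0).reshape(cin, k3 * cout)
                gp = np.pad(g.reshape(cout, d, h, wd),
                            ((0, 0), (p, p), (p, p), (p, p)))
                gcol = _im2col(gp, spatial, kernel,
                               _workspace_buffer(workspace,
                                                 ("bwd", cout, k3, n),
                                                 (k3, cout, d, h, wd),
                                                 gp.dtype))
                x._accumulate((wt @ gcol).reshape(cin, d, h, wd), fresh=True)

    return Tensor(out_data, True, parents, bw)


def instance_norm(x, gain, offset, eps: float = 1e-5) -> Tensor:
    """Per-channel spatial normalisation with affine parameters.

    ``x`` is (C, D, H, W); ``gain``/``offset`` broadcast as (C, 1, 1, 1).
    A fused primitive (rather than a composition of means and powers)
    because it sits after every convolution on the hot path.
    """
    x, gain, offset = as_tensor(x), as_tensor(gain), as_tensor(offset)
    ax = (1, 2, 3)
    mu = x.data.mean(axis=ax, keepdims=True)
    xc = x.data - mu
    var = np.mean(xc * xc, axis=ax, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out_data = gain.data * xhat + offset.data
    req = x.requires_grad or gain.requires_grad or offset.requires_grad
    if not (req and _GRAD_ENABLED):
        return Tensor(out_data)

    def bw(g):
        if offset.requires_grad:
            offset._accumulate(g.sum(axis=ax, keepdims=True), fresh=True)
        if gain.requires_grad:
            gain._accumulate((g * xhat).sum(axis=ax, keepdims=True), fresh=True)
        if x.requires_grad:
            gh = g * gain.data
            m1 = gh.mean(axis=ax, keepdims=True)
            m2 = (gh * xhat).mean(axis=ax, keepdims=True)
            x._accumulate(inv * (gh - m1 - xhat * m2), fresh=True)

    return Tensor(out_data, True, (x, gain, offset), bw)


def maxpool2(x) -> Tensor:
    """2x2x2 non-overlapping max pool; spatial dims must be even."""
    x = as_tensor(x)
    c, d, h, w = x.data.shape
    if d % 2 or h % 2 or w % 2:
        raise ValueError(f"maxpool2 needs even spatial dims, got {(d, h, w)}")
    blocks = x.data.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2)
    out_data = blocks.max(axis=(2, 4, 6))
    if not (x.requires_grad and _GRAD_ENABLED):
        return Tensor(out_data)

    expanded = out_data.reshape(c, d // 2, 1, h // 2, 1, w // 2, 1)
    mask = (blocks == expanded).astype(np.float32)
    mask /= mask.sum(axis=(2, 4, 6), keepdims=True)

    def bw(g):
        gb = mask * g.reshape(c, d // 2, 1, h // 2, 1, w // 2, 1)
        x._accumulate(gb.reshape(c, d, h, w), fresh=True)

    return Tensor(out_data, True, (x,), bw)


def upsample2(x) -> Tensor:
    """Nearest-neighbour 2x upsampling of each spatial axis."""
    x = as_tensor(x)
    c, d, h, w = x.data.shape
    out_data = np.broadcast_to(
        x.data.reshape(c, d, 1, h, 1, w, 1),
        (c, d, 2, h, 2, w, 2)).reshape(c, 2 * d, 2 * h, 2 * w)
    out_data = np.ascontiguousarray(out_data)
    if not (x.requires_grad and _GRAD_ENABLED):
        return Tensor(out_data)

    def bw(g):
        x._accumulate(g.reshape(c, d, 2, h, 2, w, 2).sum(axis=(2, 4, 6)),
                      fresh=True)

    return Tensor(out_data, True, (x,), bw)


def global_avgpool(x) -> Tensor:
    """Spatial average per channel: (C, D, H, W) -> (C,)."""
    return reduce_mean(x, axis=(1, 2, 3))


def global_maxpool(x) -> Tensor:
    """Spatial max per channel: (C, D, H, W) -> (C,)."""
    return reduce_max(x, axis=(1, 2, 3))
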