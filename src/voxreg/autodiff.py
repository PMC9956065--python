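"""Minimal reverse-mode automatic differentiation on NumPy arrays.

This engine provides exactly the operations the displacement-predicting
U-Net and its losses need: elementwise arithmetic, reductions, slicing,
channel concatenation, padded 3D convolution, 2x max-pooling, 2x nearest
upsampling, windowed box sums, a softmax for the adaptive loss weights,
and differentiable trilinear resampling of a multi-channel volume by a
dense displacement field (the spatial-transformer step).

Every tensor wraps a float64 ndarray.  Gradients are accumulated by
topological traversal of the recorded graph.  A global ``no_grad`` switch
disables graph construction for inference.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph recording within the context (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


class Tensor:
    """A float64 ndarray plus gradient bookkeeping."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_bw")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._bw: Callable[[np.ndarray], None] | None = None

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (defaults to d(self)/d(self)=1)."""
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
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._bw is not None and node.grad is not None:
                node._bw(node.grad)

    # -- operator sugar -------------------------------------------------
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
        return mul(self, power(other, -1.0))

    def __rtruediv__(self, other):
        return mul(power(self, -1.0), other)

    def __pow__(self, p):
        return power(self, p)

    def __neg__(self):
        return mul(self, -1.0)

    def __getitem__(self, idx):
        return getitem(self, idx)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data: np.ndarray, parents: Sequence[Tensor], bw: Callable) -> Tensor:
    out = Tensor(data)
    if _GRAD_ENABLED and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._bw = bw
    return out


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum gradient g down to ``shape`` (inverse of NumPy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for i, (gs, ss) in enumerate(zip(g.shape, shape)):
        if ss == 1 and gs != 1:
            g = g.sum(axis=i, keepdims=True)
    return g


# -- elementwise ---------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    data = a.data + b.data

    def bw(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g, b.data.shape))

    return _make(data, (a, b), bw)


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    data = a.data * b.data

    def bw(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * a.data, b.data.shape))

    return _make(data, (a, b), bw)


def power(a, p: float) -> Tensor:
    a = as_tensor(a)
    data = a.data ** p

    def bw(g):
        if a.requires_grad:
            a._accum(g * p * a.data ** (p - 1.0))

    return _make(data, (a,), bw)


def exp(a) -> Tensor:
    a = as_tensor(a)
    data = np.exp(a.data)

    def bw(g):
        if a.requires_grad:
            a._accum(g * data)

    return _make(data, (a,), bw)


def log(a) -> Tensor:
    a = as_tensor(a)
    data = np.log(a.data)

    def bw(g):
        if a.requires_grad:
            a._accum(g / a.data)

    return _make(data, (a,), bw)


def sqrt(a) -> Tensor:
    return power(a, 0.5)


def square(a) -> Tensor:
    return power(a, 2.0)


def maximum_const(a, c: float) -> Tensor:
    """max(a, c) with a constant floor; gradient passes where a > c."""
    a = as_tensor(a)
    data = np.maximum(a.data, c)

    def bw(g):
        if a.requires_grad:
            a._accum(g * (a.data > c))

    return _make(data, (a,), bw)


def leaky_relu(a, slope: float = 0.2) -> Tensor:
    a = as_tensor(a)
    pos = a.data > 0
    data = np.where(pos, a.data, slope * a.data)

    def bw(g):
        if a.requires_grad:
            a._accum(g * np.where(pos, 1.0, slope))

    return _make(data, (a,), bw)


# -- reductions / shape --------------------------------------------------

def tsum(a, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    data = a.data.sum(axis=axis, keepdims=keepdims)

    def bw(g):
        if not a.requires_grad:
            return
        if axis is None:
            a._accum(np.broadcast_to(g, a.data.shape).copy())
        else:
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            a._accum(np.broadcast_to(gg, a.data.shape).copy())

    return _make(data, (a,), bw)


def tmean(a, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    if axis is None:
        n = a.data.size
    else:
        axes = (axis,) if isinstance(axis, int) else tuple(axis)
        n = int(np.prod([a.data.shape[ax] for ax in axes]))
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / n)


def getitem(a, idx) -> Tensor:
    a = as_tensor(a)
    data = a.data[idx]

    def bw(g):
        if a.requires_grad:
            full = np.zeros_like(a.data)
            np.add.at(full, idx, g)
            a._accum(full)

    return _make(data, (a,), bw)


def reshape(a, shape) -> Tensor:
    a = as_tensor(a)
    data = a.data.reshape(shape)

    def bw(g):
        if a.requires_grad:
            a._accum(g.reshape(a.data.shape))

    return _make(data, (a,), bw)


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]

    def bw(g):
        splits = np.cumsum(sizes)[:-1]
        parts = np.split(g, splits, axis=axis)
        for t, part in zip(tensors, parts):
            if t.requires_grad:
                t._accum(part)

    return _make(data, tuple(tensors), bw)


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    data = np.stack([t.data for t in tensors], axis=axis)

    def bw(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accum(np.take(g, i, axis=axis))

    return _make(data, tuple(tensors), bw)


def softmax(a) -> Tensor:
    """Softmax over a 1D vector; used for the normalised loss weights."""
    a = as_tensor(a)
    z = a.data - a.data.max()
    e = np.exp(z)
    s = e / e.sum()

    def bw(g):
        if a.requires_grad:
            a._accum(s * (g - float(np.dot(g, s))))

    return _make(s, (a,), bw)


# -- spatial operators ---------------------------------------------------

def conv3d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """3D convolution, stride 1, zero padding to preserve spatial size.

    x: (C_in, D, H, W); w: (C_out, C_in, k, k, k) with odd k; b: (C_out,).
    Implemented with an im2col matmul; the backward pass scatters the
    column gradient back through the 27 (k^3) window offsets.
    """
    k = w.data.shape[2]
    pad = k // 2
    cin, D, H, W = x.data.shape
    cout = w.data.shape[0]
    nvox = D * H * W
    xp = np.pad(x.data, ((0, 0), (pad, pad), (pad, pad), (pad, pad)))
    offsets = [(di, dj, dk) for di in range(k) for dj in range(k) for dk in range(k)]
    out = np.repeat(b.data[:, None], nvox, axis=1)
    for di, dj, dk in offsets:
        shifted = np.ascontiguousarray(
            xp[:, di:di + D, dj:dj + H, dk:dk + W]
        ).reshape(cin, nvox)
        out += w.data[:, :, di, dj, dk] @ shifted
    out = out.reshape(cout, D, H, W)

    def bw(g):
        g2 = g.reshape(cout, nvox)
        if b.requires_grad:
            b._accum(g2.sum(axis=1))
        need_w, need_x = w.requires_grad, x.requires_grad
        gw = np.zeros_like(w.data) if need_w else None
        gxp = np.zeros_like(xp) if need_x else None
        for di, dj, dk in offsets:
            if need_w:
                shifted = np.ascontiguousarray(
                    xp[:, di:di + D, dj:dj + H, dk:dk + W]
                ).reshape(cin, nvox)
                gw[:, :, di, dj, dk] = g2 @ shifted.T
            if need_x:
                gxp[:, di:di + D, dj:dj + H, dk:dk + W] += (
                    w.data[:, :, di, dj, dk].T @ g2
                ).reshape(cin, D, H, W)
        if need_w:
            w._accum(gw)
        if need_x:
            x._accum(gxp[:, pad:pad + D, pad:pad + H, pad:pad + W])

    return _make(out, (x, w, b), bw)


def maxpool2(x: Tensor) -> Tensor:
    """2x2x2 max pooling with stride 2; spatial dims must be even."""
    C, D, H, W = x.data.shape
    if D % 2 or H % 2 or W % 2:
        raise ValueError(f"maxpool2 needs even spatial dims, got {(D, H, W)}")
    wins = (
        x.data.reshape(C, D // 2, 2, H // 2, 2, W // 2, 2)
        .transpose(0, 1, 3, 5, 2, 4, 6)
        .reshape(C, D // 2, H // 2, W // 2, 8)
    )
    am = wins.argmax(axis=-1)
    out = np.take_along_axis(wins, am[..., None], axis=-1)[..., 0]

    def bw(g):
        if not x.requires_grad:
            return
        gw = np.zeros((C, D // 2, H // 2, W // 2, 8))
        np.put_along_axis(gw, am[..., None], g[..., None], axis=-1)
        gx = (
            gw.reshape(C, D // 2, H // 2, W // 2, 2, 2, 2)
            .transpose(0, 1, 4, 2, 5, 3, 6)
            .reshape(C, D, H, W)
        )
        x._accum(gx)

    return _make(out, (x,), bw)


def upsample_nearest2(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x upsampling along the three spatial axes."""
    data = x.data.repeat(2, axis=1).repeat(2, axis=2).repeat(2, axis=3)
    C, D, H, W = x.data.shape

    def bw(g):
        if x.requires_grad:
            x._accum(
                g.reshape(C, D, 2, H, 2, W, 2).sum(axis=(2, 4, 6))
            )

    return _make(data, (x,), bw)


def box_sum(x: Tensor, window: int) -> Tensor:
    """Sum over a centred cubic window (zero padding outside the volume).

    The ones-kernel correlation with zero padding is self-adjoint, so the
    backward pass is the same filter applied to the gradient.
    """
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be odd and >= 3")

    def filt(arr):
        return ndimage.uniform_filter(arr, size=window, mode="constant", cval=0.0) * window**3

    data = filt(x.data)

    def bw(g):
        if x.requires_grad:
            x._accum(filt(g))

    return _make(data, (x,), bw)


def _grid_base(shape: tuple[int, int, int]) -> np.ndarray:
    """Identity coordinate grid, shape (3, D, H, W), voxel units."""
    return np.stack(
        np.meshgrid(*[np.arange(n, dtype=np.float64) for n in shape], indexing="ij")
    )


def grid_sample(img: Tensor, phi: Tensor) -> Tensor:
    """Backward-warp: out(x) = img(x + phi(x)) by trilinear interpolation.

    img: (C, D, H, W); phi: (3, D, H, W) displacements in voxel units.
    Out-of-bounds sample positions clamp to the volume edge; the gradient
    with respect to phi vanishes where the position is clamped.
    Differentiable in both arguments.
    """
    img = as_tensor(img)
    phi = as_tensor(phi)
    C = img.data.shape[0]
    spatial = img.data.shape[1:]
    if phi.data.shape != (3,) + spatial:
        raise ValueError(f"field shape {phi.data.shape} does not match image {img.data.shape}")
    D, H, W = spatial
    hi = np.array([D - 1, H - 1, W - 1], dtype=np.float64)
    pos = _grid_base(spatial) + phi.data
    inb = [(pos[a] >= 0.0) & (pos[a] <= hi[a]) for a in range(3)]
    cl = np.stack([np.clip(pos[a], 0.0, hi[a]) for a in range(3)])
    p0 = np.minimum(np.floor(cl), hi[:, None, None, None] - 1).astype(np.int64)
    p0 = np.maximum(p0, 0)
    f = cl - p0
    wgt = [[1.0 - f[a], f[a]] for a in range(3)]
    i0, j0, k0 = p0
    corners = {}
    out = np.zeros((C, D, H, W))
    for di in (0, 1):
        for dj in (0, 1):
            for dk in (0, 1):
                vals = img.data[:, i0 + di, j0 + dj, k0 + dk]
                corners[(di, dj, dk)] = vals
                out += (wgt[0][di] * wgt[1][dj] * wgt[2][dk]) * vals

    def bw(g):
        if img.requires_grad:
            gimg = np.zeros_like(img.data).reshape(C, -1)
            for (di, dj, dk), _ in corners.items():
                w = wgt[0][di] * wgt[1][dj] * wgt[2][dk]
                lin = (((i0 + di) * H + (j0 + dj)) * W + (k0 + dk)).ravel()
                contrib = (w * g).reshape(C, -1)
                for c in range(C):
                    gimg[c] += np.bincount(lin, weights=contrib[c], minlength=D * H * W)
            img._accum(gimg.reshape(img.data.shape))
        if phi.requires_grad:
            sgn = [(-1.0, 1.0)[d] for d in (0, 1)]
            gphi = np.zeros((3, D, H, W))
            for (di, dj, dk), vals in corners.items():
                contrib = (g * vals).sum(axis=0)
                gphi[0] += sgn[di] * wgt[1][dj] * wgt[2][dk] * contrib
                gphi[1] += wgt[0][di] * sgn[dj] * wgt[2][dk] * contrib
                gphi[2] += wgt[0][di] * wgt[1][dj] * sgn[dk] * contrib
            for a in range(3):
                gphi[a] *= inb[a]
            phi._accum(gphi)

    return _make(out, (img, phi), bw)


# -- optimiser -----------------------------------------------------------

class Adam:
    """Adam optimiser over a list of parameter tensors.

    Parameters whose ``requires_grad`` flag is False are skipped, which is
    how encoder freezing is realised during two-step transfer learning.
    """

    def __init__(self, params: Sequence[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if not p.requires_grad or p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
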