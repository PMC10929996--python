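"""Minimal reverse-mode automatic differentiation on numpy arrays.

The segmentation network in this package needs only a small, fixed set of
differentiable operations (3D convolutions, transpose convolutions, trilinear
up/down-sampling, normalizations, softmax, and trilinear grid sampling for
deformable attention).  This module implements exactly that set as a tape-based
reverse-mode engine over float32 numpy arrays.  Every primitive here is
covered by finite-difference gradient tests.

Tensors are unbatched: convolutional features are ``(C, H, W, D)`` grids and
token sequences are ``(N, C)`` matrices, matching the single-sample training
regime (batch size 1) used by the network.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np

_grad_enabled = True


@contextmanager
def no_grad():
    """Disable graph construction (inference / evaluation)."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._backward = None
        self._parents = ()

    # ---- construction helpers -------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    def zero_grad(self):
        self.grad = None

    # ---- autograd --------------------------------------------------------
    def backward(self, grad=None, free_graph: bool = True):
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in visited:
                    stack.append((p, False))
        _accum(self, np.asarray(grad, dtype=np.float32))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            if free_graph:
                node._backward = None
                node._parents = ()
                if not node.requires_grad:
                    node.grad = None

    # ---- operators -------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(_ensure(other), -1.0))

    def __rsub__(self, other):
        return add(_ensure(other), mul(self, -1.0))

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(_ensure(other), self)

    def __pow__(self, p):
        return power(self, p)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return getitem(self, idx)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        return reshape(self, shape)

    def transpose(self, *axes):
        return transpose(self, axes if axes else None)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def _ensure(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))


def _make(data, parents, backward) -> Tensor:
    parents = tuple(p for p in parents if isinstance(p, Tensor))
    if _grad_enabled and any(p.requires_grad or p._parents for p in parents):
        t = Tensor(data)
        t._parents = parents
        t._backward = backward
        # mark as needing grad so downstream ops keep the tape alive
        t.requires_grad = False
        return t
    return Tensor(data)


def _needs_tape(p: Tensor) -> bool:
    return p.requires_grad or p._backward is not None


def _accum(t: Tensor, g: np.ndarray):
    if t.grad is None:
        t.grad = g.astype(np.float32, copy=True)
    else:
        t.grad += g


def _unbroadcast(g: np.ndarray, shape) -> np.ndarray:
    if g.shape == tuple(shape):
        return g
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for i, (gs, ss) in enumerate(zip(g.shape, shape)):
        if ss == 1 and gs != 1:
            g = g.sum(axis=i, keepdims=True)
    return g.reshape(shape)


# ---------------------------------------------------------------------------
# elementwise / reduction primitives
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = _ensure(a), _ensure(b)
    out = a.data + b.data

    def backward(g):
        if _needs_tape(a):
            _accum(a, _unbroadcast(g, a.data.shape))
        if _needs_tape(b):
            _accum(b, _unbroadcast(g, b.data.shape))

    return _make(out, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = _ensure(a), _ensure(b)
    out = a.data * b.data

    def backward(g):
        if _needs_tape(a):
            _accum(a, _unbroadcast(g * b.data, a.data.shape))
        if _needs_tape(b):
            _accum(b, _unbroadcast(g * a.data, b.data.shape))

    return _make(out, (a, b), backward)


def div(a, b) -> Tensor:
    a, b = _ensure(a), _ensure(b)
    out = a.data / b.data

    def backward(g):
        if _needs_tape(a):
            _accum(a, _unbroadcast(g / b.data, a.data.shape))
        if _needs_tape(b):
            _accum(b, _unbroadcast(-g * a.data / (b.data * b.data), b.data.shape))

    return _make(out, (a, b), backward)


def power(a, p: float) -> Tensor:
    a = _ensure(a)
    out = a.data ** p

    def backward(g):
        if _needs_tape(a):
            _accum(a, g * p * a.data ** (p - 1))

    return _make(out, (a,), backward)


def exp(a) -> Tensor:
    a = _ensure(a)
    out = np.exp(a.data)

    def backward(g):
        if _needs_tape(a):
            _accum(a, g * out)

    return _make(out, (a,), backward)


def log(a) -> Tensor:
    a = _ensure(a)
    out = np.log(a.data)

    def backward(g):
        if _needs_tape(a):
            _accum(a, g / a.data)

    return _make(out, (a,), backward)


def sqrt(a) -> Tensor:
    a = _ensure(a)
    out = np.sqrt(a.data)

    def backward(g):
        if _needs_tape(a):
            _accum(a, g * 0.5 / out)

    return _make(out, (a,), backward)


def relu(a) -> Tensor:
    a = _ensure(a)
    mask = a.data > 0
    out = a.data * mask

    def backward(g):
        if _needs_tape(a):
            _accum(a, g * mask)

    return _make(out, (a,), backward)


def sigmoid(a) -> Tensor:
    a = _ensure(a)
    x = a.data
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)

    def backward(g):
        if _needs_tape(a):
            _accum(a, g * out * (1.0 - out))

    return _make(out, (a,), backward)


def softplus(a) -> Tensor:
    """log(1 + exp(x)), numerically stable; derivative is sigmoid(x)."""
    a = _ensure(a)
    out = np.logaddexp(0.0, a.data).astype(np.float32)

    def backward(g):
        if _needs_tape(a):
            x = a.data
            s = np.empty_like(x)
            pos = x >= 0
            s[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
            ex = np.exp(x[~pos])
            s[~pos] = ex / (1.0 + ex)
            _accum(a, g * s)

    return _make(out, (a,), backward)


def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = _ensure(a)
    out = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if _needs_tape(a):
            gg = np.asarray(g)
            if axis is not None and not keepdims:
                axes = axis if isinstance(axis, tuple) else (axis,)
                for ax in sorted(a_ % a.data.ndim for a_ in axes):
                    gg = np.expand_dims(gg, ax)
            _accum(a, np.broadcast_to(gg, a.data.shape).astype(np.float32))

    return _make(out, (a,), backward)


def tmean(a, axis=None, keepdims=False) -> Tensor:
    a = _ensure(a)
    if axis is None:
        n = a.data.size
    else:
        axes = axis if isinstance(axis, tuple) else (axis,)
        n = int(np.prod([a.data.shape[ax] for ax in axes]))
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / n)


def reshape(a, shape) -> Tensor:
    a = _ensure(a)
    old = a.data.shape
    out = a.data.reshape(shape)

    def backward(g):
        if _needs_tape(a):
            _accum(a, g.reshape(old))

    return _make(out, (a,), backward)


def transpose(a, axes=None) -> Tensor:
    a = _ensure(a)
    out = a.data.transpose(axes) if axes else a.data.T
    if axes:
        inv = np.argsort(axes)
    else:
        inv = None

    def backward(g):
        if _needs_tape(a):
            _accum(a, g.transpose(inv) if inv is not None else g.T)

    return _make(out, (a,), backward)


def _is_basic_index(idx) -> bool:
    items = idx if isinstance(idx, tuple) else (idx,)
    return all(isinstance(i, (slice, int)) or i is Ellipsis for i in items)


def getitem(a, idx) -> Tensor:
    a = _ensure(a)
    out = a.data[idx]
    basic = _is_basic_index(idx)  # basic slicing never repeats elements

    def backward(g):
        if _needs_tape(a):
            ga = np.zeros_like(a.data)
            if basic:
                ga[idx] += g
            else:
                np.add.at(ga, idx, g)
            _accum(a, ga)

    return _make(out, (a,), backward)


def concat(tensors, axis=0) -> Tensor:
    tensors = [_ensure(t) for t in tensors]
    out = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if _needs_tape(t):
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                _accum(t, g[tuple(sl)])

    return _make(out, tuple(tensors), backward)


def matmul(a, b) -> Tensor:
    a, b = _ensure(a), _ensure(b)
    out = a.data @ b.data

    def backward(g):
        if _needs_tape(a):
            _accum(a, g @ b.data.T)
        if _needs_tape(b):
            _accum(b, a.data.T @ g)

    return _make(out, (a, b), backward)


def softmax(a, axis=-1) -> Tensor:
    a = _ensure(a)
    m = a.data.max(axis=axis, keepdims=True)
    e = exp(add(a, Tensor(-m)))
    return div(e, tsum(e, axis=axis, keepdims=True))


# ---------------------------------------------------------------------------
# spatial primitives
# ---------------------------------------------------------------------------

def conv3d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1) -> Tensor:
    """3D convolution, channels-first, 'same'-style padding (odd kernels).

    ``x``: (Cin, H, W, D); ``w``: (Cout, Cin, k, k, k); output spatial dims are
    ``ceil(dim / stride)``.  Implemented as a sum of shifted GEMMs over kernel
    offsets, which keeps peak memory at one feature-map copy.
    """
    x, w = _ensure(x), _ensure(w)
    Cout, Cin, k0, k1, k2 = w.data.shape
    if x.data.shape[0] != Cin:
        raise ValueError(f"conv3d: input has {x.data.shape[0]} channels, kernel expects {Cin}")
    s = int(stride)
    p = (k0 // 2, k1 // 2, k2 // 2)
    H, W, D = x.data.shape[1:]
    if min(H, W, D) < 1:
        raise ValueError("conv3d: empty input")
    xp = np.pad(x.data, ((0, 0), (p[0], p[0]), (p[1], p[1]), (p[2], p[2])))
    Ho = (H + 2 * p[0] - k0) // s + 1
    Wo = (W + 2 * p[1] - k1) // s + 1
    Do = (D + 2 * p[2] - k2) // s + 1
    M = Ho * Wo * Do
    wd = w.data
    kk = k0 * k1 * k2
    # one-GEMM im2col path unless the unfolded buffer would be huge
    use_im2col = Cin * kk * M <= 2e8

    def _slices(i, j, l):
        return (slice(i, i + s * (Ho - 1) + 1, s),
                slice(j, j + s * (Wo - 1) + 1, s),
                slice(l, l + s * (Do - 1) + 1, s))

    if use_im2col:
        win = np.lib.stride_tricks.sliding_window_view(xp, (k0, k1, k2), axis=(1, 2, 3))
        win = win[:, ::s, ::s, ::s]  # (Cin, Ho, Wo, Do, k0, k1, k2)
        P = np.ascontiguousarray(win.transpose(0, 4, 5, 6, 1, 2, 3)).reshape(Cin * kk, M)
        out = (wd.reshape(Cout, -1) @ P).reshape(Cout, Ho, Wo, Do)
    else:
        P = None
        out = np.zeros((Cout, Ho, Wo, Do), dtype=np.float32)
        for i in range(k0):
            for j in range(k1):
                for l in range(k2):
                    s0, s1, s2 = _slices(i, j, l)
                    out += np.tensordot(wd[:, :, i, j, l], xp[:, s0, s1, s2], axes=(1, 0))
    if b is not None:
        out += b.data.reshape(-1, 1, 1, 1)

    def backward(g):
        g2 = g.reshape(Cout, M)
        need_w, need_x = _needs_tape(w), _needs_tape(x)
        if use_im2col:
            if need_w:
                _accum(w, (g2 @ P.T).reshape(wd.shape))
            if need_x:
                if s == 1:
                    # input grad = correlation of g with the flipped kernel,
                    # done as a second im2col GEMM (faster than col2im scatter)
                    gp = np.pad(g.reshape(Cout, Ho, Wo, Do),
                                ((0, 0), (k0 - 1 - p[0],) * 2, (k1 - 1 - p[1],) * 2,
                                 (k2 - 1 - p[2],) * 2))
                    gwin = np.lib.stride_tricks.sliding_window_view(
                        gp, (k0, k1, k2), axis=(1, 2, 3))
                    Pg = np.ascontiguousarray(
                        gwin.transpose(0, 4, 5, 6, 1, 2, 3)).reshape(Cout * kk, H * W * D)
                    wf = wd[:, :, ::-1, ::-1, ::-1].reshape(Cout, Cin, kk)
                    W2 = np.ascontiguousarray(
                        wf.transpose(1, 0, 2)).reshape(Cin, Cout * kk)
                    _accum(x, (W2 @ Pg).reshape(Cin, H, W, D))
                    gxp = None
                else:
                    gP = (wd.reshape(Cout, -1).T @ g2).reshape(Cin, k0, k1, k2, Ho, Wo, Do)
                    gxp = np.zeros_like(xp)
                    for i in range(k0):
                        for j in range(k1):
                            for l in range(k2):
                                gxp[(slice(None),) + _slices(i, j, l)] += gP[:, i, j, l]
        else:
            if need_w:
                gw = np.empty_like(wd)
            if need_x:
                gxp = np.zeros_like(xp)
            for i in range(k0):
                for j in range(k1):
                    for l in range(k2):
                        s0, s1, s2 = _slices(i, j, l)
                        if need_w:
                            gw[:, :, i, j, l] = np.tensordot(
                                g, xp[:, s0, s1, s2], axes=([1, 2, 3], [1, 2, 3]))
                        if need_x:
                            gxp[:, s0, s1, s2] += np.tensordot(wd[:, :, i, j, l], g, axes=(0, 0))
            if need_w:
                _accum(w, gw)
        if need_x and gxp is not None:
            gx = gxp[:, p[0]:p[0] + H, p[1]:p[1] + W, p[2]:p[2] + D]
            _accum(x, np.ascontiguousarray(gx))
        if b is not None and _needs_tape(b):
            _accum(b, g.sum(axis=(1, 2, 3)))

    parents = (x, w) if b is None else (x, w, b)
    return _make(out, parents, backward)


def conv_transpose3d_2x(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Transpose convolution with kernel 2, stride 2 (exact spatial doubling).

    ``x``: (Cin, H, W, D); ``w``: (Cin, Cout, 2, 2, 2) -> (Cout, 2H, 2W, 2D).
    """
    x, w = _ensure(x), _ensure(w)
    Cin, Cout = w.data.shape[:2]
    H, W, D = x.data.shape[1:]
    out = np.empty((Cout, 2 * H, 2 * W, 2 * D), dtype=np.float32)
    wd = w.data
    for i in range(2):
        for j in range(2):
            for l in range(2):
                out[:, i::2, j::2, l::2] = np.tensordot(wd[:, :, i, j, l], x.data, axes=(0, 0))
    if b is not None:
        out += b.data.reshape(-1, 1, 1, 1)

    def backward(g):
        if _needs_tape(x):
            gx = np.zeros_like(x.data)
        for i in range(2):
            for j in range(2):
                for l in range(2):
                    gs = g[:, i::2, j::2, l::2]
                    if _needs_tape(x):
                        gx += np.tensordot(wd[:, :, i, j, l], gs, axes=(1, 0))
                    if _needs_tape(w):
                        gw_ijl = np.tensordot(x.data, gs, axes=([1, 2, 3], [1, 2, 3]))
                        if w.grad is None:
                            w.grad = np.zeros_like(w.data)
                        w.grad[:, :, i, j, l] += gw_ijl
        if _needs_tape(x):
            _accum(x, gx)
        if b is not None and _needs_tape(b):
            _accum(b, g.sum(axis=(1, 2, 3)))

    parents = (x, w) if b is None else (x, w, b)
    return _make(out, parents, backward)


def avg_pool2(x: Tensor) -> Tensor:
    """2x2x2 average pooling (dims must be even)."""
    x = _ensure(x)
    C, H, W, D = x.data.shape
    if H % 2 or W % 2 or D % 2:
        raise ValueError(f"avg_pool2 requires even spatial dims, got {(H, W, D)}")
    out = x.data.reshape(C, H // 2, 2, W // 2, 2, D // 2, 2).mean(axis=(2, 4, 6))

    def backward(g):
        if _needs_tape(x):
            gg = g / 8.0
            gg = np.repeat(np.repeat(np.repeat(gg, 2, axis=1), 2, axis=2), 2, axis=3)
            _accum(x, gg)

    return _make(out, (x,), backward)


def _upsample_axis2(x: Tensor, axis: int) -> Tensor:
    """Double the size of one spatial axis by edge-clamped linear interpolation.

    Matches half-voxel-aligned (align_corners=False) linear resampling:
    out[2i] = 0.75 x[i] + 0.25 x[i-1], out[2i+1] = 0.75 x[i] + 0.25 x[i+1].
    """
    x = _ensure(x)
    xd = np.moveaxis(x.data, axis, -1)
    n = xd.shape[-1]
    xm = np.concatenate([xd[..., :1], xd[..., :-1]], axis=-1)
    xp = np.concatenate([xd[..., 1:], xd[..., -1:]], axis=-1)
    out = np.empty(xd.shape[:-1] + (2 * n,), dtype=np.float32)
    out[..., 0::2] = 0.75 * xd + 0.25 * xm
    out[..., 1::2] = 0.75 * xd + 0.25 * xp
    out = np.moveaxis(out, -1, axis)

    def backward(g):
        if not _needs_tape(x):
            return
        gm = np.moveaxis(g, axis, -1)
        ge = gm[..., 0::2]
        go = gm[..., 1::2]
        gx = 0.75 * (ge + go)
        gx[..., :-1] += 0.25 * ge[..., 1:]
        gx[..., 0] += 0.25 * ge[..., 0]
        gx[..., 1:] += 0.25 * go[..., :-1]
        gx[..., -1] += 0.25 * go[..., -1]
        _accum(x, np.ascontiguousarray(np.moveaxis(gx, -1, axis)))

    return _make(out, (x,), backward)


def upsample2_trilinear(x: Tensor) -> Tensor:
    """Double all three spatial axes of a (C, H, W, D) feature map."""
    for ax in (1, 2, 3):
        x = _upsample_axis2(x, ax)
    return x


def grid_sample_trilinear(grid: Tensor, coords: Tensor) -> Tensor:
    """Sample a (C, H, W, D) grid at continuous voxel coordinates (N, 3).

    Coordinates are in voxel units and clamped to the grid boundary; returns
    (N, C).  Differentiable w.r.t. both the grid values and the coordinates
    (zero coordinate-gradient where clamping is active).
    """
    grid, coords = _ensure(grid), _ensure(coords)
    C, H, W, D = grid.data.shape
    dims = np.array([H, W, D], dtype=np.float32)
    cc = np.clip(coords.data, 0.0, dims - 1.0)
    unclamped = (coords.data > 0.0) & (coords.data < dims - 1.0)
    i0 = np.minimum(np.floor(cc), dims - 2.0).astype(np.int64)
    i0 = np.maximum(i0, 0)
    f = cc - i0  # (N, 3) in [0, 1]
    gflat = grid.data.reshape(C, -1)
    N = cc.shape[0]
    out = np.zeros((N, C), dtype=np.float32)
    corners = []
    for di in range(2):
        for dj in range(2):
            for dl in range(2):
                idx = ((i0[:, 0] + di) * W + (i0[:, 1] + dj)) * D + (i0[:, 2] + dl)
                w0 = f[:, 0] if di else 1.0 - f[:, 0]
                w1 = f[:, 1] if dj else 1.0 - f[:, 1]
                w2 = f[:, 2] if dl else 1.0 - f[:, 2]
                wgt = w0 * w1 * w2
                vals = gflat[:, idx]  # (C, N)
                out += (wgt * vals).T
                corners.append((di, dj, dl, idx, (w0, w1, w2), vals))

    def backward(g):
        need_grid = _needs_tape(grid)
        need_coords = _needs_tape(coords)
        if need_grid:
            ggrid = np.zeros((H * W * D) * C, dtype=np.float64)
            ch = np.arange(C, dtype=np.int64)
        if need_coords:
            gcoord = np.zeros_like(coords.data)
        for di, dj, dl, idx, (w0, w1, w2), vals in corners:
            if need_grid:
                # scatter-add via bincount on a combined (voxel, channel) index
                flat_idx = (idx[:, None] * C + ch).ravel()
                contrib = (g * (w0 * w1 * w2)[:, None]).ravel()
                ggrid += np.bincount(flat_idx, weights=contrib, minlength=ggrid.size)
            if need_coords:
                gv = np.einsum("nc,cn->n", g, vals)
                s0 = 1.0 if di else -1.0
                s1 = 1.0 if dj else -1.0
                s2 = 1.0 if dl else -1.0
                gcoord[:, 0] += gv * s0 * w1 * w2
                gcoord[:, 1] += gv * w0 * s1 * w2
                gcoord[:, 2] += gv * w0 * w1 * s2
        if need_grid:
            _accum(grid, ggrid.reshape(H * W * D, C).astype(np.float32).T.reshape(C, H, W, D))
        if need_coords:
            _accum(coords, gcoord * unclamped)

    return _make(out, (grid, coords), backward)


# ---------------------------------------------------------------------------
# composed normalizations
# ---------------------------------------------------------------------------

def instance_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Per-channel standardization over the spatial axes of (C, H, W, D).

    Fused primitive with the analytic backward of y = (x - mu)/sigma:
    dL/dx = (g*gamma/sigma) - mean(g*gamma/sigma) - y * mean(g*gamma*y/sigma).
    """
    x, gamma, beta = _ensure(x), _ensure(gamma), _ensure(beta)
    ax = (1, 2, 3)
    mu = x.data.mean(axis=ax, keepdims=True)
    xc = x.data - mu
    var = (xc * xc).mean(axis=ax, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    y = xc * inv
    C = x.data.shape[0]
    gview = gamma.data.reshape(C, 1, 1, 1)
    out = y * gview + beta.data.reshape(C, 1, 1, 1)

    def backward(g):
        if _needs_tape(gamma):
            _accum(gamma, (g * y).sum(axis=ax))
        if _needs_tape(beta):
            _accum(beta, g.sum(axis=ax))
        if _needs_tape(x):
            gg = g * (gview * inv)
            gx = gg - gg.mean(axis=ax, keepdims=True) \
                - y * (gg * y).mean(axis=ax, keepdims=True)
            _accum(x, gx.astype(np.float32))

    return _make(out.astype(np.float32), (x, gamma, beta), backward)


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Standardize over the last (channel) axis of a (N, C) token matrix."""
    mu = tmean(x, axis=-1, keepdims=True)
    xc = x - mu
    var = tmean(mul(xc, xc), axis=-1, keepdims=True)
    y = div(xc, sqrt(add(var, eps)))
    return add(mul(y, gamma), beta)
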