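"""Minimal reverse-mode automatic differentiation over numpy arrays.

A deliberately small tensor engine: enough to express the centering,
segmentation and motion networks, their losses, and the trilinear warping
operator, with analytic gradients throughout.  Convolutions are lowered to
an im2col + matrix-multiply (BLAS) form; the pooling/upsampling primitives
act in-plane only, matching the anisotropic short-axis geometry.

Array layout: batched feature maps are (N, C, X, Y, Z) (3D) or (N, C, X, Y)
(2D); displacement fields are (N, 3, X, Y, Z) in voxel units.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "conv_nd", "maxpool_inplane", "upsample_inplane",
           "warp3d"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and grad.shape[i] != 1:
            grad = grad.sum(axis=i, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev: tuple = ()):
        data = np.asarray(data)
        if not np.issubdtype(data.dtype, np.floating):
            data = data.astype(np.float64)
        self.data = data
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev = _prev

    # -- helpers ----------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _accum(self, g: np.ndarray):
        if self.grad is None:
            self.grad = np.array(np.broadcast_to(g, self.data.shape))
        else:
            self.grad += g

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        if isinstance(other, (int, float)):
            out = Tensor(self.data + other, self.requires_grad, (self,))

            def bwd_s(g):
                if self.requires_grad:
                    self._accum(g)
            out._backward = bwd_s
            return out
        other = self._wrap(other)
        out = Tensor(self.data + other.data,
                     self.requires_grad or other.requires_grad, (self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))
        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(-g)
        out._backward = bwd
        return out

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        if isinstance(other, (int, float)):
            out = Tensor(self.data * other, self.requires_grad, (self,))

            def bwd_s(g):
                if self.requires_grad:
                    self._accum(g * other)
            out._backward = bwd_s
            return out
        other = self._wrap(other)
        out = Tensor(self.data * other.data,
                     self.requires_grad or other.requires_grad, (self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))
        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, (int, float)):
            return self * (1.0 / other)
        other = self._wrap(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return self._wrap(other) * self ** -1.0

    def __pow__(self, exponent: float):
        out = Tensor(self.data ** exponent, self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * exponent * self.data ** (exponent - 1.0))
        out._backward = bwd
        return out

    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._wrap(other)
        out = Tensor(self.data @ other.data,
                     self.requires_grad or other.requires_grad, (self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(g @ other.data.swapaxes(-1, -2))
            if other.requires_grad:
                other._accum(self.data.swapaxes(-1, -2) @ g)
        out._backward = bwd
        return out

    __matmul__ = matmul

    # -- elementwise functions -------------------------------------------
    def exp(self):
        out = Tensor(np.exp(self.data), self.requires_grad, (self,))
        out_data = out.data        # capture the array, not the tensor:
                                   # a closure over `out` would be a cycle

        def bwd(g):
            if self.requires_grad:
                self._accum(g * out_data)
        out._backward = bwd
        return out

    def log(self):
        out = Tensor(np.log(self.data), self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g / self.data)
        out._backward = bwd
        return out

    def abs(self):
        out = Tensor(np.abs(self.data), self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * np.sign(self.data))
        out._backward = bwd
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * (self.data > 0))
        out._backward = bwd
        return out

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient passes only where unclamped."""
        out = Tensor(np.clip(self.data, lo, hi), self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * ((self.data > lo) & (self.data < hi)))
        out._backward = bwd
        return out

    # -- reductions and shaping ------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     self.requires_grad, (self,))

        def bwd(g):
            if not self.requires_grad:
                return
            g = np.asarray(g)
            if axis is not None and not keepdims:
                axes = axis if isinstance(axis, tuple) else (axis,)
                for ax in sorted(a % self.ndim for a in axes):
                    g = np.expand_dims(g, ax)
            self._accum(np.broadcast_to(g, self.shape).copy())
        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g.reshape(self.shape))
        out._backward = bwd
        return out

    def transpose(self, axes):
        out = Tensor(self.data.transpose(axes), self.requires_grad, (self,))
        inv = np.argsort(axes)

        def bwd(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))
        out._backward = bwd
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], self.requires_grad, (self,))
        parts = idx if isinstance(idx, tuple) else (idx,)
        basic = all(isinstance(p, (int, slice)) for p in parts)

        def bwd(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                if basic:           # no duplicate targets with basic indexing
                    full[idx] += g
                else:
                    np.add.at(full, idx, g)
                self._accum(full)
        out._backward = bwd
        return out

    # -- autodiff driver --------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo, seen = [], set()

        def build(t: Tensor):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._prev:
                build(p)
            topo.append(t)

        build(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis),
                 any(t.requires_grad for t in tensors), tuple(tensors))
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, o0, o1 in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(o0, o1)
                t._accum(g[tuple(sl)])
    out._backward = bwd
    return out


# ---------------------------------------------------------------------------
# Convolution (stride 1, 'same' zero padding, odd kernels)
# ---------------------------------------------------------------------------


def _im2col(x: np.ndarray, kshape: tuple[int, ...]) -> np.ndarray:
    """(N, C, *spatial) -> (N * prod(spatial), C * prod(kshape)) column matrix."""
    nd = len(kshape)
    pads = [(k // 2, k // 2) for k in kshape]
    xp = np.pad(x, [(0, 0), (0, 0)] + pads)
    win = np.lib.stride_tricks.sliding_window_view(
        xp, kshape, axis=tuple(range(2, 2 + nd)))
    # win: (N, C, *spatial, *kshape) -> (N, *spatial, C, *kshape)
    order = (0,) + tuple(range(2, 2 + nd)) + (1,) + tuple(range(2 + nd, 2 + 2 * nd))
    win = win.transpose(order)
    n = x.shape[0]
    spatial = int(np.prod(x.shape[2:]))
    k = x.shape[1] * int(np.prod(kshape))
    return np.ascontiguousarray(win).reshape(n * spatial, k)


def _conv_forward(x: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """x (N, Cin, *spatial), w (Cout, Cin, *kshape) -> (y, cols).

    im2col lowering: the column matrix is materialised once and reused by
    the weight-gradient pass.
    """
    kshape = w.shape[2:]
    cols = _im2col(x, kshape)
    y = cols @ w.reshape(w.shape[0], -1).T            # (N*S, Cout)
    spatial = x.shape[2:]
    y = y.reshape((x.shape[0],) + spatial + (w.shape[0],))
    y = np.moveaxis(y, -1, 1)
    # contiguous output: downstream elementwise ops are much faster on it
    return np.ascontiguousarray(y), cols


def conv_nd(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """N-dimensional 'same' convolution (correlation), stride 1, odd kernels."""
    y, cols = _conv_forward(x.data, w.data)
    prev = (x, w) if b is None else (x, w, b)
    req = x.requires_grad or w.requires_grad or (b is not None and b.requires_grad)
    if b is not None:
        bshape = (1, -1) + (1,) * (y.ndim - 2)
        y = y + b.data.reshape(bshape)
    out = Tensor(y, req, prev)
    kshape = w.shape[2:]
    nd = len(kshape)

    def bwd(g):
        cout = w.shape[0]
        g_mat = np.moveaxis(g, 1, -1).reshape(-1, cout)   # (N*S, Cout)
        if w.requires_grad:
            dw = g_mat.T @ cols
            w._accum(dw.reshape(w.shape))
        if b is not None and b.requires_grad:
            b._accum(g_mat.sum(axis=0))
        if x.requires_grad:
            # dX = same-conv of g with flipped, channel-swapped weights
            wt = w.data
            for ax in range(2, 2 + nd):
                wt = np.flip(wt, axis=ax)
            wt = wt.swapaxes(0, 1)                        # (Cin, Cout, *k)
            dx, _ = _conv_forward(g, wt)
            x._accum(dx)
    out._backward = bwd
    return out


def batchnorm_train(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5
                    ) -> tuple[Tensor, np.ndarray, np.ndarray]:
    """Fused training-mode batch normalisation over batch and spatial axes.

    Returns (output, batch_mean, batch_var) — the statistics are needed by
    the caller to update running estimates.
    """
    axes = (0,) + tuple(range(2, x.ndim))
    shape = (1, -1) + (1,) * (x.ndim - 2)
    mu = x.data.mean(axis=axes, keepdims=True)
    xc = x.data - mu
    var = (xc * xc).mean(axis=axes, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xn = xc * inv
    g = gamma.data.reshape(shape)
    out = Tensor(xn * g + beta.data.reshape(shape),
                 x.requires_grad or gamma.requires_grad or beta.requires_grad,
                 (x, gamma, beta))
    m = x.data.size // x.data.shape[1]

    def bwd(grad):
        if gamma.requires_grad:
            gamma._accum((grad * xn).sum(axis=axes))
        if beta.requires_grad:
            beta._accum(grad.sum(axis=axes))
        if x.requires_grad:
            gxn = grad * g
            t1 = gxn.mean(axis=axes, keepdims=True)
            t2 = (gxn * xn).mean(axis=axes, keepdims=True)
            x._accum(inv * (gxn - t1 - xn * t2))
    out._backward = bwd
    return out, mu.reshape(-1), var.reshape(-1) * m / max(m - 1, 1)


def prelu(x: Tensor, alpha: Tensor) -> Tensor:
    """Fused per-channel parametric ReLU: y = x if x > 0 else alpha * x."""
    shape = (1, -1) + (1,) * (x.ndim - 2)
    a = alpha.data.reshape(shape)
    neg = x.data < 0
    out = Tensor(np.where(neg, x.data * a, x.data),
                 x.requires_grad or alpha.requires_grad, (x, alpha))

    def bwd(g):
        if x.requires_grad:
            x._accum(np.where(neg, g * a, g))
        if alpha.requires_grad:
            axes = (0,) + tuple(range(2, x.ndim))
            alpha._accum((g * np.where(neg, x.data, 0.0)).sum(axis=axes))
    out._backward = bwd
    return out


# ---------------------------------------------------------------------------
# In-plane pooling / upsampling (2x2 in x-y; the z axis is never pooled)
# ---------------------------------------------------------------------------


def maxpool_inplane(x: Tensor) -> Tensor:
    """2x2 in-plane max pool on (N, C, X, Y[, Z]); X, Y must be even."""
    d = x.data
    has_z = d.ndim == 5
    if not has_z:
        d = d[..., None]
    n, c, X, Y, Z = d.shape
    win = d.reshape(n, c, X // 2, 2, Y // 2, 2, Z).transpose(0, 1, 2, 4, 6, 3, 5)
    win = win.reshape(n, c, X // 2, Y // 2, Z, 4)
    idx = np.argmax(win, axis=-1)
    pooled = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]
    out_data = pooled if has_z else pooled[..., 0]
    out = Tensor(out_data, x.requires_grad, (x,))

    def bwd(g):
        if not x.requires_grad:
            return
        g5 = g if has_z else g[..., None]
        gwin = np.zeros((n, c, X // 2, Y // 2, Z, 4), dtype=g.dtype)
        np.put_along_axis(gwin, idx[..., None], g5[..., None], axis=-1)
        gfull = gwin.reshape(n, c, X // 2, Y // 2, Z, 2, 2).transpose(
            0, 1, 2, 5, 3, 6, 4).reshape(n, c, X, Y, Z)
        x._accum(gfull if has_z else gfull[..., 0])
    out._backward = bwd
    return out


def _up1(d: np.ndarray, axis: int) -> np.ndarray:
    """2x linear upsample along one axis: even samples coincide with the
    input (no phase shift), odd samples are midpoints."""
    up = np.repeat(d, 2, axis=axis)
    n = d.shape[axis]

    def sl(arr, s):
        idx = [slice(None)] * arr.ndim
        idx[axis] = s
        return idx

    lo = d[tuple(sl(d, slice(None, n - 1)))]
    hi = d[tuple(sl(d, slice(1, None)))]
    up[tuple(sl(up, slice(1, -1, 2)))] = 0.5 * (lo + hi)
    return up


def _up1_adjoint(g: np.ndarray, axis: int) -> np.ndarray:
    def sl(arr, s):
        idx = [slice(None)] * arr.ndim
        idx[axis] = s
        return tuple(idx)

    even = g[sl(g, slice(0, None, 2))]
    odd = g[sl(g, slice(1, None, 2))]
    out = even.copy()
    n = out.shape[axis]
    out[sl(out, slice(None, n - 1))] += 0.5 * odd[sl(odd, slice(None, n - 1))]
    out[sl(out, slice(1, None))] += 0.5 * odd[sl(odd, slice(None, n - 1))]
    out[sl(out, slice(n - 1, n))] += odd[sl(odd, slice(n - 1, n))]
    return out


def upsample_inplane(x: Tensor) -> Tensor:
    """2x linear in-plane upsample on (N, C, X, Y[, Z]).

    Linear (not nearest-neighbour) so the upsampled feature map has no
    half-voxel phase shift relative to the input.
    """
    up = _up1(_up1(x.data, 2), 3)
    out = Tensor(up, x.requires_grad, (x,))

    def bwd(g):
        if x.requires_grad:
            x._accum(_up1_adjoint(_up1_adjoint(g, 3), 2))
    out._backward = bwd
    return out


# ---------------------------------------------------------------------------
# Trilinear warping (spatial transformer)
# ---------------------------------------------------------------------------


def warp3d(x: Tensor, u: Tensor) -> Tensor:
    """Backward warp: out(v) = x(v + u(v)) with trilinear interpolation.

    ``x`` is (N, C, X, Y, Z); ``u`` is (N, 3, X, Y, Z) in voxel units.
    Sample positions are clamped to the border (clamp-to-edge); the
    gradient with respect to ``u`` is zero where a coordinate is clamped.
    Differentiable with respect to both arguments.
    """
    xd, ud = x.data, u.data
    n, c, X, Y, Z = xd.shape
    if ud.shape != (n, 3, X, Y, Z):
        raise ValueError(f"field shape {ud.shape} incompatible with {xd.shape}")
    base = np.stack(np.meshgrid(np.arange(X), np.arange(Y), np.arange(Z),
                                indexing="ij")).astype(xd.dtype)     # (3, X, Y, Z)
    pos = ud + base[None]
    dims = np.array([X, Y, Z], dtype=xd.dtype).reshape(1, 3, 1, 1, 1)
    unclamped = (pos >= 0.0) & (pos <= dims - 1.0)
    pos = np.clip(pos, 0.0, dims - 1.0)
    i0 = np.floor(pos).astype(np.int64)
    i0 = np.minimum(i0, (dims - 2).astype(np.int64))  # keep i0+1 in range
    f = pos - i0                                       # (n, 3, X, Y, Z)

    flat = xd.reshape(n, c, -1)
    strides = np.array([Y * Z, Z, 1], dtype=np.int64)

    corners = []
    out_data = np.zeros((n, c, X, Y, Z), dtype=xd.dtype)
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                ii = (i0[:, 0] + dx) * strides[0] + (i0[:, 1] + dy) * strides[1] \
                    + (i0[:, 2] + dz) * strides[2]             # (n, X, Y, Z)
                wx = f[:, 0] if dx else 1.0 - f[:, 0]
                wy = f[:, 1] if dy else 1.0 - f[:, 1]
                wz = f[:, 2] if dz else 1.0 - f[:, 2]
                wgt = wx * wy * wz
                vals = np.take_along_axis(flat, ii.reshape(n, 1, -1), axis=2
                                          ).reshape(n, c, X, Y, Z)
                out_data += wgt[:, None] * vals
                corners.append((dx, dy, dz, ii, wgt, vals))

    out = Tensor(out_data, x.requires_grad or u.requires_grad, (x, u))

    def bwd(g):
        if x.requires_grad:
            dflat = np.zeros((n, c, X * Y * Z), dtype=xd.dtype)
            for dx, dy, dz, ii, wgt, _ in corners:
                contrib = (g * wgt[:, None]).reshape(n, c, -1)
                for b in range(n):
                    np.add.at(dflat[b], (slice(None), ii[b].ravel()),
                              contrib[b])
            x._accum(dflat.reshape(n, c, X, Y, Z))
        if u.requires_grad:
            du = np.zeros((n, 3, X, Y, Z), dtype=ud.dtype)
            for dx, dy, dz, ii, wgt, vals in corners:
                gv = (g * vals).sum(axis=1)                # (n, X, Y, Z)
                wx = f[:, 0] if dx else 1.0 - f[:, 0]
                wy = f[:, 1] if dy else 1.0 - f[:, 1]
                wz = f[:, 2] if dz else 1.0 - f[:, 2]
                sx = 1.0 if dx else -1.0
                sy = 1.0 if dy else -1.0
                sz = 1.0 if dz else -1.0
                du[:, 0] += gv * sx * wy * wz
                du[:, 1] += gv * wx * sy * wz
                du[:, 2] += gv * wx * wy * sz
            du *= unclamped
            u._accum(du)
    out._backward = bwd
    return out
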