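"""Minimal reverse-mode automatic differentiation on numpy arrays.

The registration and labeling networks in this package are small 3-D
convolutional models trained at desk scale on a CPU, so they are built on
this self-contained tape-based engine rather than an external deep-learning
framework.  A :class:`Tensor` wraps an ``ndarray`` together with the
closures needed to backpropagate; operations build the tape implicitly.

Only what the networks need is implemented: broadcasting arithmetic,
matmul, slicing/reshaping/concatenation, ReLU, max-pooling, 3-D convolution
(via im2col), zero-stuffing upsampling, separable linear resizing, sliding
cube means (for the LNCC loss), and differentiable trilinear warping of
images and point sets by a displacement field.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=float)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    # -- graph construction helpers -------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    # -- arithmetic ------------------------------------------------------
    @staticmethod
    def _coerce(x):
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._coerce(other)

        def back(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        return Tensor._make(self.data + other.data, (self, other), back)

    __radd__ = __add__

    def __neg__(self):
        def back(g):
            if self.requires_grad:
                self._accumulate(-g)

        return Tensor._make(-self.data, (self,), back)

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)

        def back(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(self.data * other.data, (self, other), back)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)

        def back(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        return Tensor._make(self.data / other.data, (self, other), back)

    def __rtruediv__(self, other):
        return self._coerce(other) / self

    def __pow__(self, exponent: float):
        def back(g):
            if self.requires_grad:
                self._accumulate(g * exponent * self.data ** (exponent - 1))

        return Tensor._make(self.data**exponent, (self,), back)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def back(g):
            if self.requires_grad:
                self._accumulate(g * 0.5 / np.maximum(out_data, 1e-300))

        return Tensor._make(out_data, (self,), back)

    def exp(self):
        out_data = np.exp(self.data)

        def back(g):
            if self.requires_grad:
                self._accumulate(g * out_data)

        return Tensor._make(out_data, (self,), back)

    def log(self):
        def back(g):
            if self.requires_grad:
                self._accumulate(g / self.data)

        return Tensor._make(np.log(self.data), (self,), back)

    def relu(self):
        mask = self.data > 0

        def back(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        return Tensor._make(self.data * mask, (self,), back)

    def clip_min(self, floor: float):
        mask = self.data > floor

        def back(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        return Tensor._make(np.maximum(self.data, floor), (self,), back)

    # -- reductions / shaping ---------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def back(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(gg, self.data.shape).copy())

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), back)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            count = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            count = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape

        def back(g):
            if self.requires_grad:
                self._accumulate(g.reshape(old))

        return Tensor._make(self.data.reshape(shape), (self,), back)

    def transpose(self, axes):
        inv = np.argsort(axes)

        def back(g):
            if self.requires_grad:
                self._accumulate(g.transpose(inv))

        return Tensor._make(self.data.transpose(axes), (self,), back)

    def __getitem__(self, key):
        def back(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, key, g)
                self._accumulate(full)

        return Tensor._make(self.data[key], (self,), back)

    def __matmul__(self, other):
        other = self._coerce(other)

        def back(g):
            if self.requires_grad:
                self._accumulate(g @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ g)

        return Tensor._make(self.data @ other.data, (self, other), back)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._coerce(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def back(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accumulate(piece)

    return Tensor._make(
        np.concatenate([t.data for t in tensors], axis=axis), tensors, back
    )


# ---------------------------------------------------------------------------
# spatial operations (channel-first volumes: (C, X, Y, Z))


def conv3d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """'Same' 3-D convolution, kernel 3, via im2col + matmul.

    ``x`` is (Cin, X, Y, Z), ``w`` is (Cout, Cin, 3, 3, 3), ``b`` (Cout,).
    """
    cin, X, Y, Z = x.data.shape
    cout = w.data.shape[0]
    xp = np.pad(x.data, ((0, 0), (1, 1), (1, 1), (1, 1)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3, 3), axis=(1, 2, 3))
    # win: (Cin, X, Y, Z, 3, 3, 3) -> cols (X*Y*Z, Cin*27)
    cols = win.transpose(1, 2, 3, 0, 4, 5, 6).reshape(X * Y * Z, cin * 27)
    w2 = w.data.reshape(cout, cin * 27)
    out = (cols @ w2.T).T.reshape(cout, X, Y, Z)
    if b is not None:
        out = out + b.data.reshape(cout, 1, 1, 1)

    parents = (x, w) if b is None else (x, w, b)

    def back(g):
        g2 = g.reshape(cout, X * Y * Z)
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(1, 2, 3)))
        if w.requires_grad:
            w._accumulate((g2 @ cols).reshape(w.data.shape))
        if x.requires_grad:
            dcols = (g2.T @ w2).reshape(X, Y, Z, cin, 3, 3, 3)
            dxp = np.zeros_like(xp)
            for i in range(3):
                for j in range(3):
                    for k in range(3):
                        dxp[:, i : i + X, j : j + Y, k : k + Z] += dcols[
                            ..., i, j, k
                        ].transpose(3, 0, 1, 2)
            x._accumulate(dxp[:, 1:-1, 1:-1, 1:-1])

    return Tensor._make(out, parents, back)


def conv3d_1x1(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Pointwise convolution: ``w`` is (Cout, Cin)."""
    cin = x.data.shape[0]
    flat = x.reshape(cin, -1)
    out = w @ flat
    if b is not None:
        out = out + b.reshape(-1, 1)
    return out.reshape((w.data.shape[0],) + x.data.shape[1:])


def zero_upsample2(x: Tensor) -> Tensor:
    """Insert zeros to double each spatial dimension of (C, X, Y, Z)."""
    c, X, Y, Z = x.data.shape
    out = np.zeros((c, 2 * X, 2 * Y, 2 * Z))
    out[:, ::2, ::2, ::2] = x.data

    def back(g):
        if x.requires_grad:
            x._accumulate(g[:, ::2, ::2, ::2])

    return Tensor._make(out, (x,), back)


def maxpool2(x: Tensor) -> Tensor:
    """2x2x2 max pooling of (C, X, Y, Z); dimensions must be even."""
    c, X, Y, Z = x.data.shape
    if X % 2 or Y % 2 or Z % 2:
        raise ValueError("spatial dimensions must be even for 2^3 pooling")
    win = x.data.reshape(c, X // 2, 2, Y // 2, 2, Z // 2, 2)
    win = win.transpose(0, 1, 3, 5, 2, 4, 6).reshape(c, X // 2, Y // 2, Z // 2, 8)
    idx = win.argmax(axis=-1)
    out = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]

    def back(g):
        if not x.requires_grad:
            return
        dwin = np.zeros((c, X // 2, Y // 2, Z // 2, 8))
        np.put_along_axis(dwin, idx[..., None], g[..., None], axis=-1)
        dwin = dwin.reshape(c, X // 2, Y // 2, Z // 2, 2, 2, 2)
        dx = dwin.transpose(0, 1, 4, 2, 5, 3, 6).reshape(c, X, Y, Z)
        x._accumulate(dx)

    return Tensor._make(out, (x,), back)


def _linear_resize_matrix(src: int, dst: int) -> np.ndarray:
    """Dense (dst, src) linear-interpolation matrix (endpoint-aligned)."""
    m = np.zeros((dst, src))
    if src == 1:
        m[:, 0] = 1.0
        return m
    pos = np.linspace(0.0, src - 1, dst) if dst > 1 else np.array([(src - 1) / 2])
    lo = np.floor(pos).astype(int)
    hi = np.minimum(lo + 1, src - 1)
    frac = pos - lo
    m[np.arange(dst), lo] += 1 - frac
    m[np.arange(dst), hi] += frac
    return m


def resize_linear(x: Tensor, out_shape: tuple) -> Tensor:
    """Separable (tri)linear resize of (C, X, Y, Z) to (C, *out_shape)."""
    mats = [
        _linear_resize_matrix(s, t) for s, t in zip(x.data.shape[1:], out_shape)
    ]

    def apply(data, ms):
        for axis, m in enumerate(ms, start=1):
            data = np.moveaxis(
                np.tensordot(m, data, axes=(1, axis)), 0, axis
            )
        return data

    out = apply(x.data, mats)

    def back(g):
        if x.requires_grad:
            x._accumulate(apply(g, [m.T for m in mats]))

    return Tensor._make(out, (x,), back)


def box_mean(x: Tensor, n: int) -> Tensor:
    """Sliding-cube mean over windows anchored at each voxel of (X, Y, Z).

    Windows are clipped at the far border; matches
    :func:`neuralign.losses.sliding_mean`.
    """
    from ..losses import sliding_sum, _window_counts

    counts = _window_counts(x.data.shape, n)
    out = sliding_sum(x.data, n) / counts

    def back(g):
        if not x.requires_grad:
            return
        # transpose of the clipped anchored box filter: reverse-anchored sum
        gg = (g / counts)[::-1, ::-1, ::-1]
        x._accumulate(sliding_sum(gg, n)[::-1, ::-1, ::-1])

    return Tensor._make(out, (x,), back)


# ---------------------------------------------------------------------------
# differentiable warping by a displacement field


def _trilinear_setup(vol: np.ndarray, coords: np.ndarray):
    """Corner indices/weights for trilinear sampling with zero-padding.

    ``coords`` is (..., 3) in voxel units of ``vol``; a one-voxel zero
    border emulates zero fill, and far-out coordinates clamp onto it.
    """
    padded = np.pad(np.asarray(vol, dtype=float), 1)
    shifted = coords + 1.0
    upper = np.array(padded.shape) - 2 + 0.999999
    clamped = np.clip(shifted, 1e-6, upper)
    lo = np.floor(clamped).astype(int)
    frac = clamped - lo
    return padded, lo, frac


def warp_volume(moving: np.ndarray, ddf: Tensor) -> Tensor:
    """Trilinearly sample ``moving`` at ``p + ddf[p]``; gradient flows to ddf.

    ``moving`` is a constant (X, Y, Z) array, ``ddf`` an (X, Y, Z, 3)
    tensor; out-of-bounds samples evaluate to 0.
    """
    shape = moving.shape
    base = np.stack(
        np.meshgrid(*(np.arange(s, dtype=float) for s in shape), indexing="ij"),
        axis=-1,
    )
    coords = base + ddf.data
    # match the reference warp: any sample outside [0, S-1] is 0 (no blend)
    inside = np.ones(shape, dtype=bool)
    for m, s in enumerate(shape):
        inside &= (coords[..., m] >= 0) & (coords[..., m] <= s - 1)
    padded, lo, frac = _trilinear_setup(moving, coords)
    fx, fy, fz = frac[..., 0], frac[..., 1], frac[..., 2]
    corners = {}
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                corners[(dx, dy, dz)] = padded[
                    lo[..., 0] + dx, lo[..., 1] + dy, lo[..., 2] + dz
                ]
    wx = (1 - fx, fx)
    wy = (1 - fy, fy)
    wz = (1 - fz, fz)
    out = np.zeros(shape)
    for (dx, dy, dz), v in corners.items():
        out += v * wx[dx] * wy[dy] * wz[dz]
    out *= inside

    def back(g):
        if not ddf.requires_grad:
            return
        sx = (-1.0, 1.0)
        dval = np.zeros(shape + (3,))
        for (dx, dy, dz), v in corners.items():
            dval[..., 0] += v * sx[dx] * wy[dy] * wz[dz]
            dval[..., 1] += v * wx[dx] * sx[dy] * wz[dz]
            dval[..., 2] += v * wx[dx] * wy[dy] * sx[dz]
        ddf._accumulate((g * inside)[..., None] * dval)

    return Tensor._make(out, (ddf,), back)


def warp_points(points: np.ndarray, ddf: Tensor) -> Tensor:
    """Map fixed-grid points to ``p + ddf(p)``; gradient flows to ddf.

    The DDF is trilinearly interpolated at each (possibly fractional)
    point; points are constants.
    """
    points = np.asarray(points, dtype=float)
    shape = ddf.data.shape[:3]
    upper = np.array(shape, dtype=float) - 1
    clamped = np.clip(points, 0, upper)
    # clamp interpolation cell to the grid
    lo = np.minimum(np.floor(clamped).astype(int), np.array(shape) - 2)
    lo = np.maximum(lo, 0)
    frac = clamped - lo
    wx = (1 - frac[:, 0], frac[:, 0])
    wy = (1 - frac[:, 1], frac[:, 1])
    wz = (1 - frac[:, 2], frac[:, 2])
    weights = []
    disp = np.zeros_like(points)
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                wgt = wx[dx] * wy[dy] * wz[dz]
                weights.append(((dx, dy, dz), wgt))
                disp += wgt[:, None] * ddf.data[
                    lo[:, 0] + dx, lo[:, 1] + dy, lo[:, 2] + dz
                ]
    out = points + disp

    def back(g):
        if not ddf.requires_grad:
            return
        full = np.zeros_like(ddf.data)
        for (dx, dy, dz), wgt in weights:
            np.add.at(
                full,
                (lo[:, 0] + dx, lo[:, 1] + dy, lo[:, 2] + dz),
                g * wgt[:, None],
            )
        ddf._accumulate(full)

    return Tensor._make(out, (ddf,), back)


def log_softmax(x: Tensor, axis: int = 0) -> Tensor:
    """Numerically stable log-softmax along ``axis``."""
    shift = Tensor(x.data.max(axis=axis, keepdims=True))  # constant shift
    z = x - shift
    return z - z.exp().sum(axis=axis, keepdims=True).log()
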