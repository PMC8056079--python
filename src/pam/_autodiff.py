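"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the registration and slice-ordering
networks need: broadcast arithmetic, matmul, reductions, indexing,
concatenation, ReLU/sigmoid/exp/log/sqrt, strided 2-D/3-D convolution,
strided transposed 3-D convolution, box-filter smoothing and trilinear
warping of volumes by a displacement field. Gradients are accumulated
by a topological-order sweep; every primitive is finite-difference
checked in the test suite.

Arrays are kept in float64 throughout: the volumes involved are small
(desk-scale 32-64 voxels per axis), so accuracy is cheaper than speed.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndim_extra = grad.ndim - len(shape)
    if ndim_extra > 0:
        grad = grad.sum(axis=tuple(range(ndim_extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with a gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward",
                 "_grad_borrowed")
    __array_priority__ = 100  # so ndarray + Tensor defers to us

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple = (), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None
        self._grad_borrowed = False

    # -- graph plumbing ---------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accum(self, grad: np.ndarray) -> None:
        # First accumulation borrows the incoming array; a copy is made
        # only if a second contribution arrives (avoids one full-size
        # copy per node on the common single-consumer path).
        if self.grad is None:
            self.grad = np.asarray(grad, dtype=np.float64)
            self._grad_borrowed = True
        else:
            if self._grad_borrowed:
                self.grad = self.grad.copy()
                self._grad_borrowed = False
            self.grad += grad

    def backward(self) -> None:
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
        self._accum(np.ones_like(self.data))
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    def zero_grad(self) -> None:
        self.grad = None

    def item(self) -> float:
        return float(self.data)

    # -- arithmetic --------------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._lift(other)

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return Tensor(self.data + other.data, parents=(self, other), backward=bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            self._accum(-g)

        return Tensor(-self.data, parents=(self,), backward=bwd)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        return Tensor(self.data * other.data, parents=(self, other), backward=bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return self._lift(other) * self ** -1.0

    def __pow__(self, exponent: float):
        out_data = self.data ** exponent

        def bwd(g):
            self._accum(g * exponent * self.data ** (exponent - 1.0))

        return Tensor(out_data, parents=(self,), backward=bwd)

    def __matmul__(self, other):
        other = self._lift(other)

        def bwd(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        return Tensor(self.data @ other.data, parents=(self, other), backward=bwd)

    # -- shape ops ---------------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])

        def bwd(g):
            self._accum(g.reshape(self.shape))

        return Tensor(self.data.reshape(shape), parents=(self,), backward=bwd)

    def transpose(self, *axes):
        if not axes:
            axes = tuple(range(self.ndim))[::-1]
        inv = np.argsort(axes)

        def bwd(g):
            self._accum(g.transpose(inv))

        return Tensor(self.data.transpose(axes), parents=(self,), backward=bwd)

    def __getitem__(self, idx):
        def bwd(g):
            full = np.zeros_like(self.data)
            full[idx] = g
            self._accum(full)

        return Tensor(self.data[idx], parents=(self,), backward=bwd)

    @staticmethod
    def concat(tensors, axis: int = 0):
        tensors = [Tensor._lift(t) for t in tensors]
        sizes = [t.shape[axis] for t in tensors]
        offsets = np.cumsum([0] + sizes)

        def bwd(g):
            for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
                if t.requires_grad:
                    sl = [slice(None)] * g.ndim
                    sl[axis] = slice(a, b)
                    t._accum(g[tuple(sl)])

        return Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                      parents=tuple(tensors), backward=bwd)

    # -- reductions ---------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape))

        return Tensor(out_data, parents=(self,), backward=bwd)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- nonlinearities ------------------------------------------------------

    def relu(self):
        mask = self.data > 0

        def bwd(g):
            self._accum(g * mask)

        return Tensor(self.data * mask, parents=(self,), backward=bwd)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500)))

        def bwd(g):
            self._accum(g * out_data * (1.0 - out_data))

        return Tensor(out_data, parents=(self,), backward=bwd)

    def exp(self):
        out_data = np.exp(self.data)

        def bwd(g):
            self._accum(g * out_data)

        return Tensor(out_data, parents=(self,), backward=bwd)

    def log(self):
        def bwd(g):
            self._accum(g / self.data)

        return Tensor(np.log(self.data), parents=(self,), backward=bwd)

    def sqrt(self):
        return self ** 0.5

    # -- convolutions --------------------------------------------------------
    # Implemented as a sum over kernel offsets: cheap at desk-scale shapes
    # and trivially adjoint-consistent.

    def conv3d(self, weight: "Tensor", bias: "Tensor" = None,
               stride: int = 1, padding: int = 1):
        """3-D convolution. self: (N,Ci,D,H,W); weight: (Co,Ci,k,k,k)."""
        return _convnd(self, weight, bias, stride, padding, ndim_sp=3)

    def conv2d(self, weight: "Tensor", bias: "Tensor" = None,
               stride: int = 1, padding: int = 1):
        """2-D convolution. self: (N,Ci,H,W); weight: (Co,Ci,k,k)."""
        return _convnd(self, weight, bias, stride, padding, ndim_sp=2)

    def conv_transpose3d(self, weight: "Tensor", bias: "Tensor" = None,
                         stride: int = 2):
        """Transposed 3-D convolution, kernel == stride (non-overlapping
        upsampling). self: (N,Ci,D,H,W); weight: (Ci,Co,s,s,s)."""
        return _conv_transpose3d(self, weight, bias, stride)

    def box_smooth(self, kernel: int):
        """Spatial box-filter smoothing (average pooling with stride 1,
        zero padding, same output size) over the trailing 3 axes."""
        return _box_smooth(self, kernel)

    def warp3d(self, flow: "Tensor"):
        """Trilinear warp. self: (N,C,D,H,W); flow: (N,3,D,H,W) voxel
        displacements; out(x) = self(x + flow(x)), zero outside."""
        return _warp3d(self, flow)


def _convnd(x: Tensor, weight: Tensor, bias, stride: int, padding: int,
            ndim_sp: int) -> Tensor:
    sp = "dhw" if ndim_sp == 3 else "hw"
    fwd_sub = f"nc{sp},oc->no{sp}"
    gx_sub = f"no{sp},oc->nc{sp}"
    gw_sub = f"no{sp},nc{sp}->oc"
    k = weight.shape[2]
    pad_width = ((0, 0), (0, 0)) + ((padding, padding),) * ndim_sp
    xp = np.pad(x.data, pad_width) if padding else x.data
    sp_in = xp.shape[2:]
    sp_out = tuple((s - k) // stride + 1 for s in sp_in)
    n, co = x.shape[0], weight.shape[0]
    out = np.zeros((n, co) + sp_out)
    offsets = np.ndindex(*((k,) * ndim_sp))
    slices = {}
    for off in offsets:
        sl = tuple(slice(o, o + stride * so, stride)
                   for o, so in zip(off, sp_out))
        slices[off] = sl
        out += np.einsum(fwd_sub, xp[(slice(None), slice(None)) + sl],
                         weight.data[(slice(None), slice(None)) + off])
    if bias is not None:
        out += bias.data.reshape((1, co) + (1,) * ndim_sp)

    def bwd(g):
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for off, sl in slices.items():
                gxp[(slice(None), slice(None)) + sl] += np.einsum(
                    gx_sub, g, weight.data[(slice(None), slice(None)) + off])
            if padding:
                core = (slice(None), slice(None)) + tuple(
                    slice(padding, padding + s) for s in x.shape[2:])
                gxp = gxp[core]
            x._accum(gxp)
        if weight.requires_grad:
            gw = np.zeros_like(weight.data)
            for off, sl in slices.items():
                gw[(slice(None), slice(None)) + off] = np.einsum(
                    gw_sub, g, xp[(slice(None), slice(None)) + sl])
            weight._accum(gw)
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=(0,) + tuple(range(2, g.ndim))))

    parents = (x, weight) + ((bias,) if bias is not None else ())
    return Tensor(out, parents=parents, backward=bwd)


def _conv_transpose3d(x: Tensor, weight: Tensor, bias, stride: int) -> Tensor:
    n, ci, d, h, w = x.shape
    co = weight.shape[1]
    s = stride
    out = np.zeros((n, co, d * s, h * s, w * s))
    for off in np.ndindex(s, s, s):
        sl = tuple(slice(o, None, s) for o in off)
        out[(slice(None), slice(None)) + sl] = np.einsum(
            "ncdhw,co->nodhw", x.data,
            weight.data[(slice(None), slice(None)) + off])
    if bias is not None:
        out += bias.data.reshape(1, co, 1, 1, 1)

    def bwd(g):
        if x.requires_grad:
            gx = np.zeros_like(x.data)
            for off in np.ndindex(s, s, s):
                sl = tuple(slice(o, None, s) for o in off)
                gx += np.einsum(
                    "nodhw,co->ncdhw", g[(slice(None), slice(None)) + sl],
                    weight.data[(slice(None), slice(None)) + off])
            x._accum(gx)
        if weight.requires_grad:
            gw = np.zeros_like(weight.data)
            for off in np.ndindex(s, s, s):
                sl = tuple(slice(o, None, s) for o in off)
                gw[(slice(None), slice(None)) + off] = np.einsum(
                    "nodhw,ncdhw->co", g[(slice(None), slice(None)) + sl],
                    x.data)
            weight._accum(gw)
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2, 3, 4)))

    parents = (x, weight) + ((bias,) if bias is not None else ())
    return Tensor(out, parents=parents, backward=bwd)


def _box_kernel_filter(a: np.ndarray, k: int) -> np.ndarray:
    from scipy.ndimage import uniform_filter
    sp_axes = tuple(range(a.ndim - 3, a.ndim))
    return uniform_filter(a, size=k, axes=sp_axes, mode="constant", cval=0.0)


def _box_smooth(x: Tensor, kernel: int) -> Tensor:
    if kernel <= 1:
        return x
    out = _box_kernel_filter(x.data, kernel)

    def bwd(g):
        # symmetric kernel + zero padding makes the operator self-adjoint
        x._accum(_box_kernel_filter(g, kernel))

    return Tensor(out, parents=(x,), backward=bwd)


def _warp3d(vol: Tensor, flow: Tensor) -> Tensor:
    n, c, d, h, w = vol.shape
    base = np.stack(np.meshgrid(np.arange(d), np.arange(h), np.arange(w),
                                indexing="ij"))  # (3,D,H,W)
    coords = flow.data + base[None]  # (N,3,D,H,W)
    i0 = np.floor(coords).astype(np.int64)
    frac = coords - i0
    dims = np.array([d, h, w]).reshape(1, 3, 1, 1, 1)

    corner_cache = []
    out = np.zeros((n, c, d, h, w))
    for off in np.ndindex(2, 2, 2):
        off_arr = np.array(off).reshape(1, 3, 1, 1, 1)
        idx = i0 + off_arr  # (N,3,D,H,W)
        valid = np.all((idx >= 0) & (idx < dims), axis=1)  # (N,D,H,W)
        idx_c = np.clip(idx, 0, dims - 1)
        # per-axis weights: frac if corner at +1 else 1-frac
        wgt_axes = np.where(off_arr == 1, frac, 1.0 - frac)  # (N,3,D,H,W)
        wgt = wgt_axes.prod(axis=1) * valid  # (N,D,H,W)
        flat = (idx_c[:, 0] * h + idx_c[:, 1]) * w + idx_c[:, 2]  # (N,D,H,W)
        vol_flat = vol.data.reshape(n, c, -1)
        vals = np.empty((n, c, d, h, w))
        for b in range(n):
            vals[b] = vol_flat[b][:, flat[b].ravel()].reshape(c, d, h, w)
        out += wgt[:, None] * vals
        corner_cache.append((off_arr, valid, flat, wgt, wgt_axes, vals))

    def bwd(g):
        if vol.requires_grad:
            gvol = np.zeros((n, c, d * h * w))
            for off_arr, valid, flat, wgt, _, _ in corner_cache:
                contrib = (g * wgt[:, None]).reshape(n, c, -1)
                fl = flat.reshape(n, -1)
                for b in range(n):
                    np.add.at(gvol[b].T, fl[b], contrib[b].T)
            vol._accum(gvol.reshape(vol.shape))
        if flow.requires_grad:
            gflow = np.zeros_like(flow.data)
            for off_arr, valid, flat, wgt, wgt_axes, vals in corner_cache:
                gv = (g * vals).sum(axis=1) * valid  # (N,D,H,W)
                for ax in range(3):
                    others = [a for a in range(3) if a != ax]
                    w_other = wgt_axes[:, others[0]] * wgt_axes[:, others[1]]
                    sign = np.where(off_arr[0, ax, 0, 0, 0] == 1, 1.0, -1.0)
                    gflow[:, ax] += gv * w_other * sign
            flow._accum(gflow)

    return Tensor(out, parents=(vol, flow), backward=bwd)


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params, lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
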