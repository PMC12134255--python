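"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operator set needed by the segmentation and
classification networks in this package: broadcasting arithmetic, batched
matmul, 2-D convolution / max-pooling / nearest upsampling, slicing,
concatenation, and the usual pointwise nonlinearities.  Gradients are
accumulated on every node of the graph (not only leaves) so intermediate
activations can be inspected, e.g. for Grad-CAM.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "cat", "conv2d", "maxpool2d", "upsample2x_nearest"]

DEFAULT_DTYPE = np.float32


def _as_array(data, dtype=None):
    arr = np.asarray(data)
    if arr.dtype.kind != "f":
        arr = arr.astype(dtype or DEFAULT_DTYPE)
    elif dtype is not None:
        arr = arr.astype(dtype)
    return arr


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
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad=False, _parents=(), _backward=None):
        self.data = _as_array(data)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _parents)
        self._parents = _parents if self.requires_grad else ()
        self._backward = _backward if self.requires_grad else None

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(node):
            if id(node) in seen:
                return
            seen.add(id(node))
            for p in node._parents:
                visit(p)
            topo.append(node)

        visit(self)
        for node in topo:
            node.grad = None
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad):
        grad = np.asarray(grad)
        self.grad = grad if self.grad is None else self.grad + grad

    def _coerce(self, other) -> "Tensor":
        """Wrap non-Tensor operands; plain numbers adopt this tensor's dtype
        so scalar constants never promote float32 graphs to float64."""
        if isinstance(other, Tensor):
            return other
        if isinstance(other, (int, float)):
            return Tensor(np.asarray(other, dtype=self.data.dtype))
        return Tensor(other)

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = self._coerce(other)
        out = Tensor(self.data + other.data, _parents=(self, other))

        def bwd(g):
            self._accum(_unbroadcast(g, self.data.shape))
            other._accum(_unbroadcast(g, other.data.shape))

        out._backward = bwd
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = self._coerce(other)
        out = Tensor(self.data * other.data, _parents=(self, other))

        def bwd(g):
            self._accum(_unbroadcast(g * other.data, self.data.shape))
            other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __truediv__(self, other):
        other = self._coerce(other)
        out = Tensor(self.data / other.data, _parents=(self, other))

        def bwd(g):
            self._accum(_unbroadcast(g / other.data, self.data.shape))
            other._accum(_unbroadcast(-g * self.data / other.data ** 2,
                                      other.data.shape))

        out._backward = bwd
        return out

    def __rtruediv__(self, other):
        return self._coerce(other) / self

    def __pow__(self, exponent: float):
        out = Tensor(self.data ** exponent, _parents=(self,))

        def bwd(g):
            self._accum(g * exponent * self.data ** (exponent - 1.0))

        out._backward = bwd
        return out

    def __matmul__(self, other):
        other = self._coerce(other)
        out = Tensor(self.data @ other.data, _parents=(self, other))

        def bwd(g):
            ga = g @ np.swapaxes(other.data, -1, -2)
            gb = np.swapaxes(self.data, -1, -2) @ g
            self._accum(_unbroadcast(ga, self.data.shape))
            other._accum(_unbroadcast(gb, other.data.shape))

        out._backward = bwd
        return out

    # -------------------------------------------------------------- pointwise
    def exp(self):
        out = Tensor(np.exp(self.data), _parents=(self,))
        out._backward = lambda g: self._accum(g * out.data)
        return out

    def log(self):
        out = Tensor(np.log(self.data), _parents=(self,))
        out._backward = lambda g: self._accum(g / self.data)
        return out

    def sqrt(self):
        return self ** 0.5

    def sin(self):
        out = Tensor(np.sin(self.data), _parents=(self,))
        out._backward = lambda g: self._accum(g * np.cos(self.data))
        return out

    def cos(self):
        out = Tensor(np.cos(self.data), _parents=(self,))
        out._backward = lambda g: self._accum(g * -np.sin(self.data))
        return out

    def tanh(self):
        out = Tensor(np.tanh(self.data), _parents=(self,))
        out._backward = lambda g: self._accum(g * (1.0 - out.data ** 2))
        return out

    def sigmoid(self):
        x = self.data
        val = np.empty_like(x)
        pos = x >= 0
        val[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
        ex = np.exp(x[~pos])
        val[~pos] = ex / (1.0 + ex)
        out = Tensor(val, _parents=(self,))
        out._backward = lambda g: self._accum(g * out.data * (1.0 - out.data))
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), _parents=(self,))
        out._backward = lambda g: self._accum(g * (self.data > 0))
        return out

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient passes only through the interior."""
        out = Tensor(np.clip(self.data, lo, hi), _parents=(self,))
        inside = (self.data > lo) & (self.data < hi)
        out._backward = lambda g: self._accum(g * inside)
        return out

    # ------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _parents=(self,))

        def bwd(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # ----------------------------------------------------------------- shapes
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), _parents=(self,))
        out._backward = lambda g: self._accum(g.reshape(self.data.shape))
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), _parents=(self,))
        out._backward = lambda g: self._accum(g.transpose(inv))
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], _parents=(self,))

        def bwd(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)

        out._backward = bwd
        return out


# ---------------------------------------------------------------- structural
def cat(tensors, axis=0) -> Tensor:
    tensors = list(tensors)
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 _parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(a, b)
            t._accum(g[tuple(sl)])

    out._backward = bwd
    return out


def _pad2d(x: np.ndarray, p: int, value=0.0) -> np.ndarray:
    if p == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)), constant_values=value)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, padding: int = 0,
           groups: int = 1) -> Tensor:
    """Stride-1 cross-correlation: x (N,C,H,W), w (O,C/groups,k,k)."""
    N, C, H, W = x.data.shape
    O, Cg, kh, kw = w.data.shape
    xp = _pad2d(x.data, padding)
    Ho, Wo = H + 2 * padding - kh + 1, W + 2 * padding - kw + 1
    out_data = np.zeros((N, O, Ho, Wo), dtype=x.data.dtype)
    if groups == 1:
        for ki in range(kh):
            for kj in range(kw):
                out_data += np.einsum(
                    "nchw,oc->nohw",
                    xp[:, :, ki:ki + Ho, kj:kj + Wo], w.data[:, :, ki, kj],
                    optimize=True)
    else:
        gc_in, gc_out = C // groups, O // groups
        for gidx in range(groups):
            xs = xp[:, gidx * gc_in:(gidx + 1) * gc_in]
            ws = w.data[gidx * gc_out:(gidx + 1) * gc_out]
            for ki in range(kh):
                for kj in range(kw):
                    out_data[:, gidx * gc_out:(gidx + 1) * gc_out] += np.einsum(
                        "nchw,oc->nohw",
                        xs[:, :, ki:ki + Ho, kj:kj + Wo], ws[:, :, ki, kj],
                        optimize=True)
    if b is not None:
        out_data += b.data.reshape(1, O, 1, 1)
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(out_data, _parents=parents)

    def bwd(g):
        gx = np.zeros_like(xp)
        gw = np.zeros_like(w.data)
        if groups == 1:
            for ki in range(kh):
                for kj in range(kw):
                    gx[:, :, ki:ki + Ho, kj:kj + Wo] += np.einsum(
                        "nohw,oc->nchw", g, w.data[:, :, ki, kj], optimize=True)
                    gw[:, :, ki, kj] = np.einsum(
                        "nohw,nchw->oc", g, xp[:, :, ki:ki + Ho, kj:kj + Wo],
                        optimize=True)
        else:
            gc_in, gc_out = C // groups, O // groups
            for gidx in range(groups):
                xs = xp[:, gidx * gc_in:(gidx + 1) * gc_in]
                gs = g[:, gidx * gc_out:(gidx + 1) * gc_out]
                ws = w.data[gidx * gc_out:(gidx + 1) * gc_out]
                for ki in range(kh):
                    for kj in range(kw):
                        gx[:, gidx * gc_in:(gidx + 1) * gc_in,
                           ki:ki + Ho, kj:kj + Wo] += np.einsum(
                            "nohw,oc->nchw", gs, ws[:, :, ki, kj], optimize=True)
                        gw[gidx * gc_out:(gidx + 1) * gc_out, :, ki, kj] = np.einsum(
                            "nohw,nchw->oc", gs,
                            xs[:, :, ki:ki + Ho, kj:kj + Wo], optimize=True)
        if padding:
            gx = gx[:, :, padding:-padding, padding:-padding]
        x._accum(gx)
        w._accum(gw)
        if b is not None:
            b._accum(g.sum(axis=(0, 2, 3)))

    out._backward = bwd
    return out


def maxpool2d(x: Tensor, kernel: int, stride: int, padding: int = 0) -> Tensor:
    N, C, H, W = x.data.shape
    xp = _pad2d(x.data, padding, value=-np.inf)
    Hp, Wp = xp.shape[2], xp.shape[3]
    Ho = (Hp - kernel) // stride + 1
    Wo = (Wp - kernel) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (kernel, kernel), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]          # (N,C,Ho,Wo,k,k)
    flat = win.reshape(N, C, Ho, Wo, kernel * kernel)
    arg = flat.argmax(axis=-1)
    out = Tensor(np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0],
                 _parents=(x,))

    def bwd(g):
        gx = np.zeros_like(xp)
        ki, kj = np.divmod(arg, kernel)
        ii = np.arange(Ho)[:, None] * stride + ki
        jj = np.arange(Wo)[None, :] * stride + kj
        n_idx = np.arange(N)[:, None, None, None]
        c_idx = np.arange(C)[None, :, None, None]
        np.add.at(gx, (n_idx, c_idx, ii, jj), g)
        if padding:
            gx = gx[:, :, padding:-padding, padding:-padding]
        x._accum(gx)

    out._backward = bwd
    return out


def upsample2x_nearest(x: Tensor) -> Tensor:
    out = Tensor(x.data.repeat(2, axis=2).repeat(2, axis=3), _parents=(x,))

    def bwd(g):
        N, C, H2, W2 = g.shape
        x._accum(g.reshape(N, C, H2 // 2, 2, W2 // 2, 2).sum(axis=(3, 5)))

    out._backward = bwd
    return out
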