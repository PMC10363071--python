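"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the translation networks need: broadcasted
arithmetic, matmul, reductions, element-wise nonlinearities, concatenation,
padding/slicing, zero-insertion (for strided transpose convolution) and
N-dimensional convolution implemented as an im2col matrix product.  Gradients
are accumulated by topological traversal of the recorded graph.

All tensors are float64; batches use the (N, C, *spatial) layout.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["Tensor", "concat", "convnd", "conv_transpose_nd"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @classmethod
    def _from_op(cls, data, parents, backward) -> "Tensor":
        out = cls(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- basic protocol -------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __float__(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    # -- autodiff engine ------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
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
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray):
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.data.shape))

        return Tensor._from_op(a.data + b.data, (a, b), backward)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def backward(g):
            if a.requires_grad:
                a._accum(-g)

        return Tensor._from_op(-a.data, (a,), backward)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.data.shape))

        return Tensor._from_op(a.data * b.data, (a, b), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return self._wrap(other) * self ** -1.0

    def __pow__(self, exponent: float):
        a = self
        out_data = a.data ** exponent

        def backward(g):
            if a.requires_grad:
                a._accum(g * exponent * a.data ** (exponent - 1.0))

        return Tensor._from_op(out_data, (a,), backward)

    def __matmul__(self, other):
        other = self._wrap(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accum(g @ b.data.T)
            if b.requires_grad:
                b._accum(a.data.T @ g)

        return Tensor._from_op(a.data @ b.data, (a, b), backward)

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        a = self

        def backward(g):
            if not a.requires_grad:
                return
            if axis is None:
                a._accum(np.broadcast_to(g, a.data.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            a._accum(np.broadcast_to(g, a.data.shape).copy())

        return Tensor._from_op(a.data.sum(axis=axis, keepdims=keepdims), (a,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = math.prod(self.data.shape[ax] for ax in axes)
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- element-wise nonlinearities ------------------------------------------
    def abs(self):
        a = self

        def backward(g):
            if a.requires_grad:
                a._accum(g * np.sign(a.data))

        return Tensor._from_op(np.abs(a.data), (a,), backward)

    def log(self):
        a = self

        def backward(g):
            if a.requires_grad:
                a._accum(g / a.data)

        return Tensor._from_op(np.log(a.data), (a,), backward)

    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def backward(g):
            if a.requires_grad:
                a._accum(g * out_data)

        return Tensor._from_op(out_data, (a,), backward)

    def sigmoid(self):
        a = self
        out_data = 1.0 / (1.0 + np.exp(-a.data))

        def backward(g):
            if a.requires_grad:
                a._accum(g * out_data * (1.0 - out_data))

        return Tensor._from_op(out_data, (a,), backward)

    def leaky_relu(self, alpha: float = 0.2):
        a = self
        pos = a.data > 0

        def backward(g):
            if a.requires_grad:
                a._accum(g * np.where(pos, 1.0, alpha))

        return Tensor._from_op(np.where(pos, a.data, alpha * a.data), (a,), backward)

    def relu(self):
        return self.leaky_relu(alpha=0.0)

    def clip(self, lo: float, hi: float):
        a = self
        inside = (a.data >= lo) & (a.data <= hi)

        def backward(g):
            if a.requires_grad:
                a._accum(g * inside)

        return Tensor._from_op(np.clip(a.data, lo, hi), (a,), backward)

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape):
        a = self
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])

        def backward(g):
            if a.requires_grad:
                a._accum(g.reshape(a.data.shape))

        return Tensor._from_op(a.data.reshape(shape), (a,), backward)

    def transpose(self, axes):
        a = self
        inv = np.argsort(axes)

        def backward(g):
            if a.requires_grad:
                a._accum(g.transpose(inv))

        return Tensor._from_op(a.data.transpose(axes), (a,), backward)

    def __getitem__(self, idx):
        a = self

        def backward(g):
            if a.requires_grad:
                full = np.zeros_like(a.data)
                full[idx] = g
                a._accum(full)

        return Tensor._from_op(a.data[idx], (a,), backward)

    def pad(self, pad_width):
        """Zero-pad; `pad_width` as for np.pad."""
        a = self
        pw = tuple(tuple(p) for p in pad_width)
        sl = tuple(slice(lo, lo + s) for (lo, _), s in zip(pw, a.data.shape))

        def backward(g):
            if a.requires_grad:
                a._accum(g[sl])

        return Tensor._from_op(np.pad(a.data, pw), (a,), backward)

    def dilate(self, stride: int, axes: tuple[int, ...]):
        """Insert stride-1 zeros between entries along `axes` (for transpose conv)."""
        a = self
        if stride == 1:
            return a
        out_shape = list(a.data.shape)
        sl = [slice(None)] * a.data.ndim
        for ax in axes:
            out_shape[ax] = (a.data.shape[ax] - 1) * stride + 1
            sl[ax] = slice(None, None, stride)
        sl = tuple(sl)
        out_data = np.zeros(out_shape, dtype=np.float64)
        out_data[sl] = a.data

        def backward(g):
            if a.requires_grad:
                a._accum(g[sl])

        return Tensor._from_op(out_data, (a,), backward)

    def flip(self, axes: tuple[int, ...]):
        a = self

        def backward(g):
            if a.requires_grad:
                a._accum(np.flip(g, axes))

        return Tensor._from_op(np.flip(a.data, axes).copy(), (a,), backward)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor._from_op(
        np.concatenate([t.data for t in tensors], axis=axis), tensors, backward
    )


# -- convolution kernels ------------------------------------------------------
# Offset-loop formulation: one strided slice + small (Cout, Cin) contraction
# per kernel offset.  Much cheaper in numpy than materialising im2col columns.

def _ksl(kidx, stride, out_sp):
    return (slice(None), slice(None)) + tuple(
        slice(kidx[d], kidx[d] + stride * out_sp[d], stride)
        for d in range(len(kidx)))


def _conv_fwd(xp, w, stride, out_sp):
    """xp: padded (N, Cin, *Sp); w: (Cout, Cin, *K) -> (N, Cout, *out_sp)."""
    n, c_in = xp.shape[:2]
    c_out = w.shape[0]
    p = math.prod(out_sp)
    y = np.zeros((n, c_out, p))
    kk = (slice(None), slice(None))
    for kidx in np.ndindex(*w.shape[2:]):
        xs = xp[_ksl(kidx, stride, out_sp)].reshape(n, c_in, p)
        y += w[kk + kidx] @ xs
    return y.reshape((n, c_out) + tuple(out_sp))


def _conv_bwd_x(dy, w, xp_shape, stride):
    """Adjoint of _conv_fwd in its input: scatter dy back onto the padded grid."""
    dxp = np.zeros(xp_shape)
    out_sp = dy.shape[2:]
    n, c_out = dy.shape[:2]
    dy2 = dy.reshape(n, c_out, -1)
    kk = (slice(None), slice(None))
    for kidx in np.ndindex(*w.shape[2:]):
        contrib = w[kk + kidx].T @ dy2  # (N, Cin, P)
        dxp[_ksl(kidx, stride, out_sp)] += contrib.reshape(
            (n, xp_shape[1]) + tuple(out_sp))
    return dxp


def _conv_bwd_w(dy, xp, kshape, stride):
    out_sp = dy.shape[2:]
    n, c_out = dy.shape[:2]
    c_in = xp.shape[1]
    p = math.prod(out_sp)
    dy2 = dy.reshape(n, c_out, p)
    dw = np.empty((c_out, c_in) + tuple(kshape))
    kk = (slice(None), slice(None))
    for kidx in np.ndindex(*kshape):
        xs = xp[_ksl(kidx, stride, out_sp)].reshape(n, c_in, p)
        dw[kk + kidx] = np.tensordot(dy2, xs, axes=([0, 2], [0, 2]))
    return dw


def _pad_spatial(a, padding, nd):
    if padding == 0:
        return a
    return np.pad(a, ((0, 0), (0, 0)) + ((padding, padding),) * nd)


def _unpad_spatial(a, padding, nd):
    if padding == 0:
        return a
    sl = (slice(None), slice(None)) + tuple(
        slice(padding, a.shape[2 + d] - padding) for d in range(nd))
    return a[sl]


def convnd(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1,
           padding: int = 0) -> Tensor:
    """N-d cross-correlation. x: (N, Cin, *S); w: (Cout, Cin, *K); b: (Cout,).

    Output spatial size per axis: (S + 2*padding - K)//stride + 1.
    """
    x = Tensor._wrap(x)
    nd = w.data.ndim - 2
    k = w.data.shape[2:]
    xp = _pad_spatial(x.data, padding, nd)
    out_sp = tuple((xp.shape[2 + d] - k[d]) // stride + 1 for d in range(nd))
    y = _conv_fwd(xp, w.data, stride, out_sp)
    c_out = w.data.shape[0]
    if b is not None:
        y += b.data.reshape((1, c_out) + (1,) * nd)

    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0,) + tuple(range(2, 2 + nd))))
        if w.requires_grad:
            w._accum(_conv_bwd_w(g, xp, k, stride))
        if x.requires_grad:
            dxp = _conv_bwd_x(g, w.data, xp.shape, stride)
            x._accum(_unpad_spatial(dxp, padding, nd))

    return Tensor._from_op(y, parents, backward)


def conv_transpose_nd(x: Tensor, w: Tensor, b: Tensor | None = None,
                      stride: int = 2, padding: int = 1) -> Tensor:
    """Transpose convolution: the adjoint of `convnd` in its input.

    w: (Cin, Cout, *K) acting on x: (N, Cin, *S); output spatial size
    (S-1)*stride - 2*padding + K per axis.
    """
    x = Tensor._wrap(x)
    nd = w.data.ndim - 2
    k = w.data.shape[2:]
    c_in, c_out = w.data.shape[:2]
    n_batch = x.data.shape[0]
    s_in = x.data.shape[2:]
    out_sp = tuple((s_in[d] - 1) * stride - 2 * padding + k[d]
                   for d in range(nd))
    padded_shape = (n_batch, c_out) + tuple(o + 2 * padding for o in out_sp)
    # viewed as a conv from the output domain back to the input domain, the
    # tconv weight (Cin, Cout, *K) is that conv's (Cout_conv, Cin_conv, *K)
    yp = _conv_bwd_x(x.data, w.data, padded_shape, stride)
    y = _unpad_spatial(yp, padding, nd).copy()
    if b is not None:
        y += b.data.reshape((1, c_out) + (1,) * nd)

    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        gp = _pad_spatial(g, padding, nd)
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0,) + tuple(range(2, 2 + nd))))
        if w.requires_grad:
            w._accum(_conv_bwd_w(x.data, gp, k, stride))
        if x.requires_grad:
            x._accum(_conv_fwd(gp, w.data, stride, s_in))

    return Tensor._from_op(y, parents, backward)
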