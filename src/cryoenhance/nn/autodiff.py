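"""Reverse-mode automatic differentiation on numpy arrays.

A deliberately small tape-based engine covering exactly the operations the
3-D enhancement network needs: broadcasting arithmetic, matmul, softmax,
strided 3-D convolution and 2x transposed convolution, reductions, axis
permutations and separable trilinear regridding.  Gradients are accumulated
by topological sort over the recorded graph, torch-style but in plain numpy.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "leaky_relu",
    "softmax",
    "conv3d",
    "conv_transpose3d_2x",
    "resample3d",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
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
    """An ndarray plus an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------
    def _wrap(self, other) -> "Tensor":
        if isinstance(other, Tensor):
            return other
        # keep python scalars in the operand's dtype to avoid float64 promotion
        if np.isscalar(other):
            return Tensor(np.asarray(other, dtype=self.data.dtype))
        return Tensor(np.asarray(other))

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)
        out_data = self.data + other.data

        def backward(g):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return self._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out_data = self.data * other.data

        def backward(g):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        return self * other._pow_const(-1.0)

    def _pow_const(self, p: float) -> "Tensor":
        out_data = self.data**p

        def backward(g):
            return (g * p * self.data ** (p - 1.0),)

        return self._make(out_data, (self,), backward)

    def __pow__(self, p):
        if not np.isscalar(p):
            raise TypeError("only scalar exponents are supported")
        return self._pow_const(float(p))

    def sqrt(self):
        return self._pow_const(0.5)

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            return (g * out_data,)

        return self._make(out_data, (self,), backward)

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.shape).copy(),)

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            ax = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[a] for a in ax]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        src = self.shape
        return self._make(
            self.data.reshape(shape), (self,), lambda g: (g.reshape(src),)
        )

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = tuple(np.argsort(axes))
        return self._make(
            self.data.transpose(axes), (self,), lambda g: (g.transpose(inv),)
        )

    def swapaxes(self, a, b):
        axes = list(range(self.ndim))
        axes[a], axes[b] = axes[b], axes[a]
        return self.transpose(*axes)

    # -- matmul ---------------------------------------------------------------
    def __matmul__(self, other):
        other = self._wrap(other)
        out_data = np.matmul(self.data, other.data)

        def backward(g):
            ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
            gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
            return (_unbroadcast(ga, self.shape), _unbroadcast(gb, other.shape))

        return self._make(out_data, (self, other), backward)

    # -- backprop driver ------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: "Tensor"):
            stack = [(t, iter(t._parents))]
            if id(t) in seen:
                return
            seen.add(id(t))
            while stack:
                node, it = stack[-1]
                advanced = False
                for p in it:
                    if id(p) not in seen and p.requires_grad:
                        seen.add(id(p))
                        stack.append((p, iter(p._parents)))
                        advanced = True
                        break
                if not advanced:
                    topo.append(node)
                    stack.pop()

        visit(self)
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad and node._backward is None:
                node.grad = g if node.grad is None else node.grad + g
            if node._backward is None:
                continue
            parent_grads = node._backward(g)
            for p, pg in zip(node._parents, parent_grads):
                if pg is None or not p.requires_grad:
                    continue
                key = id(p)
                if key in grads:
                    grads[key] = grads[key] + pg
                else:
                    grads[key] = pg


def concat(tensors: list[Tensor], axis: int) -> Tensor:
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._make(out_data, tuple(tensors), backward)


def leaky_relu(x: Tensor, negative_slope: float = 0.01) -> Tensor:
    mask = x.data > 0
    scale = np.where(mask, 1.0, negative_slope).astype(x.data.dtype)
    return Tensor._make(x.data * scale, (x,), lambda g: (g * scale,))


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    out_data = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * out_data).sum(axis=axis, keepdims=True)
        return (out_data * (g - dot),)

    return Tensor._make(out_data, (x,), backward)


# -- 3-D convolution ----------------------------------------------------------


def _windows(xp: np.ndarray, k: int, stride: int) -> np.ndarray:
    """All k^3 windows of a padded (B,C,D,H,W) volume with the given stride.

    Returns a view of shape (B, C, Do, Ho, Wo, k, k, k).
    """
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))
    return win[:, :, ::stride, ::stride, ::stride]


def _corr3d(x: np.ndarray, w: np.ndarray, stride: int, pad: int) -> np.ndarray:
    """Cross-correlate (B,Cin,D,H,W) with (Cout,Cin,k,k,k)."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0)) + ((pad, pad),) * 3)
    k = w.shape[-1]
    win = _windows(x, k, stride)
    out = np.tensordot(win, w, axes=([1, 5, 6, 7], [1, 2, 3, 4]))
    return np.ascontiguousarray(np.moveaxis(out, -1, 1))


def _conv3d_grad_input(
    gy: np.ndarray, w: np.ndarray, stride: int, pad: int, in_shape
) -> np.ndarray:
    """Gradient of _corr3d w.r.t. its input.

    Zero-stuff the output gradient by `stride`, pad, and correlate with the
    spatially flipped, channel-swapped kernel at stride 1; this scatters each
    output gradient back over the k^3 input window that produced it.
    """
    k = w.shape[-1]
    b, cout = gy.shape[:2]
    if stride > 1:
        up = np.zeros(
            (b, cout) + tuple((n - 1) * stride + 1 for n in gy.shape[2:]),
            dtype=gy.dtype,
        )
        up[:, :, ::stride, ::stride, ::stride] = gy
    else:
        up = gy
    pads = []
    for i, dim in enumerate(in_shape[2:]):
        # padded forward input had length dim + 2*pad; the stride-1 correlation
        # below yields up_len + left + right - k + 1, which must equal it
        left = k - 1
        right = (dim + 2 * pad + k - 1) - up.shape[2 + i] - left
        pads.append((left, right))
    upp = np.pad(up, ((0, 0), (0, 0)) + tuple(pads))
    wflip = w[:, :, ::-1, ::-1, ::-1]
    wswap = np.ascontiguousarray(np.swapaxes(wflip, 0, 1))  # (Cin, Cout, k, k, k)
    gxp = _corr3d(upp, wswap, stride=1, pad=0)
    if pad:
        gxp = gxp[:, :, pad:-pad, pad:-pad, pad:-pad]
    return gxp


def conv3d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1, pad: int = 0) -> Tensor:
    """3-D cross-correlation, NCDHW layout, cubic kernel, symmetric padding."""
    out_data = _corr3d(x.data, w.data, stride, pad)
    if b is not None:
        out_data = out_data + b.data.reshape(1, -1, 1, 1, 1)
    k = w.shape[-1]

    def backward(g):
        xp = x.data
        if pad:
            xp = np.pad(xp, ((0, 0), (0, 0)) + ((pad, pad),) * 3)
        win = _windows(xp, k, stride)
        gw = np.tensordot(g, win, axes=([0, 2, 3, 4], [0, 2, 3, 4]))
        gx = _conv3d_grad_input(g, w.data, stride, pad, x.data.shape)
        gb = g.sum(axis=(0, 2, 3, 4)) if b is not None else None
        return (gx, gw, gb)

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._make(out_data, parents, backward)


def conv_transpose3d_2x(x: Tensor, w: Tensor, b: Tensor | None) -> Tensor:
    """Transposed conv with kernel 2, stride 2: exact 2x spatial upsampling.

    Weight layout (Cin, Cout, 2, 2, 2); output windows do not overlap, so the
    op is an einsum followed by spatial interleaving.
    """
    xb, cin, d, h, wd = x.shape
    cout = w.shape[1]
    y = np.einsum("bidhw,iojkl->bodjhkwl", x.data, w.data, optimize=True)
    out_data = y.reshape(xb, cout, 2 * d, 2 * h, 2 * wd)
    if b is not None:
        out_data = out_data + b.data.reshape(1, -1, 1, 1, 1)

    def backward(g):
        gr = g.reshape(xb, cout, d, 2, h, 2, wd, 2)
        gx = np.einsum("bodjhkwl,iojkl->bidhw", gr, w.data, optimize=True)
        gw = np.einsum("bodjhkwl,bidhw->iojkl", gr, x.data, optimize=True)
        gb = g.sum(axis=(0, 2, 3, 4)) if b is not None else None
        return (gx, gw, gb)

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._make(out_data, parents, backward)


def resample3d(x: Tensor, mats: tuple[np.ndarray, np.ndarray, np.ndarray]) -> Tensor:
    """Separable linear regridding of the last three axes.

    ``mats`` holds one (new_len, old_len) interpolation matrix per axis; the
    op is linear, so the backward pass applies the transposed matrices.
    """

    def apply(data, ms):
        for ax_from_end, m in zip((3, 2, 1), ms):
            data = np.moveaxis(
                np.tensordot(data, m, axes=([data.ndim - ax_from_end], [1])),
                -1,
                data.ndim - ax_from_end,
            )
        return data

    out_data = apply(x.data, mats)

    def backward(g):
        return (apply(g, tuple(m.T for m in mats)),)

    return Tensor._make(out_data, (x,), backward)
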