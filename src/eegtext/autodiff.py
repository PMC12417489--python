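"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Implements only the primitives the dual-encoder model needs: broadcasting
arithmetic, matmul, reductions, ReLU, exp/log/sqrt, reshaping, slicing and a
sliding-window ``unfold`` (the basis for convolution and max-pooling).
Gradients are accumulated by topological traversal of the recorded graph.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "unfold", "concat"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape``, inverting NumPy broadcasting."""
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
    """A NumPy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction -----------------------------------------------------
    @classmethod
    def _from_op(cls, data, parents, backward):
        out = cls(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- bookkeeping ------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data, dtype=np.result_type(self.data, np.float32))
        self.grad += grad

    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without an explicit gradient requires a scalar")
            grad = np.ones_like(self.data)
        self._accumulate(np.asarray(grad))

        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))

        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic -------------------------------------------------------
    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor._from_op(self.data + other.data, (self, other), None)

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor._from_op(-self.data, (self,), None)

        def backward(g):
            self._accumulate(-g)

        out._backward = backward
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor._from_op(self.data * other.data, (self, other), None)

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return self._lift(other) * self ** -1.0

    def __pow__(self, exponent: float):
        if isinstance(exponent, Tensor):
            raise TypeError("tensor exponents are not supported")
        out = Tensor._from_op(self.data ** exponent, (self,), None)

        def backward(g):
            self._accumulate(g * exponent * self.data ** (exponent - 1.0))

        out._backward = backward
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor._from_op(self.data @ other.data, (self, other), None)

        def backward(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accumulate(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accumulate(_unbroadcast(gb, other.data.shape))

        out._backward = backward
        return out

    # -- elementwise ------------------------------------------------------
    def exp(self):
        data = np.exp(self.data)
        out = Tensor._from_op(data, (self,), None)

        def backward(g):
            self._accumulate(g * data)

        out._backward = backward
        return out

    def log(self):
        out = Tensor._from_op(np.log(self.data), (self,), None)

        def backward(g):
            self._accumulate(g / self.data)

        out._backward = backward
        return out

    def sqrt(self):
        data = np.sqrt(self.data)
        out = Tensor._from_op(data, (self,), None)

        def backward(g):
            self._accumulate(g * 0.5 / data)

        out._backward = backward
        return out

    def relu(self):
        mask = self.data > 0
        out = Tensor._from_op(self.data * mask, (self,), None)

        def backward(g):
            self._accumulate(g * mask)

        out._backward = backward
        return out

    # -- reductions -------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor._from_op(self.data.sum(axis=axis, keepdims=keepdims), (self,), None)

        def backward(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis: int = -1):
        """Maximum along one axis; gradient flows to the first argmax."""
        axis_ = axis % self.data.ndim
        data = self.data.max(axis=axis_)
        argmax = np.expand_dims(self.data.argmax(axis=axis_), axis_)
        out = Tensor._from_op(data, (self,), None)

        def backward(g):
            gx = np.zeros_like(self.data, dtype=g.dtype)
            np.put_along_axis(gx, argmax, np.expand_dims(g, axis_), axis_)
            self._accumulate(gx)

        out._backward = backward
        return out

    # -- shape manipulation ----------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor._from_op(self.data.reshape(shape), (self,), None)

        def backward(g):
            self._accumulate(g.reshape(self.data.shape))

        out._backward = backward
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inverse = np.argsort(axes)
        out = Tensor._from_op(self.data.transpose(axes), (self,), None)

        def backward(g):
            self._accumulate(g.transpose(inverse))

        out._backward = backward
        return out

    def __getitem__(self, index):
        out = Tensor._from_op(self.data[index], (self,), None)

        def backward(g):
            gx = np.zeros_like(self.data, dtype=g.dtype)
            np.add.at(gx, index, g)
            self._accumulate(gx)

        out._backward = backward
        return out


def unfold(x: Tensor, size: int, step: int) -> Tensor:
    """Sliding windows of ``size`` every ``step`` samples along the last axis.

    Output shape is ``x.shape[:-1] + (n_windows, size)`` with
    ``n_windows = (L - size) // step + 1``. Windows may overlap; the backward
    pass scatter-adds into the overlapping positions.
    """
    if size <= 0 or step <= 0:
        raise ValueError("size and step must be positive")
    length = x.data.shape[-1]
    if length < size:
        raise ValueError(f"axis length {length} shorter than window size {size}")
    view = np.lib.stride_tricks.sliding_window_view(x.data, size, axis=-1)
    data = np.ascontiguousarray(view[..., ::step, :])
    out = Tensor._from_op(data, (x,), None)
    n_windows = data.shape[-2]
    starts = np.arange(n_windows) * step

    def backward(g):
        gx = np.zeros_like(x.data, dtype=g.dtype)
        # per fixed offset j the target indices are unique, so fancy-index add is safe
        for j in range(size):
            gx[..., starts + j] += g[..., :, j]
        x._accumulate(gx)

    out._backward = backward
    return out


def im2col(x: Tensor, size: int, step: int = 1) -> Tensor:
    """Convolution-ready patches: (n, C, T) -> contiguous (n, T_out, C * size).

    Column layout is channel-major (c * size + j), matching a weight matrix of
    shape (C * size, out_channels). Forward and backward move data with one
    strided copy per kernel offset, which keeps large stride-1 convolutions on
    the BLAS fast path.
    """
    n, c, length = x.data.shape
    if length < size:
        raise ValueError(f"axis length {length} shorter than window size {size}")
    t_out = (length - size) // step + 1
    starts = np.arange(t_out) * step
    out_data = np.empty((n, t_out, c, size), dtype=x.data.dtype)
    for j in range(size):
        out_data[:, :, :, j] = x.data[:, :, starts + j].transpose(0, 2, 1)
    out_data = out_data.reshape(n, t_out, c * size)
    out = Tensor._from_op(out_data, (x,), None)

    def backward(g):
        g4 = g.reshape(n, t_out, c, size)
        gx = np.zeros_like(x.data, dtype=g.dtype)
        for j in range(size):
            gx[:, :, starts + j] += g4[:, :, :, j].transpose(0, 2, 1)
        x._accumulate(gx)

    out._backward = backward
    return out


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor._from_op(np.concatenate(datas, axis=axis), tuple(tensors), None)
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    out._backward = backward
    return out
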