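"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Implements exactly the operator set the affinity model needs: broadcasting
arithmetic, matmul, elementwise nonlinearities, reductions, concatenation,
row gather and segment-sum (the scatter primitive behind graph message
passing). Gradients are accumulated in float64 via a topologically ordered
tape.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "stack_rows", "segment_sum", "segment_mean"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A NumPy array plus an optional gradient tape node."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")
    __array_priority__ = 100  # so ndarray + Tensor defers to us

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    # ---------------------------------------------------------------- utils
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @classmethod
    def _make(cls, data, parents, backward) -> "Tensor":
        out = cls(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # ------------------------------------------------------------ autograd
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = None
        self.grad = np.asarray(grad, dtype=np.float64).reshape(self.data.shape)
        # reverse topological order guarantees every node's grad is complete
        # before its backward closure runs
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def _accum(self, g):
        if self.requires_grad:
            if self.grad is None:
                self.grad = np.array(g, dtype=np.float64)
            else:
                self.grad += g

    # ---------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = self._wrap(other)
        a, b = self, other

        def backward(g):
            a._accum(_unbroadcast(g, a.data.shape))
            b._accum(_unbroadcast(g, b.data.shape))

        return Tensor._make(a.data + b.data, (a, b), backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = self._wrap(other)
        a, b = self, other

        def backward(g):
            a._accum(_unbroadcast(g * b.data, a.data.shape))
            b._accum(_unbroadcast(g * a.data, b.data.shape))

        return Tensor._make(a.data * b.data, (a, b), backward)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __truediv__(self, other):
        return self * self._wrap(other) ** (-1.0)

    def __rtruediv__(self, other):
        return self._wrap(other) * self ** (-1.0)

    def __pow__(self, exponent: float):
        a = self
        out_data = a.data ** exponent

        def backward(g):
            a._accum(g * exponent * a.data ** (exponent - 1.0))

        return Tensor._make(out_data, (a,), backward)

    def __matmul__(self, other):
        other = self._wrap(other)
        a, b = self, other

        def backward(g):
            g = np.asarray(g)
            if a.requires_grad:
                if b.data.ndim == 1:  # (..., k) @ (k,) -> outer-free case
                    a._accum(np.multiply.outer(g, b.data).reshape(a.data.shape))
                else:
                    a._accum(g @ b.data.swapaxes(-1, -2))
            if b.requires_grad:
                if a.data.ndim == 1:  # (k,) @ (k, n)
                    b._accum(np.multiply.outer(a.data, g).reshape(b.data.shape))
                else:
                    b._accum(a.data.swapaxes(-1, -2) @ g)

        return Tensor._make(a.data @ b.data, (a, b), backward)

    # ------------------------------------------------------- nonlinearities
    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def backward(g):
            a._accum(g * out_data)

        return Tensor._make(out_data, (a,), backward)

    def log(self):
        a = self

        def backward(g):
            a._accum(g / a.data)

        return Tensor._make(np.log(a.data), (a,), backward)

    def tanh(self):
        a = self
        out_data = np.tanh(a.data)

        def backward(g):
            a._accum(g * (1.0 - out_data ** 2))

        return Tensor._make(out_data, (a,), backward)

    def sigmoid(self):
        a = self
        out_data = 1.0 / (1.0 + np.exp(-a.data))

        def backward(g):
            a._accum(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (a,), backward)

    def relu(self):
        a = self
        mask = (a.data > 0).astype(np.float64)

        def backward(g):
            a._accum(g * mask)

        return Tensor._make(a.data * mask, (a,), backward)

    def leaky_relu(self, slope: float = 0.01):
        a = self
        mult = np.where(a.data > 0, 1.0, slope)

        def backward(g):
            a._accum(g * mult)

        return Tensor._make(a.data * mult, (a,), backward)

    def elu(self, alpha: float = 1.0):
        a = self
        neg = alpha * (np.exp(np.minimum(a.data, 0.0)) - 1.0)
        out_data = np.where(a.data > 0, a.data, neg)

        def backward(g):
            a._accum(g * np.where(a.data > 0, 1.0, neg + alpha))

        return Tensor._make(out_data, (a,), backward)

    # ----------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        a = self
        out_data = a.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            a._accum(np.broadcast_to(g, a.data.shape).copy())

        return Tensor._make(out_data, (a,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def softmax(self, axis: int = -1):
        shifted = self - Tensor(self.data.max(axis=axis, keepdims=True))
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)

    # -------------------------------------------------------- shape / index
    def reshape(self, *shape):
        a = self
        orig = a.data.shape

        def backward(g):
            a._accum(g.reshape(orig))

        return Tensor._make(a.data.reshape(*shape), (a,), backward)

    def transpose(self, *axes):
        a = self
        axes = axes or None
        inv = np.argsort(axes) if axes else None

        def backward(g):
            a._accum(g.transpose(inv) if inv is not None else g.transpose())

        return Tensor._make(a.data.transpose(axes) if axes else a.data.transpose(), (a,), backward)

    @property
    def T(self):
        return self.transpose()

    def gather_rows(self, index: np.ndarray):
        """Select rows by integer index (with repetition); axis 0."""
        a = self
        index = np.asarray(index, dtype=np.intp)

        def backward(g):
            acc = np.zeros_like(a.data)
            np.add.at(acc, index, g)
            a._accum(acc)

        return Tensor._make(a.data[index], (a,), backward)

    def slice_rows(self, start: int, stop: int):
        a = self

        def backward(g):
            acc = np.zeros_like(a.data)
            acc[start:stop] = g
            a._accum(acc)

        return Tensor._make(a.data[start:stop], (a,), backward)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accum(g[tuple(sl)])

    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis), tensors, backward)


def stack_rows(tensors) -> Tensor:
    """Stack 1-D tensors into a matrix (axis 0)."""
    return concat([t.reshape(1, -1) for t in tensors], axis=0)


def segment_sum(values: Tensor, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    """Sum rows of `values` into `num_segments` buckets given by `segment_ids`."""
    a = Tensor._wrap(values)
    segment_ids = np.asarray(segment_ids, dtype=np.intp)
    out_data = np.zeros((num_segments,) + a.data.shape[1:], dtype=np.float64)
    np.add.at(out_data, segment_ids, a.data)

    def backward(g):
        a._accum(g[segment_ids])

    return Tensor._make(out_data, (a,), backward)


def segment_mean(values: Tensor, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    """Mean-aggregate rows per segment; empty segments stay zero."""
    counts = np.bincount(np.asarray(segment_ids, dtype=np.intp), minlength=num_segments)
    counts = np.maximum(counts, 1).astype(np.float64)
    total = segment_sum(values, segment_ids, num_segments)
    return total * Tensor(1.0 / counts[:, None] if total.ndim == 2 else 1.0 / counts)
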