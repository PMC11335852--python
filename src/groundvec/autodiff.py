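"""A compact reverse-mode automatic-differentiation engine on numpy arrays.

This is the numerical core behind the caption encoders and the
concreteness perceptron. It implements exactly the operator set those
models need — broadcasting arithmetic, (batched) matrix products,
elementwise nonlinearities, reductions, indexing, reshaping and
concatenation — as a dynamically built computation graph over
:class:`Tensor` nodes. Gradients are accumulated by a topological-order
backward sweep; broadcasting is undone by summing gradients over the
broadcast axes. Every operator is gradient-checked against central
finite differences in the test suite.
"""
from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

Array = np.ndarray


def _unbroadcast(grad: Array, shape: tuple[int, ...]) -> Array:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum out prepended axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # sum axes that were broadcast from size 1
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: Array | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[Array], None] | None = None

    # -- graph plumbing ---------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def _accumulate(self, g: Array) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: Array | None = None) -> None:
        """Backpropagate from this node; defaults to d(self)/d(self)=1."""
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
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # -- construction helper ----------------------------------------------

    @staticmethod
    def _make(data: Array, parents: Sequence["Tensor"],
              backward: Callable[[Array], None]) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad or p._parents for p in parents):
            out.requires_grad = any(p.requires_grad for p in parents)
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other) -> "Tensor":
        other = as_tensor(other)

        def bwd(g: Array) -> None:
            self._accumulate(_unbroadcast(g, self.shape))
            other._accumulate(_unbroadcast(g, other.shape))

        return Tensor._make(self.data + other.data, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def bwd(g: Array) -> None:
            self._accumulate(-g)

        return Tensor._make(-self.data, (self,), bwd)

    def __sub__(self, other) -> "Tensor":
        return self + (-as_tensor(other))

    def __rsub__(self, other) -> "Tensor":
        return as_tensor(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = as_tensor(other)

        def bwd(g: Array) -> None:
            self._accumulate(_unbroadcast(g * other.data, self.shape))
            other._accumulate(_unbroadcast(g * self.data, other.shape))

        return Tensor._make(self.data * other.data, (self, other), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = as_tensor(other)

        def bwd(g: Array) -> None:
            self._accumulate(_unbroadcast(g / other.data, self.shape))
            other._accumulate(
                _unbroadcast(-g * self.data / other.data**2, other.shape)
            )

        return Tensor._make(self.data / other.data, (self, other), bwd)

    def __rtruediv__(self, other) -> "Tensor":
        return as_tensor(other) / self

    def __pow__(self, exponent: float) -> "Tensor":
        assert np.isscalar(exponent)

        def bwd(g: Array) -> None:
            self._accumulate(g * exponent * self.data ** (exponent - 1))

        return Tensor._make(self.data**exponent, (self,), bwd)

    def __matmul__(self, other) -> "Tensor":
        other = as_tensor(other)

        def bwd(g: Array) -> None:
            a, b = self.data, other.data
            if b.ndim == 1 and a.ndim == 1:
                self._accumulate(g * b)
                other._accumulate(g * a)
                return
            if b.ndim == 1:
                self._accumulate(np.expand_dims(g, -1) * b)
                other._accumulate(_unbroadcast(
                    (a * np.expand_dims(g, -1)).reshape(-1, b.shape[0]).sum(0), b.shape))
                return
            if a.ndim == 1:
                self._accumulate(g @ np.swapaxes(b, -1, -2))
                other._accumulate(np.outer(a, g))
                return
            ga = g @ np.swapaxes(b, -1, -2)
            gb = np.swapaxes(a, -1, -2) @ g
            self._accumulate(_unbroadcast(ga, a.shape))
            other._accumulate(_unbroadcast(gb, b.shape))

        return Tensor._make(self.data @ other.data, (self, other), bwd)

    # -- elementwise nonlinearities ----------------------------------------

    def tanh(self) -> "Tensor":
        out_data = np.tanh(self.data)

        def bwd(g: Array) -> None:
            self._accumulate(g * (1.0 - out_data**2))

        return Tensor._make(out_data, (self,), bwd)

    def sigmoid(self) -> "Tensor":
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def bwd(g: Array) -> None:
            self._accumulate(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (self,), bwd)

    def relu(self) -> "Tensor":
        mask = self.data > 0

        def bwd(g: Array) -> None:
            self._accumulate(g * mask)

        return Tensor._make(self.data * mask, (self,), bwd)

    def leaky_relu(self, alpha: float = 0.01) -> "Tensor":
        slope = np.where(self.data > 0, 1.0, alpha)

        def bwd(g: Array) -> None:
            self._accumulate(g * slope)

        return Tensor._make(self.data * slope, (self,), bwd)

    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)

        def bwd(g: Array) -> None:
            self._accumulate(g * out_data)

        return Tensor._make(out_data, (self,), bwd)

    def log(self) -> "Tensor":
        def bwd(g: Array) -> None:
            self._accumulate(g / self.data)

        return Tensor._make(np.log(self.data), (self,), bwd)

    def sqrt(self) -> "Tensor":
        return self**0.5

    # -- reductions / shape ------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        def bwd(g: Array) -> None:
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).copy())
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(gg, self.shape).copy())

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bwd)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if np.isscalar(axis) else axis
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape

        def bwd(g: Array) -> None:
            self._accumulate(g.reshape(old))

        return Tensor._make(self.data.reshape(shape), (self,), bwd)

    def transpose(self, *axes) -> "Tensor":
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        if not axes:
            axes = tuple(reversed(range(self.ndim)))
        inv = np.argsort(axes)

        def bwd(g: Array) -> None:
            self._accumulate(g.transpose(inv))

        return Tensor._make(self.data.transpose(axes), (self,), bwd)

    def __getitem__(self, idx) -> "Tensor":
        def bwd(g: Array) -> None:
            if self.grad is None:
                self.grad = np.zeros_like(self.data)
            np.add.at(self.grad, idx, g)

        return Tensor._make(self.data[idx], (self,), bwd)

    # -- composites ---------------------------------------------------------

    def softmax(self, axis: int = -1) -> "Tensor":
        shifted = self - Tensor(self.data.max(axis=axis, keepdims=True))
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    """Concatenate tensors along ``axis`` with gradient routing."""
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g: Array) -> None:
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accumulate(g[tuple(sl)])

    return Tensor._make(
        np.concatenate([t.data for t in tensors], axis=axis), tensors, bwd
    )


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]

    def bwd(g: Array) -> None:
        for i, t in enumerate(tensors):
            t._accumulate(np.take(g, i, axis=axis))

    return Tensor._make(np.stack([t.data for t in tensors], axis=axis), tensors, bwd)


def mse(pred: Tensor, target: Tensor | Array) -> Tensor:
    """Mean squared error over all elements."""
    diff = pred - as_tensor(target)
    return (diff * diff).mean()
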