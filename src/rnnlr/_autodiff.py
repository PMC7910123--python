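"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Supports exactly the operations the package's networks need (dense layers,
stacked tanh recurrences, softmax cross-entropy style compositions).  Graphs
are built eagerly; ``Tensor.backward`` runs a topological sweep.  Gradients
with respect to broadcast operands are reduced back to the operand shape.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over prepended axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """Array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")
    __array_priority__ = 100  # keep ndarray.__add__ from taking over

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    # -- helpers ---------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._prev = tuple(parents)
            out._backward = backward
        return out

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    # -- arithmetic ------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)

        def backward(g, out):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = self._lift(other)

        def backward(g, out):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            raise TypeError("division by Tensor not supported; use reciprocal ops")
        return self * (1.0 / other)

    def __matmul__(self, other):
        other = self._lift(other)

        def backward(g, out):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        return self._make(self.data @ other.data, (self, other), backward)

    # -- nonlinearities --------------------------------------------------
    def tanh(self):
        y = np.tanh(self.data)

        def backward(g, out):
            if self.requires_grad:
                self._accum(g * (1.0 - out.data ** 2))

        return self._make(y, (self,), backward)

    def relu(self):
        y = np.maximum(self.data, 0.0)

        def backward(g, out):
            if self.requires_grad:
                self._accum(g * (self.data > 0.0))

        return self._make(y, (self,), backward)

    def exp(self):
        y = np.exp(self.data)

        def backward(g, out):
            if self.requires_grad:
                self._accum(g * out.data)

        return self._make(y, (self,), backward)

    def log(self):
        def backward(g, out):
            if self.requires_grad:
                self._accum(g / self.data)

        return self._make(np.log(self.data), (self,), backward)

    def clip_min(self, lo: float):
        """max(x, lo); subgradient passes where x > lo."""

        def backward(g, out):
            if self.requires_grad:
                self._accum(g * (self.data > lo))

        return self._make(np.maximum(self.data, lo), (self,), backward)

    # -- reductions / shape ---------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def backward(g, out):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.full(self.shape, g))
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.shape).copy())

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / n

    def reshape(self, *shape):
        old = self.shape

        def backward(g, out):
            if self.requires_grad:
                self._accum(g.reshape(old))

        return self._make(self.data.reshape(*shape), (self,), backward)

    # -- machinery -------------------------------------------------------
    def _accum(self, g):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: recurrent graphs get deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad, node)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    """Concatenate tensors along ``axis`` with gradient routing."""
    tensors = [Tensor._lift(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    out = Tensor(data)
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._prev = tuple(tensors)
        sizes = [t.data.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]

        def backward(g, _out):
            parts = np.split(g, splits, axis=axis)
            for t, p in zip(tensors, parts):
                if t.requires_grad:
                    t._accum(p)

        out._backward = backward
    return out
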