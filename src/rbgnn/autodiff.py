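"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Just enough machinery to express the message-passing network, its
recurrent cells and the focal loss, and to backpropagate exactly:
elementwise arithmetic with broadcasting, 2-D matrix products,
concatenation, reductions, and the handful of nonlinearities the model
uses. Gradients are validated against central finite differences in the
test suite.

Convention: vectors are carried as (1, d) row matrices so that ``matmul``
only ever sees 2-D operands.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """Node in the computation graph. ``value`` is a float64 ndarray."""

    __slots__ = ("value", "grad", "_parents", "_grad_fn")

    def __init__(self, value, parents=(), grad_fn=None):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = None
        self._parents = parents
        self._grad_fn = grad_fn

    @property
    def shape(self):
        return self.value.shape

    # -- graph construction helpers -------------------------------------
    def __add__(self, other):
        return add(self, _as_tensor(other))

    def __radd__(self, other):
        return add(_as_tensor(other), self)

    def __sub__(self, other):
        return add(self, neg(_as_tensor(other)))

    def __rsub__(self, other):
        return add(_as_tensor(other), neg(self))

    def __mul__(self, other):
        return mul(self, _as_tensor(other))

    def __rmul__(self, other):
        return mul(_as_tensor(other), self)

    def __neg__(self):
        return neg(self)

    def __matmul__(self, other):
        return matmul(self, _as_tensor(other))

    # -- backward pass ---------------------------------------------------
    def backward(self):
        """Backpropagate from this (size-1) tensor to all leaves."""
        if self.value.size != 1:
            raise ValueError("backward() requires a scalar output")
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS topological sort
            node, expanded = stack.pop()
            if expanded:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent in node._parents:
                stack.append((parent, False))
        self.grad = np.ones_like(self.value)
        for node in reversed(order):
            if node._grad_fn is None or node.grad is None:
                continue
            for parent, pgrad in zip(node._parents, node._grad_fn(node.grad)):
                if pgrad is None:
                    continue
                if parent.grad is None:
                    parent.grad = pgrad
                else:
                    parent.grad = parent.grad + pgrad


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# -- primitive operations ----------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    out = a.value + b.value
    return Tensor(out, (a, b), lambda g: (
        _unbroadcast(g, a.value.shape), _unbroadcast(g, b.value.shape)))


def neg(a: Tensor) -> Tensor:
    return Tensor(-a.value, (a,), lambda g: (-g,))


def mul(a: Tensor, b: Tensor) -> Tensor:
    out = a.value * b.value
    return Tensor(out, (a, b), lambda g: (
        _unbroadcast(g * b.value, a.value.shape),
        _unbroadcast(g * a.value, b.value.shape)))


def matmul(a: Tensor, b: Tensor) -> Tensor:
    if a.value.ndim != 2 or b.value.ndim != 2:
        raise ValueError("matmul expects 2-D operands")
    out = a.value @ b.value
    return Tensor(out, (a, b), lambda g: (g @ b.value.T, a.value.T @ g))


def power(a: Tensor, exponent: float) -> Tensor:
    """Elementwise a**exponent for a fixed scalar exponent."""
    out = a.value ** exponent
    if exponent == 0:
        return Tensor(out, (a,), lambda g: (np.zeros_like(a.value),))
    return Tensor(out, (a,), lambda g: (
        g * exponent * a.value ** (exponent - 1),))


def log(a: Tensor) -> Tensor:
    return Tensor(np.log(a.value), (a,), lambda g: (g / a.value,))


def sigmoid(a: Tensor) -> Tensor:
    out = 1.0 / (1.0 + np.exp(-a.value))
    return Tensor(out, (a,), lambda g: (g * out * (1.0 - out),))


def tanh(a: Tensor) -> Tensor:
    out = np.tanh(a.value)
    return Tensor(out, (a,), lambda g: (g * (1.0 - out * out),))


def relu(a: Tensor) -> Tensor:
    out = np.maximum(a.value, 0.0)
    return Tensor(out, (a,), lambda g: (g * (a.value > 0.0),))


def identity(a: Tensor) -> Tensor:
    return a


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    out = np.concatenate([t.value for t in tensors], axis=axis)
    sizes = [t.value.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def grad_fn(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor(out, tuple(tensors), grad_fn)


def sum_all(a: Tensor) -> Tensor:
    out = np.asarray(a.value.sum()).reshape(1, 1)
    return Tensor(out, (a,), lambda g: (
        np.full_like(a.value, float(g.reshape(()))),))


def sum_rows(a: Tensor) -> Tensor:
    """Columnwise sum over the rows of a 2-D tensor -> (1, d)."""
    out = a.value.sum(axis=0, keepdims=True)
    return Tensor(out, (a,), lambda g: (
        np.broadcast_to(g, a.value.shape).copy(),))


def max_rows(a: Tensor) -> Tensor:
    """Columnwise max over the rows of a 2-D tensor -> (1, d).

    Gradient flows to the first-occurring argmax row of each column.
    """
    idx = np.argmax(a.value, axis=0)
    out = a.value[idx, np.arange(a.value.shape[1])].reshape(1, -1)

    def grad_fn(g):
        grad = np.zeros_like(a.value)
        grad[idx, np.arange(a.value.shape[1])] = g.reshape(-1)
        return (grad,)

    return Tensor(out, (a,), grad_fn)


ACTIVATIONS = {"relu": relu, "tanh": tanh, "identity": identity}
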