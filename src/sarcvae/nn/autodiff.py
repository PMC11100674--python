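"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operator set the mixture-density CVAE needs (affine
maps, elementwise nonlinearities, reductions, logsumexp, concatenation and
slicing) with full numpy broadcasting.  Gradients are accumulated by
topological-order backpropagation; correctness is checked against central
finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np


class Tensor:
    """A node in the computation graph."""

    __slots__ = ("value", "grad", "_parents", "_backward", "requires_grad")

    def __init__(self, value, parents=(), backward=None, requires_grad=True):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = None
        self._parents = parents
        self._backward = backward
        self.requires_grad = requires_grad

    @property
    def shape(self):
        return self.value.shape

    # -- graph mechanics ---------------------------------------------------
    def backward(self, grad=None):
        """Backpropagate; seeds with ones for scalar outputs."""
        if grad is None:
            grad = np.ones_like(self.value)
        topo: list[Tensor] = []
        seen = set()

        def visit(t: Tensor):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = np.zeros_like(t.value)
        self.grad = np.asarray(grad, dtype=np.float64)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    # -- operators ---------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __neg__(self):
        return mul(self, -1.0)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return take(self, idx)


def as_tensor(x) -> Tensor:
    if isinstance(x, Tensor):
        return x
    return Tensor(x, requires_grad=False)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


def _binary(a, b, value, da, db) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)

    def backward(g):
        if a.requires_grad:
            a.grad += _unbroadcast(da(g), a.value.shape)
        if b.requires_grad:
            b.grad += _unbroadcast(db(g), b.value.shape)

    need = a.requires_grad or b.requires_grad
    return Tensor(value, (a, b) if need else (), backward if need else None,
                  requires_grad=need)


def _unary(a, value, da) -> Tensor:
    a = as_tensor(a)

    def backward(g):
        if a.requires_grad:
            a.grad += _unbroadcast(da(g), a.value.shape)

    return Tensor(value, (a,) if a.requires_grad else (),
                  backward if a.requires_grad else None,
                  requires_grad=a.requires_grad)


def add(a, b):
    a, b = as_tensor(a), as_tensor(b)
    return _binary(a, b, a.value + b.value, lambda g: g, lambda g: g)


def mul(a, b):
    a, b = as_tensor(a), as_tensor(b)
    return _binary(a, b, a.value * b.value,
                   lambda g: g * b.value, lambda g: g * a.value)


def matmul(a, b):
    a, b = as_tensor(a), as_tensor(b)
    return _binary(a, b, a.value @ b.value,
                   lambda g: g @ np.swapaxes(b.value, -1, -2),
                   lambda g: np.swapaxes(a.value, -1, -2) @ g)


def exp(a):
    a = as_tensor(a)
    v = np.exp(a.value)
    return _unary(a, v, lambda g: g * v)


def log(a):
    a = as_tensor(a)
    return _unary(a, np.log(a.value), lambda g: g / a.value)


def tanh(a):
    a = as_tensor(a)
    v = np.tanh(a.value)
    return _unary(a, v, lambda g: g * (1.0 - v * v))


def relu(a):
    a = as_tensor(a)
    m = a.value > 0
    return _unary(a, a.value * m, lambda g: g * m)


def square(a):
    a = as_tensor(a)
    return _unary(a, a.value ** 2, lambda g: 2.0 * g * a.value)


def sum(a, axis=None, keepdims=False):  # noqa: A001 - mirrors numpy naming
    a = as_tensor(a)
    v = a.value.sum(axis=axis, keepdims=keepdims)

    def da(g):
        if axis is None:
            return np.broadcast_to(g, a.value.shape).copy()
        gg = g if keepdims else np.expand_dims(g, axis)
        return np.broadcast_to(gg, a.value.shape).copy()

    return _unary(a, v, da)


def mean(a, axis=None, keepdims=False):
    a = as_tensor(a)
    n = a.value.size if axis is None else a.value.shape[axis]
    return mul(sum(a, axis=axis, keepdims=keepdims), 1.0 / n)


def logsumexp(a, axis=-1, keepdims=False):
    a = as_tensor(a)
    m = np.max(a.value, axis=axis, keepdims=True)
    e = np.exp(a.value - m)
    s = e.sum(axis=axis, keepdims=True)
    v = (m + np.log(s))
    softmax = e / s
    if not keepdims:
        v = np.squeeze(v, axis=axis)

    def da(g):
        gg = g if keepdims else np.expand_dims(g, axis)
        return gg * softmax

    return _unary(a, v, da)


def concat(tensors, axis=-1):
    tensors = [as_tensor(t) for t in tensors]
    v = np.concatenate([t.value for t in tensors], axis=axis)
    sizes = [t.value.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis if axis >= 0 else g.ndim + axis] = slice(lo, hi)
                t.grad += g[tuple(sl)]

    need = any(t.requires_grad for t in tensors)
    return Tensor(v, tuple(tensors) if need else (),
                  backward if need else None, requires_grad=need)


def take(a, idx):
    a = as_tensor(a)
    v = a.value[idx]

    def da(g):
        out = np.zeros_like(a.value)
        np.add.at(out, idx, g)
        return out

    return _unary(a, v, da)


def reshape(a, shape):
    a = as_tensor(a)
    return _unary(a, a.value.reshape(shape),
                  lambda g: g.reshape(a.value.shape))


def bounded(a, limit: float):
    """Smoothly bound values to (-limit, limit) via scaled tanh.

    Used for predicted log-variances to keep mixture densities finite.
    """
    return mul(tanh(mul(a, 1.0 / limit)), limit)
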