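"""Reverse-mode automatic differentiation over numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied to
it; :meth:`Tensor.backward` walks the resulting DAG in reverse topological
order and accumulates gradients into every tensor created with
``requires_grad=True``.  Only the primitives needed by the retention-time
network are implemented (dense algebra, pointwise nonlinearities, gathers,
slicing, reductions); broadcasting follows numpy semantics.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "gather_rows", "concatenate"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` over the axes that numpy broadcasting introduced."""
    if grad.shape == shape:
        return grad
    # remove leading added axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


def _as_tensor(x) -> "Tensor":
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    # make numpy defer to Tensor's reflected operators (ndarray * Tensor etc.)
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad
        self.grad = None
        self._parents: tuple = ()
        self._backward = None

    # -- graph bookkeeping ------------------------------------------------
    @classmethod
    def _op(cls, data, parents, backward) -> "Tensor":
        out = cls(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads = {id(self): np.asarray(grad, dtype=np.float64)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t.requires_grad and t._backward is None:
                # leaf parameter
                t.grad = g if t.grad is None else t.grad + g
                continue
            if t._backward is None:
                continue
            for parent, pg in zip(t._parents, t._backward(g)):
                if pg is None or not parent.requires_grad:
                    continue
                if parent._backward is None:  # leaf
                    parent.grad = pg if parent.grad is None else parent.grad + pg
                else:
                    key = id(parent)
                    grads[key] = pg if key not in grads else grads[key] + pg

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        a, b = self, _as_tensor(other)
        return Tensor._op(
            a.data + b.data,
            (a, b),
            lambda g: (_unbroadcast(g, a.shape), _unbroadcast(g, b.shape)),
        )

    __radd__ = __add__

    def __mul__(self, other):
        a, b = self, _as_tensor(other)
        return Tensor._op(
            a.data * b.data,
            (a, b),
            lambda g: (
                _unbroadcast(g * b.data, a.shape),
                _unbroadcast(g * a.data, b.shape),
            ),
        )

    __rmul__ = __mul__

    def __neg__(self):
        a = self
        return Tensor._op(-a.data, (a,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __truediv__(self, other):
        b = _as_tensor(other)
        return self * (b ** -1.0)

    def __pow__(self, p: float):
        a = self
        out = a.data ** p
        return Tensor._op(out, (a,), lambda g: (g * p * a.data ** (p - 1.0),))

    def __matmul__(self, other):
        a, b = self, _as_tensor(other)
        return Tensor._op(
            a.data @ b.data,
            (a, b),
            lambda g: (g @ b.data.T, a.data.T @ g),
        )

    def __getitem__(self, idx):
        a = self

        def back(g):
            out = np.zeros_like(a.data)
            np.add.at(out, idx, g)
            return (out,)

        return Tensor._op(a.data[idx], (a,), back)

    # -- nonlinearities ---------------------------------------------------
    def sigmoid(self):
        a = self
        s = 1.0 / (1.0 + np.exp(-np.clip(a.data, -500, 500)))
        return Tensor._op(s, (a,), lambda g: (g * s * (1.0 - s),))

    def tanh(self):
        a = self
        t = np.tanh(a.data)
        return Tensor._op(t, (a,), lambda g: (g * (1.0 - t * t),))

    def relu(self):
        a = self
        m = a.data > 0
        return Tensor._op(a.data * m, (a,), lambda g: (g * m,))

    def abs(self):
        a = self
        s = np.sign(a.data)
        return Tensor._op(np.abs(a.data), (a,), lambda g: (g * s,))

    def softplus(self):
        """log(1 + exp(x)), numerically stable; d/dx = sigmoid(x)."""
        a = self
        out = np.logaddexp(0.0, a.data)
        s = 1.0 / (1.0 + np.exp(-np.clip(a.data, -500, 500)))
        return Tensor._op(out, (a,), lambda g: (g * s,))

    def log(self):
        a = self
        return Tensor._op(np.log(a.data), (a,), lambda g: (g / a.data,))

    def exp(self):
        a = self
        e = np.exp(a.data)
        return Tensor._op(e, (a,), lambda g: (g * e,))

    def sqrt(self):
        return self ** 0.5

    # -- reductions / shape ----------------------------------------------
    def sum(self, axis=None, keepdims=False):
        a = self

        def back(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, a.shape).copy(),)

        return Tensor._op(a.data.sum(axis=axis, keepdims=keepdims), (a,), back)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        a = self
        return Tensor._op(a.data.reshape(*shape), (a,), lambda g: (g.reshape(a.shape),))


def gather_rows(w: Tensor, idx: np.ndarray) -> Tensor:
    """Embedding lookup ``w[idx]`` with scatter-add backward."""
    idx = np.asarray(idx)

    def back(g):
        out = np.zeros_like(w.data)
        np.add.at(out, idx.reshape(-1), g.reshape(-1, w.data.shape[1]))
        return (out,)

    return Tensor._op(w.data[idx], (w,), back)


def concatenate(tensors, axis=-1) -> Tensor:
    parts = [_as_tensor(t) for t in tensors]
    sizes = [p.data.shape[axis] for p in parts]
    splits = np.cumsum(sizes)[:-1]

    def back(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._op(np.concatenate([p.data for p in parts], axis=axis), parts, back)
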