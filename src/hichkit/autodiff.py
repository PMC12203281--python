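"""Minimal reverse-mode automatic differentiation over numpy arrays.

This is a deliberately small tensor engine: just the primitives the
sequence-labeling stacks in :mod:`hichkit.ner` need (elementwise math,
broadcasting, matmul, log-sum-exp, gather/embedding, slicing, concat) plus
an Adam optimizer.  Everything is float64 and CPU-only, which keeps runs
bit-reproducible under a fixed seed.

Gradients are accumulated by topological-order backpropagation from a
scalar loss.  Broadcasting is handled by summing gradients back to the
operand's shape.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "embedding",
    "logsumexp",
    "Adam",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # remove prepended axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, dim in enumerate(shape):
        if dim == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], None] | None = None

    # -- construction helpers ------------------------------------------------
    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @classmethod
    def _node(cls, data: np.ndarray, parents: tuple["Tensor", ...],
              backward: Callable[[np.ndarray], None]) -> "Tensor":
        out = cls(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._backward = backward
        return out

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- autograd ------------------------------------------------------------
    def backward(self) -> None:
        """Backpropagate from a scalar."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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
        grads: dict[int, np.ndarray] = {id(self): np.ones_like(self.data)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:
                # leaf parameter: accumulate
                if node.grad is None:
                    node.grad = np.zeros_like(node.data)
                node.grad += g
                continue
            for parent, pg in node._backward(g):
                if not parent.requires_grad:
                    continue
                key = id(parent)
                if key in grads:
                    grads[key] = grads[key] + pg
                else:
                    grads[key] = pg

    # NOTE: _backward closures return [(parent, grad_contribution), ...]

    # -- operators -----------------------------------------------------------
    def __add__(self, other):
        other = Tensor._wrap(other)
        a, b = self, other
        data = a.data + b.data

        def bw(g):
            return [(a, _unbroadcast(g, a.data.shape)),
                    (b, _unbroadcast(g, b.data.shape))]

        return Tensor._node(data, (a, b), bw)

    __radd__ = __add__

    def __neg__(self):
        a = self
        return Tensor._node(-a.data, (a,), lambda g: [(a, -g)])

    def __sub__(self, other):
        return self + (-Tensor._wrap(other))

    def __rsub__(self, other):
        return Tensor._wrap(other) + (-self)

    def __mul__(self, other):
        other = Tensor._wrap(other)
        a, b = self, other
        data = a.data * b.data

        def bw(g):
            return [(a, _unbroadcast(g * b.data, a.data.shape)),
                    (b, _unbroadcast(g * a.data, b.data.shape))]

        return Tensor._node(data, (a, b), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._wrap(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return Tensor._wrap(other) * self ** -1.0

    def __pow__(self, p: float):
        a = self
        data = a.data ** p

        def bw(g):
            return [(a, g * p * a.data ** (p - 1))]

        return Tensor._node(data, (a,), bw)

    def __matmul__(self, other):
        other = Tensor._wrap(other)
        a, b = self, other
        data = a.data @ b.data

        def bw(g):
            if b.data.ndim == 1:
                ga = np.outer(g, b.data) if a.data.ndim == 2 else g * b.data
                gb = a.data.T @ g if a.data.ndim == 2 else g * a.data
            else:
                ga = g @ np.swapaxes(b.data, -1, -2)
                gb = np.swapaxes(a.data, -1, -2) @ g
            return [(a, _unbroadcast(ga, a.data.shape)),
                    (b, _unbroadcast(gb, b.data.shape))]

        return Tensor._node(data, (a, b), bw)

    def __getitem__(self, key):
        a = self
        data = a.data[key]

        def bw(g):
            full = np.zeros_like(a.data)
            np.add.at(full, key, g)
            return [(a, full)]

        return Tensor._node(data, (a,), bw)

    # -- elementwise functions ----------------------------------------------
    def tanh(self):
        a = self
        data = np.tanh(a.data)
        return Tensor._node(data, (a,), lambda g: [(a, g * (1.0 - data ** 2))])

    def sigmoid(self):
        a = self
        data = 1.0 / (1.0 + np.exp(-a.data))
        return Tensor._node(data, (a,), lambda g: [(a, g * data * (1.0 - data))])

    def relu(self):
        a = self
        mask = a.data > 0
        return Tensor._node(a.data * mask, (a,), lambda g: [(a, g * mask)])

    def exp(self):
        a = self
        data = np.exp(a.data)
        return Tensor._node(data, (a,), lambda g: [(a, g * data)])

    def log(self):
        a = self
        return Tensor._node(np.log(a.data), (a,), lambda g: [(a, g / a.data)])

    def sqrt(self):
        return self ** 0.5

    # -- reductions / shape --------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        a = self
        data = a.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return [(a, np.broadcast_to(g, a.data.shape).copy())]

        return Tensor._node(data, (a,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        a = self
        data = a.data.reshape(*shape)
        return Tensor._node(data, (a,), lambda g: [(a, g.reshape(a.data.shape))])

    def swapaxes(self, ax1: int, ax2: int):
        a = self
        data = np.swapaxes(a.data, ax1, ax2)
        return Tensor._node(data, (a,), lambda g: [(a, np.swapaxes(g, ax1, ax2))])


def logsumexp(x: Tensor, axis: int, keepdims: bool = False) -> Tensor:
    """Numerically stable log-sum-exp along ``axis`` with exact softmax grad."""
    m = x.data.max(axis=axis, keepdims=True)
    m = np.where(np.isfinite(m), m, 0.0)
    s = np.exp(x.data - m).sum(axis=axis, keepdims=True)
    out = m + np.log(s)
    soft = np.exp(x.data - out)  # softmax weights
    data = out if keepdims else np.squeeze(out, axis=axis)

    def bw(g):
        g = np.asarray(g)
        if not keepdims:
            g = np.expand_dims(g, axis)
        return [(x, g * soft)]

    return Tensor._node(data, (x,), bw)


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        out = []
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            out.append((t, g[tuple(idx)]))
        return out

    return Tensor._node(data, tuple(tensors), bw)


def embedding(table: Tensor, ids: np.ndarray) -> Tensor:
    """Row gather ``table[ids]`` with scatter-add backward."""
    ids = np.asarray(ids)
    data = table.data[ids]

    def bw(g):
        full = np.zeros_like(table.data)
        np.add.at(full, ids, g)
        return [(table, full)]

    return Tensor._node(data, (table,), bw)


class Adam:
    """Adam with bias correction; state keyed by parameter identity."""

    def __init__(self, params: Iterable[Tensor], lr: float = 1e-2,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mh = m / (1 - self.b1 ** self.t)
            vh = v / (1 - self.b2 ** self.t)
            p.data -= self.lr * mh / (np.sqrt(vh) + self.eps)
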