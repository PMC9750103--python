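"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The attention network here is small (an embedding table, one affine map per
hop, optionally a two-layer head), but it comes in several structural
variants (two aggregators, two attention modes, optional layer-wise
concatenation, arbitrary hop depth), so hand-derived gradients would have to
be re-derived per variant. Instead we record a tape of array operations and
back-propagate vector-Jacobian products through it. Everything is float64;
the op set is exactly what the forward pass needs.

Gradients are verified against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "gather",
    "concat",
    "leaky_relu",
    "sigmoid",
    "exp",
    "log",
    "matmul",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing NumPy broadcasting."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, n in enumerate(shape) if n == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A NumPy array plus the tape entries needed to back-propagate through it.

    `_parents` is a tuple of (parent, vjp) pairs where vjp maps the gradient
    w.r.t. this tensor to a gradient contribution for the parent.
    """

    __slots__ = ("data", "grad", "requires_grad", "_parents")

    # make `ndarray <op> Tensor` dispatch to the reflected Tensor operator
    __array_priority__ = 1000

    def __init__(self, data, requires_grad: bool = False, _parents=()):
        self.data = np.asarray(data, dtype=np.float64)
        self._parents = _parents
        self.requires_grad = requires_grad or any(
            p.requires_grad for p, _ in _parents
        )
        self.grad: np.ndarray | None = None

    # -- graph traversal ---------------------------------------------------

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative post-order; deep tapes must not hit the recursion limit
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent, _ in node._parents:
                stack.append((parent, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if not node._parents:  # leaf
                node.grad = g if node.grad is None else node.grad + g
                continue
            for parent, vjp in node._parents:
                if not parent.requires_grad:
                    continue
                contrib = vjp(g)
                key = id(parent)
                if key in grads:
                    grads[key] = grads[key] + contrib
                else:
                    grads[key] = contrib

    # -- shape -------------------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        return Tensor(
            self.data.reshape(shape),
            _parents=((self, lambda g, old=old: g.reshape(old)),),
        )

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other) -> "Tensor":
        other = as_tensor(other)
        return Tensor(
            self.data + other.data,
            _parents=(
                (self, lambda g: _unbroadcast(g, self.data.shape)),
                (other, lambda g: _unbroadcast(g, other.data.shape)),
            ),
        )

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        return Tensor(-self.data, _parents=((self, lambda g: -g),))

    def __sub__(self, other) -> "Tensor":
        return self + (-as_tensor(other))

    def __rsub__(self, other) -> "Tensor":
        return as_tensor(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = as_tensor(other)
        return Tensor(
            self.data * other.data,
            _parents=(
                (self, lambda g: _unbroadcast(g * other.data, self.data.shape)),
                (other, lambda g: _unbroadcast(g * self.data, other.data.shape)),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = as_tensor(other)
        return Tensor(
            self.data / other.data,
            _parents=(
                (self, lambda g: _unbroadcast(g / other.data, self.data.shape)),
                (
                    other,
                    lambda g: _unbroadcast(
                        -g * self.data / (other.data**2), other.data.shape
                    ),
                ),
            ),
        )

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def vjp(g, axis=axis, keepdims=keepdims):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return np.broadcast_to(g, self.data.shape).copy()

        return Tensor(out, _parents=((self, vjp),))

    def mean(self) -> "Tensor":
        n = self.data.size
        return self.sum() * (1.0 / n)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    """Matrix product with NumPy batch-broadcasting on leading axes."""
    a, b = as_tensor(a), as_tensor(b)
    out = a.data @ b.data

    def vjp_a(g):
        return _unbroadcast(g @ np.swapaxes(b.data, -1, -2), a.data.shape)

    def vjp_b(g):
        return _unbroadcast(np.swapaxes(a.data, -1, -2) @ g, b.data.shape)

    return Tensor(out, _parents=((a, vjp_a), (b, vjp_b)))


def exp(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out = np.exp(x.data)
    return Tensor(out, _parents=((x, lambda g: g * out),))


def log(x: Tensor) -> Tensor:
    x = as_tensor(x)
    return Tensor(np.log(x.data), _parents=((x, lambda g: g / x.data),))


def sigmoid(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out = 1.0 / (1.0 + np.exp(-x.data))
    return Tensor(out, _parents=((x, lambda g: g * out * (1.0 - out)),))


def leaky_relu(x: Tensor, alpha: float = 0.1) -> Tensor:
    x = as_tensor(x)
    slope = np.where(x.data >= 0, 1.0, alpha)
    return Tensor(x.data * slope, _parents=((x, lambda g: g * slope),))


def gather(table: Tensor, idx: np.ndarray) -> Tensor:
    """Row lookup `table[idx]`; the gradient scatter-adds into the table."""
    table = as_tensor(table)
    idx = np.asarray(idx)
    out = table.data[idx]

    def vjp(g):
        acc = np.zeros_like(table.data)
        np.add.at(acc, idx.reshape(-1), g.reshape(-1, table.data.shape[-1]))
        return acc

    return Tensor(out, _parents=((table, vjp),))


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def make_vjp(i):
        def vjp(g):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(offsets[i], offsets[i + 1])
            return g[tuple(sl)]

        return vjp

    return Tensor(out, _parents=tuple((t, make_vjp(i)) for i, t in enumerate(tensors)))
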