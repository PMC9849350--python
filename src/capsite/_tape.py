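"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The recurrent gates, capsule routing and fusion head in :mod:`capsite.network`
are trained by gradient descent; this module supplies the gradients.  It is a
deliberately small tape: a :class:`Tensor` wraps an ``ndarray`` and records,
for each primitive operation, the parent tensors together with a closure that
maps the upstream gradient to each parent's contribution.  ``backward`` walks
the graph once in reverse topological order.

Only the primitives the network actually uses are implemented (broadcasting
arithmetic, matmul, einsum, sigmoid/tanh/exp/log, axis reductions, reshape,
transpose, concatenate, row gather, slicing).  Gradients are verified against
central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "concatenate",
    "einsum",
    "log_softmax",
    "sigmoid",
    "softmax",
    "tanh",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """An ndarray plus the recipe for propagating gradients to its parents."""

    __slots__ = ("data", "grad", "_parents", "requires_grad")

    def __init__(self, data, parents=(), requires_grad=False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self._parents = tuple(parents)  # (Tensor, grad_fn) pairs
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p, _ in parents
        )

    # -- construction helpers -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- graph traversal ------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        """Accumulate gradients of ``self`` w.r.t. every upstream tensor."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a seed needs a scalar")
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
            for parent, _ in node._parents:
                if parent.requires_grad and id(parent) not in seen:
                    stack.append((parent, False))
        self.grad = grad
        for node in reversed(topo):
            g = node.grad
            if g is None:
                continue
            for parent, grad_fn in node._parents:
                if not parent.requires_grad:
                    continue
                contrib = grad_fn(g)
                if parent.grad is None:
                    parent.grad = contrib.copy()
                else:
                    parent.grad += contrib

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        return Tensor(
            self.data + other.data,
            parents=(
                (self, lambda g: _unbroadcast(g, self.shape)),
                (other, lambda g: _unbroadcast(g, other.shape)),
            ),
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.data, parents=((self, lambda g: -g),))

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        return Tensor(
            self.data * other.data,
            parents=(
                (self, lambda g: _unbroadcast(g * other.data, self.shape)),
                (other, lambda g: _unbroadcast(g * self.data, other.shape)),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = self.data / other.data
        return Tensor(
            out,
            parents=(
                (self, lambda g: _unbroadcast(g / other.data, self.shape)),
                (
                    other,
                    lambda g: _unbroadcast(
                        -g * self.data / (other.data**2), other.shape
                    ),
                ),
            ),
        )

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")
        out = self.data**exponent
        return Tensor(
            out,
            parents=(
                (self, lambda g: g * exponent * self.data ** (exponent - 1)),
            ),
        )

    def __matmul__(self, other):
        other = as_tensor(other)
        return Tensor(
            self.data @ other.data,
            parents=(
                (self, lambda g: g @ other.data.swapaxes(-1, -2)),
                (other, lambda g: self.data.swapaxes(-1, -2) @ g),
            ),
        )

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape
        return Tensor(
            self.data.reshape(shape),
            parents=((self, lambda g: g.reshape(old)),),
        )

    def transpose(self, *axes):
        if not axes:
            axes = tuple(reversed(range(self.ndim)))
        inv = np.argsort(axes)
        return Tensor(
            self.data.transpose(axes),
            parents=((self, lambda g: g.transpose(inv)),),
        )

    def __getitem__(self, key):
        out = self.data[key]
        shape = self.shape

        def grad_fn(g):
            full = np.zeros(shape)
            np.add.at(full, key, g)
            return full

        return Tensor(out, parents=((self, grad_fn),))

    def take_rows(self, index: np.ndarray) -> "Tensor":
        """Gather rows along axis 0; duplicate indices accumulate gradient."""
        index = np.asarray(index, dtype=np.intp)
        shape = self.shape

        def grad_fn(g):
            full = np.zeros(shape)
            np.add.at(full, index, g)
            return full

        return Tensor(self.data[index], parents=((self, grad_fn),))

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = self.data.sum(axis=axis, keepdims=keepdims)
        shape = self.shape

        def grad_fn(g):
            if axis is None:
                return np.broadcast_to(g, shape).copy()
            g_exp = g if keepdims else np.expand_dims(g, axis)
            return np.broadcast_to(g_exp, shape).copy()

        return Tensor(out, parents=((self, grad_fn),))

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)


def as_tensor(value) -> Tensor:
    return value if isinstance(value, Tensor) else Tensor(value)


# -- elementwise nonlinearities ----------------------------------------------


def sigmoid(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out = 1.0 / (1.0 + np.exp(-x.data))
    return Tensor(out, parents=((x, lambda g: g * out * (1.0 - out)),))


def tanh(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out = np.tanh(x.data)
    return Tensor(out, parents=((x, lambda g: g * (1.0 - out**2)),))


def exp(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out = np.exp(x.data)
    return Tensor(out, parents=((x, lambda g: g * out),))


def log(x: Tensor) -> Tensor:
    x = as_tensor(x)
    return Tensor(np.log(x.data), parents=((x, lambda g: g / x.data),))


def sqrt(x: Tensor) -> Tensor:
    return x**0.5


# -- composites ---------------------------------------------------------------


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax (max-shift is a constant, so the gradient
    is unaffected by detaching it)."""
    x = as_tensor(x)
    shift = x - Tensor(x.data.max(axis=axis, keepdims=True))
    e = exp(shift)
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    x = as_tensor(x)
    shift = x - Tensor(x.data.max(axis=axis, keepdims=True))
    return shift - log(exp(shift).sum(axis=axis, keepdims=True))


def concatenate(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)
    out = np.concatenate([t.data for t in tensors], axis=axis)

    def make_grad_fn(lo, hi):
        def grad_fn(g):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            return g[tuple(sl)]

        return grad_fn

    parents = [
        (t, make_grad_fn(offsets[i], offsets[i + 1]))
        for i, t in enumerate(tensors)
    ]
    return Tensor(out, parents=parents)


def einsum(subscripts: str, a: Tensor, b: Tensor) -> Tensor:
    """Two-operand einsum.  Every index of each operand must appear in the
    other operand or in the output (no internal traces/diagonals), which holds
    for all contractions used by the capsule layer."""
    a, b = as_tensor(a), as_tensor(b)
    lhs, out_sub = subscripts.replace(" ", "").split("->")
    sub_a, sub_b = lhs.split(",")
    for name, sub, other in (("first", sub_a, sub_b), ("second", sub_b, sub_a)):
        if len(set(sub)) != len(sub):
            raise ValueError(f"repeated index in {name} operand: {subscripts!r}")
        if not set(sub) <= set(other) | set(out_sub):
            raise ValueError(f"dangling index in {name} operand: {subscripts!r}")

    out = np.einsum(subscripts, a.data, b.data)

    def grad_a(g):
        return np.einsum(f"{out_sub},{sub_b}->{sub_a}", g, b.data)

    def grad_b(g):
        return np.einsum(f"{out_sub},{sub_a}->{sub_b}", g, a.data)

    return Tensor(out, parents=((a, grad_a), (b, grad_b)))
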