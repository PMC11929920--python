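"""Minimal reverse-mode automatic differentiation over numpy arrays.

A :class:`Var` wraps an ``ndarray`` and records the operations applied to
it; :meth:`Var.backward` runs the reverse sweep in topological order and
accumulates gradients on every leaf created with ``requires_grad=True``.
Supports the broadcasting semantics of numpy (gradients of broadcast
operands are summed back to the operand's shape).

Only the operations needed by the package's recurrent networks and
differentiable game rollouts are provided; gradient correctness is
verified against central finite differences in the test suite.
"""

from __future__ import annotations

from typing import Callable, Optional, Sequence, Union

import numpy as np

__all__ = [
    "Var",
    "concat",
    "stack",
    "matmul",
    "relu",
    "tanh",
    "sigmoid",
    "exp",
    "log",
    "softmax",
    "log_softmax",
    "broadcast_to",
    "minimum",
    "maximum",
    "clip",
    "where",
    "vsum",
]

ArrayLike = Union[np.ndarray, float, int]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Var:
    __slots__ = ("value", "grad", "parents", "_backward", "requires_grad")

    def __init__(
        self,
        value: ArrayLike,
        parents: Sequence["Var"] = (),
        backward: Optional[Callable[[np.ndarray], None]] = None,
        requires_grad: bool = False,
    ):
        self.value = np.asarray(value, dtype=float)
        self.grad: Optional[np.ndarray] = None
        self.parents = tuple(parents)
        self._backward = backward
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    # -- graph machinery --------------------------------------------------

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=float)
        else:
            self.grad = self.grad + g

    def backward(self, grad: Optional[ArrayLike] = None) -> None:
        """Reverse sweep from this node; seeds with 1 for scalars."""
        if grad is None:
            if self.value.size != 1:
                raise ValueError("backward() without a seed needs a scalar output")
            grad = np.ones_like(self.value)
        order: list[Var] = []
        seen: set[int] = set()
        stack_: list[tuple[Var, bool]] = [(self, False)]
        while stack_:
            node, done = stack_.pop()
            if done:
                order.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack_.append((node, True))
            for p in node.parents:
                stack_.append((p, False))
        self._accumulate(np.asarray(grad, dtype=float))
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- helpers -----------------------------------------------------------

    @property
    def shape(self):
        return self.value.shape

    def __repr__(self):
        return f"Var(shape={self.value.shape}, requires_grad={self.requires_grad})"

    @staticmethod
    def _wrap(x: Union["Var", ArrayLike]) -> "Var":
        return x if isinstance(x, Var) else Var(x)

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        other = Var._wrap(other)
        out = Var(self.value + other.value, (self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.value.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.value.shape))

        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Var(-self.value, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(-g)

        out._backward = bwd
        return out

    def __sub__(self, other):
        return self + (-Var._wrap(other))

    def __rsub__(self, other):
        return Var._wrap(other) + (-self)

    def __mul__(self, other):
        other = Var._wrap(other)
        out = Var(self.value * other.value, (self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.value, self.value.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.value, other.value.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Var._wrap(other)
        out = Var(self.value / other.value, (self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.value, self.value.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.value / other.value**2, other.value.shape)
                )

        out._backward = bwd
        return out

    def __rtruediv__(self, other):
        return Var._wrap(other) / self

    def __pow__(self, exponent: float):
        out = Var(self.value**exponent, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * exponent * self.value ** (exponent - 1))

        out._backward = bwd
        return out

    def __getitem__(self, idx):
        out = Var(self.value[idx], (self,))

        def bwd(g):
            if self.requires_grad:
                full = np.zeros_like(self.value)
                np.add.at(full, idx, g)
                self._accumulate(full)

        out._backward = bwd
        return out

    def reshape(self, *shape):
        out = Var(self.value.reshape(*shape), (self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g.reshape(self.value.shape))

        out._backward = bwd
        return out

    def sum(self, axis=None, keepdims: bool = False):
        out = Var(self.value.sum(axis=axis, keepdims=keepdims), (self,))

        def bwd(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.value.shape).copy())
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(g, self.value.shape).copy())

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.value.size if axis is None else self.value.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)


# -- free functions --------------------------------------------------------


def matmul(a: Var, b: Var) -> Var:
    a, b = Var._wrap(a), Var._wrap(b)
    out = Var(a.value @ b.value, (a, b))

    def bwd(g):
        if a.requires_grad:
            a._accumulate(g @ b.value.T)
        if b.requires_grad:
            b._accumulate(a.value.T @ g)

    out._backward = bwd
    return out


def relu(x: Var) -> Var:
    x = Var._wrap(x)
    mask = x.value > 0
    out = Var(x.value * mask, (x,))

    def bwd(g):
        if x.requires_grad:
            x._accumulate(g * mask)

    out._backward = bwd
    return out


def tanh(x: Var) -> Var:
    x = Var._wrap(x)
    val = np.tanh(x.value)
    out = Var(val, (x,))

    def bwd(g):
        if x.requires_grad:
            x._accumulate(g * (1.0 - val**2))

    out._backward = bwd
    return out


def sigmoid(x: Var) -> Var:
    x = Var._wrap(x)
    val = 1.0 / (1.0 + np.exp(-np.clip(x.value, -60, 60)))
    out = Var(val, (x,))

    def bwd(g):
        if x.requires_grad:
            x._accumulate(g * val * (1.0 - val))

    out._backward = bwd
    return out


def exp(x: Var) -> Var:
    x = Var._wrap(x)
    val = np.exp(x.value)
    out = Var(val, (x,))

    def bwd(g):
        if x.requires_grad:
            x._accumulate(g * val)

    out._backward = bwd
    return out


def log(x: Var) -> Var:
    x = Var._wrap(x)
    out = Var(np.log(x.value), (x,))

    def bwd(g):
        if x.requires_grad:
            x._accumulate(g / x.value)

    out._backward = bwd
    return out


def log_softmax(x: Var, axis: int = -1) -> Var:
    x = Var._wrap(x)
    shifted = x.value - x.value.max(axis=axis, keepdims=True)
    lse = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
    val = shifted - lse
    out = Var(val, (x,))
    soft = np.exp(val)

    def bwd(g):
        if x.requires_grad:
            x._accumulate(g - soft * g.sum(axis=axis, keepdims=True))

    out._backward = bwd
    return out


def softmax(x: Var, axis: int = -1) -> Var:
    return exp(log_softmax(x, axis=axis))


def minimum(x: Var, other: Union[Var, ArrayLike]) -> Var:
    """Elementwise min; ties route the gradient to the first argument."""
    x, other = Var._wrap(x), Var._wrap(other)
    take_x = x.value <= other.value
    out = Var(np.where(take_x, x.value, other.value), (x, other))

    def bwd(g):
        if x.requires_grad:
            x._accumulate(_unbroadcast(g * take_x, x.value.shape))
        if other.requires_grad:
            other._accumulate(_unbroadcast(g * ~take_x, other.value.shape))

    out._backward = bwd
    return out


def maximum(x: Var, other: Union[Var, ArrayLike]) -> Var:
    x, other = Var._wrap(x), Var._wrap(other)
    take_x = x.value >= other.value
    out = Var(np.where(take_x, x.value, other.value), (x, other))

    def bwd(g):
        if x.requires_grad:
            x._accumulate(_unbroadcast(g * take_x, x.value.shape))
        if other.requires_grad:
            other._accumulate(_unbroadcast(g * ~take_x, other.value.shape))

    out._backward = bwd
    return out


def clip(x: Var, lo: float, hi: float) -> Var:
    return minimum(maximum(x, lo), hi)


def where(cond: np.ndarray, a: Union[Var, ArrayLike], b: Union[Var, ArrayLike]) -> Var:
    """Select by a *constant* boolean mask (no gradient through cond)."""
    cond = np.asarray(cond, dtype=bool)
    a, b = Var._wrap(a), Var._wrap(b)
    out = Var(np.where(cond, a.value, b.value), (a, b))

    def bwd(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * cond, a.value.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * ~cond, b.value.shape))

    out._backward = bwd
    return out


def broadcast_to(x: Var, shape: tuple) -> Var:
    x = Var._wrap(x)
    out = Var(np.broadcast_to(x.value, shape).copy(), (x,))

    def bwd(g):
        if x.requires_grad:
            x._accumulate(_unbroadcast(g, x.value.shape))

    out._backward = bwd
    return out


def concat(vars_: Sequence[Var], axis: int = -1) -> Var:
    vars_ = [Var._wrap(v) for v in vars_]
    out = Var(np.concatenate([v.value for v in vars_], axis=axis), vars_)
    sizes = [v.value.shape[axis] for v in vars_]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for v, lo, hi in zip(vars_, offsets[:-1], offsets[1:]):
            if v.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                v._accumulate(g[tuple(sl)])

    out._backward = bwd
    return out


def stack(vars_: Sequence[Var], axis: int = 0) -> Var:
    vars_ = [Var._wrap(v) for v in vars_]
    out = Var(np.stack([v.value for v in vars_], axis=axis), vars_)

    def bwd(g):
        for i, v in enumerate(vars_):
            if v.requires_grad:
                v._accumulate(np.take(g, i, axis=axis))

    out._backward = bwd
    return out


def vsum(vars_: Sequence[Var]) -> Var:
    """Sum a list of same-shape Vars."""
    total = vars_[0]
    for v in vars_[1:]:
        total = total + v
    return total
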