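"""Minimal reverse-mode automatic differentiation over numpy arrays.

A tape-free define-by-run graph: each op returns a :class:`Tensor` holding
the forward value, its parents, and a closure that maps the output gradient
to parent-gradient contributions.  ``Tensor.backward()`` topologically
sorts the graph and accumulates gradients.  Only the handful of primitives
the transformer needs are implemented (broadcast add/mul, batched matmul,
reshape/transpose/slice/concat, reductions, GELU, softmax, layer norm,
dropout, softmax cross-entropy); every backward rule is checked against
finite differences in the test suite.

All computation is float32.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
from scipy.special import erf

__all__ = ["Tensor", "concat", "cross_entropy_logits", "gelu", "layer_norm",
           "softmax", "dropout", "parameter"]

_INV_SQRT2 = np.float32(1.0 / np.sqrt(2.0))
_INV_SQRT2PI = np.float32(1.0 / np.sqrt(2.0 * np.pi))


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array plus the bookkeeping for reverse-mode differentiation."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        parents: tuple["Tensor", ...] = (),
        backward: Callable[[np.ndarray], None] | None = None,
    ):
        arr = np.asarray(data)
        if arr.dtype != np.float64:  # keep float64 for high-precision checks
            arr = arr.astype(np.float32, copy=False)
        self.data = arr
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # -- graph -------------------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def _accum(self, g: np.ndarray) -> None:
        self.grad = g if self.grad is None else self.grad + g

    def backward(self) -> None:
        """Backpropagate from this (scalar or any-shaped) tensor."""
        order: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                order.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accum(np.ones_like(self.data))
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic ---------------------------------------------------------
    def _coerce(self, other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other) -> "Tensor":
        a, b = self, self._coerce(other)

        def back(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.shape))

        return Tensor(a.data + b.data, parents=(a, b), backward=back)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        a = self
        return Tensor(-a.data, parents=(a,),
                      backward=lambda g: a._accum(-g))

    def __sub__(self, other) -> "Tensor":
        return self + (-self._coerce(other))

    def __mul__(self, other) -> "Tensor":
        a, b = self, self._coerce(other)

        def back(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.shape))

        return Tensor(a.data * b.data, parents=(a, b), backward=back)

    __rmul__ = __mul__

    def __matmul__(self, other) -> "Tensor":
        a, b = self, self._coerce(other)

        def back(g):
            if a.requires_grad:
                ga = g @ np.swapaxes(b.data, -1, -2)
                a._accum(_unbroadcast(ga, a.shape))
            if b.requires_grad:
                gb = np.swapaxes(a.data, -1, -2) @ g
                b._accum(_unbroadcast(gb, b.shape))

        return Tensor(a.data @ b.data, parents=(a, b), backward=back)

    def __getitem__(self, idx) -> "Tensor":
        a = self

        def back(g):
            full = np.zeros_like(a.data)
            np.add.at(full, idx, g)
            a._accum(full)

        return Tensor(a.data[idx], parents=(a,), backward=back)

    # -- shape ops ----------------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        a = self
        return Tensor(a.data.reshape(*shape), parents=(a,),
                      backward=lambda g: a._accum(g.reshape(a.shape)))

    def transpose(self, *axes) -> "Tensor":
        a = self
        inv = np.argsort(axes)
        return Tensor(a.data.transpose(*axes), parents=(a,),
                      backward=lambda g: a._accum(g.transpose(*inv)))

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        a = self

        def back(g):
            if axis is None:
                a._accum(np.broadcast_to(g, a.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            a._accum(np.broadcast_to(g, a.shape).copy())

        return Tensor(a.data.sum(axis=axis, keepdims=keepdims),
                      parents=(a,), backward=back)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * np.float32(1.0 / n)


def parameter(data: np.ndarray) -> Tensor:
    """Wrap an array as a trainable leaf tensor."""
    return Tensor(data, requires_grad=True)


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    ts = list(tensors)
    sizes = [t.data.shape[axis] for t in ts]
    splits = np.cumsum(sizes)[:-1]

    def back(g):
        for t, piece in zip(ts, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accum(piece)

    return Tensor(np.concatenate([t.data for t in ts], axis=axis),
                  parents=tuple(ts), backward=back)


def gelu(x: Tensor) -> Tensor:
    """Gaussian-error linear unit, exact erf form."""
    xd = x.data
    cdf = 0.5 * (1.0 + erf(xd * _INV_SQRT2))
    out = xd * cdf

    def back(g):
        pdf = _INV_SQRT2PI * np.exp(-0.5 * xd * xd)
        x._accum(g * (cdf + xd * pdf))

    return Tensor(out, parents=(x,), backward=back)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)

    def back(g):
        dot = (g * y).sum(axis=axis, keepdims=True)
        x._accum(y * (g - dot))

    return Tensor(y, parents=(x,), backward=back)


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor,
               eps: float = 1e-5) -> Tensor:
    """Layer normalization over the trailing axis."""
    xd = x.data
    mu = xd.mean(axis=-1, keepdims=True)
    var = xd.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (xd - mu) * inv
    out = gamma.data * xhat + beta.data

    def back(g):
        if gamma.requires_grad:
            gamma._accum(_unbroadcast(g * xhat, gamma.shape))
        if beta.requires_grad:
            beta._accum(_unbroadcast(g, beta.shape))
        if x.requires_grad:
            gh = g * gamma.data
            m1 = gh.mean(axis=-1, keepdims=True)
            m2 = (gh * xhat).mean(axis=-1, keepdims=True)
            x._accum(inv * (gh - m1 - xhat * m2))

    return Tensor(out, parents=(x, gamma, beta), backward=back)


def dropout(x: Tensor, p: float, rng: np.random.Generator,
            train: bool = True) -> Tensor:
    """Inverted dropout; identity when not training or p == 0."""
    if not train or p <= 0.0:
        return x
    mask = (rng.random(x.shape) >= p).astype(np.float32) / np.float32(1.0 - p)

    def back(g):
        x._accum(g * mask)

    return Tensor(x.data * mask, parents=(x,), backward=back)


def cross_entropy_logits(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy of integer class labels."""
    z = logits.data - logits.data.max(axis=-1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=-1, keepdims=True)
    n = logits.data.shape[0]
    rows = np.arange(n)
    loss = -np.mean(np.log(p[rows, labels] + 1e-12))

    def back(g):
        d = p.copy()
        d[rows, labels] -= 1.0
        logits._accum(g * d / np.float32(n))

    return Tensor(loss, parents=(logits,), backward=back)
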