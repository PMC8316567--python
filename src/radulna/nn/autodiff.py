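"""Minimal vectorized reverse-mode automatic differentiation.

A :class:`Tensor` wraps a float64 numpy array and records the operations
that produced it; :meth:`Tensor.backward` accumulates gradients through the
recorded graph.  Only the operations the package's networks need are
implemented: broadcast arithmetic, 2D matmul, the usual activations, fused
losses (softmax cross-entropy, binary cross-entropy with logits), L1/L2
norms, softmax, reshape/concat and reductions.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(parents)
        self._backward = backward

    # -- graph -------------------------------------------------------------
    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo, seen = [], set()

        def visit(t: "Tensor"):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = None
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad = self.grad + grad

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    # -- arithmetic --------------------------------------------------------
    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = Tensor._wrap(other)
        out_data = self.data + other.data

        def bwd(g):
            self._accum(_unbroadcast(g, self.data.shape))
            other._accum(_unbroadcast(g, other.data.shape))

        return Tensor(out_data, parents=(self, other), backward=bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            self._accum(-g)

        return Tensor(-self.data, parents=(self,), backward=bwd)

    def __sub__(self, other):
        return self + (-Tensor._wrap(other))

    def __rsub__(self, other):
        return Tensor._wrap(other) + (-self)

    def __mul__(self, other):
        other = Tensor._wrap(other)
        out_data = self.data * other.data

        def bwd(g):
            self._accum(_unbroadcast(g * other.data, self.data.shape))
            other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor(out_data, parents=(self, other), backward=bwd)

    __rmul__ = __mul__

    def matmul(self, other: "Tensor") -> "Tensor":
        other = Tensor._wrap(other)
        out_data = self.data @ other.data

        def bwd(g):
            self._accum(g @ other.data.T)
            other._accum(self.data.T @ g)

        return Tensor(out_data, parents=(self, other), backward=bwd)

    __matmul__ = matmul

    def reshape(self, *shape) -> "Tensor":
        old = self.data.shape
        out_data = self.data.reshape(*shape)

        def bwd(g):
            self._accum(g.reshape(old))

        return Tensor(out_data, parents=(self,), backward=bwd)

    def transpose(self, axes) -> "Tensor":
        axes = tuple(axes)
        inv = tuple(np.argsort(axes))

        def bwd(g):
            self._accum(g.transpose(inv))

        return Tensor(self.data.transpose(axes), parents=(self,), backward=bwd)

    def sum(self) -> "Tensor":
        def bwd(g):
            self._accum(np.full_like(self.data, float(g)))

        return Tensor(self.data.sum(), parents=(self,), backward=bwd)

    def mean(self) -> "Tensor":
        n = self.data.size

        def bwd(g):
            self._accum(np.full_like(self.data, float(g) / n))

        return Tensor(self.data.mean(), parents=(self,), backward=bwd)

    # -- activations -------------------------------------------------------
    def relu(self) -> "Tensor":
        mask = self.data > 0

        def bwd(g):
            self._accum(g * mask)

        return Tensor(self.data * mask, parents=(self,), backward=bwd)

    def leaky_relu(self, alpha: float = 0.2) -> "Tensor":
        slope = np.where(self.data > 0, 1.0, alpha)

        def bwd(g):
            self._accum(g * slope)

        return Tensor(self.data * slope, parents=(self,), backward=bwd)

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))

        def bwd(g):
            self._accum(g * s * (1.0 - s))

        return Tensor(s, parents=(self,), backward=bwd)

    def tanh(self) -> "Tensor":
        t = np.tanh(self.data)

        def bwd(g):
            self._accum(g * (1.0 - t * t))

        return Tensor(t, parents=(self,), backward=bwd)

    def softplus(self) -> "Tensor":
        x = self.data
        out = np.logaddexp(0.0, x)
        s = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))

        def bwd(g):
            self._accum(g * s)

        return Tensor(out, parents=(self,), backward=bwd)


def softmax(t: Tensor, axis: int = -1) -> Tensor:
    x = t.data
    m = x.max(axis=axis, keepdims=True)
    e = np.exp(x - m)
    p = e / e.sum(axis=axis, keepdims=True)

    def bwd(g):
        dot = (g * p).sum(axis=axis, keepdims=True)
        t._accum(p * (g - dot))

    return Tensor(p, parents=(t,), backward=bwd)


def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accum(piece)

    return Tensor(out_data, parents=tuple(tensors), backward=bwd)


def l1_norm(t: Tensor) -> Tensor:
    """Sum of absolute entries."""

    def bwd(g):
        t._accum(float(g) * np.sign(t.data))

    return Tensor(np.abs(t.data).sum(), parents=(t,), backward=bwd)


def l2_norm(t: Tensor) -> Tensor:
    """Euclidean norm (not squared); gradient is zero at the origin."""
    n = float(np.sqrt((t.data**2).sum()))

    def bwd(g):
        if n > 1e-12:
            t._accum(float(g) * t.data / n)

    return Tensor(n, parents=(t,), backward=bwd)


def l1_loss(a: Tensor, b) -> Tensor:
    """Mean absolute difference."""
    b = Tensor._wrap(b)
    diff = a.data - b.data
    n = diff.size

    def bwd(g):
        s = float(g) * np.sign(diff) / n
        a._accum(s)
        b._accum(-s)

    return Tensor(np.abs(diff).mean(), parents=(a, b), backward=bwd)


def softmax_cross_entropy(logits: Tensor, target_classes: np.ndarray) -> Tensor:
    """Mean over rows of -log softmax(logits)[target]; logits shape (N, C)."""
    x = logits.data
    if x.ndim != 2:
        raise ValueError("logits must be (N, C)")
    t = np.asarray(target_classes).reshape(-1)
    n, c = x.shape
    if t.shape[0] != n:
        raise ValueError("target length must match logits rows")
    if t.min() < 0 or t.max() >= c:
        raise ValueError(f"target classes must be in [0, {c})")
    m = x.max(axis=1, keepdims=True)
    e = np.exp(x - m)
    p = e / e.sum(axis=1, keepdims=True)
    nll = -np.log(np.maximum(p[np.arange(n), t], 1e-300))

    def bwd(g):
        grad = p.copy()
        grad[np.arange(n), t] -= 1.0
        logits._accum(float(g) * grad / n)

    return Tensor(nll.mean(), parents=(logits,), backward=bwd)


def bce_with_logits(logits: Tensor, target) -> Tensor:
    """Mean binary cross-entropy on logits; target is 0/1 (array or scalar)."""
    x = logits.data
    t = np.broadcast_to(np.asarray(target, dtype=np.float64), x.shape)
    # log(1 + e^x) - x*t, numerically stable
    loss = np.logaddexp(0.0, x) - x * t
    s = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
    n = x.size

    def bwd(g):
        logits._accum(float(g) * (s - t) / n)

    return Tensor(loss.mean(), parents=(logits,), backward=bwd)
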