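"""Minimal reverse-mode automatic differentiation over numpy arrays.

A small tape-based engine providing exactly the operations the trough
prediction network needs: broadcasting arithmetic, 2-D matrix products,
sigmoid/tanh/LeakyReLU activations, sparsemax, concatenation/stacking,
reshaping, masked reductions and a numerically stable binary cross-entropy
on logits.  Gradients are accumulated by topological traversal of the
recorded graph.  Everything is plain float64 numpy, so runs are
bit-reproducible for a fixed seed on one machine.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "tensor",
    "add",
    "sub",
    "mul",
    "matmul",
    "sigmoid",
    "tanh",
    "leaky_relu",
    "sparsemax_np",
    "sparsemax",
    "concat",
    "stack",
    "reshape",
    "tsum",
    "minimum",
    "bce_with_logits",
    "backward",
]


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("value", "grad", "parents", "backward_fn", "requires_grad")

    def __init__(self, value, parents=(), backward_fn=None, requires_grad=True):
        self.value = np.asarray(value, dtype=float)
        self.grad = None
        self.parents = parents
        self.backward_fn = backward_fn
        self.requires_grad = requires_grad

    @property
    def shape(self):
        return self.value.shape

    # operator sugar (constants are promoted)
    def __add__(self, other):
        return add(self, _as_tensor(other))

    def __sub__(self, other):
        return sub(self, _as_tensor(other))

    def __mul__(self, other):
        return mul(self, _as_tensor(other))

    def __matmul__(self, other):
        return matmul(self, _as_tensor(other))

    def __neg__(self):
        return mul(self, tensor(-1.0, requires_grad=False))


def tensor(value, requires_grad=True) -> Tensor:
    return Tensor(value, requires_grad=requires_grad)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x, requires_grad=False)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum-reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


def add(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.value + b.value, (a, b))

    def bw(g):
        return _unbroadcast(g, a.value.shape), _unbroadcast(g, b.value.shape)

    out.backward_fn = bw
    return out


def sub(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.value - b.value, (a, b))

    def bw(g):
        return _unbroadcast(g, a.value.shape), _unbroadcast(-g, b.value.shape)

    out.backward_fn = bw
    return out


def mul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.value * b.value, (a, b))

    def bw(g):
        return (
            _unbroadcast(g * b.value, a.value.shape),
            _unbroadcast(g * a.value, b.value.shape),
        )

    out.backward_fn = bw
    return out


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.value @ b.value, (a, b))

    def bw(g):
        return g @ b.value.T, a.value.T @ g

    out.backward_fn = bw
    return out


def sigmoid(a: Tensor) -> Tensor:
    v = np.where(a.value >= 0, 1.0 / (1.0 + np.exp(-a.value)),
                 np.exp(a.value) / (1.0 + np.exp(a.value)))
    out = Tensor(v, (a,))
    out.backward_fn = lambda g: (g * v * (1.0 - v),)
    return out


def tanh(a: Tensor) -> Tensor:
    v = np.tanh(a.value)
    out = Tensor(v, (a,))
    out.backward_fn = lambda g: (g * (1.0 - v * v),)
    return out


def leaky_relu(a: Tensor, slope: float = 0.01) -> Tensor:
    pos = a.value > 0
    out = Tensor(np.where(pos, a.value, slope * a.value), (a,))
    out.backward_fn = lambda g: (np.where(pos, g, slope * g),)
    return out


def sparsemax_np(z: np.ndarray) -> np.ndarray:
    """Sparsemax along the last axis: Euclidean projection onto the simplex."""
    z = np.asarray(z, dtype=float)
    if z.shape[-1] == 0:
        raise ValueError("sparsemax of an empty vector")
    zs = -np.sort(-z, axis=-1)
    cs = np.cumsum(zs, axis=-1)
    k = np.arange(1, z.shape[-1] + 1, dtype=float)
    support = 1.0 + k * zs > cs
    k_star = support.sum(axis=-1, keepdims=True)
    cs_k = np.take_along_axis(cs, k_star - 1, axis=-1)
    tau = (cs_k - 1.0) / k_star
    return np.maximum(z - tau, 0.0)


def sparsemax(a: Tensor) -> Tensor:
    p = sparsemax_np(a.value)
    out = Tensor(p, (a,))
    support = p > 0

    def bw(g):
        ns = support.sum(axis=-1, keepdims=True)
        mean_g = np.where(support, g, 0.0).sum(axis=-1, keepdims=True) / ns
        return (np.where(support, g - mean_g, 0.0),)

    out.backward_fn = bw
    return out


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    out = Tensor(np.concatenate([t.value for t in tensors], axis=axis), tuple(tensors))
    sizes = [t.value.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        return tuple(np.split(g, splits, axis=axis))

    out.backward_fn = bw
    return out


def stack(tensors: list[Tensor], axis: int = 1) -> Tensor:
    out = Tensor(np.stack([t.value for t in tensors], axis=axis), tuple(tensors))

    def bw(g):
        return tuple(np.moveaxis(g, axis, 0))

    out.backward_fn = bw
    return out


def reshape(a: Tensor, shape: tuple) -> Tensor:
    out = Tensor(a.value.reshape(shape), (a,))
    out.backward_fn = lambda g: (g.reshape(a.value.shape),)
    return out


def tsum(a: Tensor) -> Tensor:
    out = Tensor(a.value.sum(), (a,))
    out.backward_fn = lambda g: (np.broadcast_to(g, a.value.shape).copy(),)
    return out


def minimum(a: Tensor, b: Tensor) -> Tensor:
    """Elementwise minimum; on ties the gradient goes to the first argument."""
    take_a = a.value <= b.value
    out = Tensor(np.where(take_a, a.value, b.value), (a, b))

    def bw(g):
        return (
            _unbroadcast(np.where(take_a, g, 0.0), a.value.shape),
            _unbroadcast(np.where(take_a, 0.0, g), b.value.shape),
        )

    out.backward_fn = bw
    return out


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Elementwise binary cross-entropy of sigmoid(logits) against targets.

    Stable form max(l,0) − l·t + log(1 + exp(−|l|)); NaN targets (masked-out
    steps) contribute zero value and zero gradient.
    """
    t = np.asarray(targets, dtype=float)
    valid = np.isfinite(t)
    tt = np.where(valid, t, 0.0)
    l = logits.value
    v = np.maximum(l, 0.0) - l * tt + np.log1p(np.exp(-np.abs(l)))
    v = np.where(valid, v, 0.0)
    out = Tensor(v, (logits,))
    sig = np.where(l >= 0, 1.0 / (1.0 + np.exp(-l)), np.exp(l) / (1.0 + np.exp(l)))

    def bw(g):
        return (np.where(valid, g * (sig - tt), 0.0),)

    out.backward_fn = bw
    return out


def backward(loss: Tensor) -> None:
    """Accumulate gradients of ``loss`` (a scalar) into the graph's leaves."""
    order: list[Tensor] = []
    seen: set[int] = set()
    stack_: list[tuple[Tensor, bool]] = [(loss, False)]
    while stack_:
        node, done = stack_.pop()
        if done:
            order.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack_.append((node, True))
        for p in node.parents:
            stack_.append((p, False))
    loss.grad = np.ones_like(loss.value)
    for node in reversed(order):
        if node.backward_fn is None or node.grad is None:
            continue
        grads = node.backward_fn(node.grad)
        for parent, g in zip(node.parents, grads):
            if not parent.requires_grad and not parent.parents:
                continue
            if parent.grad is None:
                parent.grad = np.array(g, dtype=float)
            else:
                parent.grad = parent.grad + g
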