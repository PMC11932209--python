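"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Only the operations the geometric message-passing network needs are
implemented: broadcasted arithmetic, matmul, a channel-mixing linear map
for (n, c, 3) vector fields, elementwise nonlinearities, reductions,
concatenation, row gather/scatter (the message-aggregation primitives)
and basic slicing.  Gradients are accumulated over a dynamically
recorded tape; `backward()` walks it in reverse topological order.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "gather_rows", "scatter_sum", "channel_linear", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")
    __array_priority__ = 100  # keep ndarray.__mul__ from consuming us

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers -------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- arithmetic ------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)
        return Tensor._make(
            self.data + other.data, (self, other),
            lambda g: (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape)),
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        return Tensor._make(
            self.data * other.data, (self, other),
            lambda g: (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        return Tensor._make(
            self.data / other.data, (self, other),
            lambda g: (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            ),
        )

    def __matmul__(self, other):
        other = self._lift(other)
        return Tensor._make(
            self.data @ other.data, (self, other),
            lambda g: (g @ other.data.T, self.data.T @ g),
        )

    def __getitem__(self, idx):
        def backward(g):
            out = np.zeros_like(self.data)
            np.add.at(out, idx, g)
            return (out,)
        return Tensor._make(self.data[idx], (self,), backward)

    # -- elementwise -----------------------------------------------------
    def relu(self):
        mask = self.data > 0
        return Tensor._make(self.data * mask, (self,), lambda g: (g * mask,))

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-self.data))
        return Tensor._make(y, (self,), lambda g: (g * y * (1 - y),))

    def exp(self):
        y = np.exp(self.data)
        return Tensor._make(y, (self,), lambda g: (g * y,))

    def log(self):
        return Tensor._make(
            np.log(self.data), (self,), lambda g: (g / self.data,)
        )

    def sqrt(self):
        y = np.sqrt(self.data)
        return Tensor._make(y, (self,), lambda g: (g / (2 * y),))

    # -- reductions / reshapes ------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.shape).copy(),)
        return Tensor._make(
            self.data.sum(axis=axis, keepdims=keepdims), (self,), backward
        )

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        old = self.shape
        return Tensor._make(
            self.data.reshape(*shape), (self,), lambda g: (g.reshape(old),)
        )

    def norm(self, axis: int = -1, keepdims: bool = False, eps: float = 1e-8):
        """Safe L2 norm along one axis: sqrt(sum(x^2) + eps^2)."""
        sq = (self * self).sum(axis=axis, keepdims=keepdims)
        return (sq + eps * eps).sqrt()

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    # -- backward --------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
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
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            for parent, pgrad in zip(node._parents, node._backward(node.grad)):
                if not parent.requires_grad or pgrad is None:
                    continue
                if parent.grad is None:
                    parent.grad = np.zeros_like(parent.data)
                parent.grad += pgrad

    def zero_grad(self):
        self.grad = None


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._make(
        np.concatenate([t.data for t in tensors], axis=axis), tensors, backward
    )


def gather_rows(t: Tensor, idx: np.ndarray) -> Tensor:
    """Select rows t[idx] along axis 0 (duplicates allowed)."""
    idx = np.asarray(idx, dtype=int)

    def backward(g):
        out = np.zeros_like(t.data)
        np.add.at(out, idx, g)
        return (out,)

    return Tensor._make(t.data[idx], (t,), backward)


def scatter_sum(t: Tensor, idx: np.ndarray, num_rows: int) -> Tensor:
    """Sum rows of t into `num_rows` bins given per-row destination idx."""
    idx = np.asarray(idx, dtype=int)
    out = np.zeros((num_rows,) + t.data.shape[1:], dtype=np.float64)
    np.add.at(out, idx, t.data)
    return Tensor._make(out, (t,), lambda g: (g[idx],))


def channel_linear(V: Tensor, W: Tensor) -> Tensor:
    """Mix vector channels: (n, c, 3) x (c, k) -> (n, k, 3).

    Acts only on the channel axis, so it commutes with any rotation
    applied to the trailing spatial axis (the equivariance workhorse).
    """
    def backward(g):
        gV = np.einsum("nkd,ck->ncd", g, W.data)
        gW = np.einsum("ncd,nkd->ck", V.data, g)
        return (gV, gW)

    return Tensor._make(
        np.einsum("ncd,ck->nkd", V.data, W.data), (V, W), backward
    )


class Adam:
    """Adam optimizer over a flat list of parameter Tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        for k, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
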