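"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The decoder needs batched dense linear algebra (matmul, softmax, layer
norm, sigmoid) with gradients. This module provides a small tape-based
``Tensor`` supporting exactly the operations the model uses. Arrays are
float32; broadcasting follows NumPy semantics with gradients reduced
back to the operand shape.

Memory discipline: graph edges are only recorded while gradients are
enabled (see :func:`no_grad` for inference), ``backward`` frees interior
gradients as soon as they have been propagated, and every node's edges
are cleared afterwards so no reference cycles outlive the call.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np

DTYPE = np.float32

_grad_enabled = True


@contextmanager
def no_grad():
    """Disable graph construction (inference mode)."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum gradient over axes that were broadcast to reach ``grad.shape``."""
    if grad.shape == shape:
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev: tuple = ()

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    # -- graph plumbing ----------------------------------------------------

    def _accum(self, g: np.ndarray) -> None:
        if g.dtype != DTYPE:
            g = g.astype(DTYPE)
        if self.grad is None:
            # own a copy: the same buffer may feed several parents
            self.grad = g.copy()
        else:
            self.grad += g

    def backward(self) -> None:
        """Backpropagate from a scalar tensor, freeing interior state."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
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
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            if node._prev:
                # interior node: gradient fully propagated, edges done
                node.grad = None
                node._backward = None
                node._prev = ()

    # -- arithmetic --------------------------------------------------------

    @staticmethod
    def _make(data, bwd, prev) -> "Tensor":
        rq = _grad_enabled and any(p.requires_grad for p in prev)
        out = Tensor(data, rq)
        if rq:
            out._backward, out._prev = bwd, prev
        return out

    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return Tensor._make(self.data + other.data, bwd, (self, other))

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            self._accum(-g)

        return Tensor._make(-self.data, bwd, (self,))

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        a, b = self.data, other.data

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * b, a.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * a, b.shape))

        return Tensor._make(a * b, bwd, (self, other))

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self * other ** -1.0

    def __pow__(self, p: float):
        a = self.data

        def bwd(g):
            self._accum(g * p * a ** (p - 1.0))

        return Tensor._make(a ** p, bwd, (self,))

    def matmul(self, other: "Tensor") -> "Tensor":
        a, b = self.data, other.data

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(np.matmul(g, np.swapaxes(b, -1, -2)),
                                         a.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(np.matmul(np.swapaxes(a, -1, -2), g),
                                          b.shape))

        return Tensor._make(np.matmul(a, b), bwd, (self, other))

    __matmul__ = matmul

    # -- shape ops ---------------------------------------------------------

    def reshape(self, *shape):
        orig = self.data.shape

        def bwd(g):
            self._accum(g.reshape(orig))

        return Tensor._make(self.data.reshape(*shape), bwd, (self,))

    def swapaxes(self, a: int, b: int):
        def bwd(g):
            self._accum(np.swapaxes(g, a, b))

        return Tensor._make(np.swapaxes(self.data, a, b), bwd, (self,))

    def transpose(self, axes):
        inv = tuple(np.argsort(axes))

        def bwd(g):
            self._accum(g.transpose(inv))

        return Tensor._make(self.data.transpose(axes), bwd, (self,))

    def __getitem__(self, idx):
        shape = self.data.shape

        def bwd(g):
            full = np.zeros(shape, dtype=DTYPE)
            full[idx] = g
            self._accum(full)

        return Tensor._make(self.data[idx], bwd, (self,))

    # -- reductions --------------------------------------------------------

    def sum(self, axis=None, keepdims=False):
        shape = self.data.shape

        def bwd(g):
            if axis is None:
                ge = g
            else:
                ge = g if keepdims else np.expand_dims(g, axis)
            self._accum(np.broadcast_to(ge, shape))

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims),
                            bwd, (self,))

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- nonlinearities ----------------------------------------------------

    def exp(self):
        e = np.exp(self.data)

        def bwd(g):
            self._accum(g * e)

        return Tensor._make(e, bwd, (self,))

    def log(self):
        a = self.data

        def bwd(g):
            self._accum(g / a)

        return Tensor._make(np.log(a), bwd, (self,))

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))

        def bwd(g):
            self._accum(g * s * (1.0 - s))

        return Tensor._make(s, bwd, (self,))

    def gelu(self):
        # tanh approximation of the Gaussian error linear unit
        x = self.data
        c = np.float32(np.sqrt(2.0 / np.pi))
        t = np.tanh(c * (x + np.float32(0.044715) * x ** 3))

        def bwd(g):
            dt = (1.0 - t ** 2) * c * (1.0 + 3 * np.float32(0.044715) * x ** 2)
            self._accum(g * (0.5 * (1.0 + t) + 0.5 * x * dt))

        return Tensor._make(0.5 * x * (1.0 + t), bwd, (self,))

    def softmax(self, axis: int = -1):
        m = self.data.max(axis=axis, keepdims=True)
        e = np.exp(self.data - m)
        s = e / e.sum(axis=axis, keepdims=True)

        def bwd(g):
            dot = (g * s).sum(axis=axis, keepdims=True)
            self._accum(s * (g - dot))

        return Tensor._make(s, bwd, (self,))

    def layer_norm(self, eps: float = 1e-5):
        """Normalize over the last axis to zero mean, unit variance."""
        mu = self.data.mean(axis=-1, keepdims=True)
        xc = self.data - mu
        var = (xc ** 2).mean(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        xhat = (xc * inv).astype(DTYPE)

        def bwd(g):
            gm = g.mean(axis=-1, keepdims=True)
            gxm = (g * xhat).mean(axis=-1, keepdims=True)
            self._accum(inv * (g - gm - xhat * gxm))

        return Tensor._make(xhat, bwd, (self,))


def concat(tensors: list, axis: int = 0) -> Tensor:
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(a, b)
                t._accum(g[tuple(idx)])

    return Tensor._make(np.concatenate(datas, axis=axis), bwd, tuple(tensors))


def stack(tensors: list, axis: int = 0) -> Tensor:
    def bwd(g):
        parts = np.split(g, len(tensors), axis=axis)
        for t, p in zip(tensors, parts):
            if t.requires_grad:
                t._accum(np.squeeze(p, axis=axis))

    return Tensor._make(np.stack([t.data for t in tensors], axis=axis),
                        bwd, tuple(tensors))
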