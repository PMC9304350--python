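"""Minimal reverse-mode automatic differentiation over NumPy arrays.

A small tape-based engine providing exactly the operations the recurrent
network needs: broadcast arithmetic, matrix products, the LSTM/attention
nonlinearities, slicing, concatenation and stable log-sum-exp.  Gradients
are accumulated by topological traversal of the eagerly built graph.

All arrays keep the dtype of their inputs; training runs in float32 for
speed, gradient checks run in float64.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "tensor", "concat", "stack", "logsumexp", "softmax"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading broadcast axes
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over axes that were 1 in the original shape
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """Node in the autodiff graph wrapping an ndarray."""

    __slots__ = ("value", "grad", "requires_grad", "_parents", "_vjp")

    def __init__(self, value, requires_grad=False, parents=(), vjp=None):
        self.value = np.asarray(value)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._vjp = vjp

    # -- introspection -------------------------------------------------
    @property
    def shape(self):
        return self.value.shape

    @property
    def ndim(self):
        return self.value.ndim

    @property
    def dtype(self):
        return self.value.dtype

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- graph construction --------------------------------------------
    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(np.asarray(other))

    def _make(self, value, parents, vjp):
        return Tensor(value, parents=parents, vjp=vjp)

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)
        out_val = self.value + other.value

        def vjp(g):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        return self._make(out_val, (self, other), vjp)

    __radd__ = __add__

    def __neg__(self):
        return self._make(-self.value, (self,), lambda g: (-g,))

    def __sub__(self, other):
        other = self._lift(other)
        out_val = self.value - other.value

        def vjp(g):
            return (_unbroadcast(g, self.shape), _unbroadcast(-g, other.shape))

        return self._make(out_val, (self, other), vjp)

    def __rsub__(self, other):
        return self._lift(other).__sub__(self)

    def __mul__(self, other):
        other = self._lift(other)
        out_val = self.value * other.value
        a, b = self, other

        def vjp(g):
            return (_unbroadcast(g * b.value, a.shape), _unbroadcast(g * a.value, b.shape))

        return self._make(out_val, (a, b), vjp)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        a, b = self, other
        out_val = a.value / b.value

        def vjp(g):
            ga = _unbroadcast(g / b.value, a.shape)
            gb = _unbroadcast(-g * a.value / (b.value ** 2), b.shape)
            return (ga, gb)

        return self._make(out_val, (a, b), vjp)

    def __pow__(self, exponent):
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")
        out_val = self.value ** exponent

        def vjp(g):
            return (g * exponent * self.value ** (exponent - 1),)

        return self._make(out_val, (self,), vjp)

    def __matmul__(self, other):
        other = self._lift(other)
        a, b = self, other
        if a.ndim != 2 or b.ndim != 2:
            raise ValueError("matmul supports 2-D operands only")
        out_val = a.value @ b.value

        def vjp(g):
            return (g @ b.value.T, a.value.T @ g)

        return self._make(out_val, (a, b), vjp)

    # -- nonlinearities ------------------------------------------------
    def tanh(self):
        out_val = np.tanh(self.value)

        def vjp(g):
            return (g * (1.0 - out_val ** 2),)

        return self._make(out_val, (self,), vjp)

    def sigmoid(self):
        from scipy.special import expit

        out_val = expit(self.value)

        def vjp(g):
            return (g * out_val * (1.0 - out_val),)

        return self._make(out_val, (self,), vjp)

    def relu(self):
        out_val = np.maximum(self.value, 0)
        mask = self.value > 0

        def vjp(g):
            return (g * mask,)

        return self._make(out_val, (self,), vjp)

    def exp(self):
        out_val = np.exp(self.value)

        def vjp(g):
            return (g * out_val,)

        return self._make(out_val, (self,), vjp)

    def log(self):
        def vjp(g):
            return (g / self.value,)

        return self._make(np.log(self.value), (self,), vjp)

    # -- shape ops -----------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape

        def vjp(g):
            return (g.reshape(old),)

        return self._make(self.value.reshape(shape), (self,), vjp)

    def transpose(self, *axes):
        if not axes:
            axes = tuple(reversed(range(self.ndim)))
        elif len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def vjp(g):
            return (g.transpose(inv),)

        return self._make(self.value.transpose(axes), (self,), vjp)

    @property
    def T(self):
        return self.transpose()

    def __getitem__(self, key):
        out_val = self.value[key]
        shape = self.shape
        # basic indexing cannot alias cells, so plain += is safe and fast;
        # integer-array (fancy) indexing may repeat cells and needs add.at
        parts = key if isinstance(key, tuple) else (key,)
        fancy = any(isinstance(p, (np.ndarray, list)) for p in parts)

        def vjp(g):
            full = np.zeros(shape, dtype=g.dtype)
            if fancy:
                np.add.at(full, key, g)
            else:
                full[key] += g
            return (full,)

        return self._make(out_val, (self,), vjp)

    # -- reductions ----------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_val = self.value.sum(axis=axis, keepdims=keepdims)
        shape = self.shape

        def vjp(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, shape).copy(),)

        return self._make(out_val, (self,), vjp)

    def mean(self, axis=None, keepdims=False):
        n = self.value.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- backward ------------------------------------------------------
    def backward(self, grad=None):
        """Accumulate gradients into every reachable leaf with requires_grad."""
        if grad is None:
            if self.value.size != 1:
                raise ValueError("backward() without an explicit gradient requires a scalar output")
            grad = np.ones_like(self.value)
        # iterative DFS to avoid recursion limits on long LSTM chains
        topo, seen = [], set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if not node.requires_grad or (id(node) in seen and not processed):
                continue
            if processed:
                topo.append(node)
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))

        grads = {id(self): np.asarray(grad, dtype=self.dtype)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._vjp is None:  # leaf
                node.grad = g if node.grad is None else node.grad + g
                continue
            for parent, pg in zip(node._parents, node._vjp(g)):
                if not parent.requires_grad:
                    continue
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = pg


def tensor(value, requires_grad=False, dtype=None):
    arr = np.asarray(value, dtype=dtype)
    return Tensor(arr, requires_grad=requires_grad)


def concat(tensors, axis=0):
    tensors = [Tensor._lift(t) for t in tensors]
    out_val = np.concatenate([t.value for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def vjp(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor(out_val, parents=tuple(tensors), vjp=vjp)


def stack(tensors, axis=0):
    return concat([t.reshape(t.shape[:axis] + (1,) + t.shape[axis:]) for t in tensors], axis=axis)


def logsumexp(t: Tensor, axis=-1, keepdims=False):
    """Numerically stable log-sum-exp along `axis`."""
    m = np.max(t.value, axis=axis, keepdims=True)
    shifted = t - Tensor(m)  # max treated as constant: gradient is exact anyway
    s = shifted.exp().sum(axis=axis, keepdims=True)
    out = s.log() + Tensor(m)
    if not keepdims:
        out = out.reshape(tuple(d for i, d in enumerate(out.shape) if i != (axis % t.ndim)))
    return out


def softmax(t: Tensor, axis=-1):
    return (t - logsumexp(t, axis=axis, keepdims=True)).exp()
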