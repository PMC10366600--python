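"""Minimal reverse-mode automatic differentiation over NumPy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied
to it; :meth:`Tensor.backward` runs reverse-mode accumulation through the
recorded graph.  The op set is exactly what the package's recurrent and
attention models need: broadcasting arithmetic, (batched) matmul, the
usual nonlinearities, reductions, indexing/reshaping, a numerically
stable softmax/cross-entropy, and a singular-value op for the spectral
cluster regularizer.  All primitives are verified against central finite
differences in the test suite.
"""

from __future__ import annotations

from typing import Callable, Optional, Sequence

import numpy as np
from scipy.special import expit

__all__ = ["Tensor", "concat", "stack", "cross_entropy",
           "sum_smallest_singular_values", "no_grad", "set_default_dtype",
           "get_default_dtype"]

_GRAD_ENABLED = True

# engine-wide float width; float32 halves memory traffic, which dominates
# on small recurrent/attention models
DTYPE = np.float32


def set_default_dtype(dtype) -> None:
    global DTYPE
    DTYPE = np.dtype(dtype).type


def get_default_dtype():
    return DTYPE


class no_grad:
    """Context manager disabling graph recording (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._saved = _GRAD_ENABLED
        _GRAD_ENABLED = False

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._saved
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after NumPy broadcasting."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad
        self._backward: Optional[Callable[[np.ndarray], None]] = None
        self._prev: tuple["Tensor", ...] = ()

    # -- plumbing ------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def _accumulate(self, g: np.ndarray, own: bool = False) -> None:
        # ``own=True`` promises g is a freshly allocated array of the right
        # shape that no other node holds, so it can be adopted without a copy
        if self.grad is None:
            if own and g.shape == self.data.shape and g.dtype == self.data.dtype:
                self.grad = g
            else:
                self.grad = np.array(np.broadcast_to(g, self.data.shape),
                                     dtype=self.data.dtype)
        else:
            self.grad += g

    @staticmethod
    def _make(data: np.ndarray, parents: Sequence["Tensor"],
              backward: Callable[[np.ndarray], None]) -> "Tensor":
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._prev = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [self]
        # iterative DFS post-order (graphs can be thousands of nodes deep)
        visit: list[tuple[Tensor, bool]] = [(self, False)]
        while visit:
            node, done = visit.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            visit.append((node, True))
            for p in node._prev:
                if p.requires_grad and id(p) not in seen:
                    visit.append((p, False))
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _acc_unbroadcast(self, g: np.ndarray, fresh: bool) -> None:
        r = _unbroadcast(g, self.shape)
        self._accumulate(r, own=fresh or (r is not g))

    # -- arithmetic ----------------------------------------------------

    @staticmethod
    def _coerce(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._coerce(other)
        def backward(g):
            if self.requires_grad:
                self._acc_unbroadcast(g, fresh=False)
            if other.requires_grad:
                other._acc_unbroadcast(g, fresh=False)
        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accumulate(-g, own=True)
        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        def backward(g):
            if self.requires_grad:
                self._acc_unbroadcast(g * other.data, fresh=True)
            if other.requires_grad:
                other._acc_unbroadcast(g * self.data, fresh=True)
        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        def backward(g):
            if self.requires_grad:
                self._acc_unbroadcast(g / other.data, fresh=True)
            if other.requires_grad:
                other._acc_unbroadcast(-g * self.data / other.data ** 2,
                                       fresh=True)
        return self._make(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._coerce(other) / self

    def __pow__(self, p: float):
        def backward(g):
            if self.requires_grad:
                self._accumulate(g * p * self.data ** (p - 1), own=True)
        return self._make(self.data ** p, (self,), backward)

    def __matmul__(self, other):
        other = self._coerce(other)
        def backward(g):
            if self.requires_grad:
                self._acc_unbroadcast(g @ np.swapaxes(other.data, -1, -2),
                                      fresh=True)
            if other.requires_grad:
                other._acc_unbroadcast(np.swapaxes(self.data, -1, -2) @ g,
                                       fresh=True)
        return self._make(self.data @ other.data, (self, other), backward)

    # -- nonlinearities ------------------------------------------------

    def tanh(self):
        y = np.tanh(self.data)
        def backward(g):
            if self.requires_grad:
                self._accumulate(g * (1.0 - y ** 2), own=True)
        return self._make(y, (self,), backward)

    def sigmoid(self):
        y = expit(self.data)
        def backward(g):
            if self.requires_grad:
                self._accumulate(g * y * (1.0 - y), own=True)
        return self._make(y, (self,), backward)

    def relu(self):
        y = np.maximum(self.data, 0.0)
        def backward(g):
            if self.requires_grad:
                self._accumulate(g * (self.data > 0), own=True)
        return self._make(y, (self,), backward)

    def exp(self):
        y = np.exp(self.data)
        def backward(g):
            if self.requires_grad:
                self._accumulate(g * y, own=True)
        return self._make(y, (self,), backward)

    def log(self):
        def backward(g):
            if self.requires_grad:
                self._accumulate(g / self.data, own=True)
        return self._make(np.log(self.data), (self,), backward)

    def sqrt(self):
        y = np.sqrt(self.data)
        def backward(g):
            if self.requires_grad:
                self._accumulate(g * 0.5 / y, own=True)
        return self._make(y, (self,), backward)

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        y = e / e.sum(axis=axis, keepdims=True)
        def backward(g):
            if self.requires_grad:
                dot = (g * y).sum(axis=axis, keepdims=True)
                self._accumulate(y * (g - dot), own=True)
        return self._make(y, (self,), backward)

    # -- reductions ----------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        y = self.data.sum(axis=axis, keepdims=keepdims)
        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).copy())
        return self._make(y, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape ops -----------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape
        def backward(g):
            if self.requires_grad:
                self._accumulate(g.reshape(old))
        return self._make(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        def backward(g):
            if self.requires_grad:
                self._accumulate(g.transpose(inv))
        return self._make(self.data.transpose(axes), (self,), backward)

    def __getitem__(self, idx):
        # basic indexing (ints/slices) selects distinct elements, so the
        # scatter can be a plain += ; fancy indexing may repeat elements
        # and needs the unbuffered np.add.at
        fancy = any(isinstance(i, (np.ndarray, list)) for i in
                    (idx if isinstance(idx, tuple) else (idx,)))
        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                if fancy:
                    np.add.at(full, idx, g)
                else:
                    full[idx] += g
                self._accumulate(full, own=True)
        return self._make(self.data[idx], (self,), backward)


# ---------------------------------------------------------------------------
# Free functions
# ---------------------------------------------------------------------------

def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._coerce(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)
    def backward(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accumulate(g[tuple(sl)])
    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis),
                        tensors, backward)


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._coerce(t) for t in tensors]
    def backward(g):
        parts = np.moveaxis(g, axis, 0)
        for t, gp in zip(tensors, parts):
            if t.requires_grad:
                t._accumulate(gp)
    return Tensor._make(np.stack([t.data for t in tensors], axis=axis),
                        tensors, backward)


def cross_entropy(logits: Tensor, targets: np.ndarray,
                  class_weights: Optional[np.ndarray] = None) -> Tensor:
    """Weighted mean cross-entropy over integer class targets.

    Fused log-softmax + NLL for numerical stability; ``class_weights``
    (per class) rescale each sample's contribution, normalized by the
    total weight in the batch.
    """
    targets = np.asarray(targets, dtype=int)
    z = logits.data - logits.data.max(axis=-1, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=-1, keepdims=True))
    logp = z - lse
    n = targets.shape[0]
    w = (np.ones(n) if class_weights is None
         else np.asarray(class_weights, dtype=float)[targets])
    wsum = w.sum()
    loss = -(w * logp[np.arange(n), targets]).sum() / wsum
    def backward(g):
        if logits.requires_grad:
            p = np.exp(logp)
            p[np.arange(n), targets] -= 1.0
            logits._accumulate(g * p * (w / wsum)[:, None])
    return Tensor._make(np.asarray(loss), (logits,), backward)


def sum_smallest_singular_values(a: Tensor, n_drop: int) -> Tensor:
    """Sum of the ``n_drop`` smallest singular values of a 2-D matrix.

    Zero (with zero gradient) when ``n_drop <= 0``.  The gradient of a
    singular value is the rank-one outer product of its singular vectors.
    """
    if n_drop <= 0:
        return Tensor(0.0)
    u, s, vt = np.linalg.svd(a.data, full_matrices=False)
    idx = np.argsort(s)[:n_drop]
    val = s[idx].sum()
    def backward(g):
        if a.requires_grad:
            grad = np.zeros_like(a.data)
            for i in idx:
                grad += np.outer(u[:, i], vt[i, :])
            a._accumulate(g * grad)
    return Tensor._make(np.asarray(val), (a,), backward)
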