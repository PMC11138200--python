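"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The graph neural networks in this package are small (seven-node graphs,
hidden widths of at most 128), so a compact tape-based engine over dense
``numpy`` arrays is sufficient and keeps the whole stack dependency-light
and bit-reproducible.  Only the operations the models need are provided.

Broadcasting follows NumPy semantics; gradients of broadcast operands are
summed back over the broadcast axes.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["Tensor", "concat", "softmax_cross_entropy"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast from ``shape``."""
    if grad.shape == shape:
        return grad
    # leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A NumPy array with an optional gradient tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad
        self._parents: tuple = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------
    @classmethod
    def _from_op(cls, data, parents, backward):
        out = cls(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    # -- autodiff driver ------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(node):
            if id(node) in seen or not node.requires_grad:
                return
            seen.add(id(node))
            for p in node._parents:
                visit(p)
            topo.append(node)

        visit(self)
        for node in topo:
            node.grad = np.zeros_like(node.data)
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # -- arithmetic -----------------------------------------------------------
    @staticmethod
    def _coerce(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._coerce(other)

        def bw(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g, self.data.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(g, other.data.shape)

        return Tensor._from_op(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            if self.requires_grad:
                self.grad += -g

        return Tensor._from_op(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)

        def bw(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g * other.data, self.data.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(g * self.data, other.data.shape)

        return Tensor._from_op(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)

        def bw(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g / other.data, self.data.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(
                    -g * self.data / (other.data**2), other.data.shape
                )

        return Tensor._from_op(self.data / other.data, (self, other), bw)

    def __matmul__(self, other):
        other = self._coerce(other)

        def bw(g):
            if self.requires_grad:
                self.grad += _unbroadcast(
                    np.matmul(g, np.swapaxes(other.data, -1, -2)), self.data.shape
                )
            if other.requires_grad:
                other.grad += _unbroadcast(
                    np.matmul(np.swapaxes(self.data, -1, -2), g), other.data.shape
                )

        return Tensor._from_op(np.matmul(self.data, other.data), (self, other), bw)

    def pow(self, exponent: float):
        def bw(g):
            if self.requires_grad:
                self.grad += g * exponent * self.data ** (exponent - 1)

        return Tensor._from_op(self.data**exponent, (self,), bw)

    # -- reductions & shape ---------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self.grad += np.broadcast_to(g, self.data.shape)
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self.grad += np.broadcast_to(gg, self.data.shape)

        return Tensor._from_op(
            self.data.sum(axis=axis, keepdims=keepdims), (self,), bw
        )

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        old = self.data.shape

        def bw(g):
            if self.requires_grad:
                self.grad += g.reshape(old)

        return Tensor._from_op(self.data.reshape(*shape), (self,), bw)

    def transpose(self, axes):
        inv = np.argsort(axes)

        def bw(g):
            if self.requires_grad:
                self.grad += g.transpose(inv)

        return Tensor._from_op(self.data.transpose(axes), (self,), bw)

    # -- nonlinearities -------------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def bw(g):
            if self.requires_grad:
                self.grad += g * out_data

        return Tensor._from_op(out_data, (self,), bw)

    def log(self):
        def bw(g):
            if self.requires_grad:
                self.grad += g / self.data

        return Tensor._from_op(np.log(self.data), (self,), bw)

    def tanh(self):
        out_data = np.tanh(self.data)

        def bw(g):
            if self.requires_grad:
                self.grad += g * (1.0 - out_data**2)

        return Tensor._from_op(out_data, (self,), bw)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def bw(g):
            if self.requires_grad:
                self.grad += g * out_data * (1.0 - out_data)

        return Tensor._from_op(out_data, (self,), bw)

    def relu(self):
        def bw(g):
            if self.requires_grad:
                self.grad += g * (self.data > 0)

        return Tensor._from_op(np.maximum(self.data, 0.0), (self,), bw)

    def leaky_relu(self, slope: float = 0.2):
        def bw(g):
            if self.requires_grad:
                self.grad += g * np.where(self.data > 0, 1.0, slope)

        return Tensor._from_op(
            np.where(self.data > 0, self.data, slope * self.data), (self,), bw
        )

    def elu(self, alpha: float = 1.0):
        neg = alpha * (np.exp(np.minimum(self.data, 0.0)) - 1.0)
        out_data = np.where(self.data > 0, self.data, neg)

        def bw(g):
            if self.requires_grad:
                self.grad += g * np.where(self.data > 0, 1.0, neg + alpha)

        return Tensor._from_op(out_data, (self,), bw)

    def gelu(self):
        # exact (erf) form
        from scipy.special import erf

        cdf = 0.5 * (1.0 + erf(self.data / math.sqrt(2.0)))
        pdf = np.exp(-0.5 * self.data**2) / math.sqrt(2.0 * math.pi)

        def bw(g):
            if self.requires_grad:
                self.grad += g * (cdf + self.data * pdf)

        return Tensor._from_op(self.data * cdf, (self,), bw)

    # -- composites -----------------------------------------------------------
    def l2_normalize(self, axis: int = -1, eps: float = 1e-12):
        norm = (self * self).sum(axis=axis, keepdims=True).pow(0.5)
        return self / (norm + eps)

    def softmax(self, axis: int = -1):
        shifted = self - self.data.max(axis=axis, keepdims=True)  # constant shift
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)


def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [Tensor._coerce(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        parts = np.split(g, splits, axis=axis)
        for t, p in zip(tensors, parts):
            if t.requires_grad:
                t.grad += p

    return Tensor._from_op(data, tuple(tensors), bw)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of integer ``labels`` under softmax of ``logits``.

    Combined for numerical stability; ``logits`` has shape (n, n_classes).
    """
    labels = np.asarray(labels, dtype=np.intp)
    z = logits.data - logits.data.max(axis=-1, keepdims=True)
    logsumexp = np.log(np.exp(z).sum(axis=-1, keepdims=True))
    logp = z - logsumexp
    n = logits.data.shape[0]
    loss = -logp[np.arange(n), labels].mean()

    def bw(g):
        if logits.requires_grad:
            probs = np.exp(logp)
            probs[np.arange(n), labels] -= 1.0
            logits.grad += g * probs / n

    return Tensor._from_op(loss, (logits,), bw)
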