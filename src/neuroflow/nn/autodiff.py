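"""Minimal reverse-mode automatic differentiation on numpy arrays.

Implements exactly the operator set the package's networks need: dense
affine maps, elementwise nonlinearities (ReLU, SiLU, sigmoid, tanh),
batch/layer statistics (sum, mean, var via composition), concatenation,
and two fused losses (softmax cross-entropy, mean squared error).
Gradients propagate through a dynamically built tape; broadcasting is
handled by summing gradients back to the operand's shape.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "grad_reverse",
    "softmax_cross_entropy",
    "binary_cross_entropy_with_logits",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` over broadcast axes so it matches `shape`."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


def _as_tensor(x) -> "Tensor":
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._backward = None
        self._parents: tuple = ()

    # -- graph plumbing -------------------------------------------------
    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        # topological order over the tape
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self._accum(np.asarray(grad, dtype=np.float64))
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def item(self) -> float:
        return float(self.data)

    # -- arithmetic -----------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)
        out_data = self.data + other.data

        def back(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return Tensor._make(out_data, (self, other), back)

    __radd__ = __add__

    def __neg__(self):
        def back(g):
            if self.requires_grad:
                self._accum(-g)

        return Tensor._make(-self.data, (self,), back)

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        out_data = self.data * other.data

        def back(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(out_data, (self, other), back)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)
        out_data = self.data / other.data

        def back(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        return Tensor._make(out_data, (self, other), back)

    def __pow__(self, p: float):
        out_data = self.data**p

        def back(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1))

        return Tensor._make(out_data, (self,), back)

    def __matmul__(self, other):
        other = _as_tensor(other)
        out_data = self.data @ other.data

        def back(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        return Tensor._make(out_data, (self, other), back)

    # -- reductions -----------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def back(g):
            if not self.requires_grad:
                return
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        return Tensor._make(out_data, (self,), back)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- elementwise nonlinearities ------------------------------------
    def relu(self):
        mask = self.data > 0

        def back(g):
            if self.requires_grad:
                self._accum(g * mask)

        return Tensor._make(self.data * mask, (self,), back)

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))

        def back(g):
            if self.requires_grad:
                self._accum(g * s * (1 - s))

        return Tensor._make(s, (self,), back)

    def silu(self):
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))

        def back(g):
            if self.requires_grad:
                self._accum(g * (s + self.data * s * (1 - s)))

        return Tensor._make(self.data * s, (self,), back)

    def tanh(self):
        t = np.tanh(self.data)

        def back(g):
            if self.requires_grad:
                self._accum(g * (1 - t**2))

        return Tensor._make(t, (self,), back)

    def exp(self):
        e = np.exp(self.data)

        def back(g):
            if self.requires_grad:
                self._accum(g * e)

        return Tensor._make(e, (self,), back)

    def log(self):
        def back(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return Tensor._make(np.log(self.data), (self,), back)

    def sqrt(self):
        r = np.sqrt(self.data)

        def back(g):
            if self.requires_grad:
                self._accum(g * 0.5 / r)

        return Tensor._make(r, (self,), back)


def concat(tensors, axis: int = 1) -> Tensor:
    """Concatenate tensors along `axis`, splitting gradients back."""
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def back(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(a, b)
                t._accum(g[tuple(idx)])

    return Tensor._make(out_data, tuple(tensors), back)


def grad_reverse(x: Tensor, lam: float) -> Tensor:
    """Gradient reversal: identity forward, gradient scaled by -lam backward."""
    if lam < 0:
        raise ValueError("gradient-reversal factor must be >= 0")

    def back(g):
        if x.requires_grad:
            x._accum(-lam * g)

    return Tensor._make(x.data.copy(), (x,), back)


def softmax_cross_entropy(
    logits: Tensor, labels: np.ndarray, sample_weights: np.ndarray | None = None
) -> Tensor:
    """Weighted softmax cross-entropy, normalized by the batch weight sum.

    `labels` are integer class indices; `sample_weights` (per-sample) default
    to 1. The normalization mirrors the usual weighted-mean convention, so
    equal weights reduce exactly to the unweighted mean cross-entropy.
    """
    labels = np.asarray(labels, dtype=int)
    n, k = logits.data.shape
    if sample_weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(sample_weights, dtype=np.float64)
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=1, keepdims=True)
    nll = -np.log(np.clip(p[np.arange(n), labels], 1e-300, None))
    wsum = w.sum()
    loss = float((w * nll).sum() / wsum)

    def back(g):
        if logits.requires_grad:
            onehot = np.zeros((n, k))
            onehot[np.arange(n), labels] = 1.0
            logits._accum(g * (p - onehot) * (w / wsum)[:, None])

    return Tensor._make(np.asarray(loss), (logits,), back)


def binary_cross_entropy_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy on raw logits (numerically stable)."""
    y = np.asarray(targets, dtype=np.float64).reshape(logits.data.shape)
    z = logits.data
    # log(1 + exp(-|z|)) + max(z, 0) - y*z
    loss_terms = np.log1p(np.exp(-np.abs(z))) + np.maximum(z, 0) - y * z
    n = z.size
    s = 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))

    def back(g):
        if logits.requires_grad:
            logits._accum(g * (s - y) / n)

    return Tensor._make(np.asarray(loss_terms.mean()), (logits,), back)
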