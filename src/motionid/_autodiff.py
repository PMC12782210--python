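"""A minimal reverse-mode automatic-differentiation engine over NumPy arrays.

Just enough machinery to train the dual-stream attention network in
:mod:`motionid.transformer`: broadcast-aware elementwise arithmetic, batched
matrix multiplication, softmax, layer normalization, reductions and shape
ops, plus an Adam optimizer.  Everything is float64 and deterministic.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=float)
        self.grad = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    # -- graph plumbing ----------------------------------------------------

    @classmethod
    def _node(cls, data, parents, backward):
        out = cls(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def _accumulate(self, grad: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic --------------------------------------------------------

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._wrap(other)

        def backward(g):
            self._accumulate(_unbroadcast(g, self.shape))
            other._accumulate(_unbroadcast(g, other.shape))

        return Tensor._node(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = self._wrap(other)

        def backward(g):
            self._accumulate(_unbroadcast(g * other.data, self.shape))
            other._accumulate(_unbroadcast(g * self.data, other.shape))

        return Tensor._node(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __truediv__(self, other):
        other = self._wrap(other)
        return self * other ** -1.0

    def __pow__(self, exponent: float):
        if isinstance(exponent, Tensor):
            raise TypeError("only constant exponents are supported")

        def backward(g):
            self._accumulate(g * exponent * self.data ** (exponent - 1.0))

        return Tensor._node(self.data**exponent, (self,), backward)

    def matmul(self, other):
        other = self._wrap(other)

        def backward(g):
            self._accumulate(
                _unbroadcast(np.matmul(g, np.swapaxes(other.data, -1, -2)), self.shape)
            )
            other._accumulate(
                _unbroadcast(np.matmul(np.swapaxes(self.data, -1, -2), g), other.shape)
            )

        return Tensor._node(np.matmul(self.data, other.data), (self, other), backward)

    __matmul__ = matmul

    # -- nonlinearities ----------------------------------------------------

    def relu(self):
        mask = self.data > 0

        def backward(g):
            self._accumulate(g * mask)

        return Tensor._node(self.data * mask, (self,), backward)

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            self._accumulate(g * out_data)

        return Tensor._node(out_data, (self,), backward)

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500)))

        def backward(g):
            self._accumulate(g * s * (1.0 - s))

        return Tensor._node(s, (self,), backward)

    def softplus(self):
        # Numerically stable: softplus(z) = max(z, 0) + log1p(exp(-|z|)).
        z = self.data
        out_data = np.maximum(z, 0.0) + np.log1p(np.exp(-np.abs(z)))
        s = 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))

        def backward(g):
            self._accumulate(g * s)

        return Tensor._node(out_data, (self,), backward)

    def softmax(self, axis: int = -1):
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        s = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            inner = (g * s).sum(axis=axis, keepdims=True)
            self._accumulate(s * (g - inner))

        return Tensor._node(s, (self,), backward)

    def layer_norm(self, gamma: "Tensor", beta: "Tensor", eps: float = 1e-5):
        """Normalize over the last axis, then scale and shift."""
        mu = self.data.mean(axis=-1, keepdims=True)
        xc = self.data - mu
        var = (xc**2).mean(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        xhat = xc * inv

        def backward(g):
            n = self.data.shape[-1]
            gamma._accumulate(
                _unbroadcast(g * xhat, gamma.shape)
            )
            beta._accumulate(_unbroadcast(g, beta.shape))
            gx = g * gamma.data
            term = (
                gx - gx.mean(axis=-1, keepdims=True)
                - xhat * (gx * xhat).mean(axis=-1, keepdims=True)
            )
            self._accumulate(term * inv)

        return Tensor._node(xhat * gamma.data + beta.data, (self, gamma, beta), backward)

    # -- reductions and shape ops -----------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        def backward(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).copy())

        return Tensor._node(
            self.data.sum(axis=axis, keepdims=keepdims), (self,), backward
        )

    def mean(self, axis=None, keepdims: bool = False):
        count = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def reshape(self, *shape):
        original = self.shape

        def backward(g):
            self._accumulate(g.reshape(original))

        return Tensor._node(self.data.reshape(*shape), (self,), backward)

    def transpose(self, axes):
        inverse = np.argsort(axes)

        def backward(g):
            self._accumulate(g.transpose(inverse))

        return Tensor._node(self.data.transpose(axes), (self,), backward)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            t._accumulate(g[tuple(idx)])

    return Tensor._node(
        np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), backward
    )


class Adam:
    """Adaptive-moment optimizer over a dict of parameter tensors."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, p in self.params.items():
            if p.grad is None:
                continue
            self.m[k] = b1 * self.m[k] + (1 - b1) * p.grad
            self.v[k] = b2 * self.v[k] + (1 - b2) * p.grad**2
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.zero_grad()
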