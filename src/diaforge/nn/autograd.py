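"""Minimal reverse-mode automatic differentiation on numpy arrays.

Only the operations the predictors need are implemented. Tensors are
float64; broadcasting follows numpy semantics with gradients summed back
over broadcast axes. Graphs are built eagerly and freed after backward.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev: tuple = ()):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad
        self.grad: np.ndarray | None = None
        self._backward = None
        self._prev = _prev

    # -- helpers ------------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def _accum(self, grad: np.ndarray) -> None:
        grad = _unbroadcast(np.asarray(grad, dtype=np.float64), self.data.shape)
        self.grad = grad if self.grad is None else self.grad + grad

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    # -- arithmetic ---------------------------------------------------------

    def __add__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def backward():
            if self.requires_grad or self._prev:
                self._accum(out.grad)
            if other.requires_grad or other._prev:
                other._accum(out.grad)

        out._backward = backward
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def backward():
            if self.requires_grad or self._prev:
                self._accum(out.grad * other.data)
            if other.requires_grad or other._prev:
                other._accum(out.grad * self.data)

        out._backward = backward
        return out

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

    def __rtruediv__(self, other):
        return self._wrap(other) * self ** -1.0

    def __pow__(self, exponent: float):
        out = Tensor(self.data**exponent, _prev=(self,))

        def backward():
            self._accum(out.grad * exponent * self.data ** (exponent - 1.0))

        out._backward = backward
        return out

    def __matmul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data @ other.data, _prev=(self, other))

        def backward():
            g = out.grad
            if self.requires_grad or self._prev:
                self._accum(_matmul_grad_a(g, self.data, other.data))
            if other.requires_grad or other._prev:
                other._accum(_matmul_grad_b(g, self.data, other.data))

        out._backward = backward
        return out

    # -- elementwise nonlinearities -----------------------------------------

    def exp(self):
        out = Tensor(np.exp(self.data), _prev=(self,))

        def backward():
            self._accum(out.grad * out.data)

        out._backward = backward
        return out

    def log(self):
        out = Tensor(np.log(self.data), _prev=(self,))

        def backward():
            self._accum(out.grad / self.data)

        out._backward = backward
        return out

    def tanh(self):
        out = Tensor(np.tanh(self.data), _prev=(self,))

        def backward():
            self._accum(out.grad * (1.0 - out.data**2))

        out._backward = backward
        return out

    def sigmoid(self):
        out = Tensor(1.0 / (1.0 + np.exp(-self.data)), _prev=(self,))

        def backward():
            self._accum(out.grad * out.data * (1.0 - out.data))

        out._backward = backward
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), _prev=(self,))

        def backward():
            self._accum(out.grad * (self.data > 0.0))

        out._backward = backward
        return out

    def abs(self):
        out = Tensor(np.abs(self.data), _prev=(self,))

        def backward():
            self._accum(out.grad * np.sign(self.data))

        out._backward = backward
        return out

    # -- reductions / shaping -----------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _prev=(self,))

        def backward():
            g = out.grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape))

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), _prev=(self,))

        def backward():
            self._accum(out.grad.reshape(self.data.shape))

        out._backward = backward
        return out

    def transpose(self, *axes):
        axes = axes or tuple(reversed(range(self.data.ndim)))
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), _prev=(self,))

        def backward():
            self._accum(out.grad.transpose(inv))

        out._backward = backward
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], _prev=(self,))

        def backward():
            g = np.zeros_like(self.data)
            np.add.at(g, idx, out.grad)
            self._accum(g)

        out._backward = backward
        return out

    # -- autodiff ------------------------------------------------------------

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for child in node._prev:
                if id(child) not in visited:
                    stack.append((child, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward()
        # free the graph
        for node in topo:
            if node is not self:
                node._backward = None
                node._prev = ()


def _matmul_grad_a(g, a, b):
    if b.ndim == 1:
        return np.expand_dims(g, -1) * b if a.ndim > 1 else np.outer(g, b).reshape(a.shape)
    ga = g @ np.swapaxes(b, -1, -2)
    return _unbroadcast(ga, a.shape)


def _matmul_grad_b(g, a, b):
    if a.ndim == 1:
        return np.outer(a, g).reshape(b.shape)
    gb = np.swapaxes(a, -1, -2) @ g
    return _unbroadcast(gb, b.shape)


# ---------------------------------------------------------------------------
# functional helpers
# ---------------------------------------------------------------------------


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis), _prev=tuple(tensors))
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def backward():
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * out.data.ndim
            sl[axis] = slice(lo, hi)
            t._accum(out.grad[tuple(sl)])

    out._backward = backward
    return out


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    out = Tensor(np.stack([t.data for t in tensors], axis=axis), _prev=tuple(tensors))

    def backward():
        for i, t in enumerate(tensors):
            t._accum(np.take(out.grad, i, axis=axis))

    out._backward = backward
    return out


def embedding(weight: Tensor, idx: np.ndarray) -> Tensor:
    """Row lookup ``weight[idx]`` with scatter-add backward."""
    out = Tensor(weight.data[idx], _prev=(weight,))

    def backward():
        g = np.zeros_like(weight.data)
        np.add.at(g, idx, out.grad)
        weight._accum(g)

    out._backward = backward
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    # shifting by the (detached) max leaves both value and gradient unchanged
    shifted = x - x.data.max(axis=axis, keepdims=True)
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def masked_mean_abs(pred: Tensor, target: np.ndarray, keep: np.ndarray) -> Tensor:
    """Mean |pred - target| over cells where ``keep`` is True."""
    n = int(keep.sum())
    if n == 0:
        raise ValueError("all cells are masked; loss undefined")
    diff = (pred - Tensor(target)) * keep.astype(float)
    return diff.abs().sum() * (1.0 / n)
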