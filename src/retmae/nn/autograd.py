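"""Reverse-mode automatic differentiation on NumPy arrays.

A deliberately small tape-based engine: every :class:`Tensor` records the
operation that produced it and a closure that propagates the upstream
gradient to its parents.  ``backward()`` runs a topological sort and applies
the closures in reverse order.  All arithmetic is float64, which keeps
finite-difference gradient checks tight and makes single-threaded CPU runs
bit-reproducible.

Only the operations the transformer stack actually needs are implemented;
broadcasting follows NumPy semantics with gradients summed back to the
parent shape.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "concat", "stack"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


def _as_array(value) -> np.ndarray:
    if isinstance(value, np.ndarray):
        return value.astype(np.float64, copy=False)
    return np.asarray(value, dtype=np.float64)


class Tensor:
    """A NumPy array plus the bookkeeping needed for backpropagation."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents",
                 "_accum")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # ------------------------------------------------------------------ infra
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def size(self) -> int:
        return self.data.size

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def numpy(self) -> np.ndarray:
        return self.data

    @staticmethod
    def _lift(value) -> "Tensor":
        return value if isinstance(value, Tensor) else Tensor(value)

    def _make(self, data: np.ndarray, parents: Sequence["Tensor"],
              backward: Callable[[np.ndarray], None]) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        # iterative postorder over the tape (recursion-free: graphs are deep)
        order: list[Tensor] = []
        visited: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in visited:
                    stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): grad.astype(np.float64)}
        for node in reversed(order):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is not None:
                node._accum = grads
                node._backward(g)
                del node._accum
            elif node.requires_grad:
                node.grad = g if node.grad is None else node.grad + g

    def _send(self, parent: "Tensor", grad: np.ndarray) -> None:
        """Route a gradient contribution to ``parent`` during backward."""
        if not parent.requires_grad:
            return
        if parent._backward is None:
            # leaf (parameter or input marked requires_grad)
            parent.grad = grad if parent.grad is None else parent.grad + grad
        else:
            accum: dict[int, np.ndarray] = self._accum
            key = id(parent)
            if key in accum:
                accum[key] = accum[key] + grad
            else:
                accum[key] = grad

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other) -> "Tensor":
        other = self._lift(other)
        data = self.data + other.data

        def backward(g: np.ndarray) -> None:
            out._send(self, _unbroadcast(g, self.shape))
            out._send(other, _unbroadcast(g, other.shape))

        out = self._make(data, (self, other), backward)
        return out

    __radd__ = __add__

    def __mul__(self, other) -> "Tensor":
        other = self._lift(other)
        data = self.data * other.data

        def backward(g: np.ndarray) -> None:
            out._send(self, _unbroadcast(g * other.data, self.shape))
            out._send(other, _unbroadcast(g * self.data, other.shape))

        out = self._make(data, (self, other), backward)
        return out

    __rmul__ = __mul__

    def __neg__(self) -> "Tensor":
        return self * -1.0

    def __sub__(self, other) -> "Tensor":
        return self + (-self._lift(other))

    def __rsub__(self, other) -> "Tensor":
        return self._lift(other) + (-self)

    def __truediv__(self, other) -> "Tensor":
        other = self._lift(other)
        return self * other ** -1.0

    def __rtruediv__(self, other) -> "Tensor":
        return self._lift(other) * self ** -1.0

    def __pow__(self, exponent: float) -> "Tensor":
        exponent = float(exponent)
        data = self.data ** exponent

        def backward(g: np.ndarray) -> None:
            out._send(self, g * exponent * self.data ** (exponent - 1.0))

        out = self._make(data, (self,), backward)
        return out

    def __matmul__(self, other) -> "Tensor":
        other = self._lift(other)
        data = np.matmul(self.data, other.data)

        def backward(g: np.ndarray) -> None:
            a, b = self.data, other.data
            ga = np.matmul(g, np.swapaxes(b, -1, -2))
            gb = np.matmul(np.swapaxes(a, -1, -2), g)
            out._send(self, _unbroadcast(ga, self.shape))
            out._send(other, _unbroadcast(gb, other.shape))

        out = self._make(data, (self, other), backward)
        return out

    # -------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g: np.ndarray) -> None:
            if axis is None:
                grad = np.broadcast_to(g, self.shape).copy()
            else:
                axes = (axis,) if isinstance(axis, int) else tuple(axis)
                gg = g
                if not keepdims:
                    for ax in sorted(a % self.ndim for a in axes):
                        gg = np.expand_dims(gg, ax)
                grad = np.broadcast_to(gg, self.shape).copy()
            out._send(self, grad)

        out = self._make(data, (self,), backward)
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            count = self.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            count = int(np.prod([self.shape[a % self.ndim] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    # ------------------------------------------------------------ elementwise
    def exp(self) -> "Tensor":
        data = np.exp(self.data)

        def backward(g: np.ndarray) -> None:
            out._send(self, g * data)

        out = self._make(data, (self,), backward)
        return out

    def log(self) -> "Tensor":
        data = np.log(self.data)

        def backward(g: np.ndarray) -> None:
            out._send(self, g / self.data)

        out = self._make(data, (self,), backward)
        return out

    def sqrt(self) -> "Tensor":
        return self ** 0.5

    def tanh(self) -> "Tensor":
        data = np.tanh(self.data)

        def backward(g: np.ndarray) -> None:
            out._send(self, g * (1.0 - data * data))

        out = self._make(data, (self,), backward)
        return out

    def relu(self) -> "Tensor":
        data = np.maximum(self.data, 0.0)

        def backward(g: np.ndarray) -> None:
            out._send(self, g * (self.data > 0.0))

        out = self._make(data, (self,), backward)
        return out

    def gelu(self) -> "Tensor":
        # tanh approximation of the Gaussian error linear unit
        c = np.sqrt(2.0 / np.pi)
        x = self.data
        inner = c * (x + 0.044715 * x ** 3)
        t = np.tanh(inner)
        data = 0.5 * x * (1.0 + t)

        def backward(g: np.ndarray) -> None:
            dinner = c * (1.0 + 3 * 0.044715 * x ** 2)
            grad = 0.5 * (1.0 + t) + 0.5 * x * (1.0 - t * t) * dinner
            out._send(self, g * grad)

        out = self._make(data, (self,), backward)
        return out

    def clip(self, low: float | None = None, high: float | None = None) -> "Tensor":
        data = np.clip(self.data, low, high)

        def backward(g: np.ndarray) -> None:
            mask = np.ones_like(self.data)
            if low is not None:
                mask = mask * (self.data >= low)
            if high is not None:
                mask = mask * (self.data <= high)
            out._send(self, g * mask)

        out = self._make(data, (self,), backward)
        return out

    def softmax(self, axis: int = -1) -> "Tensor":
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        data = e / e.sum(axis=axis, keepdims=True)

        def backward(g: np.ndarray) -> None:
            dot = (g * data).sum(axis=axis, keepdims=True)
            out._send(self, data * (g - dot))

        out = self._make(data, (self,), backward)
        return out

    def log_softmax(self, axis: int = -1) -> "Tensor":
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        lse = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
        data = shifted - lse

        def backward(g: np.ndarray) -> None:
            soft = np.exp(data)
            out._send(self, g - soft * g.sum(axis=axis, keepdims=True))

        out = self._make(data, (self,), backward)
        return out

    # ----------------------------------------------------------------- shape
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        data = self.data.reshape(shape)

        def backward(g: np.ndarray) -> None:
            out._send(self, g.reshape(self.shape))

        out = self._make(data, (self,), backward)
        return out

    def transpose(self, *axes) -> "Tensor":
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        data = self.data.transpose(axes)
        inverse = tuple(np.argsort(axes))

        def backward(g: np.ndarray) -> None:
            out._send(self, g.transpose(inverse))

        out = self._make(data, (self,), backward)
        return out

    def swapaxes(self, a: int, b: int) -> "Tensor":
        axes = list(range(self.ndim))
        axes[a], axes[b] = axes[b], axes[a]
        return self.transpose(*axes)

    def roll(self, shift, axis) -> "Tensor":
        data = np.roll(self.data, shift, axis=axis)

        def backward(g: np.ndarray) -> None:
            if isinstance(shift, tuple):
                inv = tuple(-s for s in shift)
            else:
                inv = -shift
            out._send(self, np.roll(g, inv, axis=axis))

        out = self._make(data, (self,), backward)
        return out

    def take(self, indices: np.ndarray, axis: int = 0) -> "Tensor":
        """Gather along ``axis`` with an integer index array (constant)."""
        indices = np.asarray(indices)
        data = np.take(self.data, indices, axis=axis)

        def backward(g: np.ndarray) -> None:
            grad = np.zeros_like(self.data)
            if axis == 0:
                np.add.at(grad, indices, g)
            else:  # move the gathered axis first, scatter, move back
                moved = np.moveaxis(grad, axis, 0)
                np.add.at(moved, indices, np.moveaxis(g, axis, 0))
            out._send(self, grad)

        out = self._make(data, (self,), backward)
        return out

    def slice(self, key) -> "Tensor":
        data = self.data[key]

        def backward(g: np.ndarray) -> None:
            grad = np.zeros_like(self.data)
            grad[key] = g
            out._send(self, grad)

        out = self._make(data, (self,), backward)
        return out

    def __getitem__(self, key) -> "Tensor":
        return self.slice(key)


def concat(tensors: Iterable[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g: np.ndarray) -> None:
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            out._send(t, g[tuple(idx)])

    out = tensors[0]._make(data, tensors, backward)
    return out


def stack(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    data = np.stack([t.data for t in tensors], axis=axis)

    def backward(g: np.ndarray) -> None:
        for i, t in enumerate(tensors):
            out._send(t, np.take(g, i, axis=axis))

    out = tensors[0]._make(data, tensors, backward)
    return out
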