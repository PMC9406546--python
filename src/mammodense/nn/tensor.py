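"""Minimal reverse-mode automatic differentiation over numpy arrays.

The model zoo in this package (U-Net, Y-Net, ECNN and the confusion-matrix
annotation heads) is small and fully convolutional, so rather than depend on
a heavyweight deep-learning framework the package carries its own compact
autodiff engine: a :class:`Tensor` wrapping a ``numpy.ndarray`` together with
a closure that accumulates gradients into its parents.  Only the operations
the architectures actually use are implemented.  Every primitive is
gradient-checked against central finite differences in the test suite.

All arrays share one configurable dtype; determinism follows from numpy's —
identical op sequences on identical inputs produce identical bits.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "concat", "set_default_dtype", "get_default_dtype"]

# float32 is the working precision (ample for Dice-loss training and ~2x the
# throughput of float64); tests that finite-difference the gradients switch
# to float64 via set_default_dtype.
DTYPE = np.dtype(np.float32)


def set_default_dtype(dtype) -> None:
    global DTYPE
    DTYPE = np.dtype(dtype)


def get_default_dtype() -> np.dtype:
    return DTYPE


def _as_array(x) -> np.ndarray:
    if isinstance(x, np.ndarray):
        return x.astype(DTYPE, copy=False)
    return np.asarray(x, dtype=DTYPE)


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (the reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading broadcast axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph.

    Parameters
    ----------
    data
        The wrapped array (cast to the engine dtype on the way in).
    requires_grad
        Leaf tensors with ``requires_grad=True`` receive a ``.grad`` array
        during :meth:`backward`; interior nodes always propagate.
    """

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], None] | None = None

    # -- graph construction -------------------------------------------------

    @classmethod
    def _from_op(cls, data: np.ndarray, parents: Sequence["Tensor"],
                 backward: Callable[[np.ndarray], None]) -> "Tensor":
        out = cls(data)
        tracked = tuple(p for p in parents if p._tracks())
        if tracked:
            out.requires_grad = True
            out._parents = tracked
            out._backward = backward
        return out

    def _tracks(self) -> bool:
        return self.requires_grad or self._parents != ()

    def _accumulate(self, grad: np.ndarray) -> None:
        grad = _unbroadcast(np.asarray(grad, dtype=self.data.dtype), self.data.shape)
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    # -- convenience --------------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- arithmetic ---------------------------------------------------------

    @staticmethod
    def _coerce(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._coerce(other)
        def backward(g):
            self._accumulate(g)
            other._accumulate(g)
        return Tensor._from_op(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accumulate(-g)
        return Tensor._from_op(-self.data, (self,), backward)

    def __sub__(self, other):
        other = self._coerce(other)
        def backward(g):
            self._accumulate(g)
            other._accumulate(-g)
        return Tensor._from_op(self.data - other.data, (self, other), backward)

    def __rsub__(self, other):
        return self._coerce(other).__sub__(self)

    def __mul__(self, other):
        other = self._coerce(other)
        def backward(g):
            self._accumulate(g * other.data)
            other._accumulate(g * self.data)
        return Tensor._from_op(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        def backward(g):
            self._accumulate(g / other.data)
            other._accumulate(-g * self.data / (other.data ** 2))
        return Tensor._from_op(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._coerce(other).__truediv__(self)

    def __pow__(self, p: float):
        assert np.isscalar(p)
        def backward(g):
            self._accumulate(g * p * self.data ** (p - 1))
        return Tensor._from_op(self.data ** p, (self,), backward)

    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._coerce(other)
        def backward(g):
            self._accumulate(g @ other.data.T)
            other._accumulate(self.data.T @ g)
        return Tensor._from_op(self.data @ other.data, (self, other), backward)

    __matmul__ = matmul

    # -- reductions ---------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = self.data.sum(axis=axis, keepdims=keepdims)
        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape))
        return Tensor._from_op(out, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if np.isscalar(axis) else tuple(axis)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- elementwise nonlinearities ----------------------------------------

    def relu(self) -> "Tensor":
        mask = self.data > 0
        def backward(g):
            self._accumulate(g * mask)
        return Tensor._from_op(self.data * mask, (self,), backward)

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        def backward(g):
            self._accumulate(g * s * (1.0 - s))
        return Tensor._from_op(s, (self,), backward)

    def softplus(self) -> "Tensor":
        # stable: log(1 + e^x) = max(x, 0) + log1p(e^{-|x|})
        out = np.maximum(self.data, 0) + np.log1p(np.exp(-np.abs(self.data)))
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        def backward(g):
            self._accumulate(g * s)
        return Tensor._from_op(out, (self,), backward)

    def exp(self) -> "Tensor":
        e = np.exp(self.data)
        def backward(g):
            self._accumulate(g * e)
        return Tensor._from_op(e, (self,), backward)

    def log(self) -> "Tensor":
        def backward(g):
            self._accumulate(g / self.data)
        return Tensor._from_op(np.log(self.data), (self,), backward)

    def sqrt(self) -> "Tensor":
        r = np.sqrt(self.data)
        def backward(g):
            self._accumulate(g * 0.5 / r)
        return Tensor._from_op(r, (self,), backward)

    def clip(self, lo: float, hi: float) -> "Tensor":
        """Clamp; gradient is zero in the saturated regions."""
        mask = (self.data > lo) & (self.data < hi)
        def backward(g):
            self._accumulate(g * mask)
        return Tensor._from_op(np.clip(self.data, lo, hi), (self,), backward)

    def softmax(self, axis: int) -> "Tensor":
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        y = e / e.sum(axis=axis, keepdims=True)
        def backward(g):
            dot = (g * y).sum(axis=axis, keepdims=True)
            self._accumulate(y * (g - dot))
        return Tensor._from_op(y, (self,), backward)

    # -- shape manipulation -------------------------------------------------

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        def backward(g):
            self._accumulate(g.reshape(old))
        return Tensor._from_op(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes) -> "Tensor":
        inv = np.argsort(axes)
        def backward(g):
            self._accumulate(g.transpose(inv))
        return Tensor._from_op(self.data.transpose(axes), (self,), backward)

    def __getitem__(self, idx) -> "Tensor":
        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accumulate(full)
        return Tensor._from_op(self.data[idx], (self,), backward)

    # -- backprop -----------------------------------------------------------

    def backward(self, grad=None) -> None:
        """Run reverse-mode accumulation from this node."""
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                if not node.requires_grad or node._parents:
                    node.grad = None  # free interior grads


def concat(tensors: Iterable[Tensor], axis: int) -> Tensor:
    """Concatenate tensors along ``axis`` (used for U-Net skip connections)."""
    tensors = list(tensors)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]
    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accumulate(piece)
    return Tensor._from_op(np.concatenate([t.data for t in tensors], axis=axis),
                           tensors, backward)
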