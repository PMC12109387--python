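"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The segmentation network in :mod:`toothseg.network` is small enough that a
tape-based scalar-loss autodiff over dense ``float64`` arrays is both fast
enough for desk-scale training and fully deterministic.  The op set is exactly
what the model needs: broadcast arithmetic, (batched) matmul, ReLU, exp/log,
reductions, axis moves, concatenation and a numerically stable softmax /
log-softmax pair.

Every backward rule here is exercised against central finite differences in
the test suite.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "Parameter", "concat", "softmax", "log_softmax", "as_tensor",
           "default_dtype", "get_default_dtype"]

_DEFAULT_DTYPE = np.float64


def get_default_dtype():
    return _DEFAULT_DTYPE


@contextlib.contextmanager
def default_dtype(dtype):
    """Temporarily change the dtype new tensors are created with.

    float64 (the default) is used wherever analytic guarantees matter
    (gradient checks, identity tests); float32 roughly halves the cost of
    the BLAS-bound training path.
    """
    global _DEFAULT_DTYPE
    old = _DEFAULT_DTYPE
    _DEFAULT_DTYPE = np.dtype(dtype).type
    try:
        yield
    finally:
        _DEFAULT_DTYPE = old


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes that were prepended by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over axes that were expanded from size 1
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """Array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        parents: tuple["Tensor", ...] = (),
        backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data, dtype=_DEFAULT_DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # -- graph plumbing ----------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(grad, dtype=self.data.dtype, copy=True)
        else:
            self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this node (defaults to d(self)/d(self) = 1)."""
        if not self.requires_grad:
            raise RuntimeError("called backward() on a tensor that requires no grad")
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other) -> "Tensor":
        other = as_tensor(other)
        out_data = self.data + other.data

        def bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        return Tensor(out_data, parents=(self, other), backward=bw)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def bw(g: np.ndarray) -> None:
            self._accumulate(-g)

        return Tensor(-self.data, parents=(self,), backward=bw)

    def __sub__(self, other) -> "Tensor":
        return self + (-as_tensor(other))

    def __rsub__(self, other) -> "Tensor":
        return as_tensor(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = as_tensor(other)
        out_data = self.data * other.data

        def bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        return Tensor(out_data, parents=(self, other), backward=bw)

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = as_tensor(other)
        out_data = self.data / other.data

        def bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        return Tensor(out_data, parents=(self, other), backward=bw)

    def __rtruediv__(self, other) -> "Tensor":
        return as_tensor(other) / self

    def __matmul__(self, other) -> "Tensor":
        other = as_tensor(other)
        out_data = self.data @ other.data

        def bw(g: np.ndarray) -> None:
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accumulate(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accumulate(_unbroadcast(gb, other.data.shape))

        return Tensor(out_data, parents=(self, other), backward=bw)

    def pow(self, exponent: float) -> "Tensor":
        out_data = self.data**exponent

        def bw(g: np.ndarray) -> None:
            self._accumulate(g * exponent * self.data ** (exponent - 1))

        return Tensor(out_data, parents=(self,), backward=bw)

    def sqrt(self) -> "Tensor":
        return self.pow(0.5)

    # -- elementwise nonlinearities ---------------------------------------
    def relu(self) -> "Tensor":
        mask = self.data > 0

        def bw(g: np.ndarray) -> None:
            self._accumulate(g * mask)

        return Tensor(self.data * mask, parents=(self,), backward=bw)

    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)

        def bw(g: np.ndarray) -> None:
            self._accumulate(g * out_data)

        return Tensor(out_data, parents=(self,), backward=bw)

    def log(self, clamp: float = 0.0) -> "Tensor":
        arg = np.maximum(self.data, clamp) if clamp else self.data
        out_data = np.log(arg)

        def bw(g: np.ndarray) -> None:
            self._accumulate(g / arg * (self.data >= clamp if clamp else 1.0))

        return Tensor(out_data, parents=(self,), backward=bw)

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(g: np.ndarray) -> None:
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape))

        return Tensor(out_data, parents=(self,), backward=bw)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False) -> "Tensor":
        """Max along one axis; subgradient routed to the first argmax."""
        idx = np.argmax(self.data, axis=axis)  # first occurrence on ties
        out_data = np.take_along_axis(self.data, np.expand_dims(idx, axis), axis)
        if not keepdims:
            out_data = np.squeeze(out_data, axis)

        def bw(g: np.ndarray) -> None:
            if not keepdims:
                g = np.expand_dims(g, axis)
            full = np.zeros_like(self.data)
            np.put_along_axis(full, np.expand_dims(idx, axis), g, axis)
            self._accumulate(full)

        return Tensor(out_data, parents=(self,), backward=bw)

    # -- shape ops ---------------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out_data = self.data.reshape(shape)

        def bw(g: np.ndarray) -> None:
            self._accumulate(g.reshape(self.data.shape))

        return Tensor(out_data, parents=(self,), backward=bw)

    def swapaxes(self, a: int, b: int) -> "Tensor":
        out_data = np.swapaxes(self.data, a, b)

        def bw(g: np.ndarray) -> None:
            self._accumulate(np.swapaxes(g, a, b))

        return Tensor(out_data, parents=(self,), backward=bw)

    def transpose(self, axes: Sequence[int]) -> "Tensor":
        axes = tuple(axes)
        inv = tuple(np.argsort(axes))
        out_data = self.data.transpose(axes)

        def bw(g: np.ndarray) -> None:
            self._accumulate(g.transpose(inv))

        return Tensor(out_data, parents=(self,), backward=bw)

    def take(self, indices: np.ndarray, axis: int = 0) -> "Tensor":
        """Gather rows (integer fancy indexing along one axis)."""
        indices = np.asarray(indices)
        out_data = np.take(self.data, indices, axis=axis)

        def bw(g: np.ndarray) -> None:
            full = np.zeros_like(self.data)
            np.add.at(full, (slice(None),) * axis + (indices,), g)
            self._accumulate(full)

        return Tensor(out_data, parents=(self,), backward=bw)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: Iterable[Tensor], axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g: np.ndarray) -> None:
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accumulate(piece)

    return Tensor(out_data, parents=tuple(tensors), backward=bw)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax, fused forward/backward.

    Backward uses the Jacobian action dx = a ⊙ (g − ⟨g, a⟩) along ``axis``.
    """
    shift = np.max(x.data, axis=axis, keepdims=True)
    e = np.exp(x.data - shift)
    a = e / e.sum(axis=axis, keepdims=True)

    def bw(g: np.ndarray) -> None:
        x._accumulate(a * (g - np.sum(g * a, axis=axis, keepdims=True)))

    return Tensor(a, parents=(x,), backward=bw)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Stable log-softmax; backward dx = g − softmax ⊙ Σg along ``axis``."""
    shift = np.max(x.data, axis=axis, keepdims=True)
    z = x.data - shift
    lse = np.log(np.sum(np.exp(z), axis=axis, keepdims=True))
    out = z - lse
    a = np.exp(out)

    def bw(g: np.ndarray) -> None:
        x._accumulate(g - a * g.sum(axis=axis, keepdims=True))

    return Tensor(out, parents=(x,), backward=bw)
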