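"""Minimal reverse-mode automatic differentiation on NumPy arrays.

A tape-free define-by-run engine in the micrograd style, but array-valued:
every :class:`Tensor` records its parents and a closure that accumulates
gradients into them.  Only the operations needed by the molecular feature
extractors are provided (dense matmul, elementwise nonlinearities, reductions,
padding/slicing for SAME convolutions, and segment sums for graph message
passing).  Arithmetic runs in a configurable global precision: float32 by
default (roughly twice the throughput of float64 on a memory-bound CPU
workload), switchable to float64 via :func:`default_dtype` where tight
numerical agreement matters.
"""

from __future__ import annotations

import contextlib
from typing import Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "concat", "segment_sum", "relu", "tanh", "sigmoid", "softmax",
           "default_dtype", "get_dtype"]

_DTYPE = np.float32
_GRAD_ENABLED = True


def get_dtype():
    """The dtype newly created tensors use."""
    return _DTYPE


@contextlib.contextmanager
def no_grad():
    """Disable graph construction (evaluation passes: no tape, less memory)."""
    global _GRAD_ENABLED
    old = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = old


@contextlib.contextmanager
def default_dtype(dtype):
    """Temporarily switch the engine precision (e.g. float64 for oracles)."""
    global _DTYPE
    old = _DTYPE
    _DTYPE = np.dtype(dtype).type
    try:
        yield
    finally:
        _DTYPE = old


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum out prepended axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, dim in enumerate(shape):
        if dim == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """An n-d array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents: tuple = (), _backward=None):
        self.data = np.asarray(data, dtype=_DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = (requires_grad or any(p.requires_grad for p in _parents)) \
            and _GRAD_ENABLED
        self._parents = _parents if self.requires_grad else ()
        self._backward = _backward if self.requires_grad else None

    # -- basic introspection ------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            # fresh buffer (the incoming grad may be a view into shared memory)
            self.grad = np.array(grad, dtype=self.data.dtype)
        else:
            self.grad += grad

    # -- autograd driver ----------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (must be scalar unless ``grad`` given)."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)
        # iterative topological sort (graphs can be deep: LSTM over 150 steps)
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited or not node.requires_grad:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            if node._parents:
                # interior node: its gradient has been fully propagated and
                # will not be read again — free it to bound peak memory
                node.grad = None

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic ---------------------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other) -> "Tensor":
        other = self._wrap(other)
        out = Tensor(self.data + other.data, _parents=(self, other))

        def _backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = _backward
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        out = Tensor(-self.data, _parents=(self,))
        out._backward = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other) -> "Tensor":
        return self + (-self._wrap(other))

    def __rsub__(self, other) -> "Tensor":
        return self._wrap(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = self._wrap(other)
        out = Tensor(self.data * other.data, _parents=(self, other))

        def _backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = _backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = self._wrap(other)
        out = Tensor(self.data / other.data, _parents=(self, other))

        def _backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(-g * self.data / other.data**2, other.data.shape))

        out._backward = _backward
        return out

    def __matmul__(self, other) -> "Tensor":
        other = self._wrap(other)
        out = Tensor(self.data @ other.data, _parents=(self, other))

        def _backward(g):
            a, b = self.data, other.data
            if self.requires_grad:
                if a.ndim == 2 and b.ndim == 2:
                    self._accumulate(g @ b.T)
                elif a.ndim == 2 and b.ndim == 1:
                    self._accumulate(np.outer(g, b))
                elif a.ndim == 1 and b.ndim == 2:
                    self._accumulate(b @ g)
                else:  # 1D @ 1D -> scalar
                    self._accumulate(g * b)
            if other.requires_grad:
                if b.ndim == 2 and a.ndim == 2:
                    other._accumulate(a.T @ g)
                elif b.ndim == 1 and a.ndim == 2:
                    other._accumulate(a.T @ g)
                elif b.ndim == 2 and a.ndim == 1:
                    other._accumulate(np.outer(a, g))
                else:
                    other._accumulate(g * a)

        out._backward = _backward
        return out

    # -- shape ops ----------------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape
        out = Tensor(self.data.reshape(shape), _parents=(self,))
        out._backward = lambda g: self._accumulate(g.reshape(orig))
        return out

    def transpose(self, *axes) -> "Tensor":
        if not axes:
            axes = tuple(reversed(range(self.data.ndim)))
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), _parents=(self,))
        out._backward = lambda g: self._accumulate(g.transpose(inv))
        return out

    @property
    def T(self) -> "Tensor":
        return self.transpose()

    def __getitem__(self, key) -> "Tensor":
        out = Tensor(self.data[key], _parents=(self,))
        basic = isinstance(key, (int, slice)) or (
            isinstance(key, tuple) and all(isinstance(k, (int, slice)) for k in key)
        )

        def _backward(g):
            # scatter straight into the (lazily allocated) gradient buffer
            # instead of materializing a full-size zeros per slice
            if self.grad is None:
                self.grad = np.zeros_like(self.data)
            if basic:  # no repeated elements: direct in-place add is valid and fast
                self.grad[key] += g
            else:
                np.add.at(self.grad, key, g)

        out._backward = _backward
        return out

    def take_rows(self, index: np.ndarray) -> "Tensor":
        """Gather rows (axis 0) by an integer index array."""
        index = np.asarray(index, dtype=np.intp)
        out = Tensor(self.data[index], _parents=(self,))

        def _backward(g):
            if self.grad is None:
                self.grad = np.zeros_like(self.data)
            np.add.at(self.grad, index, g)

        out._backward = _backward
        return out

    def pad(self, pad_width: Sequence[tuple[int, int]]) -> "Tensor":
        out = Tensor(np.pad(self.data, pad_width), _parents=(self,))

        def _backward(g):
            slices = tuple(slice(lo, g.shape[i] - hi) for i, (lo, hi) in enumerate(pad_width))
            self._accumulate(g[slices])

        out._backward = _backward
        return out

    # -- reductions ---------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _parents=(self,))

        def _backward(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        out._backward = _backward
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- nonlinearities -----------------------------------------------------
    def relu(self) -> "Tensor":
        out = Tensor(np.maximum(self.data, 0.0), _parents=(self,))
        out._backward = lambda g: self._accumulate(g * (self.data > 0))
        return out

    def tanh(self) -> "Tensor":
        t = np.tanh(self.data)
        out = Tensor(t, _parents=(self,))
        out._backward = lambda g: self._accumulate(g * (1.0 - t * t))
        return out

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500)))
        out = Tensor(s, _parents=(self,))
        out._backward = lambda g: self._accumulate(g * s * (1.0 - s))
        return out

    def exp(self) -> "Tensor":
        e = np.exp(self.data)
        out = Tensor(e, _parents=(self,))
        out._backward = lambda g: self._accumulate(g * e)
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), _parents=(self,))
        out._backward = lambda g: self._accumulate(g / self.data)
        return out

    def softmax(self, axis: int = -1) -> "Tensor":
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(s, _parents=(self,))

        def _backward(g):
            dot = (g * s).sum(axis=axis, keepdims=True)
            self._accumulate(s * (g - dot))

        out._backward = _backward
        return out

    def dropout(self, rate: float, rng: np.random.Generator, train: bool) -> "Tensor":
        """Inverted dropout: identity when ``train`` is False or rate == 0."""
        if not train or rate == 0.0:
            return self
        mask = (rng.random(self.data.shape) >= rate) / (1.0 - rate)
        return self * Tensor(mask)


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = list(tensors)
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), _parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def _backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    out._backward = _backward
    return out


def segment_sum(x: Tensor, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    """Sum rows of ``x`` into ``num_segments`` buckets (scatter-add on axis 0)."""
    segment_ids = np.asarray(segment_ids, dtype=np.intp)
    data = np.zeros((num_segments,) + x.data.shape[1:], dtype=x.data.dtype)
    np.add.at(data, segment_ids, x.data)
    out = Tensor(data, _parents=(x,))
    out._backward = lambda g: x._accumulate(g[segment_ids])
    return out


def relu(x: Tensor) -> Tensor:
    return x.relu()


def tanh(x: Tensor) -> Tensor:
    return x.tanh()


def sigmoid(x: Tensor) -> Tensor:
    return x.sigmoid()


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    return x.softmax(axis=axis)


class Adam:
    """Adam optimizer over a list of parameter tensors."""

    def __init__(self, params: Iterable[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
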