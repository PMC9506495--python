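"""Minimal reverse-mode automatic differentiation over numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied to
it on a tape; :meth:`Tensor.backward` replays the tape in reverse topological
order and accumulates gradients.  The operation set is exactly what the
graph-network models in this package need: dense linear algebra, elementwise
nonlinearities, reductions, and the gather / segment-sum pair that implements
message passing on molecular graphs.

Everything is float64.  The engine is deliberately eager and single-threaded:
at the molecule sizes this package works with, vectorized numpy dominates the
runtime and the tape overhead is negligible.
"""

from __future__ import annotations

from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "relu",
    "sigmoid",
    "concat",
    "gather",
    "segment_sum",
    "logsumexp",
    "clip_grad_norm",
    "Adam",
]


def _unbroadcast(grad: np.ndarray, shape: Tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum over leading dims added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph.

    Parameters with ``requires_grad=True`` accumulate into ``.grad`` when
    :meth:`backward` is called on a downstream scalar.
    """

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        parents: Tuple["Tensor", ...] = (),
        backward: Optional[Callable[[np.ndarray], None]] = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # -- bookkeeping ------------------------------------------------------
    @property
    def shape(self) -> Tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: List[Tensor] = []
        seen = set()

        def visit(t: Tensor) -> None:
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self._accumulate(np.ones_like(self.data))
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other) -> "Tensor":
        other = as_tensor(other)
        out_data = self.data + other.data

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        return Tensor(out_data, parents=(self, other), backward=bwd)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def bwd(g):
            self._accumulate(-g)

        return Tensor(-self.data, parents=(self,), backward=bwd)

    def __sub__(self, other) -> "Tensor":
        return self + (-as_tensor(other))

    def __rsub__(self, other) -> "Tensor":
        return as_tensor(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = as_tensor(other)
        out_data = self.data * other.data

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        return Tensor(out_data, parents=(self, other), backward=bwd)

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = as_tensor(other)
        out_data = self.data / other.data

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        return Tensor(out_data, parents=(self, other), backward=bwd)

    def __matmul__(self, other) -> "Tensor":
        other = as_tensor(other)
        out_data = self.data @ other.data

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ g)

        return Tensor(out_data, parents=(self, other), backward=bwd)

    def __pow__(self, exponent: float) -> "Tensor":
        out_data = self.data**exponent

        def bwd(g):
            self._accumulate(g * exponent * self.data ** (exponent - 1))

        return Tensor(out_data, parents=(self,), backward=bwd)

    # -- shape ops --------------------------------------------------------
    @property
    def T(self) -> "Tensor":
        def bwd(g):
            self._accumulate(g.T)

        return Tensor(self.data.T, parents=(self,), backward=bwd)

    def reshape(self, *shape) -> "Tensor":
        orig = self.data.shape

        def bwd(g):
            self._accumulate(g.reshape(orig))

        return Tensor(self.data.reshape(*shape), parents=(self,), backward=bwd)

    def __getitem__(self, idx) -> "Tensor":
        out_data = self.data[idx]

        def bwd(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accumulate(full)

        return Tensor(out_data, parents=(self,), backward=bwd)

    # -- reductions -------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())
            else:
                g_exp = g if keepdims else np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(g_exp, self.data.shape).copy())

        return Tensor(out_data, parents=(self,), backward=bwd)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- elementwise nonlinearities --------------------------------------
    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)

        def bwd(g):
            self._accumulate(g * out_data)

        return Tensor(out_data, parents=(self,), backward=bwd)

    def log(self) -> "Tensor":
        def bwd(g):
            self._accumulate(g / self.data)

        return Tensor(np.log(self.data), parents=(self,), backward=bwd)

    def clip(self, lo: float, hi: float) -> "Tensor":
        """Clamp values; gradient is passed through inside [lo, hi] only."""
        out_data = np.clip(self.data, lo, hi)
        mask = (self.data >= lo) & (self.data <= hi)

        def bwd(g):
            self._accumulate(g * mask)

        return Tensor(out_data, parents=(self,), backward=bwd)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def relu(t: Tensor) -> Tensor:
    t = as_tensor(t)
    mask = t.data > 0

    def bwd(g):
        t._accumulate(g * mask)

    return Tensor(t.data * mask, parents=(t,), backward=bwd)


def sigmoid(t: Tensor) -> Tensor:
    t = as_tensor(t)
    # numerically stable logistic
    out_data = np.empty_like(t.data)
    pos = t.data >= 0
    out_data[pos] = 1.0 / (1.0 + np.exp(-t.data[pos]))
    e = np.exp(t.data[~pos])
    out_data[~pos] = e / (1.0 + e)

    def bwd(g):
        t._accumulate(g * out_data * (1.0 - out_data))

    return Tensor(out_data, parents=(t,), backward=bwd)


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return Tensor(out_data, parents=tuple(tensors), backward=bwd)


def gather(t: Tensor, index: np.ndarray) -> Tensor:
    """Select rows ``t[index]``; backward scatter-adds into the source."""
    t = as_tensor(t)
    index = np.asarray(index, dtype=np.intp)
    out_data = t.data[index]

    def bwd(g):
        full = np.zeros_like(t.data)
        np.add.at(full, index, g)
        t._accumulate(full)

    return Tensor(out_data, parents=(t,), backward=bwd)


def segment_sum(t: Tensor, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    """Sum rows of `t` into `num_segments` buckets: out[s] = sum over rows with id s.

    The workhorse of message passing: messages computed per directed edge are
    scatter-added onto their destination atoms.
    """
    t = as_tensor(t)
    segment_ids = np.asarray(segment_ids, dtype=np.intp)
    out_data = np.zeros((num_segments,) + t.data.shape[1:], dtype=np.float64)
    np.add.at(out_data, segment_ids, t.data)

    def bwd(g):
        t._accumulate(g[segment_ids])

    return Tensor(out_data, parents=(t,), backward=bwd)


def logsumexp(t: Tensor) -> Tensor:
    """log(sum(exp(t))) over a 1-D tensor, with max-subtraction stability."""
    t = as_tensor(t)
    m = float(np.max(t.data))  # constant shift; exact gradient is preserved
    return (t - m).exp().sum().log() + m


def clip_grad_norm(params: Dict[str, "Tensor"], max_norm: float) -> float:
    """Scale all gradients so their global L2 norm is at most `max_norm`."""
    total = 0.0
    for p in params.values():
        if p.grad is not None:
            total += float((p.grad**2).sum())
    norm = np.sqrt(total)
    if norm > max_norm > 0:
        scale = max_norm / norm
        for p in params.values():
            if p.grad is not None:
                p.grad *= scale
    return norm


class Adam:
    """Adam optimizer over a dict of named parameter tensors."""

    def __init__(
        self,
        params: Dict[str, Tensor],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for k, p in self.params.items():
            if p.grad is None:
                continue
            m = self.m[k]
            v = self.v[k]
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad**2
            p.data -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
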