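"""Minimal reverse-mode automatic differentiation over numpy arrays.

The graph network needs exact gradients with respect to both parameters
(training) and continuous input features (interpretation).  The runtime
has no deep-learning framework, so this module provides the small set of
differentiable primitives the network is built from: broadcast add/mul,
matmul, row gather, reshape, axis sum, ReLU, segment mean, masked row
mean, and softmax cross-entropy.  Everything is float64 for gradient
checks against central finite differences.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with a gradient slot and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data: np.ndarray | float,
        requires_grad: bool = False,
        parents: Sequence["Tensor"] = (),
        backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = tuple(parents)
        self._backward = backward

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(grad, dtype=np.float64, copy=True)
        else:
            self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Reverse-accumulate gradients from this tensor to all leaves."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar tensor")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic ---------------------------------------------------------

    def __add__(self, other: "Tensor | float") -> "Tensor":
        other = as_tensor(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __mul__(self, other: "Tensor | float") -> "Tensor":
        other = as_tensor(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __neg__(self) -> "Tensor":
        return self * -1.0

    def __sub__(self, other: "Tensor | float") -> "Tensor":
        return self + (-as_tensor(other))

    def matmul(self, other: "Tensor") -> "Tensor":
        out = Tensor(self.data @ other.data, parents=(self, other))

        def bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ g)

        out._backward = bw
        return out

    __matmul__ = matmul

    # -- shaping ------------------------------------------------------------

    def reshape(self, *shape: int) -> "Tensor":
        orig = self.shape
        out = Tensor(self.data.reshape(*shape), parents=(self,))

        def bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g.reshape(orig))

        out._backward = bw
        return out

    def gather_rows(self, index: np.ndarray) -> "Tensor":
        """Select rows by integer index along axis 0 (embedding lookup)."""
        index = np.asarray(index, dtype=np.int64)
        out = Tensor(self.data[index], parents=(self,))

        def bw(g: np.ndarray) -> None:
            if self.requires_grad:
                acc = np.zeros_like(self.data)
                np.add.at(acc, index, g)
                self._accumulate(acc)

        out._backward = bw
        return out

    def sum(self, axis: int | None = None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))
        shape = self.shape

        def bw(g: np.ndarray) -> None:
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, shape).astype(np.float64))
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(gg, shape).astype(np.float64))

        out._backward = bw
        return out

    def relu(self) -> "Tensor":
        mask = self.data > 0
        out = Tensor(self.data * mask, parents=(self,))

        def bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g * mask)

        out._backward = bw
        return out


def as_tensor(x: "Tensor | np.ndarray | float") -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def segment_mean(x: Tensor, segment_ids: np.ndarray, n_segments: int) -> Tensor:
    """Mean of rows of ``x`` grouped by ``segment_ids``; empty segments are zero."""
    segment_ids = np.asarray(segment_ids, dtype=np.int64)
    counts = np.bincount(segment_ids, minlength=n_segments).astype(np.float64)
    sums = np.zeros((n_segments,) + x.data.shape[1:], dtype=np.float64)
    np.add.at(sums, segment_ids, x.data)
    safe = np.maximum(counts, 1.0)
    denom = safe.reshape((-1,) + (1,) * (x.data.ndim - 1))
    out = Tensor(sums / denom, parents=(x,))

    def bw(g: np.ndarray) -> None:
        if x.requires_grad:
            x._accumulate((g / denom)[segment_ids])

    out._backward = bw
    return out


def mean_rows(x: Tensor, mask: np.ndarray) -> Tensor:
    """Mean over the rows selected by a boolean mask (pooling readout)."""
    mask = np.asarray(mask, dtype=bool)
    n_sel = int(mask.sum())
    if n_sel == 0:
        raise ValueError("mean_rows: empty selection")
    out = Tensor(x.data[mask].mean(axis=0), parents=(x,))

    def bw(g: np.ndarray) -> None:
        if x.requires_grad:
            acc = np.zeros_like(x.data)
            acc[mask] = g / n_sel
            x._accumulate(acc)

    out._backward = bw
    return out


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    """Numerically stable softmax (plain numpy; not differentiable here)."""
    z = np.asarray(logits, dtype=np.float64)
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def cross_entropy_with_logits(logits: Tensor, target: int) -> Tensor:
    """Cross-entropy of a single logit vector against an integer class."""
    k = logits.data.shape[-1]
    if not (0 <= target < k):
        raise IndexError(f"target class {target} out of range for {k} categories")
    p = softmax(logits.data)
    loss = -np.log(max(p[target], 1e-300))
    out = Tensor(loss, parents=(logits,))

    def bw(g: np.ndarray) -> None:
        if logits.requires_grad:
            grad = p.copy()
            grad[target] -= 1.0
            logits._accumulate(g * grad)

    out._backward = bw
    return out
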