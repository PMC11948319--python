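"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Just the operations the energy network needs: broadcast arithmetic, matrix
products, shifted softplus, sigmoid, row gather and segment (scatter) sums,
absolute values and reductions.  Float64 throughout, so analytic gradients
check against central finite differences tightly.
"""

from __future__ import annotations

import numpy as np


def _scatter_add(n_rows: int, idx: np.ndarray, grad: np.ndarray) -> np.ndarray:
    """Row scatter-add via one flat bincount (much faster than np.add.at)."""
    if grad.ndim == 1:
        return np.bincount(idx, weights=grad, minlength=n_rows)
    n_cols = grad.shape[1]
    flat = (idx[:, None] * n_cols + np.arange(n_cols)).ravel()
    out = np.bincount(flat, weights=grad.ravel(), minlength=n_rows * n_cols)
    return out.reshape(n_rows, n_cols)


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the backward tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph bookkeeping --------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def _make(self, data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
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
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def _accumulate(self, grad: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.array(grad, dtype=np.float64)  # own a copy
        else:
            self.grad += grad

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data + other.data

        def backward(g):
            self._accumulate(_unbroadcast(g, self.shape))
            other._accumulate(_unbroadcast(g, other.shape))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accumulate(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data * other.data

        def backward(g):
            self._accumulate(_unbroadcast(g * other.data, self.shape))
            other._accumulate(_unbroadcast(g * self.data, other.shape))

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data / other.data

        def backward(g):
            self._accumulate(_unbroadcast(g / other.data, self.shape))
            other._accumulate(_unbroadcast(-g * self.data / other.data**2, other.shape))

        return self._make(out_data, (self, other), backward)

    def matmul(self, other: "Tensor") -> "Tensor":
        out_data = self.data @ other.data

        def backward(g):
            self._accumulate(g @ other.data.T)
            other._accumulate(self.data.T @ g)

        return self._make(out_data, (self, other), backward)

    __matmul__ = matmul

    # -- nonlinearities -------------------------------------------------
    def softplus(self) -> "Tensor":
        x = self.data
        out_data = np.where(x > 30, x, np.log1p(np.exp(np.minimum(x, 30))))

        def backward(g):
            self._accumulate(g / (1.0 + np.exp(-x)))

        return self._make(out_data, (self,), backward)

    def shifted_softplus(self) -> "Tensor":
        """ssp(x) = softplus(x) − ln 2, zero at the origin."""
        return self.softplus() - np.log(2.0)

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            self._accumulate(g * s * (1.0 - s))

        return self._make(s, (self,), backward)

    def abs(self) -> "Tensor":
        sign = np.sign(self.data)

        def backward(g):
            self._accumulate(g * sign)

        return self._make(np.abs(self.data), (self,), backward)

    # -- reductions & indexing -------------------------------------------
    def sum(self, axis=None, keepdims=False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape))

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis) * (1.0 / n)

    def take_rows(self, idx: np.ndarray) -> "Tensor":
        idx = np.asarray(idx, dtype=np.intp)
        out_data = self.data[idx]

        def backward(g):
            self._accumulate(
                _scatter_add(self.data.shape[0], idx, np.asarray(g)).reshape(self.shape)
            )

        return self._make(out_data, (self,), backward)

    def segment_sum(self, segment_ids: np.ndarray, num_segments: int) -> "Tensor":
        """Sum rows into ``num_segments`` buckets (scatter-add over axis 0)."""
        segment_ids = np.asarray(segment_ids, dtype=np.intp)
        out_data = _scatter_add(num_segments, segment_ids, self.data).reshape(
            (num_segments,) + self.data.shape[1:]
        )

        def backward(g):
            self._accumulate(g[segment_ids])

        return self._make(out_data, (self,), backward)

    def col(self, j: int) -> "Tensor":
        """Column ``j`` as a 1-D tensor."""
        out_data = self.data[:, j]

        def backward(g):
            acc = np.zeros_like(self.data)
            acc[:, j] = g
            self._accumulate(acc)

        return self._make(out_data, (self,), backward)

    def __repr__(self):  # pragma: no cover - cosmetic
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def parameter(data) -> Tensor:
    return Tensor(np.asarray(data, dtype=np.float64), requires_grad=True)
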