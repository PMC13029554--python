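"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Implements exactly the tensor operations the pairwise molecular scorer
needs: broadcast-aware arithmetic, (batched) matmul, reductions,
concatenation, pointwise nonlinearities, a masked softmax, and row
gather/scatter for edge-list message passing.  Gradients are accumulated
by a topological backward sweep; every op is checked against central
finite differences in the test suite.

The graph is built lazily: an op only records a backward closure when at
least one input requires a gradient, so inference-mode forward passes
carry no autodiff overhead.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "concat",
    "gather_rows",
    "scatter_rows",
    "masked_softmax",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` by summing over broadcast axes."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum axes that were size-1 in the original
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """An ndarray node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward

    # ---- introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # ---- graph machinery -----------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    def zero_grad(self) -> None:
        self.grad = None

    # ---- arithmetic ------------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)
        out_data = self.data + other.data
        if not (self.requires_grad or other.requires_grad):
            return Tensor(out_data)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        return Tensor(out_data, True, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        out_data = self.data * other.data
        if not (self.requires_grad or other.requires_grad):
            return Tensor(out_data)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        return Tensor(out_data, True, (self, other), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)
        return self * other ** -1.0

    def __pow__(self, exponent: float):
        out_data = self.data ** exponent
        if not self.requires_grad:
            return Tensor(out_data)

        def bwd(g):
            self._accumulate(g * exponent * self.data ** (exponent - 1.0))

        return Tensor(out_data, True, (self,), bwd)

    def __matmul__(self, other):
        other = _as_tensor(other)
        out_data = np.matmul(self.data, other.data)
        if not (self.requires_grad or other.requires_grad):
            return Tensor(out_data)

        def bwd(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accumulate(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accumulate(_unbroadcast(gb, other.data.shape))

        return Tensor(out_data, True, (self, other), bwd)

    # ---- shape ops -------------------------------------------------------
    def reshape(self, *shape):
        out_data = self.data.reshape(*shape)
        if not self.requires_grad:
            return Tensor(out_data)

        def bwd(g):
            self._accumulate(g.reshape(self.data.shape))

        return Tensor(out_data, True, (self,), bwd)

    def swap_last(self):
        """Transpose the last two axes."""
        out_data = np.swapaxes(self.data, -1, -2)
        if not self.requires_grad:
            return Tensor(out_data)

        def bwd(g):
            self._accumulate(np.swapaxes(g, -1, -2))

        return Tensor(out_data, True, (self,), bwd)

    # ---- reductions ------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        if not self.requires_grad:
            return Tensor(out_data)

        def bwd(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        return Tensor(out_data, True, (self,), bwd)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            n = self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ---- nonlinearities ----------------------------------------------------
    def relu(self):
        out_data = np.maximum(self.data, 0.0)
        if not self.requires_grad:
            return Tensor(out_data)

        def bwd(g):
            self._accumulate(g * (self.data > 0.0))

        return Tensor(out_data, True, (self,), bwd)

    def sigmoid(self):
        out_data = _sigmoid(self.data)
        if not self.requires_grad:
            return Tensor(out_data)

        def bwd(g):
            self._accumulate(g * out_data * (1.0 - out_data))

        return Tensor(out_data, True, (self,), bwd)

    def tanh(self):
        out_data = np.tanh(self.data)
        if not self.requires_grad:
            return Tensor(out_data)

        def bwd(g):
            self._accumulate(g * (1.0 - out_data ** 2))

        return Tensor(out_data, True, (self,), bwd)

    def exp(self):
        out_data = np.exp(self.data)
        if not self.requires_grad:
            return Tensor(out_data)

        def bwd(g):
            self._accumulate(g * out_data)

        return Tensor(out_data, True, (self,), bwd)

    def log(self):
        out_data = np.log(self.data)
        if not self.requires_grad:
            return Tensor(out_data)

        def bwd(g):
            self._accumulate(g / self.data)

        return Tensor(out_data, True, (self,), bwd)

    def softplus(self):
        """Numerically stable log(1 + exp(x))."""
        x = self.data
        out_data = np.maximum(x, 0.0) + np.log1p(np.exp(-np.abs(x)))
        if not self.requires_grad:
            return Tensor(out_data)

        def bwd(g):
            self._accumulate(g * _sigmoid(x))

        return Tensor(out_data, True, (self,), bwd)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def Parameter(data) -> Tensor:
    """A leaf tensor that accumulates gradients."""
    return Tensor(np.array(data, dtype=np.float64), requires_grad=True)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    if not any(t.requires_grad for t in tensors):
        return Tensor(out_data)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        pieces = np.split(g, splits, axis=axis)
        for t, piece in zip(tensors, pieces):
            if t.requires_grad:
                t._accumulate(piece)

    return Tensor(out_data, True, tuple(tensors), bwd)


def gather_rows(x: Tensor, idx: np.ndarray) -> Tensor:
    """Select rows of a 1-D or 2-D tensor along axis 0.

    Backward scatter-adds into the source rows (duplicate indices
    accumulate), which is exactly the adjoint of gathering.
    """
    idx = np.asarray(idx, dtype=np.intp)
    out_data = x.data[idx]
    if not x.requires_grad:
        return Tensor(out_data)

    def bwd(g):
        gx = np.zeros_like(x.data)
        np.add.at(gx, idx, g)
        x._accumulate(gx)

    return Tensor(out_data, True, (x,), bwd)


def scatter_rows(x: Tensor, idx: np.ndarray, num_rows: int) -> Tensor:
    """Sum rows of ``x`` into ``num_rows`` output slots: out[idx[k]] += x[k].

    The adjoint of :func:`gather_rows`; backward gathers the output
    gradient back to the contributing rows.
    """
    idx = np.asarray(idx, dtype=np.intp)
    out_shape = (num_rows,) + x.data.shape[1:]
    out_data = np.zeros(out_shape)
    np.add.at(out_data, idx, x.data)
    if not x.requires_grad:
        return Tensor(out_data)

    def bwd(g):
        x._accumulate(g[idx])

    return Tensor(out_data, True, (x,), bwd)


def masked_softmax(logits: Tensor, mask: np.ndarray, axis: int = -1) -> Tensor:
    """Softmax over ``axis`` restricted to positions where ``mask`` is truthy.

    Masked positions receive exactly zero weight.  Rows whose mask is
    all-zero yield an all-zero row rather than NaN (degenerate tokens,
    e.g. a molecule with no bonds).
    """
    m = np.asarray(mask, dtype=bool)
    m = np.broadcast_to(m, logits.data.shape)
    z = np.where(m, logits.data, -np.inf)
    zmax = np.max(z, axis=axis, keepdims=True)
    zmax = np.where(np.isfinite(zmax), zmax, 0.0)  # fully masked rows
    ez = np.where(m, np.exp(z - zmax), 0.0)
    denom = ez.sum(axis=axis, keepdims=True)
    out_data = np.divide(ez, denom, out=np.zeros_like(ez), where=denom > 0)
    if not logits.requires_grad:
        return Tensor(out_data)

    def bwd(g):
        dot = (g * out_data).sum(axis=axis, keepdims=True)
        logits._accumulate(out_data * (g - dot))

    return Tensor(out_data, True, (logits,), bwd)
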