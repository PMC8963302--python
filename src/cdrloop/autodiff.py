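"""Minimal reverse-mode automatic differentiation over numpy arrays.

Implements exactly the operations the equivariant network and its losses
need: broadcast arithmetic, matmul, row gather / segment sum (for message
passing on edge lists), concatenation, reductions, and a handful of
elementwise nonlinearities.  Gradients are accumulated by topological-order
backpropagation from a scalar.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "segment_sum", "gather_rows", "no_grad"]

_grad_enabled = True


class no_grad:
    """Context manager disabling graph construction (inference/evaluation):
    intermediates are freed as soon as they go out of scope."""

    def __enter__(self):
        global _grad_enabled
        self._prev = _grad_enabled
        _grad_enabled = False

    def __exit__(self, *exc):
        global _grad_enabled
        _grad_enabled = self._prev
        return False


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph plumbing -----------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def needs_grad(self) -> bool:
        return self.requires_grad or bool(self._parents)

    def _accumulate(self, g: np.ndarray) -> None:
        """Accumulate a gradient contribution that may alias other arrays."""
        if self.grad is None:
            # copy: g may be a read-only broadcast view or shared with siblings
            self.grad = np.array(g, dtype=np.float64)
            if self.grad.shape != self.data.shape:
                self.grad = np.broadcast_to(self.grad, self.data.shape).copy()
        else:
            self.grad += g

    def _accumulate_owned(self, g: np.ndarray) -> None:
        """Accumulate a freshly computed gradient array (safe to keep by ref)."""
        if self.grad is None:
            self.grad = g
        else:
            self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # -- helpers ------------------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @staticmethod
    def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
        """Sum gradient g down to the given (possibly broadcast) shape."""
        if g.shape == shape:
            return g
        extra = g.ndim - len(shape)
        if extra > 0:
            g = g.sum(axis=tuple(range(extra)))
        axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
        if axes:
            g = g.sum(axis=axes, keepdims=True)
        return g.reshape(shape)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if _grad_enabled and any(p.requires_grad or p._parents for p in parents):
            out._parents = parents
            out._backward = backward
            out.requires_grad = False
        return out

    # -- arithmetic ---------------------------------------------------------

    def __add__(self, other):
        other = self._lift(other)
        out_data = self.data + other.data

        def backward(g):
            self._accumulate(self._unbroadcast(g, self.data.shape))
            other._accumulate(self._unbroadcast(g, other.data.shape))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __sub__(self, other):
        other = self._lift(other)
        out_data = self.data - other.data

        def backward(g):
            self._accumulate(self._unbroadcast(g, self.data.shape))
            other._accumulate(-self._unbroadcast(g, other.data.shape))

        return self._make(out_data, (self, other), backward)

    def __rsub__(self, other):
        return self._lift(other).__sub__(self)

    def __neg__(self):
        def backward(g):
            self._accumulate(-g)

        return self._make(-self.data, (self,), backward)

    def __mul__(self, other):
        other = self._lift(other)
        out_data = self.data * other.data

        def backward(g):
            if self.needs_grad:
                self._accumulate_owned(
                    self._unbroadcast(g * other.data, self.data.shape)
                )
            if other.needs_grad:
                other._accumulate_owned(
                    self._unbroadcast(g * self.data, other.data.shape)
                )

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out_data = self.data / other.data

        def backward(g):
            self._accumulate(self._unbroadcast(g / other.data, self.data.shape))
            other._accumulate(
                self._unbroadcast(-g * self.data / other.data**2, other.data.shape)
            )

        return self._make(out_data, (self, other), backward)

    def __matmul__(self, other):
        # Supports batched operands (leading axes broadcast, numpy semantics);
        # gradients are summed back down to each operand's shape.
        other = self._lift(other)
        out_data = self.data @ other.data

        def backward(g):
            if self.needs_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accumulate_owned(self._unbroadcast(ga, self.data.shape))
            if other.needs_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accumulate_owned(self._unbroadcast(gb, other.data.shape))

        return self._make(out_data, (self, other), backward)

    # -- reductions ---------------------------------------------------------

    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape))

        return self._make(out_data, (self,), backward)

    def mean(self):
        n = self.data.size
        return self.sum() / float(n)

    # -- elementwise --------------------------------------------------------

    def square(self):
        def backward(g):
            self._accumulate_owned(2.0 * self.data * g)

        return self._make(self.data**2, (self,), backward)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward(g):
            self._accumulate_owned(g / (2.0 * np.maximum(out_data, 1e-12)))

        return self._make(out_data, (self,), backward)

    def log1p(self):
        def backward(g):
            self._accumulate_owned(g / (1.0 + self.data))

        return self._make(np.log1p(self.data), (self,), backward)

    def abs(self):
        def backward(g):
            self._accumulate_owned(g * np.sign(self.data))

        return self._make(np.abs(self.data), (self,), backward)

    def silu(self):
        s = _stable_sigmoid(self.data)
        out_data = self.data * s

        def backward(g):
            self._accumulate_owned(g * (s * (1.0 + self.data * (1.0 - s))))

        return self._make(out_data, (self,), backward)

    def sigmoid(self):
        s = _stable_sigmoid(self.data)

        def backward(g):
            self._accumulate_owned(g * s * (1.0 - s))

        return self._make(s, (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            self._accumulate_owned(g * (1.0 - out_data**2))

        return self._make(out_data, (self,), backward)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accumulate(piece)

    out = Tensor(out_data)
    if _grad_enabled and any(t.requires_grad or t._parents for t in tensors):
        out._parents = tuple(tensors)
        out._backward = backward
    return out


def _stable_sigmoid(x: np.ndarray) -> np.ndarray:
    # exp overflow saturates to inf -> sigmoid 0, the correct limit
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-x))


class ScatterOp:
    """Precomputed scatter-add along the row (second-to-last) axis.

    Sparse matmul is far faster than np.add.at on large edge lists and the
    operator is reusable across calls.  Handles 2-D (rows, feat) and batched
    3-D (batch, rows, feat) arrays.
    """

    def __init__(self, idx: np.ndarray, n: int):
        from scipy import sparse

        idx = np.asarray(idx)
        e = len(idx)
        self.idx = idx
        self.n = n
        self.mat = sparse.csr_matrix(
            (np.ones(e), (idx, np.arange(e))), shape=(n, e)
        )

    def __call__(self, rows: np.ndarray) -> np.ndarray:
        if rows.ndim == 2:
            return self.mat @ rows
        k, e, f = rows.shape
        flat = np.moveaxis(rows, 0, 1).reshape(e, k * f)
        out = self.mat @ flat
        return np.moveaxis(out.reshape(self.n, k, f), 1, 0)


def _scatter_fallback(g: np.ndarray, idx: np.ndarray, n: int) -> np.ndarray:
    acc = np.zeros(g.shape[:-2] + (n,) + g.shape[-1:], dtype=np.float64)
    np.add.at(acc, (..., idx, slice(None)), g)
    return acc


def gather_rows(t: Tensor, idx, scatter: ScatterOp | None = None) -> Tensor:
    """Select rows t[..., idx, :] along the node axis; gradient scatter-adds
    back."""
    if isinstance(idx, ScatterOp):
        scatter, idx = idx, idx.idx
    idx = np.asarray(idx)
    n_rows = t.data.shape[-2]

    def backward(g):
        if scatter is not None:
            t._accumulate_owned(scatter(g))
        else:
            t._accumulate_owned(_scatter_fallback(g, idx, n_rows))

    return t._make(t.data[..., idx, :], (t,), backward)


def segment_sum(t: Tensor, idx, n: int | None = None,
                scatter: ScatterOp | None = None) -> Tensor:
    """Sum rows of t into n buckets given by idx (message aggregation)."""
    if isinstance(idx, ScatterOp):
        scatter, idx, n = idx, idx.idx, idx.n
    idx = np.asarray(idx)
    if scatter is not None:
        out_data = scatter(t.data)
    else:
        out_data = _scatter_fallback(t.data, idx, n)

    def backward(g):
        t._accumulate_owned(g[..., idx, :])

    return t._make(out_data, (t,), backward)
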