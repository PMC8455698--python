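"""Minimal reverse-mode automatic differentiation over numpy arrays.

The network in :mod:`jcouple.nn` needs a handful of differentiable
primitives (broadcasted arithmetic, batched matmul, gather/segment-sum for
graph message passing, a sliding-window unfold, masked softmax).  This
module provides exactly those as a :class:`Tensor` wrapper around
``numpy.ndarray`` with taped backpropagation.  Gradients are verified
against central finite differences in the test suite.
"""

from __future__ import annotations

from typing import Callable, Optional, Sequence

import numpy as np

Array = np.ndarray


def _unbroadcast(grad: Array, shape: tuple[int, ...]) -> Array:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd_extra = grad.ndim - len(shape)
    if nd_extra > 0:
        grad = grad.sum(axis=tuple(range(nd_extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array plus the tape hooks needed for backpropagation."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        parents: tuple["Tensor", ...] = (),
        backward: Optional[Callable[[Array], None]] = None,
    ):
        arr = np.asarray(data)
        if not np.issubdtype(arr.dtype, np.floating):
            arr = arr.astype(np.float64)
        self.data = arr
        self.grad: Optional[Array] = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward

    # -- construction helpers -------------------------------------------
    @staticmethod
    def as_tensor(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def _accumulate(self, g: Array, fresh: bool = False) -> None:
        # ``fresh`` promises g is a newly allocated array owned by the
        # caller, safe to adopt as the grad buffer; otherwise copy so a
        # view/alias can never end up shared between two nodes' grads
        if self.grad is None:
            self.grad = g if fresh else np.array(g)
        else:
            self.grad += g

    # -- autodiff driver -------------------------------------------------
    def backward(self, grad: Optional[Array] = None) -> None:
        """Backpropagate from this tensor (defaults to d(self)/d(self)=1)."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        # iterative topological sort
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accumulate(grad)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic ------------------------------------------------------
    def __add__(self, other) -> "Tensor":
        other = Tensor.as_tensor(other)

        def bwd(g: Array) -> None:
            if self.requires_grad:
                r = _unbroadcast(g, self.shape)
                self._accumulate(r, fresh=r is not g)
            if other.requires_grad:
                r = _unbroadcast(g, other.shape)
                other._accumulate(r, fresh=r is not g)

        return Tensor(self.data + other.data, parents=(self, other), backward=bwd)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def bwd(g: Array) -> None:
            if self.requires_grad:
                self._accumulate(-g, fresh=True)

        return Tensor(-self.data, parents=(self,), backward=bwd)

    def __sub__(self, other) -> "Tensor":
        return self + (-Tensor.as_tensor(other))

    def __rsub__(self, other) -> "Tensor":
        return Tensor.as_tensor(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = Tensor.as_tensor(other)

        def bwd(g: Array) -> None:
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape), fresh=True)
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape), fresh=True)

        return Tensor(self.data * other.data, parents=(self, other), backward=bwd)

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = Tensor.as_tensor(other)

        def bwd(g: Array) -> None:
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.shape), fresh=True)
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data**2, other.shape),
                    fresh=True,
                )

        return Tensor(self.data / other.data, parents=(self, other), backward=bwd)

    def __pow__(self, p: float) -> "Tensor":
        def bwd(g: Array) -> None:
            if self.requires_grad:
                self._accumulate(g * p * self.data ** (p - 1), fresh=True)

        return Tensor(self.data**p, parents=(self,), backward=bwd)

    def matmul(self, other: "Tensor") -> "Tensor":
        """Batched matrix product with numpy broadcasting semantics."""
        other = Tensor.as_tensor(other)
        out = np.matmul(self.data, other.data)

        def bwd(g: Array) -> None:
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accumulate(_unbroadcast(ga, self.shape), fresh=True)
            if other.requires_grad:
                if other.data.ndim == 2 and self.data.ndim > 2:
                    # batched x @ W: contract batch dims directly instead of
                    # materialising a per-batch (k, m) gradient stack
                    k, m = other.data.shape
                    gb = self.data.reshape(-1, k).T @ g.reshape(-1, m)
                    other._accumulate(gb, fresh=True)
                else:
                    gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                    other._accumulate(_unbroadcast(gb, other.shape), fresh=True)

        return Tensor(out, parents=(self, other), backward=bwd)

    __matmul__ = matmul

    # -- shape ops -------------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        shape = shape[0] if len(shape) == 1 and isinstance(shape[0], tuple) else shape
        old = self.shape

        def bwd(g: Array) -> None:
            if self.requires_grad:
                self._accumulate(g.reshape(old))

        return Tensor(self.data.reshape(shape), parents=(self,), backward=bwd)

    def transpose(self, axes: Sequence[int]) -> "Tensor":
        axes = tuple(axes)
        inv = tuple(np.argsort(axes))

        def bwd(g: Array) -> None:
            if self.requires_grad:
                self._accumulate(g.transpose(inv))

        return Tensor(self.data.transpose(axes), parents=(self,), backward=bwd)

    @property
    def mT(self) -> "Tensor":
        """Swap the last two axes."""
        axes = tuple(range(self.ndim - 2)) + (self.ndim - 1, self.ndim - 2)
        return self.transpose(axes)

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        def bwd(g: Array) -> None:
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape))
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(gg, self.shape))

        return Tensor(
            self.data.sum(axis=axis, keepdims=keepdims), parents=(self,), backward=bwd
        )

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- nonlinearities --------------------------------------------------
    def relu(self) -> "Tensor":
        mask = self.data > 0

        def bwd(g: Array) -> None:
            if self.requires_grad:
                self._accumulate(g * mask, fresh=True)

        return Tensor(self.data * mask, parents=(self,), backward=bwd)

    def tanh(self) -> "Tensor":
        out = np.tanh(self.data)

        def bwd(g: Array) -> None:
            if self.requires_grad:
                self._accumulate(g * (1 - out**2), fresh=True)

        return Tensor(out, parents=(self,), backward=bwd)

    def exp(self) -> "Tensor":
        out = np.exp(self.data)

        def bwd(g: Array) -> None:
            if self.requires_grad:
                self._accumulate(g * out, fresh=True)

        return Tensor(out, parents=(self,), backward=bwd)

    def log(self) -> "Tensor":
        def bwd(g: Array) -> None:
            if self.requires_grad:
                self._accumulate(g / self.data, fresh=True)

        return Tensor(np.log(self.data), parents=(self,), backward=bwd)

    def abs(self) -> "Tensor":
        sign = np.sign(self.data)  # subgradient 0 at 0

        def bwd(g: Array) -> None:
            if self.requires_grad:
                self._accumulate(g * sign, fresh=True)

        return Tensor(np.abs(self.data), parents=(self,), backward=bwd)

    def clip_min(self, lo: float) -> "Tensor":
        """Elementwise max(x, lo); subgradient 0 where clamped."""
        mask = self.data > lo

        def bwd(g: Array) -> None:
            if self.requires_grad:
                self._accumulate(g * mask, fresh=True)

        return Tensor(np.maximum(self.data, lo), parents=(self,), backward=bwd)


# ---------------------------------------------------------------------------
# graph / structured ops
# ---------------------------------------------------------------------------


def gather_rows(x: Tensor, idx: Array) -> Tensor:
    """``y = x[idx]`` along axis 0 with an integer index array of any shape."""
    idx = np.asarray(idx, dtype=int)
    out = x.data[idx]

    def bwd(g: Array) -> None:
        if x.requires_grad:
            gx = np.zeros_like(x.data)
            np.add.at(gx, idx, g)
            x._accumulate(gx, fresh=True)

    return Tensor(out, parents=(x,), backward=bwd)


def segment_sum(x: Tensor, seg: Array, n_segments: int) -> Tensor:
    """Sum rows of ``x`` into ``n_segments`` buckets given by ``seg``."""
    seg = np.asarray(seg, dtype=int)
    out = np.zeros((n_segments,) + x.data.shape[1:], dtype=x.data.dtype)
    np.add.at(out, seg, x.data)

    def bwd(g: Array) -> None:
        if x.requires_grad:
            x._accumulate(g[seg], fresh=True)

    return Tensor(out, parents=(x,), backward=bwd)


def unfold(x: Tensor, window: int) -> Tensor:
    """Zero-padded sliding-window unfold of each row.

    Input (n, d) → output (n, d, window) with ``out[:, r, c] = x[:, r+c]``
    for ``r + c < d`` and 0 past the end.
    """
    n, d = x.data.shape
    out = np.zeros((n, d, window), dtype=x.data.dtype)
    for c in range(window):
        out[:, : d - c, c] = x.data[:, c:]

    def bwd(g: Array) -> None:
        if x.requires_grad:
            gx = np.zeros_like(x.data)
            for c in range(window):
                gx[:, c:] += g[:, : d - c, c]
            x._accumulate(gx, fresh=True)

    return Tensor(out, parents=(x,), backward=bwd)


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    """Concatenate tensors along ``axis``."""
    tensors = [Tensor.as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g: Array) -> None:
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        parents=tuple(tensors),
        backward=bwd,
    )


def softmax_last(x: Tensor, mask: Optional[Array] = None) -> Tensor:
    """Softmax over the last axis, optionally masking invalid positions.

    ``mask`` broadcasts against ``x`` with 1 = keep, 0 = exclude; excluded
    positions get probability 0 (a fully-masked row degrades to uniform
    over nothing and is the caller's responsibility to ignore).
    """
    z = x.data
    if mask is not None:
        mask = np.asarray(mask).astype(bool)
        z = np.where(mask, z, z.dtype.type(-1e30))
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    if mask is not None:
        e = e * mask
    denom = e.sum(axis=-1, keepdims=True)
    out = e / np.maximum(denom, 1e-30)

    def bwd(g: Array) -> None:
        if x.requires_grad:
            dot = (g * out).sum(axis=-1, keepdims=True)
            x._accumulate(out * (g - dot), fresh=True)

    return Tensor(out, parents=(x,), backward=bwd)


def parameter(data, rng: Optional[np.random.Generator] = None) -> Tensor:
    """Wrap an array as a trainable tensor."""
    return Tensor(np.asarray(data, dtype=float), requires_grad=True)


def uniform_fan_in(
    rng: np.random.Generator, shape: tuple[int, ...], fan_in: Optional[int] = None
) -> Tensor:
    """Uniform(-1/√fan_in, 1/√fan_in) initialisation, the classic default."""
    if fan_in is None:
        fan_in = shape[0] if len(shape) > 1 else max(shape[0], 1)
    bound = 1.0 / np.sqrt(max(fan_in, 1))
    return parameter(rng.uniform(-bound, bound, size=shape))
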