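"""Minimal reverse-mode automatic differentiation on numpy arrays.

The aggregate encoders in this package are small dense networks over
groups of at most a few dozen nodes, so every operation they need —
matrix products, broadcast arithmetic, masked softmax, max pooling and
the usual pointwise nonlinearities — is expressible as a handful of
dense numpy ops. This module provides a tape-based :class:`Tensor`
supporting exactly those ops, with gradients checked against finite
differences in the test suite.

All arithmetic is float64. Gradients accumulate into ``.grad`` after
calling :meth:`Tensor.backward` on a scalar result.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, inverting numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum away leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # sum axes that were size 1 in the original
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array with a gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = np.zeros_like(self.data) if requires_grad else None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    # -- helpers -------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data, prev, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in prev):
            out.requires_grad = True
            out.grad = np.zeros_like(out.data)
            out._prev = tuple(p for p in prev if p.requires_grad)
            out._backward = backward
        return out

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g, self.data.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(g, other.data.shape)

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self.grad += -g

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g * other.data, self.data.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(g * self.data, other.data.shape)

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out_data = self.data / other.data

        def backward(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g / other.data, self.data.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(
                    -g * self.data / other.data**2, other.data.shape
                )

        return self._make(out_data, (self, other), backward)

    def __matmul__(self, other):
        other = self._lift(other)
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                self.grad += g @ other.data.T
            if other.requires_grad:
                other.grad += self.data.T @ g

        return self._make(out_data, (self, other), backward)

    @property
    def T(self):
        def backward(g):
            if self.requires_grad:
                self.grad += g.T

        return self._make(self.data.T, (self,), backward)

    # -- reductions ----------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self.grad += np.broadcast_to(g, self.data.shape)
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self.grad += np.broadcast_to(gg, self.data.shape)

        return self._make(out_data, (self,), backward)

    def max(self, axis=None, keepdims=False):
        out_data = self.data.max(axis=axis, keepdims=keepdims)
        # gradient flows to the (first) argmax only; ties split would also
        # be valid, first-hit matches np.argmax and keeps runs reproducible
        if axis is None:
            mask = np.zeros_like(self.data)
            mask[np.unravel_index(np.argmax(self.data), self.data.shape)] = 1.0
        else:
            idx = np.argmax(self.data, axis=axis)
            mask = np.zeros_like(self.data)
            np.put_along_axis(mask, np.expand_dims(idx, axis), 1.0, axis=axis)

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self.grad += mask * g
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self.grad += mask * gg

        return self._make(out_data, (self,), backward)

    # -- pointwise -----------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self.grad += g * out_data

        return self._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            if self.requires_grad:
                self.grad += g / self.data

        return self._make(np.log(self.data), (self,), backward)

    def relu(self):
        pos = self.data > 0

        def backward(g):
            if self.requires_grad:
                self.grad += g * pos

        return self._make(np.where(pos, self.data, 0.0), (self,), backward)

    def leaky_relu(self, slope: float = 0.2):
        pos = self.data > 0

        def backward(g):
            if self.requires_grad:
                self.grad += g * np.where(pos, 1.0, slope)

        return self._make(
            np.where(pos, self.data, slope * self.data), (self,), backward
        )

    def elu(self, alpha: float = 1.0):
        pos = self.data > 0
        neg_part = alpha * (np.exp(np.minimum(self.data, 0.0)) - 1.0)
        out_data = np.where(pos, self.data, neg_part)

        def backward(g):
            if self.requires_grad:
                self.grad += g * np.where(pos, 1.0, neg_part + alpha)

        return self._make(out_data, (self,), backward)

    # -- composites (built from primitives, no own backward) ----------
    def softmax_rows(self, mask: np.ndarray | None = None) -> "Tensor":
        """Row-wise softmax; `mask` (0/1 array) excludes entries.

        Masked-out entries get exactly zero weight. Rows whose mask is
        all-zero would be degenerate; callers guarantee at least one
        admissible entry per row (self-loops, here).
        """
        shift = self.data.max(axis=-1, keepdims=True)  # constant, no grad
        z = self - Tensor(shift)
        e = z.exp()
        if mask is not None:
            e = e * Tensor(mask.astype(np.float64))
        return e / e.sum(axis=-1, keepdims=True)

    # -- engine --------------------------------------------------------
    def backward(self):
        if self.data.shape != ():
            raise ValueError("backward() requires a scalar output")
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
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"
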