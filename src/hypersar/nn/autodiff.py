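"""Minimal reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps an ndarray and records the operations applied to it;
:meth:`Tensor.backward` accumulates gradients by reverse topological traversal.
The op set is exactly what the networks in this package need: broadcasted
arithmetic, (batched) matmul, elementwise nonlinearities, axis reductions
(sum / mean / max), shape ops, concatenation and 1-D convolution.  Gradients
through broadcasting are handled by summing over the broadcast axes.
"""

from __future__ import annotations

import contextlib

import numpy as np

__all__ = ["Tensor", "concat", "conv1d", "layer_norm", "default_dtype"]

_DEFAULT_DTYPE = np.float64


@contextlib.contextmanager
def default_dtype(dtype):
    """Temporarily change the dtype new tensors are created with.

    Training runs use ``default_dtype(np.float32)`` to halve memory traffic
    and roughly double BLAS throughput; verification and metrics code keeps
    the float64 default.
    """
    global _DEFAULT_DTYPE
    previous = _DEFAULT_DTYPE
    _DEFAULT_DTYPE = np.dtype(dtype)
    try:
        yield
    finally:
        _DEFAULT_DTYPE = previous


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over the axes that broadcasting expanded to reach ``shape``."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An ndarray node in a dynamically built computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=_DEFAULT_DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- graph plumbing -----------------------------------------------------

    @classmethod
    def _node(cls, data, parents, backward):
        out = cls(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad=None) -> None:
        """Accumulate gradients of a scalar (or supplied cotangent) output."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient needs a scalar output")
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
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        grad = _unbroadcast(np.asarray(grad, dtype=self.data.dtype), self.data.shape)
        self.grad = grad if self.grad is None else self.grad + grad

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic ---------------------------------------------------------

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._wrap(other)

        def backward(g):
            if self.requires_grad:
                self._accum(g)
            if other.requires_grad:
                other._accum(g)

        return Tensor._node(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accum(-g)

        return Tensor._node(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)

        def backward(g):
            if self.requires_grad:
                self._accum(g * other.data)
            if other.requires_grad:
                other._accum(g * self.data)

        return Tensor._node(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * self._wrap(other) ** -1.0

    def __rtruediv__(self, other):
        return self._wrap(other) * self**-1.0

    def __pow__(self, exponent: float):
        def backward(g):
            if self.requires_grad:
                self._accum(g * exponent * self.data ** (exponent - 1.0))

        return Tensor._node(self.data**exponent, (self,), backward)

    def __matmul__(self, other):
        other = self._wrap(other)

        def backward(g):
            if self.requires_grad:
                self._accum(g @ np.swapaxes(other.data, -1, -2))
            if other.requires_grad:
                other._accum(np.swapaxes(self.data, -1, -2) @ g)

        return Tensor._node(self.data @ other.data, (self, other), backward)

    # -- elementwise --------------------------------------------------------

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data)

        return Tensor._node(out_data, (self,), backward)

    def log(self):
        def backward(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return Tensor._node(np.log(self.data), (self,), backward)

    def sqrt(self):
        return self**0.5

    def relu(self):
        def backward(g):
            if self.requires_grad:
                self._accum(g * (self.data > 0))

        return Tensor._node(np.maximum(self.data, 0.0), (self,), backward)

    def sin(self):
        def backward(g):
            if self.requires_grad:
                self._accum(g * np.cos(self.data))

        return Tensor._node(np.sin(self.data), (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * (1.0 - out_data**2))

        return Tensor._node(out_data, (self,), backward)

    def abs(self):
        def backward(g):
            if self.requires_grad:
                self._accum(g * np.sign(self.data))

        return Tensor._node(np.abs(self.data), (self,), backward)

    # -- reductions ---------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape))
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.data.shape))

        return Tensor._node(
            self.data.sum(axis=axis, keepdims=keepdims), (self,), backward
        )

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False):
        """Maximum along one axis; the gradient flows to the first argmax."""
        idx = np.argmax(self.data, axis=axis)
        out_data = np.take_along_axis(self.data, np.expand_dims(idx, axis), axis)
        if not keepdims:
            out_data = np.squeeze(out_data, axis)

        def backward(g):
            if not self.requires_grad:
                return
            gg = g if keepdims else np.expand_dims(g, axis)
            grad = np.zeros_like(self.data)
            np.put_along_axis(grad, np.expand_dims(idx, axis), gg, axis)
            self._accum(grad)

        return Tensor._node(out_data, (self,), backward)

    # -- shape --------------------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(orig))

        return Tensor._node(self.data.reshape(shape), (self,), backward)

    def swapaxes(self, ax1: int, ax2: int):
        def backward(g):
            if self.requires_grad:
                self._accum(np.swapaxes(g, ax1, ax2))

        return Tensor._node(np.swapaxes(self.data, ax1, ax2), (self,), backward)

    def __getitem__(self, key):
        def backward(g):
            if self.requires_grad:
                grad = np.zeros_like(self.data)
                np.add.at(grad, key, g)
                self._accum(grad)

        return Tensor._node(self.data[key], (self,), backward)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    """Concatenate tensors along ``axis``."""
    tensors = [Tensor._wrap(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accum(piece)

    return Tensor._node(
        np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), backward
    )


def layer_norm(x: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    """Fused layer normalisation over the last axis: ``xhat * gain + bias``.

    Implemented as a single graph node with a hand-written backward pass;
    functionally identical to composing the primitive ops but substantially
    cheaper on wide activations.
    """
    x = Tensor._wrap(x)
    mu = x.data.mean(axis=-1, keepdims=True)
    xc = x.data - mu
    inv_std = 1.0 / np.sqrt(xc.var(axis=-1, keepdims=True) + eps)
    # note: var of xc equals var of x; computed from xc for one fewer pass
    xhat = xc * inv_std
    out_data = xhat * gain.data + bias.data

    def backward(g):
        if gain.requires_grad:
            gain._accum((g * xhat).reshape(-1, g.shape[-1]).sum(axis=0))
        if bias.requires_grad:
            bias._accum(g.reshape(-1, g.shape[-1]).sum(axis=0))
        if x.requires_grad:
            dxhat = g * gain.data
            m1 = dxhat.mean(axis=-1, keepdims=True)
            m2 = (dxhat * xhat).mean(axis=-1, keepdims=True)
            x._accum(inv_std * (dxhat - m1 - xhat * m2))

    return Tensor._node(out_data, (x, gain, bias), backward)


def conv1d(x: Tensor, w: Tensor, b: Tensor | None = None, padding: int = 0) -> Tensor:
    """1-D convolution (cross-correlation) with stride 1.

    ``x`` is (B, C_in, L), ``w`` is (C_out, C_in, K), optional bias (C_out,).
    Output is (B, C_out, L + 2*padding - K + 1).
    """
    x = Tensor._wrap(x)
    w = Tensor._wrap(w)
    kb, kc, kk = w.data.shape
    xd = x.data
    if padding:
        xd = np.pad(xd, ((0, 0), (0, 0), (padding, padding)))
    windows = np.lib.stride_tricks.sliding_window_view(xd, kk, axis=2)  # (B,C,Lo,K)
    out_data = np.einsum("bclk,ock->bol", windows, w.data, optimize=True)
    if b is not None:
        out_data = out_data + b.data[None, :, None]
    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        if w.requires_grad:
            w._accum(np.einsum("bclk,bol->ock", windows, g, optimize=True))
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2)))
        if x.requires_grad:
            gx = np.zeros_like(xd)
            lo = g.shape[2]
            for k in range(kk):
                gx[:, :, k : k + lo] += np.einsum(
                    "bol,oc->bcl", g, w.data[:, :, k], optimize=True
                )
            if padding:
                gx = gx[:, :, padding:-padding]
            x._accum(gx)

    return Tensor._node(out_data, parents, backward)
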