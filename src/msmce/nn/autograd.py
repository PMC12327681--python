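"""Reverse-mode automatic differentiation on NumPy arrays.

A minimal tape-based engine: :class:`Tensor` wraps an ``ndarray`` and records
the operations applied to it; :meth:`Tensor.backward` walks the tape in
reverse topological order accumulating gradients.  Everything runs in the
array's native dtype (float64 by default), which keeps finite-difference
gradient checks tight.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "concat", "no_grad"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast to reach ``grad.shape``."""
    if grad.shape == shape:
        return grad
    # leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # axes of size 1 that were stretched
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class _GradMode:
    enabled = True


class no_grad:
    """Context manager disabling graph construction (eval-time speed)."""

    def __enter__(self):
        self._prev = _GradMode.enabled
        _GradMode.enabled = False
        return self

    def __exit__(self, *exc):
        _GradMode.enabled = self._prev
        return False


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[], None] | None = None
        self._prev: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data: np.ndarray, prev: Sequence["Tensor"], backward: Callable[[], None]) -> "Tensor":
        req = _GradMode.enabled and any(p.requires_grad for p in prev)
        out = Tensor(data, requires_grad=req)
        if req:
            out._prev = tuple(prev)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    # -- basic properties -----------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __len__(self) -> int:
        return len(self.data)

    def __repr__(self) -> str:
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    # -- autodiff driver ------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar tensor")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; deep graphs (LSTM) overflow recursion
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen and p.requires_grad:
                    stack.append((p, False))
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward()
        # break the out -> closure -> out reference cycles so whole graphs
        # are reclaimed by refcounting instead of waiting for cyclic GC
        for node in topo:
            node._backward = None
            node._prev = ()

    # -- arithmetic -----------------------------------------------------------
    @staticmethod
    def _coerce(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._coerce(other)
        out_data = self.data + other.data

        def backward():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad, other.shape))

        out = Tensor._make(out_data, (self, other), backward)
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = self._coerce(other)
        out_data = self.data * other.data

        def backward():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad * self.data, other.shape))

        out = Tensor._make(out_data, (self, other), backward)
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __truediv__(self, other):
        return self * self._coerce(other).pow(-1.0)

    def __rtruediv__(self, other):
        return self._coerce(other) * self.pow(-1.0)

    def pow(self, exponent: float) -> "Tensor":
        out_data = self.data ** exponent

        def backward():
            if self.requires_grad:
                self._accum(out.grad * exponent * self.data ** (exponent - 1.0))

        out = Tensor._make(out_data, (self,), backward)
        return out

    __pow__ = pow

    def sqrt(self) -> "Tensor":
        return self.pow(0.5)

    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)

        def backward():
            if self.requires_grad:
                self._accum(out.grad * out_data)

        out = Tensor._make(out_data, (self,), backward)
        return out

    def log(self) -> "Tensor":
        out_data = np.log(self.data)

        def backward():
            if self.requires_grad:
                self._accum(out.grad / self.data)

        out = Tensor._make(out_data, (self,), backward)
        return out

    def tanh(self) -> "Tensor":
        out_data = np.tanh(self.data)

        def backward():
            if self.requires_grad:
                self._accum(out.grad * (1.0 - out_data ** 2))

        out = Tensor._make(out_data, (self,), backward)
        return out

    def sigmoid(self) -> "Tensor":
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward():
            if self.requires_grad:
                self._accum(out.grad * out_data * (1.0 - out_data))

        out = Tensor._make(out_data, (self,), backward)
        return out

    def relu(self) -> "Tensor":
        mask = self.data > 0
        out_data = np.where(mask, self.data, 0.0)

        def backward():
            if self.requires_grad:
                self._accum(out.grad * mask)

        out = Tensor._make(out_data, (self,), backward)
        return out

    # -- linear algebra -------------------------------------------------------
    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._coerce(other)
        out_data = self.data @ other.data

        def backward():
            g = out.grad
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.shape))

        out = Tensor._make(out_data, (self, other), backward)
        return out

    __matmul__ = matmul

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward():
            if not self.requires_grad:
                return
            g = out.grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape).copy())

        out = Tensor._make(out_data, (self,), backward)
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out_data = self.data.reshape(shape)

        def backward():
            if self.requires_grad:
                self._accum(out.grad.reshape(self.shape))

        out = Tensor._make(out_data, (self,), backward)
        return out

    def transpose(self, *axes) -> "Tensor":
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        out_data = self.data.transpose(axes)
        inv = np.argsort(axes)

        def backward():
            if self.requires_grad:
                self._accum(out.grad.transpose(inv))

        out = Tensor._make(out_data, (self,), backward)
        return out

    def __getitem__(self, idx) -> "Tensor":
        out_data = self.data[idx]

        def backward():
            if self.requires_grad:
                g = np.zeros_like(self.data)
                np.add.at(g, idx, out.grad)
                self._accum(g)

        out = Tensor._make(out_data, (self,), backward)
        return out

    # -- fused numeric helpers ------------------------------------------------
    def logsumexp(self, axis: int, keepdims: bool = False) -> "Tensor":
        # subtracting the detached max is exact: logsumexp is shift-covariant
        m = self.data.max(axis=axis, keepdims=True)
        shifted = self - Tensor(m)
        out = shifted.exp().sum(axis=axis, keepdims=True).log() + Tensor(m)
        if not keepdims:
            out = out.reshape(tuple(s for i, s in enumerate(self.shape) if i != axis % self.ndim))
        return out

    def softmax(self, axis: int = -1) -> "Tensor":
        m = self.data.max(axis=axis, keepdims=True)
        e = (self - Tensor(m)).exp()
        return e / e.sum(axis=axis, keepdims=True)

    def conv1d(self, weight: "Tensor", bias: "Tensor | None" = None, padding: int = 0) -> "Tensor":
        """1-D cross-correlation: self (B, C_in, L), weight (C_out, C_in, k)."""
        x, w = self, weight
        B, C_in, L = x.shape
        C_out, C_in_w, k = w.shape
        if C_in != C_in_w:
            raise ValueError(f"conv1d channel mismatch: input has {C_in}, kernel expects {C_in_w}")
        xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding))) if padding else x.data
        L_out = L + 2 * padding - k + 1
        if L_out < 1:
            raise ValueError("conv1d: kernel longer than padded input")
        # cols: (B, C_in, k, L_out) via stride tricks (read-only view)
        s = xp.strides
        cols = np.lib.stride_tricks.as_strided(
            xp, shape=(B, C_in, k, L_out), strides=(s[0], s[1], s[2], s[2]), writeable=False
        )
        out_data = np.einsum("bikl,oik->bol", cols, w.data, optimize=True)
        if bias is not None:
            out_data = out_data + bias.data[None, :, None]

        def backward():
            g = out.grad  # (B, C_out, L_out)
            if w.requires_grad:
                w._accum(np.einsum("bol,bikl->oik", g, cols, optimize=True))
            if bias is not None and bias.requires_grad:
                bias._accum(g.sum(axis=(0, 2)))
            if x.requires_grad:
                gxp = np.zeros_like(xp)
                # col2im: scatter each kernel tap back onto the padded input
                contrib = np.einsum("bol,oik->bikl", g, w.data, optimize=True)
                for j in range(k):
                    gxp[:, :, j:j + L_out] += contrib[:, :, j, :]
                gx = gxp[:, :, padding:padding + L] if padding else gxp
                x._accum(gx)

        out = Tensor._make(out_data, tuple(t for t in (x, w, bias) if t is not None), backward)
        return out


def concat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = list(tensors)
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward():
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * out_data.ndim
                sl[axis] = slice(lo, hi)
                t._accum(out.grad[tuple(sl)])

    out = Tensor._make(out_data, tensors, backward)
    return out
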