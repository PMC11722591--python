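"""Minimal reverse-mode automatic differentiation on NumPy arrays.

This module provides the small set of differentiable tensor operations the
attention modules and the smoke-training harness need: broadcast-aware
arithmetic, matmul, the usual nonlinearities, axis reductions (sum / mean /
max), shape surgery (reshape, transpose, slicing, concatenation, zero
padding) and a same-padded 2-D convolution implemented via im2col.

The design follows the classic tape-based pattern: every operation records
its parents and a closure that accumulates gradients into them; ``backward``
runs the closures in reverse topological order.  Everything is float64 and
single-threaded — the engine targets desk-scale experiments, not production
training.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "concat", "conv2d_same"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over the axes that were broadcast to reach its shape."""
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


class Tensor:
    """A NumPy array with an attached gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        parents: tuple["Tensor", ...] = (),
        backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # ------------------------------------------------------------------ misc
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (scalar unless ``grad`` given)."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar tensor")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            # iterative DFS to avoid recursion limits on deep graphs
            stack2: list[tuple[Tensor, bool]] = [(t, False)]
            while stack2:
                node, processed = stack2.pop()
                if processed:
                    topo.append(node)
                    continue
                if id(node) in seen:
                    continue
                seen.add(id(node))
                stack2.append((node, True))
                for p in node._parents:
                    if id(p) not in seen:
                        stack2.append((p, False))

        visit(self)
        self._accum(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # ------------------------------------------------------------ arithmetic
    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out = Tensor(self.data / other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / other.data**2, other.shape)
                )

        out._backward = bw
        return out

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, p: float):
        out = Tensor(self.data**p, parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1))

        out._backward = bw
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        out._backward = bw
        return out

    # ---------------------------------------------------------- elementwise
    def exp(self):
        val = np.exp(self.data)
        out = Tensor(val, parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * val)
        return out

    def log(self):
        out = Tensor(np.log(self.data), parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g / self.data)
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), parents=(self,))
        mask = self.data > 0

        def bw(g):
            if self.requires_grad:
                self._accum(g * mask)

        out._backward = bw
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * s * (1.0 - s))

        out._backward = bw
        return out

    def silu(self):
        """x * sigmoid(x), the SiLU / swish activation."""
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(self.data * s, parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * (s + self.data * s * (1.0 - s)))

        out._backward = bw
        return out

    # ------------------------------------------------------------ reductions
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).copy())
                return
            if not keepdims:
                axes = axis if isinstance(axis, tuple) else (axis,)
                axes = tuple(a % self.ndim for a in axes)
                shape = [1 if i in axes else s for i, s in enumerate(self.shape)]
                g = g.reshape(shape)
            self._accum(np.broadcast_to(g, self.shape).copy())

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[a % self.ndim] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis=None, keepdims: bool = False):
        val = self.data.max(axis=axis, keepdims=True)
        out_val = val if keepdims or axis is None else np.squeeze(
            val, axis=axis if isinstance(axis, tuple) else (axis,)
        )
        if axis is None and not keepdims:
            out_val = self.data.max()
        out = Tensor(out_val, parents=(self,))
        mask = self.data == val
        # ties share the gradient equally, keeping the op well defined
        counts = mask.sum(axis=axis, keepdims=True) if axis is not None else mask.sum()

        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(mask / counts * g)
                return
            if not keepdims:
                axes = axis if isinstance(axis, tuple) else (axis,)
                axes = tuple(a % self.ndim for a in axes)
                shape = [1 if i in axes else s for i, s in enumerate(self.shape)]
                g = np.reshape(g, shape)
            self._accum(mask / counts * g)

        out._backward = bw
        return out

    # --------------------------------------------------------- shape surgery
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g.reshape(self.shape))

        out._backward = bw
        return out

    def transpose(self, axes: Sequence[int]):
        axes = tuple(axes)
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        out._backward = bw
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], parents=(self,))

        def bw(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)

        out._backward = bw
        return out

    def pad_last(self, before: int, after: int):
        """Zero-pad the last axis (used by the 1-D channel convolutions)."""
        pad = [(0, 0)] * (self.ndim - 1) + [(before, after)]
        out = Tensor(np.pad(self.data, pad), parents=(self,))
        n = self.shape[-1]

        def bw(g):
            if self.requires_grad:
                self._accum(g[..., before : before + n])

        out._backward = bw
        return out


def concat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = list(tensors)
    out = Tensor(
        np.concatenate([t.data for t in tensors], axis=axis), parents=tuple(tensors)
    )
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])

    out._backward = bw
    return out


def _im2col(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """(N, H+kh-1, W+kw-1, C) padded input -> (N, H, W, kh*kw*C) patches."""
    n, hp, wp, c = x.shape
    h, w = hp - kh + 1, wp - kw + 1
    s0, s1, s2, s3 = x.strides
    cols = np.lib.stride_tricks.as_strided(
        x, shape=(n, h, w, kh, kw, c), strides=(s0, s1, s2, s1, s2, s3)
    )
    return cols.reshape(n, h, w, kh * kw * c)


def conv2d_same(x: Tensor, weight: Tensor, bias: Tensor | None = None) -> Tensor:
    """Same-padded stride-1 2-D convolution, channels-last.

    ``x`` is (N, H, W, Cin), ``weight`` is (kh, kw, Cin, Cout), ``bias`` is
    (Cout,) or None.  Odd kernel sizes only.
    """
    kh, kw, cin, cout = weight.shape
    if kh % 2 == 0 or kw % 2 == 0:
        raise ValueError("conv2d_same requires odd kernel sizes")
    ph, pw = kh // 2, kw // 2
    n, h, w, _ = x.shape
    xp = np.pad(x.data, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
    cols = _im2col(xp, kh, kw)  # (N, H, W, kh*kw*Cin)
    wmat = weight.data.reshape(kh * kw * cin, cout)
    val = cols @ wmat
    if bias is not None:
        val = val + bias.data
    parents = (x, weight) + ((bias,) if bias is not None else ())
    out = Tensor(val, parents=parents)

    def bw(g):
        # g: (N, H, W, Cout)
        if weight.requires_grad:
            gw = cols.reshape(-1, kh * kw * cin).T @ g.reshape(-1, cout)
            weight._accum(gw.reshape(weight.shape))
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=(0, 1, 2)))
        if x.requires_grad:
            gcols = (g @ wmat.T).reshape(n, h, w, kh, kw, cin)
            gx = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    gx[:, i : i + h, j : j + w, :] += gcols[:, :, :, i, j, :]
            x._accum(gx[:, ph : ph + h, pw : pw + w, :])

    out._backward = bw
    return out
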