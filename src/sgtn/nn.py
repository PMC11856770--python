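"""Minimal reverse-mode automatic differentiation on NumPy arrays.

This is the numerical core the classifier is built on: a :class:`Tensor`
that records the operations applied to it and can back-propagate gradients
through them.  Only the operations the network needs are implemented —
broadcast arithmetic, matrix products, size-preserving 2-D convolution and
average pooling (channels-last layout), the usual activations, reductions,
reshapes and concatenation.  Gradients of every primitive are verified
against central finite differences in the test suite.

Arrays are kept in whatever float dtype they arrive in; training code uses
float32, gradient checks use float64.
"""

from __future__ import annotations

import math
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.special import erf

__all__ = ["Tensor", "concat", "conv2d_same", "avgpool3x3_same"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, n in enumerate(shape) if n == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """An n-d array plus the closure that routes its gradient to its parents."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], None] | None = None

    # -- construction helpers -------------------------------------------------

    @classmethod
    def _from_op(cls, data, parents: Sequence["Tensor"],
                 backward: Callable[[np.ndarray], None]) -> "Tensor":
        out = cls(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- autograd driver ------------------------------------------------------

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Back-propagate from this tensor (default seed: ones)."""
        if grad is None:
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
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            if grad.dtype != self.data.dtype:
                grad = grad.astype(self.data.dtype)
            self.grad = grad
        else:
            self.grad = self.grad + grad

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic -----------------------------------------------------------

    @staticmethod
    def _coerce(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x))

    def __add__(self, other) -> "Tensor":
        other = self._coerce(other)
        a, b = self, other

        def bwd(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.shape))

        return Tensor._from_op(a.data + b.data, (a, b), bwd)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        a = self
        return Tensor._from_op(-a.data, (a,),
                               lambda g: a._accum(-g) if a.requires_grad else None)

    def __sub__(self, other) -> "Tensor":
        return self + (-self._coerce(other))

    def __rsub__(self, other) -> "Tensor":
        return self._coerce(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = self._coerce(other)
        a, b = self, other

        def bwd(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.shape))

        return Tensor._from_op(a.data * b.data, (a, b), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        return self * self._coerce(other) ** -1.0

    def __rtruediv__(self, other) -> "Tensor":
        return self._coerce(other) * self ** -1.0

    def __pow__(self, p: float) -> "Tensor":
        a = self
        out = a.data ** p

        def bwd(g):
            a._accum(g * p * a.data ** (p - 1.0))

        return Tensor._from_op(out, (a,), bwd)

    def __matmul__(self, other) -> "Tensor":
        other = self._coerce(other)
        a, b = self, other

        def bwd(g):
            if a.requires_grad:
                ga = g @ np.swapaxes(b.data, -1, -2)
                a._accum(_unbroadcast(ga, a.shape))
            if b.requires_grad:
                gb = np.swapaxes(a.data, -1, -2) @ g
                b._accum(_unbroadcast(gb, b.shape))

        return Tensor._from_op(a.data @ b.data, (a, b), bwd)

    # -- elementwise nonlinearities -------------------------------------------

    def relu(self) -> "Tensor":
        a = self
        mask = a.data > 0
        return Tensor._from_op(np.where(mask, a.data, 0.0), (a,),
                               lambda g: a._accum(g * mask))

    def sigmoid(self) -> "Tensor":
        a = self
        s = 1.0 / (1.0 + np.exp(-a.data))
        return Tensor._from_op(s, (a,), lambda g: a._accum(g * s * (1.0 - s)))

    def gelu(self) -> "Tensor":
        """Exact (erf-based) Gaussian error linear unit."""
        a = self
        x = a.data
        cdf = 0.5 * (1.0 + erf(x / math.sqrt(2.0)))
        pdf = np.exp(-0.5 * x * x) / math.sqrt(2.0 * math.pi)

        def bwd(g):
            a._accum(g * (cdf + x * pdf))

        return Tensor._from_op(x * cdf, (a,), bwd)

    def exp(self) -> "Tensor":
        a = self
        e = np.exp(a.data)
        return Tensor._from_op(e, (a,), lambda g: a._accum(g * e))

    def log(self) -> "Tensor":
        a = self
        return Tensor._from_op(np.log(a.data), (a,),
                               lambda g: a._accum(g / a.data))

    # -- reductions and shape ops ----------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        a = self
        out = a.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                axes = axis if isinstance(axis, tuple) else (axis,)
                g = np.expand_dims(g, tuple(ax % a.data.ndim for ax in axes))
            a._accum(np.broadcast_to(g, a.shape).copy())

        return Tensor._from_op(out, (a,), bwd)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else (
            np.prod([self.shape[ax] for ax in
                     (axis if isinstance(axis, tuple) else (axis,))]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape) -> "Tensor":
        a = self
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return Tensor._from_op(a.data.reshape(shape), (a,),
                               lambda g: a._accum(g.reshape(a.shape)))

    def transpose(self, *axes) -> "Tensor":
        a = self
        if not axes:
            axes = tuple(reversed(range(a.ndim)))
        inv = np.argsort(axes)
        return Tensor._from_op(a.data.transpose(axes), (a,),
                               lambda g: a._accum(g.transpose(inv)))

    def __getitem__(self, idx) -> "Tensor":
        a = self

        def bwd(g):
            full = np.zeros_like(a.data)
            full[idx] = g
            a._accum(full)

        return Tensor._from_op(a.data[idx], (a,), bwd)

    # -- composite ops ----------------------------------------------------------

    def softmax(self, axis: int = -1) -> "Tensor":
        """Row-wise softmax; the max-shift is a constant so gradients flow
        only through the exponentials (softmax is shift-invariant)."""
        shift = self - Tensor(self.data.max(axis=axis, keepdims=True))
        e = shift.exp()
        return e / e.sum(axis=axis, keepdims=True)

    def logsumexp(self, axis: int = -1) -> "Tensor":
        m = Tensor(self.data.max(axis=axis, keepdims=True))
        return (self - m).exp().sum(axis=axis, keepdims=True).log() + m


def concat(tensors: Iterable[Tensor], axis: int = -1) -> Tensor:
    ts = [Tensor._coerce(t) for t in tensors]
    out = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.data.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor._from_op(out, ts, bwd)


# -- spatial primitives (channels-last: N, H, W, C) ------------------------------


def _im2col(xp: np.ndarray, kh: int, kw: int, H: int, W: int) -> np.ndarray:
    """Stack the kh*kw shifted views of a zero-padded input.

    Returns (N, H, W, kh*kw, C)."""
    n, _, _, c = xp.shape
    cols = np.empty((n, H, W, kh * kw, c), dtype=xp.dtype)
    k = 0
    for i in range(kh):
        for j in range(kw):
            cols[:, :, :, k, :] = xp[:, i:i + H, j:j + W, :]
            k += 1
    return cols


def conv2d_same(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Size-preserving 2-D convolution (zero padding, stride 1).

    ``x``: (N, H, W, Cin); ``w``: (kh, kw, Cin, Cout); ``b``: (Cout,).
    """
    n, H, W, cin = x.shape
    kh, kw, wcin, cout = w.shape
    if wcin != cin:
        raise ValueError(f"channel mismatch: input has {cin}, kernel expects {wcin}")
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x.data, ((0, 0), (ph, kh - 1 - ph), (pw, kw - 1 - pw), (0, 0)))
    cols = _im2col(xp, kh, kw, H, W)                       # N,H,W,kk,Cin
    flat = cols.reshape(n * H * W, kh * kw * cin)
    wf = w.data.reshape(kh * kw * cin, cout)
    out = (flat @ wf).reshape(n, H, W, cout)
    if b is not None:
        out = out + b.data

    parents = [x, w] + ([b] if b is not None else [])

    def bwd(g):
        gf = g.reshape(n * H * W, cout)
        if w.requires_grad:
            w._accum((flat.T @ gf).reshape(w.shape))
        if b is not None and b.requires_grad:
            b._accum(gf.sum(axis=0))
        if x.requires_grad:
            gcols = (gf @ wf.T).reshape(n, H, W, kh * kw, cin)
            gxp = np.zeros_like(xp)
            k = 0
            for i in range(kh):
                for j in range(kw):
                    gxp[:, i:i + H, j:j + W, :] += gcols[:, :, :, k, :]
                    k += 1
            x._accum(gxp[:, ph:ph + H, pw:pw + W, :])

    return Tensor._from_op(out, parents, bwd)


def avgpool3x3_same(x: Tensor) -> Tensor:
    """3x3 average pooling, stride 1, size preserving.

    Border means are taken over the cells actually inside the image
    (divisor = number of valid cells), so a constant field stays constant
    all the way to the corners.
    """
    n, H, W, c = x.shape
    ones = np.ones((H, W), dtype=x.data.dtype)
    onep = np.pad(ones, 1)
    count = np.zeros((H, W), dtype=x.data.dtype)
    for i in range(3):
        for j in range(3):
            count += onep[i:i + H, j:j + W]
    count = count[None, :, :, None]

    xp = np.pad(x.data, ((0, 0), (1, 1), (1, 1), (0, 0)))
    acc = np.zeros_like(x.data)
    for i in range(3):
        for j in range(3):
            acc += xp[:, i:i + H, j:j + W, :]
    out = acc / count

    def bwd(g):
        gn = g / count
        gp = np.pad(gn, ((0, 0), (1, 1), (1, 1), (0, 0)))
        gx = np.zeros_like(x.data)
        for i in range(3):
            for j in range(3):
                gx += gp[:, i:i + H, j:j + W, :]
        x._accum(gx)

    return Tensor._from_op(out, (x,), bwd)
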