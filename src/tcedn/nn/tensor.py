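"""Reverse-mode automatic differentiation over numpy arrays.

The network is trained end-to-end with gradient descent, so every operation
used in the forward pass carries a backward rule.  The engine is a small
dynamic tape: each operation returns a new :class:`Tensor` holding a closure
that routes the upstream gradient to its parents; ``Tensor.backward`` runs the
closures in reverse topological order.

Only the operations the severity-regression network needs are implemented:
broadcast arithmetic, matmul, 3-D convolution (im2col), the pointwise
nonlinearities, reductions, shape surgery (pad / narrow / concat / reshape /
transpose) and a max-absolute-value normalization used by the frame-attention
weighting.  Arrays keep their dtype; float32 is used for training, float64 for
finite-difference gradient checks.
"""

from __future__ import annotations

import itertools
from contextlib import contextmanager

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Tensor", "no_grad", "concat", "conv3d", "maxabs_normalize"]

_GRAD_ENABLED = [True]


@contextmanager
def no_grad():
    """Disable graph construction (evaluation / inference mode)."""
    _GRAD_ENABLED.append(False)
    try:
        yield
    finally:
        _GRAD_ENABLED.pop()


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum over leading broadcast axes
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over axes that were 1 in the original shape
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data)
        if self.data.dtype.kind not in "f":
            self.data = self.data.astype(np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._backward = None
        self._parents = ()

    # ---------------------------------------------------------------- infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    def _accumulate(self, g: np.ndarray):
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if _GRAD_ENABLED[-1] and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad=None):
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that does not require grad")
        if grad is None:
            if self.data.size != 1:
                raise RuntimeError("grad must be supplied for non-scalar output")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    # ------------------------------------------------------------ arithmetic
    def __add__(self, other):
        if np.isscalar(other):  # dtype-preserving scalar path
            c = other

            def backward_s(g):
                if self.requires_grad:
                    self._accumulate(g)

            return Tensor._make(self.data + c, (self,), backward_s)
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        return Tensor._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __mul__(self, other):
        if np.isscalar(other):
            c = other

            def backward_s(g):
                if self.requires_grad:
                    self._accumulate(g * c)

            return Tensor._make(self.data * c, (self,), backward_s)
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        return Tensor._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __truediv__(self, other):
        if np.isscalar(other):
            return self * (1.0 / other)
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data**2, other.shape)
                )

        return Tensor._make(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other):
        return Tensor(other) / self

    def __pow__(self, p):
        if not np.isscalar(p):
            raise TypeError("only scalar exponents are supported")

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * p * self.data ** (p - 1))

        return Tensor._make(self.data**p, (self,), backward)

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ g)

        return Tensor._make(self.data @ other.data, (self, other), backward)

    # --------------------------------------------------------- nonlinearities
    def relu(self):
        mask = self.data > 0

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        return Tensor._make(self.data * mask, (self,), backward)

    def sigmoid(self):
        with np.errstate(over="ignore"):  # exp overflow saturates correctly
            out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * (1.0 - out_data**2))

        return Tensor._make(out_data, (self,), backward)

    def abs(self):
        sign = np.sign(self.data)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * sign)

        return Tensor._make(np.abs(self.data), (self,), backward)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * 0.5 / out_data)

        return Tensor._make(out_data, (self,), backward)

    # -------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(gg, self.shape).copy())

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            ax = (axis,) if np.isscalar(axis) else axis
            n = int(np.prod([self.shape[a] for a in ax]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ----------------------------------------------------------- shape surgery
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.reshape(old))

        return Tensor._make(self.data.reshape(shape), (self,), backward)

    def transpose(self, axes):
        inv = np.argsort(axes)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.transpose(inv))

        return Tensor._make(self.data.transpose(axes), (self,), backward)

    def narrow(self, axis: int, start: int, length: int):
        """Slice ``length`` entries from ``start`` along ``axis``."""
        idx = [slice(None)] * self.ndim
        idx[axis] = slice(start, start + length)
        idx = tuple(idx)

        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                full[idx] = g
                self._accumulate(full)

        return Tensor._make(self.data[idx], (self,), backward)

    def pad_axis(self, axis: int, before: int, after: int):
        """Zero-pad along a single axis."""
        widths = [(0, 0)] * self.ndim
        widths[axis] = (before, after)
        idx = [slice(None)] * self.ndim
        idx[axis] = slice(before, before + self.shape[axis])
        idx = tuple(idx)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g[idx])

        return Tensor._make(np.pad(self.data, widths), (self,), backward)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [t if isinstance(t, Tensor) else Tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * t.ndim
                idx[axis] = slice(lo, hi)
                t._accumulate(g[tuple(idx)])

    return Tensor._make(
        np.concatenate([t.data for t in tensors], axis=axis), tensors, backward
    )


def maxabs_normalize(x: Tensor, axes: tuple) -> Tensor:
    """Divide by the maximum absolute value over ``axes`` (kept dims).

    An all-zero slice maps to all zeros; a constant positive slice maps to all
    ones.  The result always lies in [-1, 1].  The gradient flows both through
    the numerator and through the maximizing element.
    """
    x = x if isinstance(x, Tensor) else Tensor(x)
    a = np.abs(x.data)
    m = a.max(axis=axes, keepdims=True)
    safe = np.where(m == 0, 1.0, m)
    out_data = x.data / safe

    def backward(g):
        if not x.requires_grad:
            return
        grad = g / safe
        # route the gradient of the divisor to the arg-max entries
        gm = (g * x.data * (-1.0 / safe**2)).sum(axis=axes, keepdims=True)
        gm = np.where(m == 0, 0.0, gm)
        mask = (a == m).astype(x.data.dtype)
        count = mask.sum(axis=axes, keepdims=True)
        grad = grad + mask * np.sign(x.data) * gm / np.maximum(count, 1.0)
        x._accumulate(grad)

    return Tensor._make(out_data, (x,), backward)


# ---------------------------------------------------------------- convolution
def _conv3d_geometry(x_shape, w_shape, stride, padding):
    _, _, T, H, W = x_shape
    _, _, kT, kH, kW = w_shape
    sT, sH, sW = stride
    if padding == "same":
        padding = (kT // 2, kH // 2, kW // 2)
    pT, pH, pW = padding
    To = (T + 2 * pT - kT) // sT + 1
    Ho = (H + 2 * pH - kH) // sH + 1
    Wo = (W + 2 * pW - kW) // sW + 1
    return (pT, pH, pW), (To, Ho, Wo)


def conv3d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride=(1, 1, 1), padding="same") -> Tensor:
    """3-D convolution (cross-correlation) over (B, C, T, H, W) input.

    ``w`` has shape (C_out, C_in, kT, kH, kW).  ``padding='same'`` pads each
    spatial/temporal side by k // 2, so stride 1 preserves extent and stride 2
    halves it (ceil).  Implemented as im2col + matmul.
    """
    x = x if isinstance(x, Tensor) else Tensor(x)
    w = w if isinstance(w, Tensor) else Tensor(w)
    B, Cin, T, H, W = x.shape
    Cout, Cin_w, kT, kH, kW = w.shape
    if Cin != Cin_w:
        raise ValueError(f"channel mismatch: input {Cin}, kernel {Cin_w}")
    sT, sH, sW = stride
    (pT, pH, pW), (To, Ho, Wo) = _conv3d_geometry(x.shape, w.shape, stride, padding)
    if To < 1 or Ho < 1 or Wo < 1:
        raise ValueError("input extent smaller than kernel after padding")

    K = Cin * kT * kH * kW
    L = To * Ho * Wo
    pad_widths = ((0, 0), (0, 0), (pT, pT), (pH, pH), (pW, pW))

    def im2col(xp):
        # gather patches offset by offset (contiguous inner copies)
        cols = np.empty((B, Cin, kT, kH, kW, To, Ho, Wo), dtype=xp.dtype)
        for it, ih, iw in itertools.product(range(kT), range(kH), range(kW)):
            cols[:, :, it, ih, iw] = xp[:, :,
                                        it:it + sT * To:sT,
                                        ih:ih + sH * Ho:sH,
                                        iw:iw + sW * Wo:sW]
        return cols.reshape(B, K, L)

    xp = np.pad(x.data, pad_widths)
    wmat = w.data.reshape(Cout, K)
    out = np.matmul(wmat, im2col(xp)).reshape(B, Cout, To, Ho, Wo)
    if b is not None:
        out = out + b.data.reshape(1, Cout, 1, 1, 1)

    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        # cast keeps the GEMMs on the forward dtype's BLAS path; the patch
        # matrix is recomputed here rather than saved (memory >> recompute)
        g2 = np.ascontiguousarray(g, dtype=wmat.dtype).reshape(B, Cout, L)
        xp = np.pad(x.data, pad_widths)
        if w.requires_grad:
            dw = np.matmul(g2, im2col(xp).swapaxes(1, 2)).sum(axis=0)
            w._accumulate(dw.reshape(w.shape))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3, 4)).reshape(b.shape))
        if x.requires_grad:
            dcols = np.matmul(np.ascontiguousarray(wmat.T), g2).reshape(
                B, Cin, kT, kH, kW, To, Ho, Wo)
            dxp = np.zeros_like(xp)
            for it, ih, iw in itertools.product(range(kT), range(kH), range(kW)):
                dxp[:, :,
                    it:it + sT * To:sT,
                    ih:ih + sH * Ho:sH,
                    iw:iw + sW * Wo:sW] += dcols[:, :, it, ih, iw]
            x._accumulate(dxp[:, :, pT:pT + T, pH:pH + H, pW:pW + W])

    return Tensor._make(out, parents, backward)
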