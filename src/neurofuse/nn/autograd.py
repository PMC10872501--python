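"""Minimal reverse-mode automatic differentiation over numpy arrays.

Implements exactly the operator set needed for small volumetric contrastive
models: elementwise arithmetic, matmul, reductions, a masked log-sum-exp (the
InfoNCE denominator), strided 3D convolution and its transpose, and batch
normalization.  Gradients are accumulated by a topological backward sweep.
All gradient formulas are exercised against central finite differences in the
test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor", "no_grad", "concat", "use_dtype", "default_dtype"]

_grad_enabled = True
_default_dtype = np.float64


def default_dtype():
    return _default_dtype


class use_dtype:
    """Context manager setting the default floating dtype for new tensors.

    float64 is the default (and what the numerical tests assume); float32
    roughly halves the cost of the convolution-heavy training loops.
    Existing float32/float64 arrays keep their dtype when wrapped.
    """

    def __init__(self, dtype):
        self.dtype = np.dtype(dtype).type

    def __enter__(self):
        global _default_dtype
        self._prev = _default_dtype
        _default_dtype = self.dtype

    def __exit__(self, *exc):
        global _default_dtype
        _default_dtype = self._prev
        return False


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        global _grad_enabled
        self._prev = _grad_enabled
        _grad_enabled = False

    def __exit__(self, *exc):
        global _grad_enabled
        _grad_enabled = self._prev
        return False


def _sum_to_shape(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reverse numpy broadcasting: reduce ``grad`` back to ``shape``."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")
    __array_priority__ = 100.0

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, np.ndarray) and data.dtype in (np.float32, np.float64):
            self.data = data
        else:
            self.data = np.asarray(data, dtype=_default_dtype)
        self.grad = None
        self.requires_grad = bool(requires_grad) and _grad_enabled
        self._parents: tuple = ()
        self._backward = None

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = None
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    # ------------------------------------------------------------- arithmetic
    def _make(self, data, parents, backward):
        out = Tensor(data)
        if _grad_enabled and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._backward = backward
        return out

    @staticmethod
    def _accum(t: "Tensor", g: np.ndarray):
        if not t.requires_grad:
            return
        g = _sum_to_shape(g, t.data.shape)
        t.grad = g if t.grad is None else t.grad + g

    def __add__(self, other):
        other = as_tensor(other)

        def bw(g):
            Tensor._accum(self, g)
            Tensor._accum(other, g)

        return self._make(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            Tensor._accum(self, -g)

        return self._make(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)

        def bw(g):
            Tensor._accum(self, g * other.data)
            Tensor._accum(other, g * self.data)

        return self._make(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)

        def bw(g):
            Tensor._accum(self, g / other.data)
            Tensor._accum(other, -g * self.data / other.data**2)

        return self._make(self.data / other.data, (self, other), bw)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        def bw(g):
            Tensor._accum(self, g * p * self.data ** (p - 1))

        return self._make(self.data**p, (self,), bw)

    def __matmul__(self, other):
        other = as_tensor(other)
        if self.data.ndim != 2 or other.data.ndim != 2:
            raise ValueError("matmul supports 2-D tensors only")

        def bw(g):
            Tensor._accum(self, g @ other.data.T)
            Tensor._accum(other, self.data.T @ g)

        return self._make(self.data @ other.data, (self, other), bw)

    # ------------------------------------------------------------- shape ops
    def reshape(self, *shape):
        orig = self.data.shape

        def bw(g):
            Tensor._accum(self, g.reshape(orig))

        return self._make(self.data.reshape(*shape), (self,), bw)

    def transpose(self, *axes):
        if not axes:
            axes = tuple(reversed(range(self.data.ndim)))
        inv = np.argsort(axes)

        def bw(g):
            Tensor._accum(self, g.transpose(inv))

        return self._make(self.data.transpose(axes), (self,), bw)

    @property
    def T(self):
        return self.transpose()

    def __getitem__(self, idx):
        def bw(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                Tensor._accum(self, full)

        return self._make(self.data[idx], (self,), bw)

    # ------------------------------------------------------------ reductions
    def sum(self, axis=None, keepdims=False):
        def bw(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            Tensor._accum(self, np.broadcast_to(g, self.data.shape).copy())

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bw)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    # ---------------------------------------------------------- elementwise
    def exp(self):
        out_data = np.exp(self.data)

        def bw(g):
            Tensor._accum(self, g * out_data)

        return self._make(out_data, (self,), bw)

    def log(self):
        def bw(g):
            Tensor._accum(self, g / self.data)

        return self._make(np.log(self.data), (self,), bw)

    def tanh(self):
        out_data = np.tanh(self.data)

        def bw(g):
            Tensor._accum(self, g * (1.0 - out_data**2))

        return self._make(out_data, (self,), bw)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def bw(g):
            Tensor._accum(self, g * out_data * (1.0 - out_data))

        return self._make(out_data, (self,), bw)

    def relu(self):
        mask = self.data > 0

        def bw(g):
            Tensor._accum(self, g * mask)

        return self._make(self.data * mask, (self,), bw)

    def leaky_relu(self, slope: float = 0.2):
        mult = np.where(self.data > 0, 1.0, slope)

        def bw(g):
            Tensor._accum(self, g * mult)

        return self._make(self.data * mult, (self,), bw)

    # ------------------------------------------------------------- logsumexp
    def logsumexp(self, axis: int, mask: np.ndarray | None = None):
        """log Σ e^x over ``axis``; entries where ``mask`` is False are excluded.

        The mask is a constant (no gradient flows through it).
        """
        x = self.data
        if mask is not None:
            x = np.where(mask, x, -np.inf)
        m = np.max(x, axis=axis, keepdims=True)
        m = np.where(np.isfinite(m), m, 0.0)
        e = np.exp(x - m)
        s = e.sum(axis=axis, keepdims=True)
        out_data = (np.log(s) + m).squeeze(axis)
        softmax = e / s

        def bw(g):
            Tensor._accum(self, np.expand_dims(g, axis) * softmax)

        return self._make(out_data, (self,), bw)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors, axis=0):
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis))
    if _grad_enabled and any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)

        def bw(g):
            for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
                Tensor._accum(t, piece)

        out._backward = bw
    return out


# ---------------------------------------------------------------------------
# volumetric convolution primitives
# ---------------------------------------------------------------------------

def _pad5(x, p):
    if p == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))


def _patches(xp, k, stride):
    """(N,C,D,H,W) -> (N,C,Do,Ho,Wo,k,k,k) strided view."""
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))
    return win[:, :, ::stride, ::stride, ::stride]


def conv3d(x: Tensor, w: Tensor, b: Tensor | None, stride: int, padding: int) -> Tensor:
    """x: (N,Cin,D,H,W); w: (Cout,Cin,k,k,k); b: (Cout,) or None."""
    k = w.data.shape[2]
    O, C = w.data.shape[:2]
    xp = _pad5(x.data, padding)
    pat = _patches(xp, k, stride)               # (N,C,Do,Ho,Wo,k,k,k) view
    N, _, Do, Ho, Wo = pat.shape[:5]
    L = Do * Ho * Wo
    # im2col GEMM: one contiguous copy in (sample, location, channel-patch)
    # order, reused by the weight-gradient contraction
    Pm = np.ascontiguousarray(pat.transpose(0, 2, 3, 4, 1, 5, 6, 7)
                              ).reshape(N * L, C * k**3)
    Wm = w.data.reshape(O, C * k**3)
    out_data = (Pm @ Wm.T).reshape(N, Do, Ho, Wo, O).transpose(0, 4, 1, 2, 3)
    if b is not None:
        out_data = out_data + b.data[None, :, None, None, None]
    else:
        out_data = np.ascontiguousarray(out_data)
    parents = (x, w) if b is None else (x, w, b)

    def bw(g):
        G2 = np.ascontiguousarray(g.transpose(0, 2, 3, 4, 1)).reshape(N * L, O)
        if w.requires_grad:
            Tensor._accum(w, (G2.T @ Pm).reshape(O, C, k, k, k))
        if b is not None and b.requires_grad:
            Tensor._accum(b, g.sum(axis=(0, 2, 3, 4)))
        if x.requires_grad:
            gP = (G2 @ Wm).reshape(N, Do, Ho, Wo, C, k, k, k)
            gx = np.zeros_like(xp)
            for i in range(k):
                for j in range(k):
                    for l in range(k):
                        gx[:, :,
                           i:i + stride * Do:stride,
                           j:j + stride * Ho:stride,
                           l:l + stride * Wo:stride] += gP[..., i, j, l].transpose(0, 4, 1, 2, 3)
            if padding:
                gx = gx[:, :, padding:-padding, padding:-padding, padding:-padding]
            Tensor._accum(x, gx)

    out = Tensor(out_data)
    if _grad_enabled and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = parents
        out._backward = bw
    return out


def _conv3d_input_grad(g, w, xp_shape, stride):
    """Scatter grad of conv output back onto the (padded) input."""
    N, C = xp_shape[0], xp_shape[1]
    k = w.shape[2]
    gx = np.zeros((N, C) + xp_shape[2:], dtype=g.dtype)
    Do, Ho, Wo = g.shape[2:]
    # (N,O,Do,Ho,Wo) x (O,C,k,k,k) -> (N,C,Do,Ho,Wo,k,k,k), contracted once
    P = np.einsum("nodhw,ocijl->ncdhwijl", g, w, optimize=True)
    for i in range(k):
        for j in range(k):
            for l in range(k):
                gx[:, :,
                   i:i + stride * Do:stride,
                   j:j + stride * Ho:stride,
                   l:l + stride * Wo:stride] += P[..., i, j, l]
    return gx


def conv_transpose3d(x: Tensor, w: Tensor, b: Tensor | None, stride: int,
                     padding: int) -> Tensor:
    """Transposed 3D convolution. x: (N,Cin,D,H,W); w: (Cin,Cout,k,k,k).

    Output extent = (D-1)*stride - 2*padding + k.
    """
    k = w.data.shape[2]
    N, Cin, D, H, W = x.data.shape
    Cout = w.data.shape[1]
    full = ((D - 1) * stride + k, (H - 1) * stride + k, (W - 1) * stride + k)
    out_full = np.zeros((N, Cout) + full, dtype=x.data.dtype)
    P = np.einsum("ncdhw,coijl->nodhwijl", x.data, w.data, optimize=True)
    for i in range(k):
        for j in range(k):
            for l in range(k):
                out_full[:, :,
                         i:i + stride * D:stride,
                         j:j + stride * H:stride,
                         l:l + stride * W:stride] += P[..., i, j, l]
    p = padding
    out_data = out_full[:, :, p:full[0] - p, p:full[1] - p, p:full[2] - p]
    if b is not None:
        out_data = out_data + b.data[None, :, None, None, None]
    parents = (x, w) if b is None else (x, w, b)

    def bw(g):
        gp = _pad5(g, p)
        pat = _patches(gp, k, stride)  # (N,Cout,D,H,W,k,k,k)
        if x.requires_grad:
            gx = np.einsum("nodhwijl,coijl->ncdhw", pat, w.data, optimize=True)
            Tensor._accum(x, gx)
        if w.requires_grad:
            gw = np.einsum("nodhwijl,ncdhw->coijl", pat, x.data, optimize=True)
            Tensor._accum(w, gw)
        if b is not None and b.requires_grad:
            Tensor._accum(b, g.sum(axis=(0, 2, 3, 4)))

    out = Tensor(out_data)
    if _grad_enabled and any(p_.requires_grad for p_ in parents):
        out.requires_grad = True
        out._parents = parents
        out._backward = bw
    return out


def batchnorm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Training-mode batch normalization over all axes except channel (axis 1)."""
    axes = (0,) + tuple(range(2, x.data.ndim))
    mu = x.data.mean(axis=axes, keepdims=True)
    var = x.data.var(axis=axes, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    shape = [1] * x.data.ndim
    shape[1] = -1
    gsh = gamma.data.reshape(shape)
    out_data = xhat * gsh + beta.data.reshape(shape)
    m = float(np.prod([x.data.shape[a] for a in axes]))

    def bw(g):
        if gamma.requires_grad:
            Tensor._accum(gamma, (g * xhat).sum(axis=axes))
        if beta.requires_grad:
            Tensor._accum(beta, g.sum(axis=axes))
        if x.requires_grad:
            gxhat = g * gsh
            gx = (inv / m) * (
                m * gxhat
                - gxhat.sum(axis=axes, keepdims=True)
                - xhat * (gxhat * xhat).sum(axis=axes, keepdims=True)
            )
            Tensor._accum(x, gx)

    out = Tensor(out_data)
    if _grad_enabled and any(p.requires_grad for p in (x, gamma, beta)):
        out.requires_grad = True
        out._parents = (x, gamma, beta)
        out._backward = bw
    return out
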