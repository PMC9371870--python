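"""Minimal reverse-mode automatic differentiation on numpy arrays.

This module provides the small set of differentiable operations the OCTA
pipeline needs: 2-D convolution (via im2col + BLAS matmul), max pooling,
batch normalisation, bilinear upsampling, concatenation, dense layers and
the two fused cross-entropy losses. Gradients are accumulated on every
tensor in the graph (not only leaves), which is what Grad-CAM needs to read
``d score / d feature-map`` at an intermediate layer.

All operations preserve the dtype of their inputs, so gradient checking can
run in float64 while training runs in float32.
"""

from __future__ import annotations

import contextlib
from typing import Callable, List, Sequence, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_GRAD_ENABLED = True


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


@contextlib.contextmanager
def no_grad():
    """Disable graph construction (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


class Tensor:
    """An n-d array plus the closures needed to backpropagate through it."""

    __slots__ = ("data", "grad", "requires_grad", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = requires_grad
        # list of (parent Tensor, fn mapping upstream grad -> parent grad)
        self._parents: List[Tuple["Tensor", Callable]] = []

    @property
    def shape(self):
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def zero_grad(self):
        self.grad = None

    def backward(self, grad=None):
        """Backpropagate from this tensor (scalar unless ``grad`` given)."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar tensor")
            grad = np.ones_like(self.data)
        topo: List[Tensor] = []
        seen = set()

        def visit(t: Tensor):
            stack = [(t, iter(t._parents))]
            seen.add(id(t))
            while stack:
                node, it = stack[-1]
                advanced = False
                for parent, _ in it:
                    if id(parent) not in seen:
                        seen.add(id(parent))
                        stack.append((parent, iter(parent._parents)))
                        advanced = True
                        break
                if not advanced:
                    topo.append(node)
                    stack.pop()

        visit(self)
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node.grad is None:
                continue
            for parent, fn in node._parents:
                g = fn(node.grad)
                if g is None:
                    continue
                if parent.grad is None:
                    parent.grad = g
                else:
                    parent.grad = parent.grad + g


def _make(data, parents) -> Tensor:
    out = Tensor(data)
    if _GRAD_ENABLED and any(p.requires_grad or p._parents for p, _ in parents):
        out.requires_grad = True
        out._parents = list(parents)
    return out


# ---------------------------------------------------------------------------
# elementwise / structural ops
# ---------------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    if a.data.shape != b.data.shape:
        raise ValueError(f"add requires equal shapes, got {a.shape} vs {b.shape}")
    return _make(a.data + b.data, [(a, lambda g: g), (b, lambda g: g)])


def scale(a: Tensor, s: float) -> Tensor:
    return _make(a.data * s, [(a, lambda g: g * s)])


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0
    return _make(np.where(mask, a.data, 0), [(a, lambda g: g * mask)])


def sigmoid(a: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-a.data))
    return _make(s, [(a, lambda g: g * s * (1.0 - s))])


def reshape(a: Tensor, shape) -> Tensor:
    old = a.data.shape
    return _make(a.data.reshape(shape), [(a, lambda g: g.reshape(old))])


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)
    data = np.concatenate([t.data for t in tensors], axis=axis)

    def make_fn(i):
        sl = [slice(None)] * data.ndim
        sl[axis] = slice(int(offsets[i]), int(offsets[i + 1]))
        sl = tuple(sl)
        return lambda g: g[sl]

    return _make(data, [(t, make_fn(i)) for i, t in enumerate(tensors)])


def select(a: Tensor, index) -> Tensor:
    """Indexing that backpropagates (scatter of the upstream gradient)."""
    def back(g):
        out = np.zeros_like(a.data)
        out[index] = g
        return out

    return _make(np.asarray(a.data[index]), [(a, back)])


def mean_spatial(a: Tensor) -> Tensor:
    """Global average pooling: (B, C, H, W) -> (B, C)."""
    B, C, H, W = a.data.shape
    out = a.data.mean(axis=(2, 3))

    def back(g):
        return np.broadcast_to(g[:, :, None, None] / (H * W), (B, C, H, W)).astype(g.dtype)

    return _make(out, [(a, back)])


def mean_all(a: Tensor) -> Tensor:
    n = a.data.size
    return _make(np.asarray(a.data.mean()), [(a, lambda g: np.broadcast_to(g / n, a.data.shape).astype(g.dtype))])


# ---------------------------------------------------------------------------
# dense
# ---------------------------------------------------------------------------

def linear(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """x: (B, F), w: (out, F), b: (out,)."""
    out = x.data @ w.data.T + b.data
    return _make(out, [
        (x, lambda g: g @ w.data),
        (w, lambda g: g.T @ x.data),
        (b, lambda g: g.sum(axis=0)),
    ])


# ---------------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------------

def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1, padding: int = 0) -> Tensor:
    """x: (B, C, H, W); w: (Cout, C, kh, kw); b: (Cout,) or None."""
    B, C, H, W = x.data.shape
    Cout, Cin, kh, kw = w.data.shape
    if Cin != C:
        raise ValueError(f"conv2d channel mismatch: input has {C}, kernel expects {Cin}")
    s = stride
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding))) if padding else x.data
    Hp, Wp = xp.shape[2], xp.shape[3]
    Ho = (Hp - kh) // s + 1
    Wo = (Wp - kw) // s + 1
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::s, ::s]  # B,C,Ho,Wo,kh,kw
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(B * Ho * Wo, C * kh * kw)
    wmat = w.data.reshape(Cout, C * kh * kw)
    out = cols @ wmat.T
    if b is not None:
        out += b.data
    out = out.reshape(B, Ho, Wo, Cout).transpose(0, 3, 1, 2)

    def back_x(g):
        gc = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(B * Ho * Wo, Cout)
        dcols = (gc @ wmat).reshape(B, Ho, Wo, C, kh, kw).transpose(0, 3, 1, 2, 4, 5)
        dxp = np.zeros((B, C, Hp, Wp), dtype=g.dtype)
        for i in range(kh):
            for j in range(kw):
                dxp[:, :, i:i + s * Ho:s, j:j + s * Wo:s] += dcols[:, :, :, :, i, j]
        if padding:
            return dxp[:, :, padding:Hp - padding, padding:Wp - padding]
        return dxp

    def back_w(g):
        gc = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(B * Ho * Wo, Cout)
        return (gc.T @ cols).reshape(Cout, C, kh, kw)

    parents = [(x, back_x), (w, back_w)]
    if b is not None:
        parents.append((b, lambda g: g.sum(axis=(0, 2, 3))))
    return _make(out, parents)


def max_pool2d(x: Tensor, kernel: int, stride: int, padding: int = 0) -> Tensor:
    B, C, H, W = x.data.shape
    s, k = stride, kernel
    if padding:
        fill = np.finfo(x.data.dtype).min if np.issubdtype(x.data.dtype, np.floating) else np.iinfo(x.data.dtype).min
        xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)),
                    constant_values=fill)
    else:
        xp = x.data
    Hp, Wp = xp.shape[2], xp.shape[3]
    Ho = (Hp - k) // s + 1
    Wo = (Wp - k) // s + 1
    win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
    winf = np.ascontiguousarray(win).reshape(B, C, Ho, Wo, k * k)
    idx = winf.argmax(axis=-1)
    out = np.take_along_axis(winf, idx[..., None], axis=-1)[..., 0]

    def back(g):
        di, dj = idx // k, idx % k
        oi, oj = np.meshgrid(np.arange(Ho), np.arange(Wo), indexing="ij")
        rows = oi[None, None] * s + di
        cols_ = oj[None, None] * s + dj
        flat = rows * Wp + cols_
        dxp = np.zeros((B, C, Hp * Wp), dtype=g.dtype)
        bi = np.arange(B)[:, None, None, None]
        ci = np.arange(C)[None, :, None, None]
        np.add.at(dxp, (bi, ci, flat), g)
        dxp = dxp.reshape(B, C, Hp, Wp)
        if padding:
            return dxp[:, :, padding:Hp - padding, padding:Wp - padding]
        return dxp

    return _make(out, [(x, back)])


# ---------------------------------------------------------------------------
# bilinear upsampling
# ---------------------------------------------------------------------------

def _interp_matrix(n_out: int, n_in: int, dtype) -> np.ndarray:
    """Dense 1-D bilinear interpolation matrix (half-pixel centres)."""
    A = np.zeros((n_out, n_in), dtype=dtype)
    if n_in == 1:
        A[:, 0] = 1.0
        return A
    coord = (np.arange(n_out) + 0.5) * n_in / n_out - 0.5
    coord = np.clip(coord, 0, n_in - 1)
    i0 = np.floor(coord).astype(int)
    i1 = np.minimum(i0 + 1, n_in - 1)
    frac = coord - i0
    A[np.arange(n_out), i0] += 1.0 - frac
    A[np.arange(n_out), i1] += frac
    return A


def upsample_bilinear(x: Tensor, out_h: int, out_w: int) -> Tensor:
    B, C, H, W = x.data.shape
    Ah = _interp_matrix(out_h, H, x.data.dtype)
    Aw = _interp_matrix(out_w, W, x.data.dtype)
    out = np.einsum("oh,bchw,pw->bcop", Ah, x.data, Aw, optimize=True)

    def back(g):
        return np.einsum("oh,bcop,pw->bchw", Ah, g, Aw, optimize=True)

    return _make(out, [(x, back)])


def upsample_bilinear_array(a: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    """Non-differentiable bilinear resize of a 2-D array (same kernel as above)."""
    Ah = _interp_matrix(out_h, a.shape[0], np.float64)
    Aw = _interp_matrix(out_w, a.shape[1], np.float64)
    return Ah @ a.astype(np.float64) @ Aw.T


# ---------------------------------------------------------------------------
# batch normalisation
# ---------------------------------------------------------------------------

def batch_norm2d_train(x: Tensor, gamma: Tensor, beta: Tensor, eps: float):
    """Returns (out, batch_mean, batch_var) using batch statistics."""
    B, C, H, W = x.data.shape
    m = B * H * W
    axes = (0, 2, 3)
    mu = x.data.mean(axis=axes)
    var = x.data.var(axis=axes)
    std = np.sqrt(var + eps)
    xhat = (x.data - mu[None, :, None, None]) / std[None, :, None, None]
    out = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

    def back_x(g):
        dxhat = g * gamma.data[None, :, None, None]
        t1 = dxhat.sum(axis=axes) / m
        t2 = (dxhat * xhat).sum(axis=axes) / m
        return (dxhat - t1[None, :, None, None] - xhat * t2[None, :, None, None]) / std[None, :, None, None]

    parents = [
        (x, back_x),
        (gamma, lambda g: (g * xhat).sum(axis=axes)),
        (beta, lambda g: g.sum(axis=axes)),
    ]
    return _make(out, parents), mu, var


def batch_norm2d_eval(x: Tensor, gamma: Tensor, beta: Tensor,
                      running_mean: np.ndarray, running_var: np.ndarray, eps: float) -> Tensor:
    std = np.sqrt(running_var + eps)
    xhat = (x.data - running_mean[None, :, None, None]) / std[None, :, None, None]
    out = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]
    parents = [
        (x, lambda g: g * (gamma.data / std)[None, :, None, None]),
        (gamma, lambda g: (g * xhat).sum(axis=(0, 2, 3))),
        (beta, lambda g: g.sum(axis=(0, 2, 3))),
    ]
    return _make(out, parents)


# ---------------------------------------------------------------------------
# fused losses
# ---------------------------------------------------------------------------

def _softmax(z: np.ndarray, axis: int) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax(logits: Tensor, axis: int = 1) -> Tensor:
    f = _softmax(logits.data, axis)

    def back(g):
        return f * (g - (f * g).sum(axis=axis, keepdims=True))

    return _make(f, [(logits, back)])


def cross_entropy_logits(logits: Tensor, onehot: np.ndarray, eps: float = 1e-7) -> Tensor:
    """Multiclass cross-entropy -sum_c t_c log f_c averaged over the batch.

    ``f`` is the softmax of the logits, clamped to [eps, 1-eps] before log.
    """
    B = logits.data.shape[0]
    f = _softmax(logits.data, axis=1)
    fc = np.clip(f, eps, 1.0 - eps)
    loss = -(onehot * np.log(fc)).sum() / B

    def back(g):
        free = (f > eps) & (f < 1.0 - eps)
        df = np.where(free, -onehot / fc, 0.0) * (g / B)
        return f * (df - (f * df).sum(axis=1, keepdims=True))

    return _make(np.asarray(loss), [(logits, back)])


def channel_bce_logits(logits: Tensor, onehot: np.ndarray, eps: float = 1e-7) -> Tensor:
    """Per-pixel binary cross-entropy against one-hot truth, summed over the
    class channels and averaged over pixels (and the batch).

    logits, onehot: (B, C, H, W). ``f`` is the per-pixel softmax over C.
    """
    B, C, H, W = logits.data.shape
    n = B * H * W
    f = _softmax(logits.data, axis=1)
    fc = np.clip(f, eps, 1.0 - eps)
    loss = -(onehot * np.log(fc) + (1.0 - onehot) * np.log(1.0 - fc)).sum() / n

    def back(g):
        free = (f > eps) & (f < 1.0 - eps)
        df = np.where(free, -onehot / fc + (1.0 - onehot) / (1.0 - fc), 0.0) * (g / n)
        return f * (df - (f * df).sum(axis=1, keepdims=True))

    return _make(np.asarray(loss), [(logits, back)])
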