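"""Minimal reverse-mode automatic differentiation on numpy arrays.

This module provides just enough autodiff to train the gain-modulated
convolutional networks in :mod:`gainlisten.gainnet`: elementwise arithmetic
with numpy broadcasting, matrix multiplication, reductions, the logistic
function, 2-D convolution with valid-time / zero-padded-same-frequency
boundary handling, Hanning-weighted average pooling, dropout, and a fused
softmax cross-entropy loss.  Graphs are only recorded when a tensor in the
expression requires gradients, so inference-mode forward passes carry no
bookkeeping overhead.

Conventions: activations are 4-D ``(batch, channels, freq, time)`` arrays;
all data is float32 unless the caller supplies float64.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import expit

__all__ = ["Tensor", "as_tensor"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum away prepended axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # sum over axes that were broadcast from size 1
    axes = tuple(i for i, (g, s) in enumerate(zip(grad.shape, shape)) if s == 1 and g != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """An ndarray plus an optional gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        arr = np.asarray(data)
        if not np.issubdtype(arr.dtype, np.floating):
            arr = arr.astype(np.float64)
        self.data = arr
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = _parents
        self._backward = _backward

    # -- infrastructure ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accumulate(self, grad: np.ndarray) -> None:
        grad = _unbroadcast(np.asarray(grad), self.data.shape)
        if self.grad is None:
            self.grad = grad.astype(self.data.dtype, copy=True)
        else:
            self.grad += grad

    def backward(self, grad=None) -> None:
        """Backpropagate from this tensor (defaults to d(self)/d(self)=1)."""
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
        self._accumulate(np.ones_like(self.data) if grad is None else grad)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def _co(self, other) -> "Tensor":
        """Coerce an operand; python scalars adopt this tensor's dtype."""
        if isinstance(other, Tensor):
            return other
        if np.isscalar(other):
            return Tensor(np.asarray(other, dtype=self.data.dtype))
        return Tensor(other)

    # -- elementwise arithmetic -------------------------------------------
    def __add__(self, other):
        other = self._co(other)
        out_req = self.requires_grad or other.requires_grad
        out = Tensor(self.data + other.data, out_req, (self, other))
        if out_req:
            def bw(g):
                if self.requires_grad:
                    self._accumulate(g)
                if other.requires_grad:
                    other._accumulate(g)
            out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, self.requires_grad, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-self._co(other))

    def __rsub__(self, other):
        return (-self) + other

    def __mul__(self, other):
        other = self._co(other)
        out_req = self.requires_grad or other.requires_grad
        out = Tensor(self.data * other.data, out_req, (self, other))
        if out_req:
            def bw(g):
                if self.requires_grad:
                    self._accumulate(g * other.data)
                if other.requires_grad:
                    other._accumulate(g * self.data)
            out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._co(other)
        out_req = self.requires_grad or other.requires_grad
        out = Tensor(self.data / other.data, out_req, (self, other))
        if out_req:
            def bw(g):
                if self.requires_grad:
                    self._accumulate(g / other.data)
                if other.requires_grad:
                    other._accumulate(-g * self.data / other.data**2)
            out._backward = bw
        return out

    def __pow__(self, exponent: float):
        out = Tensor(self.data**exponent, self.requires_grad, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(
                g * exponent * self.data ** (exponent - 1)
            )
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out_req = self.requires_grad or other.requires_grad
        out = Tensor(self.data @ other.data, out_req, (self, other))
        if out_req:
            def bw(g):
                if self.requires_grad:
                    self._accumulate(g @ other.data.T)
                if other.requires_grad:
                    other._accumulate(self.data.T @ g)
            out._backward = bw
        return out

    # -- shaping and reductions -------------------------------------------
    def reshape(self, *shape):
        orig = self.data.shape
        out = Tensor(self.data.reshape(*shape), self.requires_grad, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g.reshape(orig))
        return out

    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), self.requires_grad, (self,))
        if out.requires_grad:
            shape = self.data.shape

            def bw(g):
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(g, shape))
            out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- nonlinearities ----------------------------------------------------
    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), self.requires_grad, (self,))
        if out.requires_grad:
            mask = self.data > 0
            out._backward = lambda g: self._accumulate(g * mask)
        return out

    def sigmoid(self):
        y = expit(self.data)
        out = Tensor(y, self.requires_grad, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g * y * (1.0 - y))
        return out

    def sqrt(self):
        y = np.sqrt(self.data)
        out = Tensor(y, self.requires_grad, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g * 0.5 / y)
        return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ---------------------------------------------------------------------------
# Structured ops: convolution, pooling, dropout, softmax cross-entropy.
# ---------------------------------------------------------------------------

def _pad_freq(x: np.ndarray, n_f: int) -> tuple[np.ndarray, int]:
    """Zero-pad the frequency axis of (B,C,F,T) for 'same' output size."""
    lo = (n_f - 1) // 2
    hi = n_f - 1 - lo
    if lo == 0 and hi == 0:
        return x, 0
    return np.pad(x, ((0, 0), (0, 0), (lo, hi), (0, 0))), lo


def conv2d(x: Tensor, w: Tensor) -> Tensor:
    """2-D convolution (cross-correlation) over (freq, time).

    Input ``x`` is (B, C_in, F, T) and ``w`` is (C_out, C_in, n_f, n_t).
    Frequency uses zero-padded 'same' boundaries, time uses 'valid', the
    stride is 1 and no bias is added, so the output is
    (B, C_out, F, T - n_t + 1).
    """
    xd, wd = x.data, w.data
    c_out, c_in, n_f, n_t = wd.shape
    if xd.shape[1] != c_in:
        raise ValueError(f"input has {xd.shape[1]} channels, kernel expects {c_in}")
    if xd.shape[3] < n_t:
        raise ValueError(f"time axis ({xd.shape[3]}) shorter than kernel ({n_t})")
    xp, lo = _pad_freq(xd, n_f)
    out_data, cols = _corr_valid(xp, wd)
    out_req = x.requires_grad or w.requires_grad
    out = Tensor(out_data, out_req, (x, w))
    if out_req:
        def bw(g):
            if w.requires_grad:
                g2 = np.ascontiguousarray(np.moveaxis(g, 1, 3)).reshape(-1, c_out)
                w._accumulate((g2.T @ cols).reshape(wd.shape))
            if x.requires_grad:
                # transposed convolution: valid correlation of the padded
                # output gradient with the spatially flipped kernel
                hi = n_f - 1 - lo
                gp = np.pad(g, ((0, 0), (0, 0), (hi, lo), (n_t - 1, n_t - 1)))
                wflip = np.ascontiguousarray(
                    wd[:, :, ::-1, ::-1].transpose(1, 0, 2, 3))
                dx, _ = _corr_valid(gp, wflip)
                x._accumulate(dx)
        out._backward = bw
    return out


def _corr_valid(xd: np.ndarray, wd: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Valid-mode correlation via im2col matmul; returns (output, columns)."""
    c_out, c_in, n_f, n_t = wd.shape
    n_b, _, f_in, t_in = xd.shape
    f_out, t_out = f_in - n_f + 1, t_in - n_t + 1
    win = sliding_window_view(xd, (n_f, n_t), axis=(2, 3))
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        n_b * f_out * t_out, c_in * n_f * n_t)
    out = (cols @ wd.reshape(c_out, -1).T).reshape(n_b, f_out, t_out, c_out)
    return np.ascontiguousarray(np.moveaxis(out, 3, 1)), cols


def hann_kernel(stride: int) -> np.ndarray:
    """1-D Hanning pooling kernel: extent 1 for stride 1, else 4*stride."""
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if stride == 1:
        return np.ones(1)
    n = 4 * stride
    # periodic-style window with nonzero interior taps
    return np.hanning(n + 2)[1:-1]


def _pool1d_fwd(xd: np.ndarray, kern: np.ndarray, stride: int, axis: int):
    """Zero-padded 'same' correlation along `axis` then stride-subsampling."""
    extent = len(kern)
    dim = xd.shape[axis]
    n_out = dim // stride
    lo = (extent - 1) // 2
    hi = extent - 1 - lo
    pad = [(0, 0)] * xd.ndim
    pad[axis] = (lo, hi)
    xp = np.pad(xd, pad)
    acc = None
    for a, ka in enumerate(kern):
        sl = [slice(None)] * xd.ndim
        sl[axis] = slice(a, a + stride * (n_out - 1) + 1, stride)
        term = ka * xp[tuple(sl)]
        acc = term if acc is None else acc + term
    return acc, (xp.shape, lo, n_out)


def _pool1d_bwd(g: np.ndarray, kern: np.ndarray, stride: int, axis: int,
                meta, orig_dim: int) -> np.ndarray:
    xp_shape, lo, n_out = meta
    dxp = np.zeros(xp_shape, dtype=g.dtype)
    for a, ka in enumerate(kern):
        sl = [slice(None)] * len(xp_shape)
        sl[axis] = slice(a, a + stride * (n_out - 1) + 1, stride)
        dxp[tuple(sl)] += ka * g
    sl = [slice(None)] * len(xp_shape)
    sl[axis] = slice(lo, lo + orig_dim)
    return dxp[tuple(sl)]


def hann_pool2d(x: Tensor, s_f: int, s_t: int) -> Tensor:
    """Hanning-weighted average pooling with strides (s_f, s_t).

    The 2-D kernel is the outer product of unit-sum 1-D Hanning windows
    whose extent is 1 where the stride is 1 and 4*stride otherwise; the
    pooling is computed separably.  The input is zero-padded ('same'),
    convolved, then subsampled, giving (B, C, F//s_f, T//s_t).
    """
    kf = hann_kernel(s_f)
    kt = hann_kernel(s_t)
    kf = kf / kf.sum()
    kt = kt / kt.sum()
    xd = x.data
    _, _, f, t = xd.shape
    mid, meta_f = _pool1d_fwd(xd, kf, s_f, axis=2)
    acc, meta_t = _pool1d_fwd(mid, kt, s_t, axis=3)
    out = Tensor(acc, x.requires_grad, (x,))
    if out.requires_grad:
        mid_dim = mid.shape[3]

        def bw(g):
            dmid = _pool1d_bwd(g, kt, s_t, 3, meta_t, mid_dim)
            x._accumulate(_pool1d_bwd(dmid, kf, s_f, 2, meta_f, f))
        out._backward = bw
    return out


def dropout(x: Tensor, p: float, rng: np.random.Generator) -> Tensor:
    """Inverted dropout: zero a fraction p of units, rescale the rest."""
    if p <= 0.0:
        return x
    keep = (rng.random(x.data.shape) >= p).astype(x.data.dtype) / (1.0 - p)
    return x * Tensor(keep)


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> tuple[Tensor, np.ndarray]:
    """Mean cross-entropy over a batch; returns (loss, probabilities)."""
    probs = softmax(logits.data, axis=1)
    n = logits.data.shape[0]
    eps = np.finfo(probs.dtype).tiny
    loss_val = -np.mean(np.log(probs[np.arange(n), labels] + eps))
    out = Tensor(np.asarray(loss_val, dtype=logits.data.dtype), logits.requires_grad, (logits,))
    if out.requires_grad:
        def bw(g):
            d = probs.copy()
            d[np.arange(n), labels] -= 1.0
            logits._accumulate(d * (g / n))
        out._backward = bw
    return out, probs
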