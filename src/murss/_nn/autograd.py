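"""Minimal reverse-mode automatic differentiation over numpy arrays.

Only the operations the segmentation network needs are provided: elementwise
arithmetic with broadcasting, matmul, reductions, reshapes, 2-D convolution
(im2col), bilinear upsampling, softmax, sigmoid, ReLU and a fused pixel-wise
cross-entropy. Gradients are accumulated into ``Tensor.grad`` by
:meth:`Tensor.backward`, which walks the recorded graph in reverse
topological order.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "concat",
    "conv2d",
    "upsample_bilinear2d",
    "cross_entropy_map",
    "softmax",
]


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "name")

    def __init__(self, data, requires_grad=False, _parents=(), name=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents = _parents
        self.name = name

    # -- basic protocol -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def zero_grad(self):
        self.grad = None

    def item(self):
        return float(self.data)

    # -- graph construction ---------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        req = any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=req, _parents=parents if req else ())
        if req:
            out._backward = backward
        return out

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar tensor")
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
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    # -- arithmetic ------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        return Tensor._make(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            if self.requires_grad:
                self._accumulate(-g)

        return Tensor._make(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        return Tensor._make(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data**2, other.shape)
                )

        return Tensor._make(self.data / other.data, (self, other), bw)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p):
        assert np.isscalar(p)

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * p * self.data ** (p - 1))

        return Tensor._make(self.data**p, (self,), bw)

    def __matmul__(self, other):
        other = as_tensor(other)

        def bw(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accumulate(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accumulate(_unbroadcast(gb, other.shape))

        return Tensor._make(self.data @ other.data, (self, other), bw)

    def __getitem__(self, idx):
        def bw(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accumulate(full)

        return Tensor._make(self.data[idx], (self,), bw)

    # -- elementwise nonlinearities --------------------------------------
    def relu(self):
        mask = self.data > 0

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        return Tensor._make(self.data * mask, (self,), bw)

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * s * (1.0 - s))

        return Tensor._make(s, (self,), bw)

    def exp(self):
        e = np.exp(self.data)

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * e)

        return Tensor._make(e, (self,), bw)

    def log(self):
        def bw(g):
            if self.requires_grad:
                self._accumulate(g / self.data)

        return Tensor._make(np.log(self.data), (self,), bw)

    def sqrt(self):
        r = np.sqrt(self.data)

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * 0.5 / r)

        return Tensor._make(r, (self,), bw)

    # -- reductions & shape ----------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(gg, self.shape).copy())

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bw)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])

        def bw(g):
            if self.requires_grad:
                self._accumulate(g.reshape(self.shape))

        return Tensor._make(self.data.reshape(shape), (self,), bw)

    def transpose(self, axes):
        inv = np.argsort(axes)

        def bw(g):
            if self.requires_grad:
                self._accumulate(g.transpose(inv))

        return Tensor._make(self.data.transpose(axes), (self,), bw)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(grad, shape):
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and grad.shape[i] != 1:
            grad = grad.sum(axis=i, keepdims=True)
    return grad


def concat(tensors, axis):
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        parts = np.split(g, splits, axis=axis)
        for t, p in zip(tensors, parts):
            if t.requires_grad:
                t._accumulate(p)

    return Tensor._make(
        np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), bw
    )


def softmax(x: Tensor, axis: int) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)

    def bw(g):
        if x.requires_grad:
            dot = (g * s).sum(axis=axis, keepdims=True)
            x._accumulate(s * (g - dot))

    return Tensor._make(s, (x,), bw)


# ---------------------------------------------------------------------------
# 2-D convolution via im2col
# ---------------------------------------------------------------------------

def _im2col(x, kh, kw, stride, pad):
    b, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    oh = (h + 2 * pad - kh) // stride + 1
    ow = (w + 2 * pad - kw) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]  # (b, c, oh, ow, kh, kw)
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(b, oh * ow, c * kh * kw)
    return cols, oh, ow


def _col2im(cols, x_shape, kh, kw, stride, pad, oh, ow):
    b, c, h, w = x_shape
    dxp = np.zeros((b, c, h + 2 * pad, w + 2 * pad))
    cols = cols.reshape(b, oh, ow, c, kh, kw).transpose(0, 3, 1, 2, 4, 5)
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i : i + oh * stride : stride, j : j + ow * stride : stride] += (
                cols[:, :, :, :, i, j]
            )
    if pad:
        return dxp[:, :, pad:-pad, pad:-pad]
    return dxp


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None, stride=1, pad=0) -> Tensor:
    """Cross-correlation of ``x`` (B,C,H,W) with ``weight`` (F,C,kh,kw)."""
    f, c, kh, kw = weight.shape
    cols, oh, ow = _im2col(x.data, kh, kw, stride, pad)  # (b, ohw, ckk)
    wmat = weight.data.reshape(f, c * kh * kw)
    out = cols @ wmat.T  # (b, ohw, f)
    if bias is not None:
        out = out + bias.data
    b = x.shape[0]
    out = out.transpose(0, 2, 1).reshape(b, f, oh, ow)
    parents = (x, weight) if bias is None else (x, weight, bias)

    def bw(g):
        gmat = g.reshape(b, f, oh * ow).transpose(0, 2, 1)  # (b, ohw, f)
        if bias is not None and bias.requires_grad:
            bias._accumulate(gmat.sum(axis=(0, 1)))
        if weight.requires_grad:
            dw = np.einsum("bif,bik->fk", gmat, cols)
            weight._accumulate(dw.reshape(weight.shape))
        if x.requires_grad:
            dcols = gmat @ wmat  # (b, ohw, ckk)
            x._accumulate(_col2im(dcols, x.shape, kh, kw, stride, pad, oh, ow))

    return Tensor._make(out, parents, bw)


# ---------------------------------------------------------------------------
# Bilinear upsampling as a separable linear operator
# ---------------------------------------------------------------------------

def _interp_matrix(n_in, n_out):
    """(n_out, n_in) bilinear interpolation weights, half-pixel centers."""
    a = np.zeros((n_out, n_in))
    scale = n_in / n_out
    for i in range(n_out):
        src = (i + 0.5) * scale - 0.5
        lo = int(np.floor(src))
        t = src - lo
        lo_c = min(max(lo, 0), n_in - 1)
        hi_c = min(max(lo + 1, 0), n_in - 1)
        a[i, lo_c] += 1.0 - t
        a[i, hi_c] += t
    return a


def upsample_bilinear2d(x: Tensor, factor: int) -> Tensor:
    b, c, h, w = x.shape
    ah = _interp_matrix(h, h * factor)
    aw = _interp_matrix(w, w * factor)
    out = np.einsum("Ih,bchw,Jw->bcIJ", ah, x.data, aw)

    def bw(g):
        if x.requires_grad:
            x._accumulate(np.einsum("Ih,bcIJ,Jw->bchw", ah, g, aw))

    return Tensor._make(out, (x,), bw)


# ---------------------------------------------------------------------------
# Pixel-wise cross-entropy
# ---------------------------------------------------------------------------

def cross_entropy_map(
    logits: Tensor,
    labels: np.ndarray,
    ignore_label: int = 255,
    class_weights: np.ndarray | None = None,
) -> Tensor:
    """Per-pixel cross-entropy (natural log) from raw class scores.

    ``logits`` is (B, K, H, W); ``labels`` is (B, H, W) with values in
    {0..K-1} or ``ignore_label``. Pixels carrying the ignore label get loss 0
    and receive no gradient. Returns a (B, H, W) tensor.
    """
    labels = np.asarray(labels)
    k = logits.shape[1]
    valid = labels != ignore_label
    if not np.all(np.isin(labels[valid], np.arange(k))):
        raise ValueError(f"labels must be in 0..{k - 1} or {ignore_label}")
    safe = np.where(valid, labels, 0)
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    picked = np.take_along_axis(logp, safe[:, None], axis=1)[:, 0]
    wpix = np.ones_like(picked)
    if class_weights is not None:
        wpix = np.asarray(class_weights, dtype=np.float64)[safe]
    loss = np.where(valid, -picked * wpix, 0.0)
    p = np.exp(logp)

    def bw(g):
        if logits.requires_grad:
            onehot = np.zeros_like(p)
            np.put_along_axis(onehot, safe[:, None], 1.0, axis=1)
            gg = (g * wpix * valid)[:, None]
            logits._accumulate(gg * (p - onehot))

    return Tensor._make(loss, (logits,), bw)
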