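"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The engine is deliberately small: a :class:`Tensor` wraps a float32
``ndarray`` and records the closure that propagates gradients to its
parents.  ``Tensor.backward()`` runs a topological sort of the recorded
graph and accumulates gradients.  Only the operations required by the
segmentation network live here; each op defines its analytic gradient,
and all of them are checked against central finite differences in the
test suite.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "add",
    "scale",
    "concat_channels",
    "relu",
    "selu",
    "sigmoid",
    "conv2d",
    "conv_transpose2d_2x2",
    "maxpool2d",
    "upsample_nearest",
    "soft_dice_loss",
]

# SELU constants (Klambauer et al. self-normalizing networks)
_SELU_LAMBDA = 1.0507009873554805
_SELU_ALPHA = 1.6732632423543772


class Tensor:
    """A float32 array node in a dynamically built computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        data = np.asarray(data, dtype=np.float32)
        self.data = np.ascontiguousarray(data) if data.ndim else data
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], None] | None = None

    @property
    def shape(self):
        return self.data.shape

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the graph."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; deep networks overflow recursion
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def _make(data: np.ndarray, parents: Sequence[Tensor],
          backward: Callable[[np.ndarray], None] | None) -> Tensor:
    out = Tensor(data)
    needs = any(p.requires_grad or p._parents for p in parents)
    if needs:
        out._parents = tuple(parents)
        out._backward = backward
        out.requires_grad = True
    return out


# ---------------------------------------------------------------------------
# elementwise / structural ops
# ---------------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    """Elementwise sum; shapes must match exactly (no broadcasting)."""
    if a.data.shape != b.data.shape:
        raise ValueError(f"add shape mismatch: {a.data.shape} vs {b.data.shape}")

    def backward(g):
        a._accumulate(g)
        b._accumulate(g)

    return _make(a.data + b.data, (a, b), backward)


def scale(a: Tensor, c: float) -> Tensor:
    c = float(c)

    def backward(g):
        a._accumulate(g * c)

    return _make(a.data * c, (a,), backward)


def concat_channels(tensors: Sequence[Tensor]) -> Tensor:
    """Concatenate NCHW tensors along the channel axis."""
    sizes = [t.data.shape[1] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            t._accumulate(g[:, lo:hi])

    return _make(np.concatenate([t.data for t in tensors], axis=1),
                 tuple(tensors), backward)


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0

    def backward(g):
        a._accumulate(g * mask)

    return _make(a.data * mask, (a,), backward)


def selu(a: Tensor) -> Tensor:
    pos = a.data > 0
    expm = _SELU_ALPHA * np.expm1(np.minimum(a.data, 0.0))
    out = _SELU_LAMBDA * np.where(pos, a.data, expm)
    # d/dx = lambda for x>0, lambda*alpha*exp(x) = lambda*(expm + alpha) else
    deriv = _SELU_LAMBDA * np.where(pos, 1.0, expm + _SELU_ALPHA).astype(np.float32)

    def backward(g):
        a._accumulate(g * deriv)

    return _make(out, (a,), backward)


def sigmoid(a: Tensor) -> Tensor:
    # numerically stable in both tails
    x = a.data
    out = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))),
                   np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x)))).astype(np.float32)

    def backward(g):
        a._accumulate(g * out * (1.0 - out))

    return _make(out, (a,), backward)


# ---------------------------------------------------------------------------
# convolutions
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    """(N,C,H,W) -> (N,Ho,Wo,C*k*k) patch matrix."""
    n, c, _, _ = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(x, (k, k), axis=(2, 3))[:, :, ::stride, ::stride]
    _, _, ho, wo, _, _ = win.shape
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, ho, wo, c * k * k)
    return np.ascontiguousarray(cols), ho, wo


def _corr2d_raw(x: np.ndarray, w: np.ndarray, stride: int, pad: int) -> np.ndarray:
    """Plain cross-correlation used inside forward and backward passes."""
    f, c, k, _ = w.shape
    cols, ho, wo, = _im2col(x, k, stride, pad)
    y = cols.reshape(-1, c * k * k) @ w.reshape(f, -1).T
    return y.reshape(x.shape[0], ho, wo, f).transpose(0, 3, 1, 2)


def conv2d(x: Tensor, w: Tensor, b: Tensor, stride: int = 1,
           pad: int | None = None) -> Tensor:
    """2-D cross-correlation, NCHW input, OIHW weights, per-channel bias.

    Default padding is "same" for stride 1 (``pad = k // 2``); for larger
    strides the same pad halves even spatial dims exactly.
    """
    f, cin, k, _ = w.data.shape
    n, c, h, wid = x.data.shape
    if c != cin:
        raise ValueError(f"conv2d channel mismatch: input {c}, weight {cin}")
    if pad is None:
        pad = k // 2
    cols, ho, wo = _im2col(x.data, k, stride, pad)
    y = cols.reshape(-1, cin * k * k) @ w.data.reshape(f, -1).T
    y = y.reshape(n, ho, wo, f).transpose(0, 3, 1, 2) + b.data[None, :, None, None]

    def backward(g):
        gm = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(-1, f)
        if w.requires_grad:
            gw = gm.T @ cols.reshape(-1, cin * k * k)
            w._accumulate(gw.reshape(w.data.shape))
        if b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad or x._parents:
            # zero-stuff the output gradient back onto the stride-1 grid
            # (including the stride remainder at the high edge), then
            # full-correlate with the spatially flipped kernel
            hs = h + 2 * pad - k + 1
            ws = wid + 2 * pad - k + 1
            gs = np.zeros((n, f, hs, ws), dtype=np.float32)
            gs[:, :, ::stride, ::stride][:, :, :ho, :wo] = g
            wt = w.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
            gx = _corr2d_raw(gs, wt, 1, k - 1 - pad)
            x._accumulate(gx)

    return _make(y, (x, w, b), backward)


def conv_transpose2d_2x2(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Transposed convolution, kernel 2, stride 2 (non-overlapping).

    Doubles both spatial dims.  Weights are IOHW: (C_in, C_out, 2, 2).
    """
    n, c, h, wid = x.data.shape
    cin, cout, _, _ = w.data.shape
    if c != cin:
        raise ValueError(f"conv_transpose channel mismatch: input {c}, weight {cin}")
    y = np.einsum("ncij,cfuv->nfiujv", x.data, w.data, optimize=True)
    y = y.reshape(n, cout, 2 * h, 2 * wid) + b.data[None, :, None, None]

    def backward(g):
        gr = g.reshape(n, cout, h, 2, wid, 2)
        if w.requires_grad:
            gw = np.einsum("ncij,nfiujv->cfuv", x.data, gr, optimize=True)
            w._accumulate(gw)
        if b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad or x._parents:
            gx = np.einsum("nfiujv,cfuv->ncij", gr, w.data, optimize=True)
            x._accumulate(gx)

    return _make(y, (x, w, b), backward)


def maxpool2d(x: Tensor) -> Tensor:
    """2x2 max pooling, stride 2; spatial dims must be even."""
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError(f"maxpool2d requires even spatial dims, got {h}x{w}")
    win = x.data.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    win = win.reshape(n, c, h // 2, w // 2, 4)
    idx = win.argmax(axis=-1)
    out = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        gwin = np.zeros((n, c, h // 2, w // 2, 4), dtype=np.float32)
        np.put_along_axis(gwin, idx[..., None], g[..., None], axis=-1)
        gx = gwin.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        x._accumulate(gx.reshape(n, c, h, w))

    return _make(out, (x,), backward)


def upsample_nearest(x: Tensor, factor: int) -> Tensor:
    """Nearest-neighbour upsampling by an integer factor along H and W."""
    f = int(factor)
    if f < 1:
        raise ValueError("upsample factor must be >= 1")
    if f == 1:
        return x
    out = np.repeat(np.repeat(x.data, f, axis=2), f, axis=3)

    def backward(g):
        n, c, h, w = x.data.shape
        gx = g.reshape(n, c, h, f, w, f).sum(axis=(3, 5))
        x._accumulate(gx)

    return _make(out, (x,), backward)


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def soft_dice_loss(pred: Tensor, truth: np.ndarray, smooth: float = 1e-6) -> Tensor:
    """Per-sample soft Dice loss averaged over the batch.

    ``pred`` is an (N, 1, H, W) probability map, ``truth`` a binary array of
    the same shape.  Loss per sample is ``1 - (2*sum(p*t)+s)/(sum(p)+sum(t)+s)``.
    """
    t = np.asarray(truth, dtype=np.float32)
    if pred.data.shape != t.shape:
        raise ValueError(
            f"dice loss shape mismatch: {pred.data.shape} vs {t.shape}")
    n = pred.data.shape[0]
    p = pred.data.reshape(n, -1)
    tf = t.reshape(n, -1)
    num = 2.0 * (p * tf).sum(axis=1) + smooth
    den = p.sum(axis=1) + tf.sum(axis=1) + smooth
    loss = float(np.mean(1.0 - num / den))

    def backward(g):
        # d loss_i / d p = (num/den^2 - 2*t/den) / n ; g is a size-1 array
        gp = (num / den ** 2)[:, None] - 2.0 * tf / den[:, None]
        pred._accumulate((float(np.sum(g)) / n) * gp.reshape(pred.data.shape))

    return _make(np.float32(loss), (pred,), backward)
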