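"""A small reverse-mode automatic differentiation engine on numpy arrays.

Only the operations needed by the segmentation U-Net and the slice classifier
are implemented: broadcast arithmetic, matmul, ReLU, same-padding 2D
convolution (im2col), stride-2 kernel-2 transposed convolution, max pooling,
batch normalization, channel concatenation, log-softmax and the dice /
cross-entropy losses.  Every op is gradient-checked against central finite
differences in the test suite.

Tensors hold float64 data; ``backward()`` runs a topological sweep over the
recorded tape.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self.grad = None
        self._parents = tuple(parents)
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        topo, seen = [], set()

        def visit(t: Tensor) -> None:
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self._accumulate(np.ones_like(self.data) if grad is None else np.asarray(grad))
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    # convenience arithmetic
    def __add__(self, other):
        return add(self, other)

    def __mul__(self, other):
        return mul(self, other)

    def detach(self) -> np.ndarray:
        return self.data


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum gradient ``g`` back down to ``shape`` after numpy broadcasting."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


# ---------------------------------------------------------------------------
# arithmetic
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out = Tensor(a.data + b.data, parents=(a, b))

    def bw(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.shape))

    out._backward = bw
    return out


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out = Tensor(a.data * b.data, parents=(a, b))

    def bw(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.shape))

    out._backward = bw
    return out


def matmul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out = Tensor(a.data @ b.data, parents=(a, b))

    def bw(g):
        if a.requires_grad:
            a._accumulate(g @ b.data.T)
        if b.requires_grad:
            b._accumulate(a.data.T @ g)

    out._backward = bw
    return out


def relu(x) -> Tensor:
    x = _as_tensor(x)
    out = Tensor(np.maximum(x.data, 0.0), parents=(x,))

    def bw(g):
        if x.requires_grad:
            x._accumulate(g * (x.data > 0))

    out._backward = bw
    return out


def reshape(x, shape) -> Tensor:
    x = _as_tensor(x)
    out = Tensor(x.data.reshape(shape), parents=(x,))

    def bw(g):
        if x.requires_grad:
            x._accumulate(g.reshape(x.shape))

    out._backward = bw
    return out


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), parents=tuple(tensors))
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accumulate(g[tuple(idx)])

    out._backward = bw
    return out


# ---------------------------------------------------------------------------
# convolution / pooling
# ---------------------------------------------------------------------------

def conv2d(x, w, b=None) -> Tensor:
    """Same-padding, stride-1 2D convolution (cross-correlation).

    ``x``: (N, C, H, W); ``w``: (O, C, k, k) with odd k; ``b``: (O,) or None.
    """
    x, w = _as_tensor(x), _as_tensor(w)
    k = w.shape[-1]
    p = k // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)))
    win = sliding_window_view(xp, (k, k), axis=(2, 3))  # N,C,H,W,k,k
    out_data = np.einsum("nchwij,ocij->nohw", win, w.data, optimize=True)
    parents = [x, w]
    if b is not None:
        b = _as_tensor(b)
        out_data = out_data + b.data[None, :, None, None]
        parents.append(b)
    out = Tensor(out_data, parents=tuple(parents))

    def bw(g):
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            w._accumulate(np.einsum("nchwij,nohw->ocij", win, g, optimize=True))
        if x.requires_grad:
            # full correlation of g with the flipped, transposed kernel
            gp = np.pad(g, ((0, 0), (0, 0), (p, p), (p, p)))
            gwin = sliding_window_view(gp, (k, k), axis=(2, 3))
            wf = w.data[:, :, ::-1, ::-1]  # O,C,k,k
            x._accumulate(np.einsum("nohwij,ocij->nchw", gwin, wf, optimize=True))

    out._backward = bw
    return out


def conv_transpose2d(x, w, b=None) -> Tensor:
    """Transposed convolution with kernel 2 and stride 2 (exact upsampling).

    ``x``: (N, C, H, W); ``w``: (C, O, 2, 2); output (N, O, 2H, 2W).
    """
    x, w = _as_tensor(x), _as_tensor(w)
    n, c, h, wd = x.shape
    o = w.shape[1]
    y6 = np.einsum("nchw,codk->nohdwk", x.data, w.data, optimize=True)
    out_data = y6.reshape(n, o, 2 * h, 2 * wd)
    parents = [x, w]
    if b is not None:
        b = _as_tensor(b)
        out_data = out_data + b.data[None, :, None, None]
        parents.append(b)
    out = Tensor(out_data, parents=tuple(parents))

    def bw(g):
        g6 = g.reshape(n, o, h, 2, wd, 2)
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            w._accumulate(np.einsum("nchw,nohdwk->codk", x.data, g6, optimize=True))
        if x.requires_grad:
            x._accumulate(np.einsum("nohdwk,codk->nchw", g6, w.data, optimize=True))

    out._backward = bw
    return out


def maxpool2d(x, kernel: int, stride: int, padding: int = 0) -> Tensor:
    """Max pooling; with padding the pad value is -inf (never selected)."""
    x = _as_tensor(x)
    n, c, h, w = x.shape
    if padding:
        xp = np.pad(
            x.data,
            ((0, 0), (0, 0), (padding, padding), (padding, padding)),
            constant_values=-np.inf,
        )
    else:
        xp = x.data
    hp, wp = xp.shape[2], xp.shape[3]
    ho = (hp - kernel) // stride + 1
    wo = (wp - kernel) // stride + 1
    win = sliding_window_view(xp, (kernel, kernel), axis=(2, 3))[:, :, ::stride, ::stride]
    flat = win.reshape(n, c, ho, wo, kernel * kernel)
    arg = flat.argmax(axis=-1)
    out = Tensor(np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0], parents=(x,))

    def bw(g):
        if not x.requires_grad:
            return
        gx = np.zeros((n, c, hp, wp))
        ii, jj = np.meshgrid(np.arange(ho), np.arange(wo), indexing="ij")
        di, dj = np.divmod(arg, kernel)
        rows = ii[None, None] * stride + di
        cols = jj[None, None] * stride + dj
        nn_, cc_ = np.meshgrid(np.arange(n), np.arange(c), indexing="ij")
        nn_ = nn_[:, :, None, None]
        cc_ = cc_[:, :, None, None]
        np.add.at(gx, (nn_, cc_, rows, cols), g)
        if padding:
            gx = gx[:, :, padding:-padding, padding:-padding]
        x._accumulate(gx)

    out._backward = bw
    return out


# ---------------------------------------------------------------------------
# normalization and heads
# ---------------------------------------------------------------------------

def batch_norm2d(x, gamma, beta, running_mean, running_var, training: bool,
                 momentum: float = 0.1, eps: float = 1e-5) -> Tensor:
    """Batch normalization over (N, H, W) per channel.

    ``running_mean``/``running_var`` are plain arrays updated in place during
    training and used verbatim in eval mode.
    """
    x, gamma, beta = _as_tensor(x), _as_tensor(gamma), _as_tensor(beta)
    axes = (0, 2, 3)
    if training:
        mean = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
        running_mean *= 1.0 - momentum
        running_mean += momentum * mean
        running_var *= 1.0 - momentum
        running_var += momentum * var * (m / max(m - 1, 1))  # unbiased for running stats
    else:
        mean, var = running_mean, running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean[None, :, None, None]) * inv_std[None, :, None, None]
    out = Tensor(gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None],
                 parents=(x, gamma, beta))

    def bw(g):
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=axes))
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=axes))
        if x.requires_grad:
            gs = gamma.data[None, :, None, None] * inv_std[None, :, None, None]
            if training:
                m = g.shape[0] * g.shape[2] * g.shape[3]
                mg = g.mean(axis=axes)[None, :, None, None]
                mgx = (g * xhat).mean(axis=axes)[None, :, None, None]
                x._accumulate(gs * (g - mg - xhat * mgx))
            else:
                x._accumulate(gs * g)

    out._backward = bw
    return out


def log_softmax(x, axis: int = 1) -> Tensor:
    x = _as_tensor(x)
    z = x.data - x.data.max(axis=axis, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
    logp = z - lse
    out = Tensor(logp, parents=(x,))

    def bw(g):
        if x.requires_grad:
            s = np.exp(logp)
            x._accumulate(g - s * g.sum(axis=axis, keepdims=True))

    out._backward = bw
    return out


def softmax(x, axis: int = 1) -> Tensor:
    x = _as_tensor(x)
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(s, parents=(x,))

    def bw(g):
        if x.requires_grad:
            x._accumulate(s * (g - (g * s).sum(axis=axis, keepdims=True)))

    out._backward = bw
    return out


# ---------------------------------------------------------------------------
# losses (graph ops)
# ---------------------------------------------------------------------------

def nll_loss(log_probs, target_onehot, class_axis: int = 1) -> Tensor:
    """Cross-entropy from log-probabilities, averaged over non-class positions."""
    lp = _as_tensor(log_probs)
    t = np.asarray(target_onehot, dtype=np.float64)
    n_items = t.size // t.shape[class_axis]
    out = Tensor(-np.sum(t * lp.data) / n_items, parents=(lp,))

    def bw(g):
        if lp.requires_grad:
            lp._accumulate(-g * t / n_items)

    out._backward = bw
    return out


def dice_loss_op(probs, target_onehot) -> Tensor:
    """Dice loss over the flattened probability and one-hot fields."""
    q = _as_tensor(probs)
    p = np.asarray(target_onehot, dtype=np.float64)
    s = float(np.sum(p * q.data))
    d = float(np.sum(p * p) + np.sum(q.data * q.data))
    out = Tensor(1.0 - 2.0 * s / d, parents=(q,))

    def bw(g):
        if q.requires_grad:
            q._accumulate(g * (-2.0 * p * d + 4.0 * s * q.data) / (d * d))

    out._backward = bw
    return out
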