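"""A minimal reverse-mode autodiff engine on numpy arrays.

Just enough machinery for the part-parsing model: 2-D convolution with
dilation, sigmoid/ReLU, elementwise products with channel broadcasting,
channel concatenation, separable bilinear/nearest resizing, 2x average
pooling, and the reductions the losses need.  Feature tensors are
``(channels, height, width)``.
"""

from __future__ import annotations

import numpy as np


class Tensor:
    """A node in the computation graph."""

    __slots__ = ("data", "grad", "parents", "_backward", "requires_grad")

    def __init__(self, data, parents=(), backward=None, requires_grad=False):
        self.data = np.asarray(data, dtype=float)
        self.grad = None
        self.parents = tuple(parents)
        self._backward = backward
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    @property
    def shape(self):
        return self.data.shape

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t.parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = np.zeros_like(t.data)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)


def parameter(data, rng: np.random.Generator | None = None, scale: float | None = None):
    if scale is not None:
        data = (rng or np.random.default_rng()).normal(0.0, scale, size=data)
    return Tensor(np.asarray(data, dtype=float), requires_grad=True)


def _accum(t: Tensor, g: np.ndarray) -> None:
    if t.requires_grad:
        t.grad += g


def add(a: Tensor, b: Tensor) -> Tensor:
    def bwd(g):
        _accum(a, _unbroadcast(g, a.data.shape))
        _accum(b, _unbroadcast(g, b.data.shape))
    return Tensor(a.data + b.data, (a, b), bwd)


def mul(a: Tensor, b: Tensor) -> Tensor:
    def bwd(g):
        _accum(a, _unbroadcast(g * b.data, a.data.shape))
        _accum(b, _unbroadcast(g * a.data, b.data.shape))
    return Tensor(a.data * b.data, (a, b), bwd)


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum gradient over axes that were broadcast in the forward pass."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    def bwd(g):
        _accum(x, g * mask)
    return Tensor(x.data * mask, (x,), bwd)


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-np.clip(x.data, -60, 60)))
    def bwd(g):
        _accum(x, g * s * (1.0 - s))
    return Tensor(s, (x,), bwd)


def concat_channels(tensors: list[Tensor]) -> Tensor:
    sizes = [t.data.shape[0] for t in tensors]
    def bwd(g):
        off = 0
        for t, n in zip(tensors, sizes):
            _accum(t, g[off:off + n])
            off += n
    return Tensor(np.concatenate([t.data for t in tensors], axis=0), tuple(tensors), bwd)


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           dilation: int = 1) -> Tensor:
    """Same-padding 2-D convolution, (C,H,W) x (Co,Ci,k,k) -> (Co,H,W)."""
    co, ci, kh, kw = weight.data.shape
    if x.data.shape[0] != ci:
        raise ValueError(f"conv2d: expected {ci} input channels, got {x.data.shape[0]}")
    ph = dilation * (kh - 1) // 2
    pw = dilation * (kw - 1) // 2
    xp = np.pad(x.data, ((0, 0), (ph, ph), (pw, pw)))
    _, H, W = x.data.shape
    out = np.zeros((co, H, W))
    for i in range(kh):
        for j in range(kw):
            sl = xp[:, i * dilation:i * dilation + H, j * dilation:j * dilation + W]
            out += np.tensordot(weight.data[:, :, i, j], sl, axes=([1], [0]))
    if bias is not None:
        out += bias.data[:, None, None]

    def bwd(g):
        if x.requires_grad:
            gxp = np.zeros_like(xp)
        for i in range(kh):
            for j in range(kw):
                sl = xp[:, i * dilation:i * dilation + H, j * dilation:j * dilation + W]
                if weight.requires_grad:
                    weight.grad[:, :, i, j] += np.tensordot(g, sl, axes=([1, 2], [1, 2]))
                if x.requires_grad:
                    gxp[:, i * dilation:i * dilation + H, j * dilation:j * dilation + W] += \
                        np.tensordot(weight.data[:, :, i, j].T, g, axes=([1], [0]))
        if bias is not None and bias.requires_grad:
            bias.grad += g.sum(axis=(1, 2))
        if x.requires_grad:
            _accum(x, gxp[:, ph:ph + H, pw:pw + W] if (ph or pw) else gxp)

    parents = (x, weight) if bias is None else (x, weight, bias)
    return Tensor(out, parents, bwd)


def _interp_matrix(n_out: int, n_in: int, mode: str) -> np.ndarray:
    """1-D interpolation matrix (n_out x n_in), align-corners-false style."""
    A = np.zeros((n_out, n_in))
    scale = n_in / n_out
    pos = (np.arange(n_out) + 0.5) * scale - 0.5
    if mode == "nearest":
        idx = np.clip(np.round(pos).astype(int), 0, n_in - 1)
        A[np.arange(n_out), idx] = 1.0
    elif mode == "bilinear":
        p = np.clip(pos, 0, n_in - 1)
        lo = np.floor(p).astype(int)
        hi = np.minimum(lo + 1, n_in - 1)
        frac = p - lo
        A[np.arange(n_out), lo] += 1.0 - frac
        A[np.arange(n_out), hi] += frac
    else:
        raise ValueError(f"unknown resize mode {mode!r}")
    return A


def resize(x: Tensor, out_shape: tuple[int, int], mode: str = "bilinear") -> Tensor:
    """Spatial resize of a (C,H,W) tensor by separable interpolation."""
    _, H, W = x.data.shape
    Ah = _interp_matrix(out_shape[0], H, mode)
    Aw = _interp_matrix(out_shape[1], W, mode)
    out = np.einsum("oh,chw,pw->cop", Ah, x.data, Aw, optimize=True)
    def bwd(g):
        _accum(x, np.einsum("oh,cop,pw->chw", Ah, g, Aw, optimize=True))
    return Tensor(out, (x,), bwd)


def avg_pool2(x: Tensor) -> Tensor:
    """2x2 average pooling with stride 2 (odd trailing row/col dropped)."""
    c, H, W = x.data.shape
    H2, W2 = H // 2, W // 2
    v = x.data[:, :H2 * 2, :W2 * 2].reshape(c, H2, 2, W2, 2)
    out = v.mean(axis=(2, 4))
    def bwd(g):
        gx = np.zeros_like(x.data)
        gx[:, :H2 * 2, :W2 * 2] = np.repeat(np.repeat(g, 2, axis=1), 2, axis=2) / 4.0
        _accum(x, gx)
    return Tensor(out, (x,), bwd)


def bce_with_probs(probs: Tensor, targets: np.ndarray, eps: float = 1e-7,
                   pos_weight=None) -> Tensor:
    """Mean binary cross-entropy of probabilities against {0,1} targets.

    ``pos_weight`` (broadcastable to the data shape) scales the positive
    term, the usual counterweight to heavy class imbalance.
    """
    p = np.clip(probs.data, eps, 1.0 - eps)
    t = np.asarray(targets, dtype=float)
    a = 1.0 if pos_weight is None else np.asarray(pos_weight, dtype=float)
    loss = -np.mean(a * t * np.log(p) + (1.0 - t) * np.log(1.0 - p))
    def bwd(g):
        inside = (p > eps) & (p < 1.0 - eps)  # clip zeroes the gradient outside
        grad = -a * t / p + (1.0 - t) / (1.0 - p)
        _accum(probs, g * np.where(inside, grad, 0.0) / p.size)
    return Tensor(loss, (probs,), bwd)


def scalar_sum(terms: list[Tensor], weights: list[float] | None = None) -> Tensor:
    weights = weights or [1.0] * len(terms)
    val = sum(w * t.data for w, t in zip(weights, terms))
    def bwd(g):
        for w, t in zip(weights, terms):
            _accum(t, g * w)
    return Tensor(val, tuple(terms), bwd)
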