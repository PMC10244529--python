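"""Differentiable NN primitives: convolution, pooling, batch norm, padding,
activations, dropout.

Convolution is the cross-correlation convention used by every deep-learning
framework (no kernel flip).  Forward passes are im2col + one BLAS matmul;
backward passes are the matching col2im scatter.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, default_rng

__all__ = [
    "conv2d",
    "linear",
    "batch_norm2d",
    "max_pool2d",
    "avg_pool2d",
    "global_avg_pool",
    "pad2d",
    "crop2d",
    "relu",
    "leaky_relu",
    "sigmoid",
    "softmax",
    "dropout",
]


def _pair(v):
    return tuple(v) if isinstance(v, (tuple, list)) else (v, v)


# ---------------------------------------------------------------------------
# padding / cropping
# ---------------------------------------------------------------------------

def pad2d(x: Tensor, pad, mode: str = "zero") -> Tensor:
    """Pad the last two axes. ``pad`` = (top, bottom, left, right).

    ``mode`` is ``"zero"`` or ``"reflect"``. Reflect padding mirrors without
    repeating the edge sample, so its adjoint folds gradients back onto the
    interior source rows/columns.
    """
    pt, pb, pl, pr = pad
    if (pt, pb, pl, pr) == (0, 0, 0, 0):
        return x
    H, W = x.shape[-2], x.shape[-1]
    if mode == "zero":
        widths = [(0, 0)] * (x.ndim - 2) + [(pt, pb), (pl, pr)]
        out_data = np.pad(x.data, widths)

        def bw(g):
            sl = (Ellipsis, slice(pt, pt + H), slice(pl, pl + W))
            x._accumulate(g[sl])

        return Tensor._make(out_data, (x,), bw)
    if mode == "reflect":
        iy = np.pad(np.arange(H), (pt, pb), mode="reflect")
        ix = np.pad(np.arange(W), (pl, pr), mode="reflect")
        out_data = x.data[..., iy[:, None], ix[None, :]]

        def bw(g):
            full = np.zeros_like(x.data)
            np.add.at(full, (Ellipsis, iy[:, None], ix[None, :]), g)
            x._accumulate(full)

        return Tensor._make(out_data, (x,), bw)
    raise ValueError(f"unknown pad mode {mode!r}")


def crop2d(x: Tensor, H: int, W: int) -> Tensor:
    """Crop the last two axes to ``H``×``W`` (top-left anchored)."""
    if x.shape[-2] == H and x.shape[-1] == W:
        return x

    def bw(g):
        full = np.zeros_like(x.data)
        full[..., :H, :W] = g
        x._accumulate(full)

    return Tensor._make(x.data[..., :H, :W].copy(), (x,), bw)


# ---------------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------------

def _im2col(xp: np.ndarray, kh: int, kw: int, sh: int, sw: int):
    """(N, C, Hp, Wp) -> columns (N, C*kh*kw, Ho*Wo) plus output dims."""
    N, C, Hp, Wp = xp.shape
    Ho = (Hp - kh) // sh + 1
    Wo = (Wp - kw) // sw + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    win = win[:, :, ::sh, ::sw]                      # (N, C, Ho, Wo, kh, kw)
    cols = win.transpose(0, 1, 4, 5, 2, 3).reshape(N, C * kh * kw, Ho * Wo)
    return np.ascontiguousarray(cols), Ho, Wo


def _col2im(gcols: np.ndarray, xshape, kh, kw, sh, sw, Ho, Wo) -> np.ndarray:
    N, C, Hp, Wp = xshape
    g = gcols.reshape(N, C, kh, kw, Ho, Wo)
    dx = np.zeros(xshape, dtype=gcols.dtype)
    for i in range(kh):
        for j in range(kw):
            dx[:, :, i:i + sh * Ho:sh, j:j + sw * Wo:sw] += g[:, :, i, j]
    return dx


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride=1, padding=0) -> Tensor:
    """2-D cross-correlation. ``x``: (N, Cin, H, W); ``w``: (Cout, Cin, kh, kw)."""
    sh, sw = _pair(stride)
    ph, pw = _pair(padding)
    Cout, Cin, kh, kw = w.shape
    if x.shape[1] != Cin:
        raise ValueError(f"conv2d: input has {x.shape[1]} channels, weight expects {Cin}")
    xp = np.pad(x.data, [(0, 0), (0, 0), (ph, ph), (pw, pw)]) if (ph or pw) else x.data
    cols, Ho, Wo = _im2col(xp, kh, kw, sh, sw)
    W2 = w.data.reshape(Cout, -1)
    out = np.matmul(W2, cols)                        # (N, Cout, Ho*Wo)
    N = x.shape[0]
    out = out.reshape(N, Cout, Ho, Wo)
    if b is not None:
        out = out + b.data.reshape(1, Cout, 1, 1)
    parents = (x, w) if b is None else (x, w, b)

    def bw(g):
        g2 = g.reshape(N, Cout, Ho * Wo)
        if b is not None and (b.requires_grad or b._prev):
            b._accumulate(g2.sum(axis=(0, 2)))
        gT = np.ascontiguousarray(g2.transpose(1, 0, 2)).reshape(Cout, -1)
        if w.requires_grad or w._prev:
            colsT = cols.transpose(1, 0, 2).reshape(Cin * kh * kw, -1)
            dW = np.matmul(gT, colsT.T)              # one 2-D GEMM
            w._accumulate(dW.reshape(w.shape))
        if x.requires_grad or x._prev:
            dcols = np.matmul(W2.T, gT).reshape(Cin * kh * kw, N, Ho * Wo)
            dcols = dcols.transpose(1, 0, 2)
            dxp = _col2im(dcols, xp.shape, kh, kw, sh, sw, Ho, Wo)
            if ph or pw:
                dxp = dxp[:, :, ph:ph + x.shape[2], pw:pw + x.shape[3]]
            x._accumulate(dxp)

    return Tensor._make(out, parents, bw)


def linear(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Affine map ``x @ w.T + b`` with ``w``: (out_features, in_features)."""
    out = Tensor._make(np.matmul(x.data, w.data.T), (x, w), None)

    def bw(g):
        if w.requires_grad or w._prev:
            gw = np.matmul(g.reshape(-1, g.shape[-1]).T, x.data.reshape(-1, x.shape[-1]))
            w._accumulate(gw)
        if x.requires_grad or x._prev:
            x._accumulate(np.matmul(g, w.data))

    out._backward = bw
    if b is not None:
        out = out + b
    return out


# ---------------------------------------------------------------------------
# pooling
# ---------------------------------------------------------------------------

def max_pool2d(x: Tensor, kernel_size, stride=None, padding=0) -> Tensor:
    kh, kw = _pair(kernel_size)
    sh, sw = _pair(stride if stride is not None else kernel_size)
    ph, pw = _pair(padding)
    neg = np.finfo(x.data.dtype).min
    xp = (np.pad(x.data, [(0, 0), (0, 0), (ph, ph), (pw, pw)], constant_values=neg)
          if (ph or pw) else x.data)
    N, C, Hp, Wp = xp.shape
    Ho = (Hp - kh) // sh + 1
    Wo = (Wp - kw) // sw + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::sh, ::sw]
    flat = win.reshape(N, C, Ho, Wo, kh * kw)
    amax = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, amax[..., None], axis=-1)[..., 0]

    def bw(g):
        dxp = np.zeros((N, C, Hp, Wp), dtype=g.dtype)
        ki, kj = np.unravel_index(amax, (kh, kw))
        oi = np.arange(Ho)[:, None] * sh
        oj = np.arange(Wo)[None, :] * sw
        rows = (oi[None, None] + ki)
        colsx = (oj[None, None] + kj)
        nn = np.arange(N)[:, None, None, None]
        cc = np.arange(C)[None, :, None, None]
        np.add.at(dxp, (nn, cc, rows, colsx), g)
        if ph or pw:
            dxp = dxp[:, :, ph:ph + x.shape[2], pw:pw + x.shape[3]]
        x._accumulate(dxp)

    return Tensor._make(out, (x,), bw)


def avg_pool2d(x: Tensor, kernel_size, stride=None) -> Tensor:
    kh, kw = _pair(kernel_size)
    sh, sw = _pair(stride if stride is not None else kernel_size)
    N, C, H, W = x.shape
    Ho = (H - kh) // sh + 1
    Wo = (W - kw) // sw + 1
    win = np.lib.stride_tricks.sliding_window_view(x.data, (kh, kw), axis=(2, 3))[:, :, ::sh, ::sw]
    out = win.mean(axis=(-2, -1))

    def bw(g):
        dx = np.zeros_like(x.data)
        gg = g / (kh * kw)
        for i in range(kh):
            for j in range(kw):
                dx[:, :, i:i + sh * Ho:sh, j:j + sw * Wo:sw] += gg
        x._accumulate(dx)

    return Tensor._make(out, (x,), bw)


def global_avg_pool(x: Tensor) -> Tensor:
    """(N, C, H, W) -> (N, C) spatial mean."""
    return x.mean(axis=(-2, -1))


# ---------------------------------------------------------------------------
# batch norm
# ---------------------------------------------------------------------------

def batch_norm2d(x: Tensor, gamma: Tensor, beta: Tensor,
                 running_mean: np.ndarray, running_var: np.ndarray,
                 training: bool, momentum: float = 0.1, eps: float = 1e-5) -> Tensor:
    """Batch normalisation over (N, H, W) per channel.

    In training mode batch statistics are used and the running buffers are
    updated in place (population variance in the normaliser, unbiased variance
    in the running buffer, matching common framework practice).
    """
    N, C, H, W = x.shape
    cshape = (1, C, 1, 1)
    if training:
        mu = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        n = N * H * W
        running_mean *= (1 - momentum)
        running_mean += momentum * mu
        running_var *= (1 - momentum)
        running_var += momentum * (var * n / max(n - 1, 1))
        invstd = 1.0 / np.sqrt(var + eps)
        xhat = (x.data - mu.reshape(cshape)) * invstd.reshape(cshape)
        out = gamma.data.reshape(cshape) * xhat + beta.data.reshape(cshape)

        def bw(g):
            if beta.requires_grad or beta._prev:
                beta._accumulate(g.sum(axis=(0, 2, 3)))
            if gamma.requires_grad or gamma._prev:
                gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
            if x.requires_grad or x._prev:
                gxh = g * gamma.data.reshape(cshape)
                s1 = gxh.sum(axis=(0, 2, 3), keepdims=True)
                s2 = (gxh * xhat).sum(axis=(0, 2, 3), keepdims=True)
                dx = (gxh - s1 / n - xhat * s2 / n) * invstd.reshape(cshape)
                x._accumulate(dx)

        return Tensor._make(out, (x, gamma, beta), bw)

    invstd = 1.0 / np.sqrt(running_var + eps)
    xhat = (x.data - running_mean.reshape(cshape)) * invstd.reshape(cshape)
    out = gamma.data.reshape(cshape) * xhat + beta.data.reshape(cshape)

    def bw(g):
        if beta.requires_grad or beta._prev:
            beta._accumulate(g.sum(axis=(0, 2, 3)))
        if gamma.requires_grad or gamma._prev:
            gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
        if x.requires_grad or x._prev:
            x._accumulate(g * (gamma.data * invstd).reshape(cshape))

    return Tensor._make(out, (x, gamma, beta), bw)


# ---------------------------------------------------------------------------
# activations & regularisation
# ---------------------------------------------------------------------------

def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def bw(g):
        x._accumulate(g * mask)

    return Tensor._make(x.data * mask, (x,), bw)


def leaky_relu(x: Tensor, negative_slope: float = 0.01) -> Tensor:
    mask = x.data > 0
    scale = np.where(mask, 1.0, negative_slope).astype(x.data.dtype)

    def bw(g):
        x._accumulate(g * scale)

    return Tensor._make(x.data * scale, (x,), bw)


def sigmoid(x: Tensor) -> Tensor:
    with np.errstate(over="ignore"):      # exp overflow saturates correctly to 0/1
        out_data = 1.0 / (1.0 + np.exp(-x.data))

    def bw(g):
        x._accumulate(g * out_data * (1.0 - out_data))

    return Tensor._make(out_data, (x,), bw)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    out_data = e / e.sum(axis=axis, keepdims=True)

    def bw(g):
        dot = (g * out_data).sum(axis=axis, keepdims=True)
        x._accumulate(out_data * (g - dot))

    return Tensor._make(out_data, (x,), bw)


def dropout(x: Tensor, p: float, training: bool) -> Tensor:
    """Inverted dropout: active only in training mode."""
    if not training or p <= 0.0:
        return x
    mask = (default_rng().random(x.shape) >= p).astype(x.data.dtype) / (1.0 - p)

    def bw(g):
        x._accumulate(g * mask)

    return Tensor._make(x.data * mask, (x,), bw)
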