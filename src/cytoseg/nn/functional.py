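"""Differentiable operations for the segmentation networks.

All ops take/return :class:`~cytoseg.nn.tensor.Tensor` and register a
backward closure when gradients are required. Convolution is evaluated
through ``sliding_window_view`` windows contracted with ``einsum`` (BLAS
underneath), with the input-gradient scatter done as one vectorised slice
assignment per kernel offset — no per-pixel Python loops anywhere.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .tensor import Tensor

__all__ = [
    "add", "relu", "sigmoid", "concat", "conv2d", "batch_norm2d",
    "max_pool2d", "avg_pool2d_2x2", "global_avg_pool",
    "upsample_nearest2x", "upsample_bilinear", "bce_with_logits",
]


def _pair(v):
    return (v, v) if np.isscalar(v) else tuple(v)


def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a.accumulate_grad(g)
        if b.requires_grad:
            b.accumulate_grad(g)

    return Tensor._result(out_data, (a, b), backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out_data = np.where(mask, x.data, 0)

    def backward(g):
        x.accumulate_grad(g * mask)

    return Tensor._result(out_data, (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    out_data = _sigmoid(x.data)

    def backward(g):
        x.accumulate_grad(g * out_data * (1.0 - out_data))

    return Tensor._result(out_data, (x,), backward)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t.accumulate_grad(g[tuple(sl)])

    return Tensor._result(out_data, tuple(tensors), backward)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride=1,
           padding=0, dilation=1, groups: int = 1) -> Tensor:
    """2-D cross-correlation, NCHW layout, weight (F, C//groups, KH, KW)."""
    sh, sw = _pair(stride)
    ph, pw = _pair(padding)
    dh, dw = _pair(dilation)
    N, C, H, W = x.data.shape
    F, Cg, KH, KW = w.data.shape
    if C != Cg * groups or F % groups:
        raise ValueError(
            f"conv2d channel mismatch: input {C}, weight {w.data.shape}, groups {groups}")
    ekh, ekw = (KH - 1) * dh + 1, (KW - 1) * dw + 1
    OH = (H + 2 * ph - ekh) // sh + 1
    OW = (W + 2 * pw - ekw) // sw + 1
    if OH < 1 or OW < 1:
        raise ValueError("conv2d: output would be empty")
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw))) if (ph or pw) else x.data

    win = sliding_window_view(xp, (ekh, ekw), axis=(2, 3))
    win = win[:, :, ::sh, ::sw, ::dh, ::dw][:, :, :OH, :OW]
    G, Fg = groups, F // groups
    win_g = win.reshape(N, G, Cg, OH, OW, KH, KW)
    w_g = w.data.reshape(G, Fg, Cg, KH, KW)
    out_data = np.einsum("ngchwkl,gfckl->ngfhw", win_g, w_g,
                         optimize=True).reshape(N, F, OH, OW)
    if b is not None:
        out_data = out_data + b.data.reshape(1, F, 1, 1)

    def backward(g):
        go = g.reshape(N, G, Fg, OH, OW)
        if b is not None and b.requires_grad:
            b.accumulate_grad(g.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            gw = np.einsum("ngchwkl,ngfhw->gfckl", win_g, go, optimize=True)
            w.accumulate_grad(gw.reshape(F, Cg, KH, KW).astype(w.data.dtype))
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            gxp_g = gxp.reshape(N, G, Cg, *xp.shape[2:])
            for k in range(KH):
                for l in range(KW):
                    contrib = np.einsum("ngfhw,gfc->ngchw", go,
                                        w_g[:, :, :, k, l], optimize=True)
                    gxp_g[:, :, :,
                          k * dh: k * dh + sh * OH: sh,
                          l * dw: l * dw + sw * OW: sw] += contrib
            if ph or pw:
                gxp = gxp[:, :, ph: ph + H, pw: pw + W]
            x.accumulate_grad(gxp)

    return Tensor._result(out_data, (x, w) if b is None else (x, w, b), backward)


def batch_norm2d(x: Tensor, gamma: Tensor, beta: Tensor, running_mean: np.ndarray,
                 running_var: np.ndarray, training: bool, momentum: float = 0.1,
                 eps: float = 1e-5) -> Tensor:
    """Channel-wise batch normalisation; updates running stats in place."""
    N, C, H, W = x.data.shape
    if training:
        mean = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))  # biased, used for normalisation
        n = N * H * W
        unbiased = var * n / max(n - 1, 1)
        running_mean *= (1 - momentum)
        running_mean += momentum * mean
        running_var *= (1 - momentum)
        running_var += momentum * unbiased
    else:
        mean, var = running_mean, running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean[:, None, None]) * inv_std[:, None, None]
    out_data = gamma.data[:, None, None] * xhat + beta.data[:, None, None]

    def backward(g):
        if beta.requires_grad:
            beta.accumulate_grad(g.sum(axis=(0, 2, 3)).astype(beta.data.dtype))
        if gamma.requires_grad:
            gamma.accumulate_grad((g * xhat).sum(axis=(0, 2, 3)).astype(gamma.data.dtype))
        if x.requires_grad:
            gxhat = g * gamma.data[:, None, None]
            if training:
                m = gxhat.mean(axis=(0, 2, 3), keepdims=True)
                mx = (gxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
                gx = (gxhat - m - xhat * mx) * inv_std[:, None, None]
            else:
                gx = gxhat * inv_std[:, None, None]
            x.accumulate_grad(gx.astype(x.data.dtype))

    return Tensor._result(out_data, (x, gamma, beta), backward)


def max_pool2d(x: Tensor, kernel: int = 3, stride: int = 2, padding: int = 1) -> Tensor:
    N, C, H, W = x.data.shape
    k, s, p = kernel, stride, padding
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)),
                constant_values=-np.inf) if p else x.data
    OH = (H + 2 * p - k) // s + 1
    OW = (W + 2 * p - k) // s + 1
    win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s][:, :, :OH, :OW]
    flat = win.reshape(N, C, OH, OW, k * k)
    idx = flat.argmax(axis=-1)
    out_data = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        gxp = np.zeros((N, C, H + 2 * p, W + 2 * p), dtype=x.data.dtype)
        oh = np.arange(OH)[:, None]
        ow = np.arange(OW)[None, :]
        hi = oh * s + idx // k  # padded coords; -inf pad is never the argmax
        wj = ow * s + idx % k
        nn = np.arange(N)[:, None, None, None]
        cc = np.arange(C)[None, :, None, None]
        np.add.at(gxp, (nn, cc, hi, wj), g)
        x.accumulate_grad(gxp[:, :, p: p + H, p: p + W] if p else gxp)

    return Tensor._result(out_data, (x,), backward)


def avg_pool2d_2x2(x: Tensor) -> Tensor:
    N, C, H, W = x.data.shape
    out_data = x.data.reshape(N, C, H // 2, 2, W // 2, 2).mean(axis=(3, 5))

    def backward(g):
        gx = np.repeat(np.repeat(g, 2, axis=2), 2, axis=3) * 0.25
        x.accumulate_grad(gx.astype(x.data.dtype))

    return Tensor._result(out_data, (x,), backward)


def global_avg_pool(x: Tensor) -> Tensor:
    N, C, H, W = x.data.shape
    out_data = x.data.mean(axis=(2, 3), keepdims=True)

    def backward(g):
        x.accumulate_grad(np.broadcast_to(g / (H * W), x.data.shape).astype(x.data.dtype))

    return Tensor._result(out_data, (x,), backward)


def upsample_nearest2x(x: Tensor) -> Tensor:
    N, C, H, W = x.data.shape
    out_data = x.data.repeat(2, axis=2).repeat(2, axis=3)

    def backward(g):
        gx = g.reshape(N, C, H, 2, W, 2).sum(axis=(3, 5))
        x.accumulate_grad(gx.astype(x.data.dtype))

    return Tensor._result(out_data, (x,), backward)


def _bilinear_axis(in_size: int, out_size: int):
    """Source indices and weights, half-pixel-centre convention."""
    src = (np.arange(out_size) + 0.5) * (in_size / out_size) - 0.5
    src = np.clip(src, 0, in_size - 1)
    lo = np.floor(src).astype(np.int64)
    hi = np.minimum(lo + 1, in_size - 1)
    frac = src - lo
    return lo, hi, frac


def upsample_bilinear(x: Tensor, out_size: tuple[int, int]) -> Tensor:
    N, C, H, W = x.data.shape
    OH, OW = out_size
    i0, i1, fi = _bilinear_axis(H, OH)
    j0, j1, fj = _bilinear_axis(W, OW)
    wi = fi[:, None]
    wj = fj[None, :]
    corners = (
        (i0, j0, (1 - wi) * (1 - wj)),
        (i0, j1, (1 - wi) * wj),
        (i1, j0, wi * (1 - wj)),
        (i1, j1, wi * wj),
    )
    out_data = np.zeros((N, C, OH, OW), dtype=x.data.dtype)
    for ii, jj, ww in corners:
        out_data += x.data[:, :, ii[:, None], jj[None, :]] * ww

    def backward(g):
        gx = np.zeros_like(x.data)
        for ii, jj, ww in corners:
            np.add.at(gx, (slice(None), slice(None), ii[:, None], jj[None, :]), g * ww)
        x.accumulate_grad(gx)

    return Tensor._result(out_data, (x,), backward)


def _softplus(z: np.ndarray) -> np.ndarray:
    return np.maximum(z, 0) + np.log1p(np.exp(-np.abs(z)))


def bce_with_logits(logits: Tensor, targets: np.ndarray, pos_weight: float = 1.0) -> Tensor:
    """Mean of ``pos_weight*t*softplus(-z) + (1-t)*softplus(z)`` over all elements.

    Numerically stable logit-space form of the weighted binary cross-entropy
    on probabilities; the two agree wherever ``p = sigmoid(z)``.
    """
    t = np.asarray(targets, dtype=logits.data.dtype)
    z = logits.data
    loss = pos_weight * t * _softplus(-z) + (1.0 - t) * _softplus(z)
    out_data = np.asarray(loss.mean(), dtype=z.dtype)
    n = z.size

    def backward(g):
        gz = ((1.0 - t) * _sigmoid(z) - pos_weight * t * _sigmoid(-z)) * (g / n)
        logits.accumulate_grad(gz.astype(z.dtype))

    return Tensor._result(out_data, (logits,), backward)
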