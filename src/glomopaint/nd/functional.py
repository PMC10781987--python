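"""Convolution, normalisation and resampling ops for the autodiff engine.

Convolutions are evaluated with a loop over kernel offsets: for each (ki, kj)
a strided slice of the padded input is contracted against one kernel column
via ``einsum``.  For the small kernels used here (7x7 at most) this is both
memory-light and fast enough for CPU training at desk scale, and the backward
pass mirrors the forward slices exactly.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = [
    "conv2d",
    "conv_transpose2d",
    "batch_norm2d",
    "upsample_nearest",
    "upsample_bilinear",
]


def conv2d(
    x: Tensor,
    w: Tensor,
    b: Tensor | None = None,
    stride: int = 1,
    padding: int = 0,
    dilation: int = 1,
) -> Tensor:
    """2-D cross-correlation, NCHW layout, weight (O, C, kh, kw)."""
    n, c, h, width = x.shape
    o, cw, kh, kw = w.shape
    if cw != c:
        raise ValueError(f"channel mismatch: input {c}, weight {cw}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    hp, wp = xp.shape[2], xp.shape[3]
    eff_kh = (kh - 1) * dilation + 1
    eff_kw = (kw - 1) * dilation + 1
    oh = (hp - eff_kh) // stride + 1
    ow = (wp - eff_kw) // stride + 1
    if oh < 1 or ow < 1:
        raise ValueError("kernel larger than padded input")
    out_data = np.zeros((n, o, oh, ow), dtype=x.data.dtype)
    for ki in range(kh):
        for kj in range(kw):
            xs = xp[
                :,
                :,
                ki * dilation : ki * dilation + stride * oh : stride,
                kj * dilation : kj * dilation + stride * ow : stride,
            ]
            out_data += np.einsum("nchw,oc->nohw", xs, w.data[:, :, ki, kj])
    if b is not None:
        out_data += b.data.reshape(1, o, 1, 1)

    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        if x.requires_grad:
            gxp = np.zeros_like(xp)
        for ki in range(kh):
            for kj in range(kw):
                sl = (
                    slice(None),
                    slice(None),
                    slice(ki * dilation, ki * dilation + stride * oh, stride),
                    slice(kj * dilation, kj * dilation + stride * ow, stride),
                )
                if w.requires_grad:
                    if w.grad is None:
                        w.grad = np.zeros_like(w.data)
                    w.grad[:, :, ki, kj] += np.einsum("nchw,nohw->oc", xp[sl], g)
                if x.requires_grad:
                    gxp[sl] += np.einsum("nohw,oc->nchw", g, w.data[:, :, ki, kj])
        if x.requires_grad:
            if padding:
                gxp = gxp[:, :, padding:-padding, padding:-padding]
            x._accum(gxp)
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))

    return Tensor._make(out_data, parents, backward)


def conv_transpose2d(
    x: Tensor,
    w: Tensor,
    b: Tensor | None = None,
    stride: int = 2,
    padding: int = 1,
) -> Tensor:
    """Transposed convolution, weight (C_in, C_out, kh, kw).

    Output size is ``(H-1)*stride - 2*padding + kh`` (no output_padding).
    """
    n, c, h, width = x.shape
    cw, o, kh, kw = w.shape
    if cw != c:
        raise ValueError(f"channel mismatch: input {c}, weight {cw}")
    oh_full = (h - 1) * stride + kh
    ow_full = (width - 1) * stride + kw
    oh = oh_full - 2 * padding
    ow = ow_full - 2 * padding
    full = np.zeros((n, o, oh_full, ow_full), dtype=x.data.dtype)
    for ki in range(kh):
        for kj in range(kw):
            full[
                :, :, ki : ki + stride * h : stride, kj : kj + stride * width : stride
            ] += np.einsum("nchw,co->nohw", x.data, w.data[:, :, ki, kj])
    out_data = full[:, :, padding : padding + oh, padding : padding + ow]
    if b is not None:
        out_data = out_data + b.data.reshape(1, o, 1, 1)

    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        gf = np.zeros((n, o, oh_full, ow_full), dtype=x.data.dtype)
        gf[:, :, padding : padding + oh, padding : padding + ow] = g
        for ki in range(kh):
            for kj in range(kw):
                sl = (
                    slice(None),
                    slice(None),
                    slice(ki, ki + stride * h, stride),
                    slice(kj, kj + stride * width, stride),
                )
                if w.requires_grad:
                    if w.grad is None:
                        w.grad = np.zeros_like(w.data)
                    w.grad[:, :, ki, kj] += np.einsum("nchw,nohw->co", x.data, gf[sl])
                if x.requires_grad:
                    if x.grad is None:
                        x.grad = np.zeros_like(x.data)
                    x.grad += np.einsum("nohw,co->nchw", gf[sl], w.data[:, :, ki, kj])
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))

    return Tensor._make(out_data, parents, backward)


def batch_norm2d(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Batch normalisation over (N, H, W) per channel; updates running stats in place."""
    if training:
        mu = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mu, var = running_mean, running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu.reshape(1, -1, 1, 1)) * inv_std.reshape(1, -1, 1, 1)
    out_data = gamma.data.reshape(1, -1, 1, 1) * xhat + beta.data.reshape(1, -1, 1, 1)
    m = x.shape[0] * x.shape[2] * x.shape[3]

    def backward(g):
        if gamma.requires_grad:
            gamma._accum((g * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            beta._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gxhat = g * gamma.data.reshape(1, -1, 1, 1)
            if training:
                # full batch-stat Jacobian
                term1 = gxhat
                term2 = gxhat.mean(axis=(0, 2, 3), keepdims=True)
                term3 = xhat * (gxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
                gx = (term1 - term2 - term3) * inv_std.reshape(1, -1, 1, 1)
            else:
                gx = gxhat * inv_std.reshape(1, -1, 1, 1)
            x._accum(gx.astype(x.data.dtype))

    return Tensor._make(out_data, (x, gamma, beta), backward)


def upsample_nearest(x: Tensor, factor: int) -> Tensor:
    out_data = x.data.repeat(factor, axis=2).repeat(factor, axis=3)

    def backward(g):
        if x.requires_grad:
            n, c, h, w = x.shape
            gr = g.reshape(n, c, h, factor, w, factor).sum(axis=(3, 5))
            x._accum(gr)

    return Tensor._make(out_data, (x,), backward)


def _bilinear_weights(n_out: int, n_in: int):
    """Align-corners=False sampling positions, clamped to the input range."""
    scale = n_in / n_out
    pos = (np.arange(n_out) + 0.5) * scale - 0.5
    pos = np.clip(pos, 0, n_in - 1)
    lo = np.floor(pos).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    frac = pos - lo
    return lo, hi, frac


def upsample_bilinear(x: Tensor, size: tuple[int, int]) -> Tensor:
    n, c, h, w = x.shape
    oh, ow = size
    ylo, yhi, fy = _bilinear_weights(oh, h)
    xlo, xhi, fx = _bilinear_weights(ow, w)
    fy = fy.reshape(1, 1, oh, 1)
    fx = fx.reshape(1, 1, 1, ow)
    d = x.data
    top = d[:, :, ylo][:, :, :, xlo] * (1 - fx) + d[:, :, ylo][:, :, :, xhi] * fx
    bot = d[:, :, yhi][:, :, :, xlo] * (1 - fx) + d[:, :, yhi][:, :, :, xhi] * fx
    out_data = top * (1 - fy) + bot * fy

    def backward(g):
        if not x.requires_grad:
            return
        gx = np.zeros_like(d)
        # four corner contributions of the bilinear stencil
        for gv, rows_idx in ((g * (1 - fy), ylo), (g * fy, yhi)):
            for gc, cols_idx in ((gv * (1 - fx), xlo), (gv * fx, xhi)):
                np.add.at(
                    gx,
                    (slice(None), slice(None), rows_idx[:, None], cols_idx[None, :]),
                    gc,
                )
        x._accum(gx.astype(x.data.dtype))

    return Tensor._make(out_data.astype(x.data.dtype), (x,), backward)
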