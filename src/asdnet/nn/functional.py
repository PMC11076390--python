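"""Spatial operations (convolution, pooling, upsampling) for rank-4 maps.

All ops take and return tensors shaped ``(batch, channels, height, width)``.
Convolution is stride-1 correlation implemented by im2col + one BLAS
matmul; "same" padding is the caller's responsibility (the module layer
computes it from kernel size and dilation).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .tensor import Tensor, as_tensor


def _pair(v):
    return tuple(v) if isinstance(v, (tuple, list)) else (v, v)


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           padding=0, dilation=1) -> Tensor:
    """Stride-1 2-D cross-correlation.

    ``x``: (N, C, H, W); ``weight``: (O, C, kh, kw); ``bias``: (O,).
    Output spatial size is ``H + 2p - (k-1)*d`` per axis.
    """
    x, weight = as_tensor(x), as_tensor(weight)
    N, C, H, W = x.data.shape
    O, Cw, kh, kw = weight.data.shape
    if Cw != C:
        raise ValueError(f"conv2d channel mismatch: input has {C}, weight expects {Cw}")
    ph, pw = _pair(padding)
    dh, dw = _pair(dilation)
    eh, ew = (kh - 1) * dh + 1, (kw - 1) * dw + 1  # effective kernel extent
    if H + 2 * ph < eh or W + 2 * pw < ew:
        raise ValueError(
            f"conv2d: padded input {H + 2 * ph}x{W + 2 * pw} smaller than "
            f"effective kernel {eh}x{ew}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw))) if (ph or pw) else x.data
    Ho, Wo = xp.shape[2] - eh + 1, xp.shape[3] - ew + 1
    win = sliding_window_view(xp, (eh, ew), axis=(2, 3))[..., ::dh, ::dw]
    # (N, C, Ho, Wo, kh, kw) -> (N*Ho*Wo, C*kh*kw)
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        N * Ho * Wo, C * kh * kw)
    wmat = weight.data.reshape(O, -1)
    out = cols @ wmat.T
    if bias is not None:
        out += bias.data
    out_data = out.reshape(N, Ho, Wo, O).transpose(0, 3, 1, 2)

    prev = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        gm = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(N * Ho * Wo, O)
        if bias is not None and bias.requires_grad:
            bias._accumulate(gm.sum(axis=0))
        if weight.requires_grad:
            weight._accumulate((gm.T @ cols).reshape(weight.data.shape))
        if x.requires_grad:
            dcols = (gm @ wmat).reshape(N, Ho, Wo, C, kh, kw)
            dxp = np.zeros((N, C, H + 2 * ph, W + 2 * pw), dtype=g.dtype)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i * dh:i * dh + Ho, j * dw:j * dw + Wo] += \
                        dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
            if ph or pw:
                dxp = dxp[:, :, ph:ph + H, pw:pw + W]
            x._accumulate(dxp)

    return Tensor._node(out_data, prev, backward)


def conv_transpose2d_2x2(x: Tensor, weight: Tensor, bias: Tensor | None = None) -> Tensor:
    """Transposed convolution with kernel 2, stride 2 (exact 2x upsampling).

    ``weight``: (C_in, C_out, 2, 2).  ``out[:, :, 2i+a, 2j+b] = x . W[:, :, a, b]``.
    """
    x, weight = as_tensor(x), as_tensor(weight)
    N, C, H, W = x.data.shape
    Cin, O, _, _ = weight.data.shape
    if Cin != C:
        raise ValueError(f"conv_transpose channel mismatch: {C} vs {Cin}")
    out_data = np.empty((N, O, 2 * H, 2 * W), dtype=x.data.dtype)
    for a in range(2):
        for b in range(2):
            out_data[:, :, a::2, b::2] = np.einsum(
                "nchw,co->nohw", x.data, weight.data[:, :, a, b], optimize=True)
    if bias is not None:
        out_data += bias.data.reshape(1, O, 1, 1)

    prev = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        if weight.requires_grad:
            dw = np.empty_like(weight.data)
            for a in range(2):
                for b in range(2):
                    dw[:, :, a, b] = np.einsum(
                        "nchw,nohw->co", x.data, g[:, :, a::2, b::2], optimize=True)
            weight._accumulate(dw)
        if x.requires_grad:
            dx = np.zeros_like(x.data)
            for a in range(2):
                for b in range(2):
                    dx += np.einsum("nohw,co->nchw", g[:, :, a::2, b::2],
                                    weight.data[:, :, a, b], optimize=True)
            x._accumulate(dx)

    return Tensor._node(out_data, prev, backward)


def max_pool2d(x: Tensor) -> Tensor:
    """2x2 max pooling, stride 2.  Spatial dims must be even."""
    x = as_tensor(x)
    N, C, H, W = x.data.shape
    if H % 2 or W % 2:
        raise ValueError(f"max_pool2d requires even spatial dims, got {H}x{W}")
    blocks = x.data.reshape(N, C, H // 2, 2, W // 2, 2)
    flat = blocks.transpose(0, 1, 2, 4, 3, 5).reshape(N, C, H // 2, W // 2, 4)
    idx = flat.argmax(axis=-1)
    out_data = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        if not x.requires_grad:
            return
        dflat = np.zeros_like(flat)
        np.put_along_axis(dflat, idx[..., None], g[..., None], axis=-1)
        dx = dflat.reshape(N, C, H // 2, W // 2, 2, 2).transpose(
            0, 1, 2, 4, 3, 5).reshape(N, C, H, W)
        x._accumulate(dx)

    return Tensor._node(out_data, (x,), backward)


def global_avg_pool(x: Tensor) -> Tensor:
    """Mean over the spatial axes, keeping them as size-1 dims: (N,C,1,1)."""
    return as_tensor(x).mean(axis=(2, 3), keepdims=True)


def broadcast_hw(x: Tensor, height: int, width: int) -> Tensor:
    """Tile a (N, C, 1, 1) map to (N, C, height, width)."""
    x = as_tensor(x)
    N, C, h, w = x.data.shape
    if (h, w) != (1, 1):
        raise ValueError("broadcast_hw expects spatial dims of size 1")
    out_data = np.broadcast_to(x.data, (N, C, height, width)).copy()

    def backward(g):
        if x.requires_grad:
            x._accumulate(g.sum(axis=(2, 3), keepdims=True))

    return Tensor._node(out_data, (x,), backward)
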