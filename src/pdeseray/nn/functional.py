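"""Differentiable neural-network operations (conv, norms, activations).

Convolution is implemented as an im2col view + ``einsum`` contraction; its
backward pass loops over the (small) kernel footprint with strided
scatter-adds, which keeps everything vectorised in NumPy.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import erf

from .tensor import Tensor

__all__ = [
    "conv2d", "conv_transpose2x2", "layer_norm_channels", "batch_norm2d",
    "gelu", "relu", "sigmoid", "upsample_nearest2x", "concat_channels",
]

_SQRT2 = np.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / np.sqrt(2.0 * np.pi)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, *,
           stride: int = 1, padding: int = 0, groups: int = 1) -> Tensor:
    """2-D cross-correlation with optional channel groups.

    ``x``: (N, Cin, H, W); ``w``: (Cout, Cin/groups, kh, kw); ``b``: (Cout,).
    ``groups == Cin`` with single-channel kernels gives a depthwise
    convolution.
    """
    n, cin, h, wd = x.shape
    cout, cg, kh, kw = w.shape
    g = groups
    if cin % g or cout % g or cg != cin // g:
        raise ValueError("channel counts incompatible with groups")
    s, p = stride, padding
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
    ho = (h + 2 * p - kh) // s + 1
    wo = (wd + 2 * p - kw) // s + 1
    view = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::s, ::s]
    viewg = view.reshape(n, g, cin // g, ho, wo, kh, kw)
    wg = w.data.reshape(g, cout // g, cin // g, kh, kw)
    out_data = np.einsum("ngchwuv,gocuv->ngohw", viewg, wg,
                         optimize=True).reshape(n, cout, ho, wo)
    if b is not None:
        out_data = out_data + b.data[None, :, None, None]

    def backward():
        go = out.grad.reshape(n, g, cout // g, ho, wo)
        if w.requires_grad:
            dw = np.einsum("ngchwuv,ngohw->gocuv", viewg, go, optimize=True)
            w._accum(dw.reshape(w.data.shape))
        if b is not None and b.requires_grad:
            b._accum(out.grad.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dxp = np.zeros_like(xp)
            dxp_g = dxp.reshape(n, g, cin // g, *xp.shape[2:])
            for u in range(kh):
                for v in range(kw):
                    t = np.einsum("ngohw,goc->ngchw", go, wg[:, :, :, u, v],
                                  optimize=True)
                    dxp_g[:, :, :, u:u + s * ho:s, v:v + s * wo:s] += t
            x._accum(dxp[:, :, p:p + h, p:p + wd] if p else dxp)

    out = Tensor._make(out_data, (x, w) + ((b,) if b is not None else ()), backward)
    return out


def conv_transpose2x2(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Transposed convolution with a 2x2 kernel and stride 2 (exact x2 upsample).

    ``w``: (Cin, Cout, 2, 2). Because kernel size equals stride, output
    positions never overlap.
    """
    n, cin, h, wd = x.shape
    _, cout = w.shape[:2]
    out_data = np.empty((n, cout, 2 * h, 2 * wd))
    for u in range(2):
        for v in range(2):
            out_data[:, :, u::2, v::2] = np.einsum(
                "nchw,co->nohw", x.data, w.data[:, :, u, v], optimize=True)
    if b is not None:
        out_data += b.data[None, :, None, None]

    def backward():
        if x.requires_grad:
            dx = np.zeros_like(x.data)
            for u in range(2):
                for v in range(2):
                    dx += np.einsum("nohw,co->nchw", out.grad[:, :, u::2, v::2],
                                    w.data[:, :, u, v], optimize=True)
            x._accum(dx)
        if w.requires_grad:
            dw = np.empty_like(w.data)
            for u in range(2):
                for v in range(2):
                    dw[:, :, u, v] = np.einsum(
                        "nchw,nohw->co", x.data, out.grad[:, :, u::2, v::2],
                        optimize=True)
            w._accum(dw)
        if b is not None and b.requires_grad:
            b._accum(out.grad.sum(axis=(0, 2, 3)))

    out = Tensor._make(out_data, (x, w) + ((b,) if b is not None else ()), backward)
    return out


def _norm_backward(go, xhat, inv_std, gamma, axes, m):
    dxhat = go * gamma
    mean_dxhat = dxhat.mean(axis=axes, keepdims=True)
    mean_dxhat_xhat = (dxhat * xhat).mean(axis=axes, keepdims=True)
    return inv_std * (dxhat - mean_dxhat - xhat * mean_dxhat_xhat)


def layer_norm_channels(x: Tensor, gamma: Tensor, beta: Tensor,
                        eps: float = 1e-6) -> Tensor:
    """LayerNorm over the channel axis of an (N, C, H, W) tensor.

    Each spatial position is normalised across its C-vector, the convention
    used throughout ConvNeXt-style backbones (channels-first LayerNorm).
    """
    mu = x.data.mean(axis=1, keepdims=True)
    var = x.data.var(axis=1, keepdims=True)
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv_std
    gm = gamma.data[None, :, None, None]
    bt = beta.data[None, :, None, None]
    out_data = gm * xhat + bt

    def backward():
        go = out.grad
        if gamma.requires_grad:
            gamma._accum((go * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            beta._accum(go.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            x._accum(_norm_backward(go, xhat, inv_std, gm, 1, x.shape[1]))

    out = Tensor._make(out_data, (x, gamma, beta), backward)
    return out


def batch_norm2d(x: Tensor, gamma: Tensor, beta: Tensor,
                 running_mean: np.ndarray, running_var: np.ndarray, *,
                 training: bool, momentum: float = 0.1,
                 eps: float = 1e-5) -> Tensor:
    """BatchNorm over (N, H, W) per channel; updates running stats in place."""
    if training:
        mu = x.data.mean(axis=(0, 2, 3), keepdims=True)
        var = x.data.var(axis=(0, 2, 3), keepdims=True)
        m = x.data.size / x.shape[1]
        running_mean *= (1.0 - momentum)
        running_mean += momentum * mu.ravel()
        running_var *= (1.0 - momentum)
        # unbiased variance for the running estimate, biased in the forward
        running_var += momentum * var.ravel() * (m / max(m - 1.0, 1.0))
    else:
        mu = running_mean[None, :, None, None]
        var = running_var[None, :, None, None]
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv_std
    gm = gamma.data[None, :, None, None]
    out_data = gm * xhat + beta.data[None, :, None, None]

    def backward():
        go = out.grad
        if gamma.requires_grad:
            gamma._accum((go * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            beta._accum(go.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            if training:
                x._accum(_norm_backward(go, xhat, inv_std, gm, (0, 2, 3),
                                        x.data.size / x.shape[1]))
            else:
                x._accum(go * gm * inv_std)

    out = Tensor._make(out_data, (x, gamma, beta), backward)
    return out


def gelu(x: Tensor) -> Tensor:
    """Exact (erf-based) Gaussian Error Linear Unit."""
    cdf = 0.5 * (1.0 + erf(x.data / _SQRT2))
    out_data = x.data * cdf

    def backward():
        pdf = _INV_SQRT_2PI * np.exp(-0.5 * x.data ** 2)
        x._accum(out.grad * (cdf + x.data * pdf))

    out = Tensor._make(out_data, (x,), backward)
    return out


def relu(x: Tensor) -> Tensor:
    out_data = np.maximum(x.data, 0.0)

    def backward():
        x._accum(out.grad * (x.data > 0))

    out = Tensor._make(out_data, (x,), backward)
    return out


def sigmoid(x: Tensor) -> Tensor:
    # numerically stable logistic
    out_data = np.where(x.data >= 0, 1.0 / (1.0 + np.exp(-np.abs(x.data))),
                        np.exp(-np.abs(x.data)) / (1.0 + np.exp(-np.abs(x.data))))

    def backward():
        x._accum(out.grad * out_data * (1.0 - out_data))

    out = Tensor._make(out_data, (x,), backward)
    return out


def upsample_nearest2x(x: Tensor) -> Tensor:
    """Parameter-free x2 nearest-neighbour upsampling."""
    out_data = x.data.repeat(2, axis=2).repeat(2, axis=3)

    def backward():
        n, c, h2, w2 = out.grad.shape
        g = out.grad.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5))
        x._accum(g)

    out = Tensor._make(out_data, (x,), backward)
    return out


def concat_channels(a: Tensor, b: Tensor) -> Tensor:
    out_data = np.concatenate([a.data, b.data], axis=1)
    ca = a.shape[1]

    def backward():
        a._accum(out.grad[:, :ca])
        b._accum(out.grad[:, ca:])

    out = Tensor._make(out_data, (a, b), backward)
    return out
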