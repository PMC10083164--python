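"""Convolutional primitives with hand-written backward passes.

conv2d uses im2col + BLAS matmul, which is the fastest pure-NumPy route at the
image sizes this package trains on.  Layout is NCHW throughout.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .autograd import Tensor

__all__ = ["conv2d", "upsample_nearest2x", "instance_norm", "global_mean_pool"]


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """2-D convolution (cross-correlation). x: (N,C,H,W), w: (Co,Ci,kh,kw)."""
    n, c, h, wdt = x.shape
    co, ci, kh, kw = w.shape
    if ci != c:
        raise ValueError(f"channel mismatch: input {c}, kernel expects {ci}")
    xd = x.data
    if padding:
        xd = np.pad(xd, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    ho = (xd.shape[2] - kh) // stride + 1
    wo = (xd.shape[3] - kw) // stride + 1
    win = sliding_window_view(xd, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
    # (N,C,Ho,Wo,kh,kw) -> (N*Ho*Wo, C*kh*kw)
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        n * ho * wo, c * kh * kw)
    wmat = w.data.reshape(co, -1)
    out = cols @ wmat.T
    if b is not None:
        out += b.data
    out = out.reshape(n, ho, wo, co).transpose(0, 3, 1, 2)

    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        gmat = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(n * ho * wo, co)
        if b is not None and b.requires_grad:
            b._accum(gmat.sum(axis=0))
        if w.requires_grad:
            w._accum((gmat.T @ cols).reshape(w.shape))
        if x.requires_grad:
            dcols = (gmat @ wmat).reshape(n, ho, wo, c, kh, kw)
            hp = h + 2 * padding
            wp = wdt + 2 * padding
            dxp = np.zeros((n, c, hp, wp), dtype=g.dtype)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i:i + stride * ho:stride,
                        j:j + stride * wo:stride] += dcols[:, :, :, :, i, j].transpose(
                            0, 3, 1, 2)
            if padding:
                dxp = dxp[:, :, padding:hp - padding, padding:wp - padding]
            x._accum(dxp)

    return Tensor._make(out, parents, backward)


def upsample_nearest2x(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x spatial upsampling (used before decoder convs to
    avoid transposed-convolution checkerboard artefacts)."""
    out = x.data.repeat(2, axis=2).repeat(2, axis=3)

    def backward(g):
        n, c, h2, w2 = g.shape
        x._accum(g.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5)))

    return Tensor._make(out, (x,), backward)


def instance_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Per-sample, per-channel normalisation over the spatial axes, with a
    learned channel-wise affine map.  Composed from autodiff primitives."""
    mu = x.mean(axis=(2, 3), keepdims=True)
    centred = x - mu
    var = (centred * centred).mean(axis=(2, 3), keepdims=True)
    inv = (var + eps) ** -0.5
    g = gamma.reshape(1, -1, 1, 1)
    b = beta.reshape(1, -1, 1, 1)
    return centred * inv * g + b


def global_mean_pool(x: Tensor) -> Tensor:
    """(N,C,H,W) -> (N,C) spatial mean."""
    return x.mean(axis=(2, 3))
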