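"""Array primitives shared by the network layers.

Everything operates on float arrays in NCHW (images) or BTF (sequences)
layout.  The im2col/col2im pair turns convolution into a single GEMM,
which is where essentially all of the training time is spent.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "im2col",
    "col2im",
    "sigmoid",
    "softmax",
    "log_softmax",
    "softmax_cross_entropy",
    "resize_bilinear_batch",
]


def im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int) -> np.ndarray:
    """Unfold ``x`` (B, C, H, W) into patches of shape (B, OH, OW, C, kh, kw).

    The returned array is contiguous (a copy), so callers may reshape it
    freely for the GEMM.
    """
    if pad > 0:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    # (B, C, H', W', kh, kw) with unit stride, then subsample by `stride`
    win = sliding_window_view(x, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
    return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5))


def col2im(
    cols: np.ndarray,
    x_shape: tuple[int, int, int, int],
    kh: int,
    kw: int,
    stride: int,
    pad: int,
) -> np.ndarray:
    """Adjoint of :func:`im2col`: scatter-add patches back onto the image."""
    b, c, h, w = x_shape
    oh, ow = cols.shape[1], cols.shape[2]
    xp = np.zeros((b, c, h + 2 * pad, w + 2 * pad), dtype=cols.dtype)
    # loop over the k*k kernel offsets; each iteration is one vectorised add
    patches = cols.transpose(0, 3, 1, 2, 4, 5)  # (B, C, OH, OW, kh, kw)
    for i in range(kh):
        for j in range(kw):
            xp[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride] += (
                patches[:, :, :, :, i, j]
            )
    if pad > 0:
        return xp[:, :, pad : pad + h, pad : pad + w]
    return xp


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    return z - np.log(np.exp(z).sum(axis=axis, keepdims=True))


def softmax_cross_entropy(
    logits: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over a (B, K) batch and its gradient w.r.t. logits."""
    b = logits.shape[0]
    logp = log_softmax(logits, axis=1)
    loss = -logp[np.arange(b), labels].mean()
    grad = softmax(logits, axis=1)
    grad[np.arange(b), labels] -= 1.0
    return float(loss), grad / b


def resize_bilinear_batch(frames: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    """Bilinear resize of a stack of 2-D frames (B, H, W) -> (B, out_h, out_w).

    Uses half-pixel sample centres with edge clamping; vectorised over the
    batch so per-frame overhead stays negligible in the augmentation loop.
    """
    b, h, w = frames.shape
    if (h, w) == (out_h, out_w):
        return frames.copy()
    ys = (np.arange(out_h) + 0.5) * (h / out_h) - 0.5
    xs = (np.arange(out_w) + 0.5) * (w / out_w) - 0.5
    y0 = np.clip(np.floor(ys).astype(np.intp), 0, h - 1)
    x0 = np.clip(np.floor(xs).astype(np.intp), 0, w - 1)
    y1 = np.minimum(y0 + 1, h - 1)
    x1 = np.minimum(x0 + 1, w - 1)
    wy = np.clip(ys - y0, 0.0, 1.0)[:, None]
    wx = np.clip(xs - x0, 0.0, 1.0)[None, :]
    f00 = frames[:, y0[:, None], x0[None, :]]
    f01 = frames[:, y0[:, None], x1[None, :]]
    f10 = frames[:, y1[:, None], x0[None, :]]
    f11 = frames[:, y1[:, None], x1[None, :]]
    top = f00 * (1 - wx) + f01 * wx
    bot = f10 * (1 - wx) + f11 * wx
    return (top * (1 - wy) + bot * wy).astype(frames.dtype)
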