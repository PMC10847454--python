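"""Low-level 3D convolution primitives.

All tensors are float32 ``numpy`` arrays in ``(N, C, D, H, W)`` layout.
Convolutions are computed as a single GEMM over an im2col view built with
``sliding_window_view``, so no per-voxel Python loops are involved; the
backward pass reuses the same view for the weight gradient and scatters the
input gradient with one slice-add per kernel offset (k**3 adds total).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _pad_amount(kernel: int) -> int:
    # 'same' padding for odd kernels
    return kernel // 2


def conv3d_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray, stride: int = 1,
                   return_cols: bool = False):
    """Cross-correlate ``x`` (N,C,D,H,W) with ``w`` (O,C,kd,kh,kw), 'same' padding.

    Returns ``y`` of shape (N, O, D', H', W') with D' = ceil-ish (D+2p-k)//s + 1.
    """
    n, c, _, _, _ = x.shape
    o, c2, kd, kh, kw = w.shape
    if c != c2:
        raise ValueError(f"channel mismatch: input has {c}, kernel expects {c2}")
    p = (_pad_amount(kd), _pad_amount(kh), _pad_amount(kw))
    xp = np.pad(x, ((0, 0), (0, 0), (p[0], p[0]), (p[1], p[1]), (p[2], p[2])))
    v = sliding_window_view(xp, (kd, kh, kw), axis=(2, 3, 4))
    v = v[:, :, ::stride, ::stride, ::stride]  # (N,C,D',H',W',kd,kh,kw)
    dp, hp, wp = v.shape[2:5]
    cols = np.ascontiguousarray(v.transpose(0, 2, 3, 4, 1, 5, 6, 7))
    cols = cols.reshape(n * dp * hp * wp, c * kd * kh * kw)
    y = cols @ w.reshape(o, -1).T
    y += b
    y = y.reshape(n, dp, hp, wp, o).transpose(0, 4, 1, 2, 3)
    return (y, cols) if return_cols else y


def conv3d_backward(x: np.ndarray, w: np.ndarray, dy: np.ndarray, stride: int = 1,
                    compute_dx: bool = True, cols: np.ndarray | None = None):
    """Gradients of :func:`conv3d_forward` w.r.t. input, weight and bias.

    ``compute_dx=False`` skips the input gradient (first-layer shortcut) and
    returns ``None`` in its place.
    """
    n, c, d, h, wd = x.shape
    o, _, kd, kh, kw = w.shape
    p = (_pad_amount(kd), _pad_amount(kh), _pad_amount(kw))
    dp_, hp_, wp_ = dy.shape[2:]
    dy_flat = dy.transpose(0, 2, 3, 4, 1).reshape(-1, o)  # (NP, O)

    if cols is None:
        xp = np.pad(x, ((0, 0), (0, 0), (p[0], p[0]), (p[1], p[1]), (p[2], p[2])))
        v = sliding_window_view(xp, (kd, kh, kw), axis=(2, 3, 4))
        v = v[:, :, ::stride, ::stride, ::stride]
        cols = np.ascontiguousarray(v.transpose(0, 2, 3, 4, 1, 5, 6, 7))
        cols = cols.reshape(n * dp_ * hp_ * wp_, c * kd * kh * kw)
    dw = (dy_flat.T @ cols).reshape(o, c, kd, kh, kw)
    db = dy_flat.sum(axis=0)
    if not compute_dx:
        return None, dw, db

    dcols = dy_flat @ w.reshape(o, -1)  # (NP, C*k^3)
    dcols = dcols.reshape(n, dp_, hp_, wp_, c, kd, kh, kw)
    dxp = np.zeros((n, c, d + 2 * p[0], h + 2 * p[1], wd + 2 * p[2]),
                   dtype=x.dtype)
    s = stride
    for i in range(kd):
        for j in range(kh):
            for k in range(kw):
                dxp[:, :, i:i + s * dp_:s, j:j + s * hp_:s, k:k + s * wp_:s] += (
                    dcols[:, :, :, :, :, i, j, k].transpose(0, 4, 1, 2, 3)
                )
    dx = dxp[:, :, p[0]:p[0] + d, p[1]:p[1] + h, p[2]:p[2] + wd]
    return dx, dw, db


def avgpool2_forward(x: np.ndarray) -> np.ndarray:
    n, c, d, h, w = x.shape
    if d % 2 or h % 2 or w % 2:
        raise ValueError(f"avg pool 2 requires even spatial dims, got {(d, h, w)}")
    return x.reshape(n, c, d // 2, 2, h // 2, 2, w // 2, 2).mean(axis=(3, 5, 7))


def avgpool2_backward(dy: np.ndarray) -> np.ndarray:
    n, c, d, h, w = dy.shape
    g = dy[:, :, :, None, :, None, :, None] / 8.0
    return np.broadcast_to(g, (n, c, d, 2, h, 2, w, 2)).reshape(n, c, 2 * d, 2 * h, 2 * w)


def upsample2_forward(x: np.ndarray) -> np.ndarray:
    return x.repeat(2, axis=2).repeat(2, axis=3).repeat(2, axis=4)


def upsample2_backward(dy: np.ndarray) -> np.ndarray:
    n, c, d, h, w = dy.shape
    return dy.reshape(n, c, d // 2, 2, h // 2, 2, w // 2, 2).sum(axis=(3, 5, 7))


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out
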