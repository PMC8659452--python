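"""NumPy tensor operations with forward and backward passes.

Layout is NCHW throughout.  Each forward returns (output, cache); each
backward consumes (grad_output, cache) and returns gradients.  Convolutions
use im2col + BLAS matmul; only the group counts that occur in the supported
architectures (1 and C) are implemented.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


# ------------------------------------------------------------------- conv

def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    """(N, C, Ho, Wo, k, k) window view of the padded input."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(x, (k, k), axis=(2, 3))
    return win[:, :, ::stride, ::stride], x.shape


def conv2d_forward(x, w, b, stride=1):
    """w: (Do, C, k, k); b: (Do,) or None; 'same' padding for odd k."""
    do, c, k, _ = w.shape
    pad = k // 2
    win, padded_shape = _im2col(x, k, stride, pad)
    n, _, ho, wo = win.shape[:4]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * k * k)
    out = cols @ w.reshape(do, -1).T
    if b is not None:
        out += b
    out = out.reshape(n, ho, wo, do).transpose(0, 3, 1, 2)
    cache = (cols, x.shape, w.shape, stride, pad, padded_shape)
    return np.ascontiguousarray(out), cache


def conv2d_backward(dy, w, cache, has_bias):
    cols, x_shape, w_shape, stride, pad, padded_shape = cache
    do, c, k, _ = w_shape
    n, _, ho, wo = dy.shape
    dy_mat = dy.transpose(0, 2, 3, 1).reshape(n * ho * wo, do)
    dw = (dy_mat.T @ cols).reshape(w_shape)
    db = dy_mat.sum(axis=0) if has_bias else None
    dcols = (dy_mat @ w.reshape(do, -1)).reshape(n, ho, wo, c, k, k)
    dx_pad = np.zeros(padded_shape, dtype=dy.dtype)
    for i in range(k):
        for j in range(k):
            dx_pad[:, :, i:i + ho * stride:stride, j:j + wo * stride:stride] += \
                dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
    h, wdt = x_shape[2], x_shape[3]
    dx = dx_pad[:, :, pad:pad + h, pad:pad + wdt]
    return dx, dw, db


def depthwise_forward(x, w, b, stride=1):
    """w: (C, k, k) per-channel filters; 'same' padding."""
    c, k, _ = w.shape
    pad = k // 2
    win, padded_shape = _im2col(x, k, stride, pad)  # (N, C, Ho, Wo, k, k)
    out = np.einsum("nchwij,cij->nchw", win, w, optimize=True)
    if b is not None:
        out += b[None, :, None, None]
    cache = (win, x.shape, w.shape, stride, pad, padded_shape)
    return out, cache


def depthwise_backward(dy, w, cache, has_bias):
    win, x_shape, w_shape, stride, pad, padded_shape = cache
    c, k, _ = w_shape
    n, _, ho, wo = dy.shape
    dw = np.einsum("nchw,nchwij->cij", dy, win, optimize=True)
    db = dy.sum(axis=(0, 2, 3)) if has_bias else None
    dx_pad = np.zeros(padded_shape, dtype=dy.dtype)
    for i in range(k):
        for j in range(k):
            dx_pad[:, :, i:i + ho * stride:stride, j:j + wo * stride:stride] += \
                dy * w[None, :, i, j, None, None]
    h, wdt = x_shape[2], x_shape[3]
    dx = dx_pad[:, :, pad:pad + h, pad:pad + wdt]
    return dx, dw, db


# -------------------------------------------------------------- batchnorm

def batchnorm_forward(x, gamma, beta, running, momentum=0.03, eps=1e-5, train=True):
    """running = (mean, var) buffers, updated in place during training."""
    if train:
        mean = x.mean(axis=(0, 2, 3))
        var = x.var(axis=(0, 2, 3))
        running[0][:] = (1 - momentum) * running[0] + momentum * mean
        running[1][:] = (1 - momentum) * running[1] + momentum * var
    else:
        mean, var = running
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
    out = gamma[None, :, None, None] * xhat + beta[None, :, None, None]
    return out, (xhat, inv_std, gamma)


def batchnorm_backward(dy, cache):
    xhat, inv_std, gamma = cache
    m = dy.shape[0] * dy.shape[2] * dy.shape[3]
    dgamma = (dy * xhat).sum(axis=(0, 2, 3))
    dbeta = dy.sum(axis=(0, 2, 3))
    dxhat = dy * gamma[None, :, None, None]
    dx = (inv_std[None, :, None, None] / m) * (
        m * dxhat
        - dxhat.sum(axis=(0, 2, 3), keepdims=True)
        - xhat * (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
    )
    return dx, dgamma, dbeta


# ------------------------------------------------------------- activations

def activation_forward(x, kind):
    if kind == "leaky_relu":
        return np.where(x > 0, x, 0.1 * x), x
    if kind == "relu":
        return np.maximum(x, 0), x
    if kind == "relu6":
        return np.clip(x, 0, 6), x
    if kind == "mish":
        sp = np.log1p(np.exp(-np.abs(x))) + np.maximum(x, 0)  # stable softplus
        return x * np.tanh(sp), x
    if kind == "h_swish":
        return x * np.clip(x + 3, 0, 6) / 6.0, x
    if kind == "h_sigmoid":
        return np.clip(x + 3, 0, 6) / 6.0, x
    if kind == "sigmoid":
        return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60))), x
    if kind == "linear":
        return x, x
    raise ValueError(f"unknown activation {kind!r}")


def activation_backward(dy, x, kind):
    if kind == "leaky_relu":
        return dy * np.where(x > 0, 1.0, 0.1)
    if kind == "relu":
        return dy * (x > 0)
    if kind == "relu6":
        return dy * ((x > 0) & (x < 6))
    if kind == "mish":
        sp = np.log1p(np.exp(-np.abs(x))) + np.maximum(x, 0)
        t = np.tanh(sp)
        sig = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
        return dy * (t + x * (1 - t * t) * sig)
    if kind == "h_swish":
        g = np.where(x <= -3, 0.0, np.where(x >= 3, 1.0, (2 * x + 3) / 6.0))
        return dy * g
    if kind == "h_sigmoid":
        return dy * np.where((x > -3) & (x < 3), 1.0 / 6.0, 0.0)
    if kind == "sigmoid":
        s = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
        return dy * s * (1 - s)
    if kind == "linear":
        return dy
    raise ValueError(f"unknown activation {kind!r}")


# ------------------------------------------------------------------ pools

def maxpool_forward(x, k, stride):
    if k == stride == 2:
        n, c, h, w = x.shape
        h2, w2 = h // 2, w // 2
        v = x[:, :, : h2 * 2, : w2 * 2].reshape(n, c, h2, 2, w2, 2)
        out = v.max(axis=(3, 5))
        mask = v == out[:, :, :, None, :, None]
        return out, ("s2", mask, x.shape)
    # stride-1 'same' pooling (SPP); forward only
    pad = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)), constant_values=-np.inf)
    win = sliding_window_view(xp, (k, k), axis=(2, 3))
    return win.max(axis=(4, 5)), ("spp", None, x.shape)


def maxpool_backward(dy, cache):
    tag, mask, x_shape = cache
    if tag != "s2":
        raise NotImplementedError("backward implemented only for 2x2/2 pooling")
    n, c, h, w = x_shape
    h2, w2 = h // 2, w // 2
    dv = mask * dy[:, :, :, None, :, None]
    dx = np.zeros(x_shape, dtype=dy.dtype)
    dx[:, :, : h2 * 2, : w2 * 2] = dv.reshape(n, c, h2 * 2, w2 * 2)
    return dx


def upsample_forward(x):
    return x.repeat(2, axis=2).repeat(2, axis=3), x.shape


def upsample_backward(dy, x_shape):
    n, c, h, w = x_shape
    return dy.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5))


def global_pool_forward(x):
    return x.mean(axis=(2, 3)), x.shape


def global_pool_backward(dy, x_shape):
    n, c, h, w = x_shape
    return np.broadcast_to(dy[:, :, None, None], x_shape) / (h * w)


def dense_forward(x, w, b):
    """x: (N, Di); w: (Do, Di)."""
    return x @ w.T + b, x


def dense_backward(dy, w, x):
    return dy @ w, dy.T @ x, dy.sum(axis=0)


def se_scale_forward(x, gate):
    """gate: (N, C) channel weights."""
    return x * gate[:, :, None, None], (x, gate)


def se_scale_backward(dy, cache):
    x, gate = cache
    dx = dy * gate[:, :, None, None]
    dgate = (dy * x).sum(axis=(2, 3))
    return dx, dgate
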