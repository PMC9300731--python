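"""Minimal neural-network primitives on numpy.

Every operation comes as a forward function returning ``(output, cache)``
and a matching backward function mapping the upstream gradient to input
(and, where applicable, weight) gradients.  Convolutions are evaluated as
batched GEMMs over im2col patch matrices, which is where essentially all
of the training time goes, so those two functions are written for speed;
everything else favors clarity.

Conventions: activations are ``float32`` arrays in ``(B, C, H, W)``
layout; weights of a k x k convolution are stored as ``(C_out, C_in*k*k)``
so that the forward pass is a single matmul per image batch.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

DTYPE = np.float32


class Parameter:
    """A named trainable array with an optional gradient slot."""

    __slots__ = ("name", "data", "grad")

    def __init__(self, name: str, data: np.ndarray):
        self.name = name
        self.data = np.ascontiguousarray(data, dtype=DTYPE)
        self.grad = None

    @property
    def size(self) -> int:
        return self.data.size

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Parameter({self.name}, shape={self.data.shape})"


def kaiming_uniform(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    """Kaiming-uniform draw with ReLU gain: U(-b, b), b = sqrt(6 / fan_in)."""
    bound = math.sqrt(6.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(DTYPE)


# ---------------------------------------------------------------------------
# convolution


@njit(cache=True)
def _im2col3_fill(x, cols):
    b, c, h, w = x.shape
    n = b * h * w
    for ci in range(c):
        for ky in range(3):
            for kx in range(3):
                row = (ci * 3 + ky) * 3 + kx
                for bi in range(b):
                    for y in range(h):
                        sy = y + ky - 1
                        base = (bi * h + y) * w
                        if sy < 0 or sy >= h:
                            for xx in range(w):
                                cols[row, base + xx] = 0.0
                        else:
                            for xx in range(w):
                                sx = xx + kx - 1
                                if sx < 0 or sx >= w:
                                    cols[row, base + xx] = 0.0
                                else:
                                    cols[row, base + xx] = x[bi, ci, sy, sx]
    return cols


@njit(cache=True)
def _col2im3_accum(dcols, dx):
    b, c, h, w = dx.shape
    for ci in range(c):
        for ky in range(3):
            for kx in range(3):
                row = (ci * 3 + ky) * 3 + kx
                for bi in range(b):
                    for y in range(h):
                        sy = y + ky - 1
                        if sy < 0 or sy >= h:
                            continue
                        base = (bi * h + y) * w
                        for xx in range(w):
                            sx = xx + kx - 1
                            if 0 <= sx < w:
                                dx[bi, ci, sy, sx] += dcols[row, base + xx]
    return dx


@njit(cache=True)
def _nchw_to_cn(src, dst):
    # (B, C, H, W) -> (C, B*H*W)
    b, c, h, w = src.shape
    for ci in range(c):
        for bi in range(b):
            for y in range(h):
                base = (bi * h + y) * w
                for xx in range(w):
                    dst[ci, base + xx] = src[bi, ci, y, xx]
    return dst


@njit(cache=True)
def _cn_to_nchw(src, dst):
    # (C, B*H*W) -> (B, C, H, W)
    b, c, h, w = dst.shape
    for ci in range(c):
        for bi in range(b):
            for y in range(h):
                base = (bi * h + y) * w
                for xx in range(w):
                    dst[bi, ci, y, xx] = src[ci, base + xx]
    return dst


def _im2col3(x: np.ndarray) -> np.ndarray:
    """Patch matrix of a 3x3/pad-1/stride-1 convolution: (C*9, B*H*W).

    Channel-major layout so the convolution is ONE large GEMM per layer,
    which keeps BLAS efficient even for narrow output widths.
    """
    b, c, h, w = x.shape
    cols = np.empty((c * 9, b * h * w), dtype=x.dtype)
    return _im2col3_fill(np.ascontiguousarray(x), cols)


def conv3x3_forward(x: np.ndarray, w: Parameter, bias: Parameter):
    """3x3 same-padding convolution; weight shape (C_out, C_in*9)."""
    b, c, h, wd = x.shape
    cols = _im2col3(x)
    out = w.data @ cols  # (C_out, B*H*W)
    out += bias.data[:, None]
    res = np.empty((b, out.shape[0], h, wd), dtype=out.dtype)
    return _cn_to_nchw(out, res), (x, cols)


def conv3x3_backward(dout: np.ndarray, cache, w: Parameter, bias: Parameter):
    x, cols = cache
    b, c, h, wd = x.shape
    c_out = w.data.shape[0]
    dflat = np.empty((c_out, b * h * wd), dtype=dout.dtype)
    _nchw_to_cn(np.ascontiguousarray(dout), dflat)
    w.grad = _accum(w.grad, dflat @ cols.T)
    bias.grad = _accum(bias.grad, dflat.sum(axis=1))
    dcols = w.data.T @ dflat
    dx = np.zeros((b, c, h, wd), dtype=x.dtype)
    return _col2im3_accum(dcols, dx)


def conv1x1_forward(x: np.ndarray, w: Parameter, bias: Parameter):
    b, c, h, wd = x.shape
    flat = x.reshape(b, c, h * wd)
    out = np.matmul(w.data, flat) + bias.data[:, None]
    return out.reshape(b, -1, h, wd), (x,)


def conv1x1_backward(dout: np.ndarray, cache, w: Parameter, bias: Parameter):
    (x,) = cache
    b, c, h, wd = x.shape
    dflat = dout.reshape(b, -1, h * wd)
    flat = x.reshape(b, c, h * wd)
    w.grad = _accum(w.grad, np.matmul(dflat, flat.transpose(0, 2, 1)).sum(axis=0))
    bias.grad = _accum(bias.grad, dflat.sum(axis=(0, 2)))
    return np.matmul(w.data.T, dflat).reshape(b, c, h, wd)


def _accum(slot, g):
    return g if slot is None else slot + g


# ---------------------------------------------------------------------------
# pooling / upsampling


@njit(cache=True)
def _maxpool2_fwd(x, out, idx):
    b, c, hh, ww = out.shape
    for bi in range(b):
        for ci in range(c):
            for y in range(hh):
                for xx in range(ww):
                    best = x[bi, ci, 2 * y, 2 * xx]
                    k = 0
                    for dy in range(2):
                        for dx in range(2):
                            v = x[bi, ci, 2 * y + dy, 2 * xx + dx]
                            if v > best:
                                best = v
                                k = dy * 2 + dx
                    out[bi, ci, y, xx] = best
                    idx[bi, ci, y, xx] = k


@njit(cache=True)
def _maxpool2_bwd(dout, idx, dx):
    b, c, hh, ww = dout.shape
    for bi in range(b):
        for ci in range(c):
            for y in range(hh):
                for xx in range(ww):
                    k = idx[bi, ci, y, xx]
                    dx[bi, ci, 2 * y + k // 2, 2 * xx + k % 2] = dout[bi, ci, y, xx]


def maxpool2_forward(x: np.ndarray):
    b, c, h, w = x.shape
    x = np.ascontiguousarray(x)
    out = np.empty((b, c, h // 2, w // 2), dtype=x.dtype)
    idx = np.empty((b, c, h // 2, w // 2), dtype=np.int8)
    _maxpool2_fwd(x, out, idx)
    return out, (idx, x.shape)


def maxpool2_backward(dout: np.ndarray, cache):
    idx, shape = cache
    dx = np.zeros(shape, dtype=dout.dtype)
    _maxpool2_bwd(np.ascontiguousarray(dout), idx, dx)
    return dx


# Bilinear x2 with half-pixel centers, per axis: output 2k is
# 0.75 x[k] + 0.25 x[k-1], output 2k+1 is 0.75 x[k] + 0.25 x[k+1],
# edges clamped.  The 2-D kernel applies the row pass then the column
# pass per element; the backward kernel is its exact adjoint.


@njit(cache=True)
def _upsample2_fwd(x, out):
    b, c, h, w = x.shape
    for bi in range(b):
        for ci in range(c):
            for i in range(2 * h):
                k = i // 2  # near neighbor (weight 0.75); kk far (0.25)
                kk = (k - 1 if k > 0 else 0) if i % 2 == 0 else (k + 1 if k + 1 < h else h - 1)
                for j in range(2 * w):
                    l = j // 2
                    ll = (l - 1 if l > 0 else 0) if j % 2 == 0 else (l + 1 if l + 1 < w else w - 1)
                    rn = 0.75 * x[bi, ci, k, l] + 0.25 * x[bi, ci, k, ll]
                    rf = 0.75 * x[bi, ci, kk, l] + 0.25 * x[bi, ci, kk, ll]
                    out[bi, ci, i, j] = 0.75 * rn + 0.25 * rf


@njit(cache=True)
def _upsample2_bwd(dout, dx):
    b, c, h, w = dx.shape
    for bi in range(b):
        for ci in range(c):
            for i in range(2 * h):
                k = i // 2
                kk = (k - 1 if k > 0 else 0) if i % 2 == 0 else (k + 1 if k + 1 < h else h - 1)
                for j in range(2 * w):
                    l = j // 2
                    ll = (l - 1 if l > 0 else 0) if j % 2 == 0 else (l + 1 if l + 1 < w else w - 1)
                    g = dout[bi, ci, i, j]
                    dx[bi, ci, k, l] += 0.75 * 0.75 * g
                    dx[bi, ci, k, ll] += 0.75 * 0.25 * g
                    dx[bi, ci, kk, l] += 0.25 * 0.75 * g
                    dx[bi, ci, kk, ll] += 0.25 * 0.25 * g


def upsample2_forward(x: np.ndarray):
    """Parameter-free bilinear doubling of both spatial axes."""
    b, c, h, w = x.shape
    x = np.ascontiguousarray(x)
    out = np.empty((b, c, 2 * h, 2 * w), dtype=x.dtype)
    _upsample2_fwd(x, out)
    return out, (x.shape,)


def upsample2_backward(dout: np.ndarray, cache=None):
    if cache is None:
        b, c, h2, w2 = dout.shape
        shape = (b, c, h2 // 2, w2 // 2)
    else:
        (shape,) = cache
    dx = np.zeros(shape, dtype=dout.dtype)
    _upsample2_bwd(np.ascontiguousarray(dout), dx)
    return dx


# ---------------------------------------------------------------------------
# pointwise / dense


def relu_forward(x: np.ndarray):
    out = np.maximum(x, 0)
    return out, (out,)


def relu_backward(dout: np.ndarray, cache):
    (out,) = cache  # out > 0 exactly where x > 0
    return dout * (out > 0)


def sigmoid(x: np.ndarray) -> np.ndarray:
    # evaluated in float64 to keep extreme logits finite, returned as input dtype
    with np.errstate(over="ignore"):
        out = 1.0 / (1.0 + np.exp(-x.astype(np.float64)))
    return out.astype(x.dtype)


def linear_forward(x: np.ndarray, w: Parameter, bias: Parameter):
    """Dense layer; weight shape (n_out, n_in), input (B, n_in)."""
    return x @ w.data.T + bias.data, (x,)


def linear_backward(dout: np.ndarray, cache, w: Parameter, bias: Parameter):
    (x,) = cache
    w.grad = _accum(w.grad, dout.T @ x)
    bias.grad = _accum(bias.grad, dout.sum(axis=0))
    return dout @ w.data


def global_avg_pool_forward(x: np.ndarray):
    b, c, h, w = x.shape
    return x.mean(axis=(2, 3)), (x.shape,)


def global_avg_pool_backward(dout: np.ndarray, cache):
    (shape,) = cache
    b, c, h, w = shape
    return np.broadcast_to(dout[:, :, None, None] / (h * w), shape).astype(dout.dtype)
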