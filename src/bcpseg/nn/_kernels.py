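"""Compute kernels behind the neural-network layers.

Convolutions run as nine batched strided matmuls (one per kernel tap) —
BLAS sees contiguous (W, C) panels of the channels-last tensor, so no
im2col patch matrix is ever materialised. Batch-norm and max-pool have
numba-fused single-pass kernels for float32, with NumPy fallbacks that
preserve the input dtype (used by the float64 gradient checks).
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an install requirement
    HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore[misc]
        def wrap(f):
            return f
        return wrap


def _pad(x: np.ndarray, p: int) -> np.ndarray:
    if p == 0:
        return x
    return np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))


# -- convolution ------------------------------------------------------------


def conv_forward(x: np.ndarray, weight: np.ndarray, bias: np.ndarray,
                 pad: int):
    """'Same' stride-1 convolution; returns (out, padded input for backward).

    ``weight`` has layout (k, k, C_in, C_out); ``x`` is (N, H, W, C_in).
    """
    k = weight.shape[0]
    n, h, w = x.shape[0], x.shape[1], x.shape[2]
    co = weight.shape[3]
    if k == 1:
        out = x.reshape(-1, x.shape[3]) @ weight[0, 0] + bias
        return out.reshape(n, h, w, co), x
    xp = _pad(x, pad)
    out = np.empty((n, h, w, co), dtype=x.dtype)
    out[...] = bias
    for ki in range(k):
        for kj in range(k):
            np.add(out, xp[:, ki:ki + h, kj:kj + w, :] @ weight[ki, kj],
                   out=out)
    return out, xp


def conv_backward(dout: np.ndarray, xp: np.ndarray, weight: np.ndarray,
                  pad: int, want_bias: bool = True, want_dx: bool = True):
    """Returns (dx, dweight, dbias); ``xp`` is the saved padded input."""
    k = weight.shape[0]
    c_in, c_out = weight.shape[2], weight.shape[3]
    n, h, w = dout.shape[0], dout.shape[1], dout.shape[2]
    dbias = dout.sum(axis=(0, 1, 2)) if want_bias else None
    dmat = dout.reshape(-1, c_out)
    if k == 1:
        dweight = (xp.reshape(-1, c_in).T @ dmat).reshape(weight.shape)
        dx = (dmat @ weight[0, 0].T).reshape(n, h, w, c_in)
        return dx, dweight, dbias
    # dW via full-width bands: one zero-embedded copy of dout per kj tap,
    # then per-ki batched GEMMs over contiguous (h*Wp, C) panels
    wp = xp.shape[2]
    dweight = np.empty_like(weight)
    for kj in range(k):
        dpw = np.zeros((n, h, wp, c_out), dtype=dout.dtype)
        dpw[:, :, kj:kj + w] = dout
        dpwf = dpw.reshape(n, h * wp, c_out)
        for ki in range(k):
            band = xp[:, ki:ki + h].reshape(n, h * wp, c_in)
            dweight[ki, kj] = np.matmul(
                band.transpose(0, 2, 1), dpwf).sum(axis=0)
    if not want_dx:
        return None, dweight, dbias
    # dx = dout (*) flipped kernel, channels transposed; 'same' padding
    dp = _pad(dout, k - 1 - pad)
    dx = np.zeros((n, h, w, c_in), dtype=dout.dtype)
    for ki in range(k):
        for kj in range(k):
            wf = weight[k - 1 - ki, k - 1 - kj].T
            np.add(dx, dp[:, ki:ki + h, kj:kj + w, :] @ wf, out=dx)
    return dx, dweight, dbias


# -- batch norm -------------------------------------------------------------


@njit(fastmath=True, cache=False)
def _bn_stats_jit(x2d):  # pragma: no cover - thin numba wrapper
    n, c = x2d.shape
    s = np.zeros(c, dtype=np.float64)
    sq = np.zeros(c, dtype=np.float64)
    for i in range(n):
        for j in range(c):
            v = x2d[i, j]
            s[j] += v
            sq[j] += v * v
    mean = (s / n).astype(np.float32)
    var = (sq / n).astype(np.float32) - mean * mean
    return mean, np.maximum(var, 0.0)


@njit(fastmath=True, cache=False)
def _bn_norm_jit(x2d, mean, inv, gamma, beta, relu):  # pragma: no cover
    n, c = x2d.shape
    xhat = np.empty((n, c), dtype=np.float32)
    out = np.empty((n, c), dtype=np.float32)
    for i in range(n):
        for j in range(c):
            v = (x2d[i, j] - mean[j]) * inv[j]
            xhat[i, j] = v
            o = gamma[j] * v + beta[j]
            if relu and o < 0.0:
                o = 0.0
            out[i, j] = o
    return xhat, out


@njit(fastmath=True, cache=False)
def _bn_bwd_reduce_jit(dout2d, xhat):  # pragma: no cover
    n, c = dout2d.shape
    s1 = np.zeros(c, dtype=np.float64)
    s2 = np.zeros(c, dtype=np.float64)
    for i in range(n):
        for j in range(c):
            d = dout2d[i, j]
            s1[j] += d
            s2[j] += d * xhat[i, j]
    return s1.astype(np.float32), s2.astype(np.float32)


@njit(fastmath=True, cache=False)
def _bn_bwd_dx_jit(dout2d, xhat, gamma, inv, s1, s2):  # pragma: no cover
    n, c = dout2d.shape
    dx = np.empty((n, c), dtype=np.float32)
    for i in range(n):
        for j in range(c):
            dx[i, j] = (dout2d[i, j] - s1[j] / n
                        - xhat[i, j] * (s2[j] / n)) * gamma[j] * inv[j]
    return dx


# -- max pool ---------------------------------------------------------------


@njit(fastmath=True, cache=False)
def _pool_fwd_jit(x):  # pragma: no cover - thin numba wrapper
    n_im, h, w, c = x.shape
    ho, wo = h // 2, w // 2
    out = np.empty((n_im, ho, wo, c), dtype=np.float32)
    arg = np.empty((n_im, ho, wo, c), dtype=np.uint8)
    for n in range(n_im):
        for i in range(ho):
            for j in range(wo):
                for ch in range(c):
                    best = x[n, 2 * i, 2 * j, ch]
                    bidx = 0
                    idx = 1
                    for a in range(2):
                        for b in range(2):
                            if a or b:
                                v = x[n, 2 * i + a, 2 * j + b, ch]
                                if v > best:
                                    best = v
                                    bidx = idx
                                idx += 1
                            else:
                                pass
                    out[n, i, j, ch] = best
                    arg[n, i, j, ch] = bidx
    return out, arg


@njit(fastmath=True, cache=False)
def _pool_bwd_jit(dout, arg):  # pragma: no cover - thin numba wrapper
    n_im, ho, wo, c = dout.shape
    dx = np.zeros((n_im, 2 * ho, 2 * wo, c), dtype=np.float32)
    for n in range(n_im):
        for i in range(ho):
            for j in range(wo):
                for ch in range(c):
                    k = arg[n, i, j, ch]
                    dx[n, 2 * i + k // 2, 2 * j + k % 2, ch] = \
                        dout[n, i, j, ch]
    return dx
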