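"""Minimal NumPy neural-network layers with hand-written backprop.

Everything here operates on float32 NHWC tensors — channels-last is the
cache-friendly layout for CPU convolutions via BLAS. Each layer owns its
trainable parameters in ``params`` (dict name -> array), matching gradient
arrays in ``grads``, and non-trainable state (batch-norm running statistics)
in ``buffers``. A layer caches whatever it needs from the last
``forward(train=True)`` call so that a single subsequent ``backward`` can be
evaluated.
"""

from __future__ import annotations

import numpy as np

from ._kernels import (
    HAVE_NUMBA,
    _bn_bwd_dx_jit,
    _bn_bwd_reduce_jit,
    _bn_norm_jit,
    _bn_stats_jit,
    _pool_bwd_jit,
    _pool_fwd_jit,
    conv_backward,
    conv_forward,
)


class Layer:
    """Base class: parameter-free identity."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.buffers: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def zero_grad(self) -> None:
        for k in self.params:
            self.grads[k] = np.zeros_like(self.params[k])


def kaiming_conv(rng: np.random.Generator, shape: tuple[int, ...],
                 fan_in: int) -> np.ndarray:
    """He-normal initialisation for convolution weights."""
    std = np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(np.float32)


class Conv2d(Layer):
    """k x k convolution, stride 1, 'same' zero padding (k odd).

    Compute is delegated to :mod:`._kernels` (batched strided matmuls,
    one per kernel tap). The input gradient is a convolution of the
    output gradient with the spatially flipped, channel-transposed
    kernel, so no scatter-add is needed. Weight layout:
    (k, k, C_in, C_out).
    """

    def __init__(self, in_ch: int, out_ch: int, ksize: int,
                 rng: np.random.Generator, bias: bool = True,
                 track_input_grad: bool = True) -> None:
        super().__init__()
        if ksize % 2 != 1:
            raise ValueError("Conv2d supports odd kernel sizes only")
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, ksize
        self.pad = ksize // 2
        self.use_bias = bias
        # the network's very first conv never needs d(loss)/d(input)
        self.track_input_grad = track_input_grad
        fan_in = in_ch * ksize * ksize
        self.params["weight"] = kaiming_conv(
            rng, (ksize, ksize, in_ch, out_ch), fan_in)
        # bias is redundant (and its gradient exactly zero) when the conv
        # feeds a batch-norm layer, so blocks disable it
        if bias:
            self.params["bias"] = np.zeros(out_ch, dtype=np.float32)
        self._zero_bias = np.zeros(out_ch, dtype=np.float32)
        self.zero_grad()
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.shape[3] != self.in_ch:
            raise ValueError(
                f"expected {self.in_ch} channels, got {x.shape[3]}")
        bias = self.params["bias"] if self.use_bias else self._zero_bias
        out, xp = conv_forward(x, self.params["weight"], bias, self.pad)
        if train:
            self._cache = xp
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._cache is None:
            raise RuntimeError("backward before forward(train=True)")
        xp = self._cache
        self._cache = None
        dx, dweight, dbias = conv_backward(
            dout, xp, self.params["weight"], self.pad,
            want_bias=self.use_bias, want_dx=self.track_input_grad)
        self.grads["weight"] += dweight
        if self.use_bias:
            self.grads["bias"] += dbias
        return dx


class BatchNorm2d(Layer):
    """Batch normalisation over (N, H, W) per channel, channels-last.

    With ``relu=True`` the trailing ReLU of a conv-BN-ReLU block is fused
    into this layer (identical math, one fewer full pass over the tensor).
    """

    def __init__(self, ch: int, momentum: float = 0.1,
                 eps: float = 1e-5, relu: bool = False) -> None:
        super().__init__()
        self.ch, self.momentum, self.eps = ch, momentum, eps
        self.relu = relu
        self.params["gamma"] = np.ones(ch, dtype=np.float32)
        self.params["beta"] = np.zeros(ch, dtype=np.float32)
        self.buffers["running_mean"] = np.zeros(ch, dtype=np.float32)
        self.buffers["running_var"] = np.ones(ch, dtype=np.float32)
        self.zero_grad()
        self._cache: tuple | None = None

    @staticmethod
    def _use_jit(x: np.ndarray) -> bool:
        return HAVE_NUMBA and x.dtype == np.float32

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        jit = self._use_jit(x)
        if train:
            if jit:
                x2d = np.ascontiguousarray(x).reshape(-1, self.ch)
                mean, var = _bn_stats_jit(x2d)
            else:
                mean = x.mean(axis=(0, 1, 2))
                var = x.var(axis=(0, 1, 2))
            m = self.momentum
            n = x.shape[0] * x.shape[1] * x.shape[2]
            unbiased = var * (n / max(n - 1, 1))
            self.buffers["running_mean"] *= (1 - m)
            self.buffers["running_mean"] += (m * mean).astype(np.float32)
            self.buffers["running_var"] *= (1 - m)
            self.buffers["running_var"] += (m * unbiased).astype(np.float32)
        else:
            # inference: fold into a single affine pass over x
            mean = self.buffers["running_mean"]
            var = self.buffers["running_var"]
            inv = 1.0 / np.sqrt(var + self.eps)
            a = self.params["gamma"] * inv
            out = x * a + (self.params["beta"] - a * mean)
            if self.relu:
                out = np.maximum(out, 0.0)
            return out.astype(x.dtype, copy=False)
        inv = 1.0 / np.sqrt(var + self.eps)
        if train and jit:
            xhat2d, out2d = _bn_norm_jit(
                x2d, mean, inv.astype(np.float32),
                self.params["gamma"], self.params["beta"], self.relu)
            mask = (out2d > 0) if self.relu else None
            self._cache = (xhat2d, inv.astype(np.float32), mask)
            return out2d.reshape(x.shape)
        xhat = (x - mean) * inv
        out = self.params["gamma"] * xhat + self.params["beta"]
        if self.relu:
            out = np.maximum(out, 0.0)
        if train:
            self._cache = (xhat, inv, (out > 0) if self.relu else None)
        return out.astype(x.dtype, copy=False)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._cache is None:
            raise RuntimeError("backward before forward(train=True)")
        xhat, inv, mask = self._cache
        self._cache = None
        n = dout.shape[0] * dout.shape[1] * dout.shape[2]
        if self._use_jit(dout) and xhat.ndim == 2:
            d2d = np.ascontiguousarray(dout).reshape(-1, self.ch)
            if mask is not None:
                d2d = d2d * mask
            s1, s2 = _bn_bwd_reduce_jit(d2d, xhat)
            self.grads["beta"] += s1
            self.grads["gamma"] += s2
            dx = _bn_bwd_dx_jit(d2d, xhat, self.params["gamma"],
                                inv, s1, s2)
            return dx.reshape(dout.shape)
        if mask is not None:
            dout = dout * mask.reshape(dout.shape)
        self.grads["gamma"] += (dout * xhat).sum(axis=(0, 1, 2))
        self.grads["beta"] += dout.sum(axis=(0, 1, 2))
        dxhat = dout * self.params["gamma"]
        s1 = dxhat.sum(axis=(0, 1, 2))
        s2 = (dxhat * xhat).sum(axis=(0, 1, 2))
        dx = (dxhat - s1 / n - xhat * (s2 / n)) * inv
        return dx.astype(dout.dtype, copy=False)


class ReLU(Layer):
    def __init__(self) -> None:
        super().__init__()
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._mask is None:
            raise RuntimeError("backward before forward(train=True)")
        dx = dout * self._mask
        self._mask = None
        return dx


class MaxPool2d(Layer):
    """2x2 max pooling, stride 2. Ties break to the first window element."""

    def __init__(self) -> None:
        super().__init__()
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ValueError("MaxPool2d needs even spatial dims")
        if HAVE_NUMBA and x.dtype == np.float32:
            out, arg = _pool_fwd_jit(np.ascontiguousarray(x))
        else:
            xf = x.reshape(n, h // 2, 2, w // 2, 2, c)
            xf = np.ascontiguousarray(xf.transpose(0, 1, 3, 5, 2, 4))
            xf = xf.reshape(n, h // 2, w // 2, c, 4)
            arg = xf.argmax(axis=-1)
            out = np.take_along_axis(xf, arg[..., None], axis=-1)[..., 0]
        if train:
            self._cache = (arg, x.shape)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._cache is None:
            raise RuntimeError("backward before forward(train=True)")
        arg, xshape = self._cache
        self._cache = None
        n, h, w, c = xshape
        if HAVE_NUMBA and dout.dtype == np.float32 and arg.dtype == np.uint8:
            return _pool_bwd_jit(np.ascontiguousarray(dout), arg)
        dxf = np.zeros((n, h // 2, w // 2, c, 4), dtype=dout.dtype)
        np.put_along_axis(dxf, arg[..., None], dout[..., None], axis=-1)
        dx = dxf.reshape(n, h // 2, w // 2, c, 2, 2)
        dx = dx.transpose(0, 1, 4, 2, 5, 3).reshape(n, h, w, c)
        return np.ascontiguousarray(dx)


class ConvTranspose2d(Layer):
    """2x2 transposed convolution with stride 2 (learned upsampling).

    Kernel size equals stride, so output blocks do not overlap and both
    directions reduce to a single tensordot. Weight layout: (2, 2, C_in,
    C_out).
    """

    def __init__(self, in_ch: int, out_ch: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        self.in_ch, self.out_ch = in_ch, out_ch
        self.params["weight"] = kaiming_conv(
            rng, (2, 2, in_ch, out_ch), in_ch)
        self.params["bias"] = np.zeros(out_ch, dtype=np.float32)
        self.zero_grad()
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, h, w, c = x.shape
        # (N,H,W,2,2,Co) -> (N,H,2,W,2,Co) -> (N,2H,2W,Co)
        t = np.tensordot(x, self.params["weight"], axes=([3], [2]))
        out = np.ascontiguousarray(t.transpose(0, 1, 3, 2, 4, 5))
        out = out.reshape(n, 2 * h, 2 * w, self.out_ch)
        out += self.params["bias"]
        if train:
            self._x = x
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._x is None:
            raise RuntimeError("backward before forward(train=True)")
        x = self._x
        self._x = None
        n, h2, w2, co = dout.shape
        h, w = h2 // 2, w2 // 2
        dblk = dout.reshape(n, h, 2, w, 2, co).transpose(0, 1, 3, 2, 4, 5)
        dblk = np.ascontiguousarray(dblk)  # (N,H,W,2,2,Co)
        self.grads["weight"] += np.tensordot(
            x, dblk, axes=([0, 1, 2], [0, 1, 2])).transpose(1, 2, 0, 3)
        self.grads["bias"] += dout.sum(axis=(0, 1, 2))
        dx = np.tensordot(dblk, self.params["weight"],
                          axes=([3, 4, 5], [0, 1, 3]))
        return dx.astype(dout.dtype, copy=False)


class NearestUpsample2d(Layer):
    """Parameter-free 2x nearest-neighbour upsampling (alternative to the
    learned transposed convolution)."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return np.repeat(np.repeat(x, 2, axis=1), 2, axis=2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h2, w2, c = dout.shape
        return dout.reshape(n, h2 // 2, 2, w2 // 2, 2, c).sum(axis=(2, 4))
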