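"""Minimal 3D neural-network primitives on NumPy.

Layers operate on channels-last batches ``(n, d, w, h, c)`` in float32.
Convolutions are realised as im2col + BLAS matmul; the backward pass for
the input is the correlation of the output gradient with the spatially
flipped, channel-transposed kernel, so both directions go through the
same fast path.  Every layer exposes ``params()`` / ``grads()`` so the
Adam optimizer can treat the model as a flat list of arrays.
"""

from __future__ import annotations

import numpy as np

from .errors import DomainError

DTYPE = np.float32  # tests may switch to float64 for finite-difference checks

__all__ = [
    "DTYPE",
    "configure_malloc",
    "truncated_normal",
    "Conv3dSame",
    "BatchNorm",
    "ReLU",
    "MaxPool3d",
    "Flatten",
    "Linear",
    "softmax",
    "softmax_cross_entropy_sum",
    "Adam",
]


_MALLOC_CONFIGURED = False


def configure_malloc():
    """Keep large freed blocks in the glibc heap instead of unmapping them.

    Training allocates and frees ~2 GB of buffers per mini-batch; with the
    default mmap threshold glibc returns them to the kernel on free, and
    the resulting page-fault storm dominates runtime on slow-fault kernels
    (5-10x observed).  Safe no-op on non-glibc platforms.
    """
    global _MALLOC_CONFIGURED
    if _MALLOC_CONFIGURED:
        return
    _MALLOC_CONFIGURED = True
    try:
        import ctypes

        libc = ctypes.CDLL("libc.so.6")
        libc.mallopt(-3, 1 << 30)  # M_MMAP_THRESHOLD
        libc.mallopt(-1, 1 << 30)  # M_TRIM_THRESHOLD
    except Exception:
        pass


def truncated_normal(rng: np.random.Generator, shape, sd: float, bound_sds: float = 2.0) -> np.ndarray:
    """Normal(0, sd) samples with values beyond ``bound_sds``·sd resampled."""
    out = rng.normal(0.0, sd, size=shape)
    bad = np.abs(out) > bound_sds * sd
    while bad.any():
        out[bad] = rng.normal(0.0, sd, size=int(bad.sum()))
        bad = np.abs(out) > bound_sds * sd
    return out.astype(DTYPE)


class Layer:
    def params(self):
        return []

    def grads(self):
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _offsets():
    for kd in range(3):
        for kw in range(3):
            for kh in range(3):
                yield kd, kw, kh


def _im2col_3x3x3(x: np.ndarray) -> np.ndarray:
    """(n,d,w,h,c) -> (n*d*w*h, 27*c) columns for a SAME 3x3x3 window.

    Built with 27 strided slice copies from the zero-padded volume, which
    is far cheaper than materialising a transposed sliding-window view.
    """
    n, d, w, h, c = x.shape
    xp = np.zeros((n, d + 2, w + 2, h + 2, c), dtype=DTYPE)
    xp[:, 1 : d + 1, 1 : w + 1, 1 : h + 1, :] = x
    if c == 1:
        # single channel: write k-major (contiguous per offset), hand BLAS
        # the Fortran-ordered transpose view
        xp3 = xp[..., 0]
        colsT = np.empty((27, n, d, w, h), dtype=DTYPE)
        for k, (kd, kw, kh) in enumerate(_offsets()):
            colsT[k] = xp3[:, kd : kd + d, kw : kw + w, kh : kh + h]
        return colsT.reshape(27, n * d * w * h).T
    cols = np.empty((n, d, w, h, 27, c), dtype=DTYPE)
    for k, (kd, kw, kh) in enumerate(_offsets()):
        cols[:, :, :, :, k, :] = xp[:, kd : kd + d, kw : kw + w, kh : kh + h, :]
    return cols.reshape(n * d * w * h, 27 * c)


def _col2im_3x3x3(dcols: np.ndarray, shape) -> np.ndarray:
    """Scatter-add (n*v, 27*c) column gradients back onto the input grid."""
    n, d, w, h, c = shape
    dc = dcols.reshape(n, d, w, h, 27, c)
    dxp = np.zeros((n, d + 2, w + 2, h + 2, c), dtype=DTYPE)
    for k, (kd, kw, kh) in enumerate(_offsets()):
        dxp[:, kd : kd + d, kw : kw + w, kh : kh + h, :] += dc[:, :, :, :, k, :]
    return np.ascontiguousarray(dxp[:, 1 : d + 1, 1 : w + 1, 1 : h + 1, :])


class Conv3dSame(Layer):
    """3x3x3 convolution, stride 1, SAME padding, channels-last.

    ``skip_input_grad`` suppresses the (unused) gradient with respect to
    the network input when this is the first layer.
    """

    def __init__(
        self,
        c_in: int,
        c_out: int,
        rng: np.random.Generator,
        init_sd: float = 0.1,
        skip_input_grad: bool = False,
    ):
        self.c_in = c_in
        self.c_out = c_out
        # stored flat as (27*c_in, c_out); logical layout (3,3,3,c_in,c_out)
        self.W = truncated_normal(rng, (27 * c_in, c_out), init_sd)
        self.b = np.zeros(c_out, dtype=DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.skip_input_grad = skip_input_grad
        self._cols = None
        self._in_shape = None

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x, training):
        n, d, w, h, c = x.shape
        if c != self.c_in:
            raise DomainError(f"expected {self.c_in} input channels, got {c}")
        cols = _im2col_3x3x3(x)
        out = cols @ self.W + self.b
        self._cols = cols if training else None
        self._in_shape = x.shape
        return out.reshape(n, d, w, h, self.c_out)

    def backward(self, dout):
        dflat = dout.reshape(-1, self.c_out)
        self.dW[...] = self._cols.T @ dflat
        self.db[...] = dflat.sum(axis=0)
        self._cols = None
        if self.skip_input_grad:
            return None
        return _col2im_3x3x3(dflat @ self.W.T, self._in_shape)


class BatchNorm(Layer):
    """Per-channel batch normalization over (n, d, w, h)."""

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(c, dtype=DTYPE)
        self.beta = np.zeros(c, dtype=DTYPE)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(c, dtype=DTYPE)
        self.running_var = np.ones(c, dtype=DTYPE)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.dgamma, self.dbeta]

    def forward(self, x, training):
        axes = (0, 1, 2, 3)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean[...] = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var[...] = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean = self.running_mean
            var = self.running_var
        ivar = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * ivar
        if training:
            self._cache = (xhat, ivar.astype(DTYPE))
        return (self.gamma * xhat + self.beta).astype(DTYPE, copy=False)

    def backward(self, dout):
        xhat, ivar = self._cache
        axes = (0, 1, 2, 3)
        m = float(np.prod([dout.shape[i] for i in range(4)]))
        self.dgamma[...] = (dout * xhat).sum(axis=axes)
        self.dbeta[...] = dout.sum(axis=axes)
        dx = (self.gamma * ivar / m) * (m * dout - self.dbeta - xhat * self.dgamma)
        self._cache = None
        return dx.astype(DTYPE, copy=False)


class ReLU(Layer):
    def __init__(self):
        self._mask = None

    def forward(self, x, training):
        mask = x > 0
        if training:
            self._mask = mask
        return np.where(mask, x, 0).astype(DTYPE, copy=False)

    def backward(self, dout):
        dx = np.where(self._mask, dout, 0).astype(DTYPE, copy=False)
        self._mask = None
        return dx


class MaxPool3d(Layer):
    """2x2x2 max pooling, stride 2, ceil mode (odd dims padded with -inf)."""

    def __init__(self):
        self._cache = None

    @staticmethod
    def out_shape(spatial):
        return tuple(-(-s // 2) for s in spatial)

    def forward(self, x, training):
        n, d, w, h, c = x.shape
        d2, w2, h2 = self.out_shape((d, w, h))
        if (d, w, h) != (2 * d2, 2 * w2, 2 * h2):
            pad = ((0, 0), (0, 2 * d2 - d), (0, 2 * w2 - w), (0, 2 * h2 - h), (0, 0))
            x0 = np.pad(x, pad, constant_values=-np.inf)
        else:
            x0 = x
        # three pairwise-max passes, one per spatial axis
        s1 = np.maximum(x0[:, 0::2], x0[:, 1::2])
        s2 = np.maximum(s1[:, :, 0::2], s1[:, :, 1::2])
        s3 = np.maximum(s2[:, :, :, 0::2], s2[:, :, :, 1::2])
        if training:
            self._cache = (x.shape, x0, s1, s2)
        return s3

    def backward(self, dout):
        (n, d, w, h, c), x0, s1, s2 = self._cache

        def unpool(g, s, axis):
            lo = [slice(None)] * 5
            hi = [slice(None)] * 5
            lo[axis] = slice(0, None, 2)
            hi[axis] = slice(1, None, 2)
            lo, hi = tuple(lo), tuple(hi)
            mask = s[lo] >= s[hi]  # ties route to the first element
            gs = np.zeros(s.shape, dtype=DTYPE)
            gs[lo] = np.where(mask, g, 0)
            gs[hi] = np.where(mask, 0, g)
            return gs

        g = unpool(dout, s2, 3)
        g = unpool(g, s1, 2)
        g = unpool(g, x0, 1)
        self._cache = None
        return np.ascontiguousarray(g[:, :d, :w, :h, :])


class Flatten(Layer):
    def __init__(self):
        self._shape = None

    def forward(self, x, training):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, init_sd: float = 0.1):
        self.W = truncated_normal(rng, (n_in, n_out), init_sd)
        self.b = np.zeros(n_out, dtype=DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x = None

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x, training):
        if training:
            self._x = x
        return x @ self.W + self.b

    def backward(self, dout):
        self.dW[...] = self._x.T @ dout
        self.db[...] = dout.sum(axis=0)
        dx = dout @ self.W.T
        self._x = None
        return dx


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy_sum(probs: np.ndarray, onehot: np.ndarray, floor: float = 1e-12) -> float:
    """Batch-summed cross entropy -sum log p(true class), probabilities floored."""
    if probs.shape != onehot.shape:
        raise DomainError(f"shape mismatch {probs.shape} vs {onehot.shape}")
    p_true = (np.clip(probs, floor, 1.0) * onehot).sum(axis=1)
    return float(-np.log(p_true).sum())


class Adam:
    """Adam with bias-corrected first/second moment estimates."""

    def __init__(self, params, lr=0.001, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]

    def step(self, grads):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        lr_t = self.lr * np.sqrt(1 - b2**self.t) / (1 - b1**self.t)
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            p -= lr_t * m / (np.sqrt(v) + self.eps)
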