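"""Minimal 3D convolutional network machinery in numpy.

Implements exactly what the dose engine needs: 3D convolutions (kernel 1 or
3, stride 1 or 2, zero 'same' padding) with hand-written backward passes
via im2col/GEMM, nearest-neighbour 2x upsampling, ReLU, an Adam optimizer
and an L1 (mean-absolute-error) loss.  All layers operate channels-last on
arrays of shape (N, D, H, W, C); float32 by default.  The channels-last
layout lets im2col be assembled from 27 contiguous block copies (one per
kernel offset), which keeps the whole network GEMM-bound.

The backward pass of a strided convolution is computed as a stride-1
correlation of the zero-stuffed output gradient with the spatially flipped
kernel, so every gradient is a single GEMM.  Layer gradients are verified
against finite differences in the test suite.

Weight layout: ``w`` has shape (k^3 * c_in, c_out), offset-major — row
``o * c_in + c`` holds kernel offset o = kd*k^2 + kh*k + kw, input channel c.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv3d", "Upsample3d", "Adam", "mae_loss"]


try:  # JIT-compiled gather; the numpy path below is the reference fallback
    import numba

    @numba.njit(cache=True, fastmath=False)
    def _gather(xp, cols, d, h, w, stride):  # pragma: no cover - jitted
        n = xp.shape[0]
        c = xp.shape[4]
        do = (d - 1) // stride + 1
        ho = (h - 1) // stride + 1
        wo = (w - 1) // stride + 1
        for i in range(n):
            for od in range(do):
                for oh in range(ho):
                    row2 = cols[i, od, oh]
                    for ow in range(wo):
                        r1 = row2[ow]
                        col = 0
                        iw = ow * stride
                        for kd in range(3):
                            for kh in range(3):
                                src = xp[i, od * stride + kd, oh * stride + kh]
                                for kw in range(3):
                                    s1 = src[iw + kw]
                                    for cc in range(c):
                                        r1[col] = s1[cc]
                                        col += 1

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def _im2col(x: np.ndarray, kernel: int, stride: int) -> np.ndarray:
    """(N, D, H, W, C) -> (N*Do*Ho*Wo, k^3*C) with 'same' zero padding."""
    n, d, h, w, c = x.shape
    if kernel == 1:
        cols = x[:, ::stride, ::stride, ::stride, :]
        return np.ascontiguousarray(cols).reshape(-1, c)
    pad = kernel // 2
    xp = np.zeros((n, d + 2 * pad, h + 2 * pad, w + 2 * pad, c), dtype=x.dtype)
    xp[:, pad : pad + d, pad : pad + h, pad : pad + w, :] = x
    do, ho, wo = ((s - 1) // stride + 1 for s in (d, h, w))
    cols = np.empty((n, do, ho, wo, kernel**3 * c), dtype=x.dtype)
    if _HAVE_NUMBA and kernel == 3:
        _gather(xp, cols, d, h, w, stride)
        return cols.reshape(-1, kernel**3 * c)
    o = 0
    for kd in range(kernel):
        for kh in range(kernel):
            for kw in range(kernel):
                cols[..., o * c : (o + 1) * c] = xp[
                    :, kd : kd + d : stride, kh : kh + h : stride, kw : kw + w : stride, :
                ]
                o += 1
    return cols.reshape(-1, kernel**3 * c)


class Conv3d:
    """3D convolution, 'same' zero padding, optional stride-2 and ReLU."""

    def __init__(
        self,
        c_in: int,
        c_out: int,
        rng: np.random.Generator,
        kernel: int = 3,
        stride: int = 1,
        relu: bool = True,
        dtype=np.float32,
    ):
        if kernel not in (1, 3):
            raise ValueError("kernel must be 1 or 3")
        if stride not in (1, 2):
            raise ValueError("stride must be 1 or 2")
        self.c_in, self.c_out = c_in, c_out
        self.kernel, self.stride, self.relu = kernel, stride, relu
        fan_in = c_in * kernel**3
        scale = np.sqrt(2.0 / fan_in)  # He initialization for ReLU nets
        self.w = (rng.standard_normal((fan_in, c_out)) * scale).astype(dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self._cache = None

    @property
    def params(self):
        return [self.w, self.b]

    @property
    def grads(self):
        return [self.dw, self.db]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, d, h, w, _ = x.shape
        self._in_shape = x.shape
        s = self.stride
        do, ho, wo = ((dim - 1) // s + 1 for dim in (d, h, w))
        flat = _im2col(x, self.kernel, s)
        y = flat @ self.w
        y += self.b
        if self.relu:
            mask = y > 0
            np.multiply(y, mask, out=y)
        else:
            mask = None
        if train:
            self._cache = (flat, mask)
        return y.reshape(n, do, ho, wo, self.c_out)

    def backward(self, dy: np.ndarray, need_dx: bool = True) -> np.ndarray | None:
        flat, mask = self._cache
        n, d, h, w, _ = self._in_shape
        dyf = dy.reshape(-1, self.c_out)
        if self.relu:
            dyf = dyf * mask
        self.dw = flat.T @ dyf
        self.db = dyf.sum(axis=0)
        if not need_dx:
            return None

        # gradient w.r.t. the input: correlate the (zero-stuffed) output
        # gradient with the spatially flipped kernel
        if self.stride == 2:
            dy_full = np.zeros((n, d, h, w, self.c_out), dtype=dy.dtype)
            dy_full[:, ::2, ::2, ::2, :] = dyf.reshape(dy.shape)
        else:
            dy_full = dyf.reshape(dy.shape)
        if self.kernel == 1:
            dx = dy_full.reshape(-1, self.c_out) @ self.w.T
            return dx.reshape(n, d, h, w, self.c_in)
        k3 = self.kernel**3
        wg = self.w.reshape(k3, self.c_in, self.c_out)
        # spatial flip: kernel offset o maps to k^3-1-o
        wt = wg[::-1].transpose(0, 2, 1).reshape(k3 * self.c_out, self.c_in)
        cols = _im2col(dy_full, self.kernel, 1)
        dx = cols @ np.ascontiguousarray(wt)
        return dx.reshape(n, d, h, w, self.c_in)


class Upsample3d:
    """Nearest-neighbour 2x upsampling along all spatial axes."""

    params: list = []
    grads: list = []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return x.repeat(2, axis=1).repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, d, h, w, c = dy.shape
        return dy.reshape(n, d // 2, 2, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4, 6))


class Adam:
    """Adam optimizer over a flat list of parameter arrays (updated in place)."""

    def __init__(self, params: list[np.ndarray], lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            g = g.astype(p.dtype, copy=False)
            m += (1 - self.b1) * (g - m)
            v += (1 - self.b2) * (g * g - v)
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def mae_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean absolute error and its gradient w.r.t. the prediction."""
    diff = pred - target
    loss = float(np.abs(diff).mean())
    grad = np.sign(diff) / diff.size
    return loss, grad.astype(pred.dtype, copy=False)
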