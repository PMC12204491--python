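"""Minimal numpy neural-network layers with explicit backward passes.

Just enough machinery for the desk-scale dilated U-Net: 2D (dilated)
convolution via im2col, ReLU, 2x2 max pooling, nearest-neighbour
upsampling, channel concatenation and Adam.  All layers store what their
backward pass needs; arrays are NCHW float64.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Conv2d", "ReLU", "MaxPool2", "Upsample2", "Adam", "sigmoid"]


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Conv2d:
    """Same-padded KxK convolution with integer dilation.

    Effective receptive field of the kernel is (k-1)*d + 1; padding is
    chosen so output spatial size equals input size (odd k only).
    """

    def __init__(self, c_in: int, c_out: int, k: int = 3, dilation: int = 1,
                 rng: np.random.Generator | None = None):
        if k % 2 != 1:
            raise ValueError("odd kernel sizes only")
        if dilation < 1:
            raise ValueError("dilation must be >= 1")
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / (c_in * k * k))
        self.W = rng.normal(0.0, scale, size=(c_out, c_in, k, k))
        self.b = np.zeros(c_out)
        self.k = k
        self.d = dilation
        self.pad = (k - 1) * dilation // 2
        self._cols = None
        self._x_shape = None

    @property
    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        B, C, H, Wd = x.shape
        p, k, d = self.pad, self.k, self.d
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        eff = (k - 1) * d + 1
        win = sliding_window_view(xp, (eff, eff), axis=(2, 3))[..., ::d, ::d]
        # win: (B, C, H, W, k, k) -> cols (B*H*W, C*k*k)
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(B * H * Wd, C * k * k)
        Wmat = self.W.reshape(self.W.shape[0], -1)      # (c_out, C*k*k)
        out = cols @ Wmat.T + self.b
        if train:
            self._cols = cols
            self._x_shape = x.shape
        return out.reshape(B, H, Wd, -1).transpose(0, 3, 1, 2)

    def backward(self, dy: np.ndarray):
        B, c_out, H, Wd = dy.shape
        dyf = dy.transpose(0, 2, 3, 1).reshape(-1, c_out)   # (B*H*W, c_out)
        self.dW = (dyf.T @ self._cols).reshape(self.W.shape)
        self.db = dyf.sum(axis=0)
        Wmat = self.W.reshape(c_out, -1)
        dcols = dyf @ Wmat                                   # (B*H*W, C*k*k)
        _, C, Hx, Wx = self._x_shape
        p, k, d = self.pad, self.k, self.d
        dxp = np.zeros((B, C, Hx + 2 * p, Wx + 2 * p))
        dcols = dcols.reshape(B, H, Wd, C, k, k)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i * d:i * d + H, j * d:j * d + Wd] += \
                    dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        self._cols = None
        return dxp[:, :, p:p + Hx, p:p + Wx]

    @property
    def grads(self):
        return [self.dW, self.db]


class ReLU:
    def forward(self, x, train: bool = True):
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, dy):
        return dy * self._mask


class MaxPool2:
    """2x2 max pooling, stride 2 (even spatial sizes assumed)."""

    def forward(self, x, train: bool = True):
        B, C, H, W = x.shape
        xr = x.reshape(B, C, H // 2, 2, W // 2, 2)
        out = xr.max(axis=(3, 5))
        if train:
            self._mask = (xr == out[:, :, :, None, :, None])
            self._shape = x.shape
        return out

    def backward(self, dy):
        B, C, H, W = self._shape
        dyr = dy[:, :, :, None, :, None] * self._mask
        return dyr.reshape(B, C, H, W)


class Upsample2:
    """Nearest-neighbour x2 upsampling; backward sums 2x2 blocks."""

    def forward(self, x, train: bool = True):
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dy):
        B, C, H, W = dy.shape
        return dy.reshape(B, C, H // 2, 2, W // 2, 2).sum(axis=(3, 5))


class Adam:
    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
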