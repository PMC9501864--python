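"""Minimal CPU neural-network layers with explicit forward/backward.

Tensors are float32 NCHW.  Convolution is im2col + BLAS matmul; each
layer caches what its backward pass needs.  Only the pieces the
detector uses are implemented: strided 2-D convolution, ReLU, 2×2 max
pooling, batch normalisation, nearest-neighbour ×2 upsampling, channel
concatenation, and an SGD-with-momentum optimiser with L2 weight decay.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Param", "Conv2d", "ReLU", "MaxPool2", "BatchNorm2d",
           "UpsampleNearest2", "concat_channels", "split_channels", "SGDM",
           "sigmoid"]


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Param:
    """A learnable tensor with its gradient and momentum buffer."""

    def __init__(self, value: np.ndarray, weight_decay: bool = True):
        self.value = value.astype(np.float32)
        self.grad = np.zeros_like(self.value)
        self.momentum = np.zeros_like(self.value)
        self.weight_decay = weight_decay


class Conv2d:
    def __init__(self, in_ch: int, out_ch: int, k: int, stride: int = 1,
                 pad: int | None = None, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.k, self.stride = k, stride
        self.pad = (k // 2) if pad is None else pad
        fan_in = in_ch * k * k
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_ch, fan_in))
        self.W = Param(w.astype(np.float32))
        self.b = Param(np.zeros(out_ch, dtype=np.float32), weight_decay=False)
        self.in_ch, self.out_ch = in_ch, out_ch
        self._cache = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        k, s, p = self.k, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        oh = (h + 2 * p - k) // s + 1
        ow = (w + 2 * p - k) // s + 1
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        win = win[:, :, ::s, ::s]                       # (n, c, oh, ow, k, k)
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * oh * ow, c * k * k)
        out = cols @ self.W.value.T + self.b.value
        out = out.reshape(n, oh, ow, self.out_ch).transpose(0, 3, 1, 2)
        if train:
            self._cache = (cols, (n, c, h, w), (oh, ow))
        return np.ascontiguousarray(out)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, (n, c, h, w), (oh, ow) = self._cache
        k, s, p = self.k, self.stride, self.pad
        d2 = dout.transpose(0, 2, 3, 1).reshape(n * oh * ow, self.out_ch)
        self.W.grad += (d2.T @ cols).astype(np.float32)
        self.b.grad += d2.sum(axis=0).astype(np.float32)
        dcols = (d2 @ self.W.value).reshape(n, oh, ow, c, k, k)
        dcols = dcols.transpose(0, 3, 4, 5, 1, 2)       # (n, c, k, k, oh, ow)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + s * oh:s, j:j + s * ow:s] += dcols[:, :, i, j]
        self._cache = None
        return dxp[:, :, p:p + h, p:p + w] if p else dxp


class ReLU:
    def __init__(self):
        self._mask = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx = dout * self._mask
        self._mask = None
        return dx


class MaxPool2:
    """2×2 max pooling with stride 2 (spatial dims must be even)."""

    def __init__(self):
        self._cache = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"MaxPool2 needs even spatial dims, got {h}x{w}")
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(n, c, h // 2, w // 2, 4)
        idx = xr.argmax(axis=-1)
        out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        if train:
            self._cache = (idx, (n, c, h, w))
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        idx, (n, c, h, w) = self._cache
        dxr = np.zeros((n, c, h // 2, w // 2, 4), dtype=np.float32)
        np.put_along_axis(dxr, idx[..., None], dout[..., None], axis=-1)
        dx = dxr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        self._cache = None
        return dx.reshape(n, c, h, w)


class BatchNorm2d:
    def __init__(self, ch: int, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = Param(np.ones(ch, dtype=np.float32), weight_decay=False)
        self.beta = Param(np.zeros(ch, dtype=np.float32), weight_decay=False)
        self.eps, self.momentum = eps, momentum
        self.running_mean = np.zeros(ch, dtype=np.float32)
        self.running_var = np.ones(ch, dtype=np.float32)
        self._cache = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        out = (self.gamma.value[None, :, None, None] * xhat
               + self.beta.value[None, :, None, None])
        if train:
            self._cache = (xhat, inv, x.shape)
        return out.astype(np.float32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv, shape = self._cache
        n, c, h, w = shape
        m = n * h * w
        self.gamma.grad += (dout * xhat).sum(axis=(0, 2, 3)).astype(np.float32)
        self.beta.grad += dout.sum(axis=(0, 2, 3)).astype(np.float32)
        g = self.gamma.value[None, :, None, None]
        dxhat = dout * g
        dx = (inv[None, :, None, None] / m) * (
            m * dxhat
            - dxhat.sum(axis=(0, 2, 3), keepdims=True)
            - xhat * (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        )
        self._cache = None
        return dx.astype(np.float32)


class UpsampleNearest2:
    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = dout.shape
        return dout.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


def concat_channels(*xs: np.ndarray) -> np.ndarray:
    return np.concatenate(xs, axis=1)


def split_channels(d: np.ndarray, sizes: list[int]) -> list[np.ndarray]:
    return list(np.split(d, np.cumsum(sizes)[:-1], axis=1))


class SGDM:
    """Stochastic gradient descent with momentum and L2 regularisation."""

    def __init__(self, params: list[Param], momentum: float = 0.9,
                 l2_reg: float = 0.0005):
        self.params = params
        self.mu = momentum
        self.l2 = l2_reg

    def step(self, lr: float) -> None:
        for p in self.params:
            g = p.grad
            if p.weight_decay and self.l2:
                g = g + self.l2 * p.value
            p.momentum = self.mu * p.momentum - lr * g
            p.value += p.momentum

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0
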