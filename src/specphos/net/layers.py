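"""Numpy layers with explicit forward/backward passes.

Every layer caches what its backward pass needs during forward; ``params()``
exposes (value, gradient) pairs for the optimizer.  Shapes follow the
(batch, channels, length) convention for convolutional tensors.
"""

from __future__ import annotations

import numpy as np


class Layer:
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return []


class Conv1d(Layer):
    """1D convolution with length-preserving (same) padding, stride 1."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int,
                 rng: np.random.Generator, dtype=np.float32):
        scale = np.sqrt(2.0 / (in_ch * kernel))
        self.W = rng.normal(0.0, scale, (out_ch, in_ch, kernel)).astype(dtype)
        self.b = np.zeros(out_ch, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.kernel = kernel
        self.pad_left = (kernel - 1) // 2
        self.pad_right = kernel - 1 - self.pad_left

    def forward(self, x, train=False):
        n, c, L = x.shape
        k = self.kernel
        x = x.astype(self.W.dtype, copy=False)
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad_left, self.pad_right)))
        # im2col: (N, C, L, K) window view -> (N*L, C*K) matrix, one GEMM
        win = np.lib.stride_tricks.sliding_window_view(xp, k, axis=2)
        cols = np.ascontiguousarray(win.transpose(0, 2, 1, 3)).reshape(n * L, c * k)
        self._cols, self._L, self._n, self._c = cols, L, n, c
        wmat = self.W.reshape(self.W.shape[0], c * k)
        out = cols @ wmat.T + self.b
        return out.reshape(n, L, -1).transpose(0, 2, 1)

    def backward(self, grad):
        n, L, c, k = self._n, self._L, self._c, self.kernel
        g2 = np.ascontiguousarray(grad.transpose(0, 2, 1)).reshape(n * L, -1)
        self.db[:] = g2.sum(axis=0)
        self.dW[:] = (g2.T @ self._cols).reshape(self.W.shape)
        dcols = (g2 @ self.W.reshape(self.W.shape[0], c * k)).reshape(n, L, c, k)
        dcols = np.ascontiguousarray(dcols.transpose(0, 2, 3, 1))  # (n, c, k, L)
        dxp = np.zeros((n, c, L + k - 1), dtype=self.W.dtype)
        for i in range(k):
            dxp[:, :, i:i + L] += dcols[:, :, i, :]
        return dxp[:, :, self.pad_left:self.pad_left + L]

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


class BatchNorm1d(Layer):
    """Per-channel batch normalization over (batch, length)."""

    def __init__(self, n_ch: int, momentum: float = 0.1, eps: float = 1e-5,
                 dtype=np.float32):
        self.gamma = np.ones(n_ch, dtype=dtype)
        self.beta = np.zeros(n_ch, dtype=dtype)
        self.dgamma = np.zeros(n_ch, dtype=dtype)
        self.dbeta = np.zeros(n_ch, dtype=dtype)
        self.running_mean = np.zeros(n_ch, dtype=dtype)
        self.running_var = np.ones(n_ch, dtype=dtype)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x, train=False):
        if train:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None]) * invstd[None, :, None]
        self._xhat, self._invstd, self._train = xhat, invstd, train
        return self.gamma[None, :, None] * xhat + self.beta[None, :, None]

    def backward(self, grad):
        xhat, invstd = self._xhat, self._invstd
        self.dgamma[:] = (grad * xhat).sum(axis=(0, 2))
        self.dbeta[:] = grad.sum(axis=(0, 2))
        dxhat = grad * self.gamma[None, :, None]
        if not self._train:
            return dxhat * invstd[None, :, None]
        m = grad.shape[0] * grad.shape[2]
        term = (
            m * dxhat
            - dxhat.sum(axis=(0, 2), keepdims=True)
            - xhat * (dxhat * xhat).sum(axis=(0, 2), keepdims=True)
        )
        return term * invstd[None, :, None] / m

    def params(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class AvgPool1d(Layer):
    """Average pooling, window 4 / stride 3 by default (windows overlap)."""

    def __init__(self, window: int = 4, stride: int = 3):
        self.window, self.stride = window, stride

    def out_length(self, L: int) -> int:
        if L < self.window:
            raise ValueError(f"input length {L} shorter than pool window {self.window}")
        return (L - self.window) // self.stride + 1

    def forward(self, x, train=False):
        n, c, L = x.shape
        Lo = self.out_length(L)
        self._L = L
        out = np.zeros((n, c, Lo), dtype=x.dtype)
        for i in range(self.window):
            out += x[:, :, i:i + (Lo - 1) * self.stride + 1:self.stride]
        return out / self.window

    def backward(self, grad):
        n, c, Lo = grad.shape
        dx = np.zeros((n, c, self._L), dtype=grad.dtype)
        g = grad / self.window
        for i in range(self.window):
            dx[:, :, i:i + (Lo - 1) * self.stride + 1:self.stride] += g
        return dx


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Reshape(Layer):
    """(N, C*L) <-> (N, C, L) for the decoder entry point."""

    def __init__(self, channels: int, length: int):
        self.channels, self.length = channels, length

    def forward(self, x, train=False):
        return x.reshape(x.shape[0], self.channels, self.length)

    def backward(self, grad):
        return grad.reshape(grad.shape[0], -1)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 dtype=np.float32):
        scale = np.sqrt(2.0 / n_in)
        self.W = rng.normal(0.0, scale, (n_in, n_out)).astype(dtype)
        self.b = np.zeros(n_out, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x, train=False):
        x = x.astype(self.W.dtype, copy=False)
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        grad = grad.astype(self.W.dtype, copy=False)
        self.dW[:] = self._x.T @ grad
        self.db[:] = grad.sum(axis=0)
        return grad @ self.W.T

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


class Dropout(Layer):
    """Inverted dropout; identity in eval mode."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0 <= rate < 1:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng

    def forward(self, x, train=False):
        if not train or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Upsample(Layer):
    """Nearest-neighbour upsampling by an integer factor along length."""

    def __init__(self, factor: int = 2):
        self.factor = factor

    def forward(self, x, train=False):
        return np.repeat(x, self.factor, axis=2)

    def backward(self, grad):
        n, c, L = grad.shape
        return grad.reshape(n, c, L // self.factor, self.factor).sum(axis=3)


class Adam:
    """Adam optimizer over (value, grad) parameter pairs."""

    def __init__(self, params: list[tuple[np.ndarray, np.ndarray]],
                 lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for i, (p, g) in enumerate(self.params):
            m, v = self.m[i], self.v[i]
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * np.square(g)
            denom = np.sqrt(v / b2t)
            denom += self.eps
            p -= (self.lr / b1t) * m / denom


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)
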