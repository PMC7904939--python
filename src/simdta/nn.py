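"""Minimal NumPy building blocks for the 2D CNN regressor.

Layers operate on NCHW arrays and implement exact analytic gradients
(verified by finite differences in the test suite).  Only the pieces the
architecture needs exist: valid 2D convolution, overlapping 2x2 max-pooling
with stride 1, flatten, inverted dropout, dense layers and Adam.

Weight initialization is Glorot-uniform (limit sqrt(6 / (fan_in + fan_out)))
with zero biases, drawn from the run's seeded generator so training is
bit-reproducible.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv2D", "MaxPool2x2", "Flatten", "Dropout", "Dense", "ReLU", "Adam"]


def _glorot(rng: np.random.Generator, shape, fan_in, fan_out):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Conv2D:
    """Valid (no padding) 2D convolution, stride 1."""

    def __init__(self, in_channels, out_channels, kernel, rng):
        kh, kw = kernel
        fan_in = in_channels * kh * kw
        fan_out = out_channels * kh * kw
        self.W = _glorot(rng, (out_channels, in_channels, kh, kw), fan_in, fan_out)
        self.b = np.zeros(out_channels)
        self.kernel = (kh, kw)

    @property
    def params(self):
        return [self.W, self.b]

    def out_shape(self, h, w):
        kh, kw = self.kernel
        return h - kh + 1, w - kw + 1

    def forward(self, x, train=False):
        kh, kw = self.kernel
        # windows: (N, C, Ho, Wo, kh, kw)
        win = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
        self._win = win
        self._x_shape = x.shape
        out = np.tensordot(win, self.W, axes=[(1, 4, 5), (1, 2, 3)])
        # out: (N, Ho, Wo, F) -> (N, F, Ho, Wo)
        out = np.transpose(out, (0, 3, 1, 2)) + self.b[None, :, None, None]
        return out

    def backward(self, dout):
        # dout: (N, F, Ho, Wo)
        kh, kw = self.kernel
        self.db = dout.sum(axis=(0, 2, 3))
        # dW[f,c,i,j] = sum_{n,ho,wo} dout[n,f,ho,wo] * win[n,c,ho,wo,i,j]
        self.dW = np.tensordot(dout, self._win, axes=[(0, 2, 3), (0, 2, 3)])
        # dx via scatter-add of W weighted by dout
        n, _, ho, wo = dout.shape
        dx = np.zeros(self._x_shape)
        # dcols[n,ho,wo,c,i,j] = sum_f dout[n,f,ho,wo] * W[f,c,i,j]
        dcols = np.tensordot(np.transpose(dout, (0, 2, 3, 1)), self.W, axes=[(3,), (0,)])
        for i in range(kh):
            for j in range(kw):
                dx[:, :, i:i + ho, j:j + wo] += np.transpose(
                    dcols[:, :, :, :, i, j], (0, 3, 1, 2)
                )
        self._win = None
        return dx

    @property
    def grads(self):
        return [self.dW, self.db]


class MaxPool2x2:
    """2x2 max pooling with stride 1 in both dimensions (overlapping)."""

    params: list = []
    grads: list = []

    def out_shape(self, h, w):
        return h - 1, w - 1

    def forward(self, x, train=False):
        # stack the four window corners: (4, N, C, Ho, Wo)
        cand = np.stack(
            [x[:, :, :-1, :-1], x[:, :, :-1, 1:], x[:, :, 1:, :-1], x[:, :, 1:, 1:]]
        )
        self._argmax = cand.argmax(axis=0)
        self._x_shape = x.shape
        return cand.max(axis=0)

    def backward(self, dout):
        dx = np.zeros(self._x_shape)
        offsets = [(0, 0), (0, 1), (1, 0), (1, 1)]
        n, c, ho, wo = dout.shape
        for k, (di, dj) in enumerate(offsets):
            mask = self._argmax == k
            dx[:, :, di:di + ho, dj:dj + wo] += np.where(mask, dout, 0.0)
        self._argmax = None
        return dx


class Flatten:
    params: list = []
    grads: list = []

    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dropout:
    """Inverted dropout; identity outside training."""

    params: list = []
    grads: list = []

    def __init__(self, rate, rng):
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x, train=False):
        if not train or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dout):
        if self._mask is None:
            return dout
        return dout * self._mask


class ReLU:
    params: list = []
    grads: list = []

    def forward(self, x, train=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout):
        return dout * self._mask


class Dense:
    def __init__(self, n_in, n_out, rng):
        self.W = _glorot(rng, (n_in, n_out), n_in, n_out)
        self.b = np.zeros(n_out)

    @property
    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=False):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout):
        self.dW = self._x.T @ dout
        self.db = dout.sum(axis=0)
        dx = dout @ self.W.T
        self._x = None
        return dx

    @property
    def grads(self):
        return [self.dW, self.db]


class Adam:
    """Adam with the standard defaults (beta1 0.9, beta2 0.999, eps 1e-8)."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
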