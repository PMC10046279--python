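"""Minimal 2D convolutional network engine in numpy.

Implements exactly the pieces the quality classifier's topology needs:
valid-mode 2D convolution (im2col + GEMM), overlapping average pooling,
leaky rectification, inverted dropout, dense layers, softmax cross-entropy
with L2 weight decay, and Adam.  Forward and backward passes are exact
gradients (checked against finite differences in the test suite).

All arrays are float32, NHWC layout.  Randomness (initialisation, dropout,
shuffling) comes from one explicit Generator, so training is reproducible
for a fixed seed.
"""

from __future__ import annotations

from typing import List, Sequence

import numpy as np

__all__ = ["Conv2D", "AvgPool2D", "LeakyReLU", "Dropout", "Flatten", "Dense",
           "Network", "softmax", "cross_entropy"]


def _windows(x: np.ndarray, k: int, stride: int) -> np.ndarray:
    """View of sliding (k x k) windows: (N, Ho, Wo, k, k, C)."""
    n, h, w, c = x.shape
    ho = (h - k) // stride + 1
    wo = (w - k) // stride + 1
    sN, sH, sW, sC = x.strides
    return np.lib.stride_tricks.as_strided(
        x,
        shape=(n, ho, wo, k, k, c),
        strides=(sN, sH * stride, sW * stride, sH, sW, sC),
        writeable=False,
    )


class Layer:
    params: List[np.ndarray] = []
    grads: List[np.ndarray] = []
    #: per-parameter L2 flags (weights decay, biases do not)
    decay: List[bool] = []

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2D(Layer):
    """Valid-mode 2D convolution, kernel (k, k), NHWC."""

    def __init__(self, in_ch: int, out_ch: int, k: int, rng: np.random.Generator):
        fan_in = k * k * in_ch
        scale = np.sqrt(2.0 / fan_in)  # He init for rectified units
        self.W = (rng.standard_normal((k, k, in_ch, out_ch)) * scale).astype(np.float32)
        self.b = np.zeros(out_ch, dtype=np.float32)
        self.k = k
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]
        self.decay = [True, False]

    def forward(self, x, train, rng):
        self.x_shape = x.shape
        k = self.k
        cols = _windows(x, k, 1).reshape(x.shape[0], -1, k * k * x.shape[3])
        self.cols = cols  # (N, Ho*Wo, k*k*C)
        n, h, w, c = x.shape
        ho, wo = h - k + 1, w - k + 1
        out = cols @ self.W.reshape(-1, self.W.shape[-1]) + self.b
        return out.reshape(n, ho, wo, -1)

    def backward(self, grad):
        n, ho, wo, f = grad.shape
        g2 = grad.reshape(n, ho * wo, f)
        wflat = self.W.reshape(-1, f)
        # parameter gradients
        gW = np.einsum("npk,npf->kf", self.cols, g2, optimize=True)
        self.grads[0][...] = gW.reshape(self.W.shape)
        self.grads[1][...] = grad.sum(axis=(0, 1, 2))
        # input gradient: scatter columns back
        gcols = g2 @ wflat.T  # (N, Ho*Wo, k*k*C)
        k, c = self.k, self.x_shape[3]
        gx = np.zeros(self.x_shape, dtype=np.float32)
        gcols = gcols.reshape(n, ho, wo, k, k, c)
        for di in range(k):
            for dj in range(k):
                gx[:, di : di + ho, dj : dj + wo, :] += gcols[:, :, :, di, dj, :]
        return gx


class AvgPool2D(Layer):
    """Average pooling with pool size possibly exceeding the stride (overlapping)."""

    def __init__(self, pool: int, stride: int):
        self.p, self.s = pool, stride

    def forward(self, x, train, rng):
        self.x_shape = x.shape
        return _windows(x, self.p, self.s).mean(axis=(3, 4))

    def backward(self, grad):
        n, ho, wo, c = grad.shape
        gx = np.zeros(self.x_shape, dtype=np.float32)
        g = (grad / (self.p * self.p)).astype(np.float32)
        p, s = self.p, self.s
        for di in range(p):
            for dj in range(p):
                gx[:, di : di + ho * s : s, dj : dj + wo * s : s, :] += g
        return gx


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.002):
        self.slope = slope

    def forward(self, x, train, rng):
        self.mask = x > 0
        return np.where(self.mask, x, self.slope * x)

    def backward(self, grad):
        return np.where(self.mask, grad, self.slope * grad).astype(np.float32)


class Dropout(Layer):
    """Inverted dropout; *keep* is the probability a unit survives."""

    def __init__(self, keep: float = 0.5):
        self.keep = keep

    def forward(self, x, train, rng):
        if not train or self.keep >= 1.0:
            self.mask = None
            return x
        self.mask = (rng.random(x.shape) < self.keep).astype(np.float32) / self.keep
        return x * self.mask

    def backward(self, grad):
        return grad if self.mask is None else grad * self.mask


class Flatten(Layer):
    def forward(self, x, train, rng):
        self.x_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self.x_shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.W = (rng.standard_normal((n_in, n_out)) * scale).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]
        self.decay = [True, False]

    def forward(self, x, train, rng):
        self.x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.grads[0][...] = self.x.T @ grad
        self.grads[1][...] = grad.sum(axis=0)
        return grad @ self.W.T


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(probs: np.ndarray, y: np.ndarray) -> float:
    """Mean negative log-likelihood of integer labels *y* under *probs*."""
    eps = 1e-12
    return float(-np.log(probs[np.arange(len(y)), y] + eps).mean())


class Network:
    """A layer stack with softmax cross-entropy loss, L2 decay and Adam."""

    def __init__(self, layers: Sequence[Layer], l2_alpha: float, lr: float,
                 seed: int = 0):
        self.layers = list(layers)
        self.l2_alpha = l2_alpha
        self.lr = lr
        self.rng = np.random.default_rng(seed)
        self._m = [np.zeros_like(p) for layer in self.layers for p in layer.params]
        self._v = [np.zeros_like(p) for layer in self.layers for p in layer.params]
        self._t = 0

    def _all_params(self):
        for layer in self.layers:
            for p, g, d in zip(layer.params, layer.grads, layer.decay):
                yield p, g, d

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = x.astype(np.float32)
        for layer in self.layers:
            out = layer.forward(out, train, self.rng)
        return softmax(out)

    def loss(self, x: np.ndarray, y: np.ndarray) -> float:
        data = cross_entropy(self.forward(x, train=False), y)
        reg = sum(float((p**2).sum()) for p, _, d in self._all_params() if d)
        return data + 0.5 * self.l2_alpha * reg / max(1, len(y))

    def train_batch(self, x: np.ndarray, y: np.ndarray) -> float:
        probs = self.forward(x, train=True)
        n = len(y)
        grad = probs.copy()
        grad[np.arange(n), y] -= 1.0
        grad = (grad / n).astype(np.float32)
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        # L2 decay on weight matrices
        for p, g, d in self._all_params():
            if d:
                g += (self.l2_alpha / n) * p
        self._adam_step()
        return cross_entropy(probs, y)

    def _adam_step(self, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self._t += 1
        for i, (p, g, _) in enumerate(self._all_params()):
            self._m[i] = beta1 * self._m[i] + (1 - beta1) * g
            self._v[i] = beta2 * self._v[i] + (1 - beta2) * g * g
            mhat = self._m[i] / (1 - beta1**self._t)
            vhat = self._v[i] / (1 - beta2**self._t)
            p -= self.lr * mhat / (np.sqrt(vhat) + eps)

    # -- weight snapshots for early stopping -------------------------------
    def get_weights(self) -> List[np.ndarray]:
        return [p.copy() for p, _, _ in self._all_params()]

    def set_weights(self, weights: Sequence[np.ndarray]) -> None:
        for (p, _, _), w in zip(self._all_params(), weights):
            p[...] = w
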