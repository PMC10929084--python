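"""Minimal feed-forward neural-network engine on numpy.

Implements exactly the layer set the multi-branch classifier needs —
1-D valid convolution (im2col), ReLU, per-channel batch normalization,
max pooling, flatten, dense layers, and a fused softmax cross-entropy
loss — with explicit forward/backward passes and Adam/SGD optimizers.
All randomness (weight init, batch shuffling) flows through a single
seeded ``numpy.random.Generator``, so CPU runs are reproducible.
"""

from __future__ import annotations

import numpy as np


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


class Layer:
    """Base layer: stateless by default, no parameters."""

    params: list[Param] = []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv1d(Layer):
    """Valid 1-D convolution, stride 1. Input (N, C_in, L)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * kernel))  # He init
        self.w = Param(rng.normal(0.0, scale, size=(c_out, c_in, kernel)))
        self.b = Param(np.zeros(c_out))
        self.params = [self.w, self.b]
        self.kernel = kernel

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        # cols: (N, C_in, L_out, k) sliding windows
        self._cols = np.lib.stride_tricks.sliding_window_view(
            x, self.kernel, axis=2
        )
        self._in_shape = x.shape
        out = np.einsum("nclk,ock->nol", self._cols, self.w.value, optimize=True)
        return out + self.b.value[None, :, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.w.grad = np.einsum(
            "nol,nclk->ock", grad, self._cols, optimize=True
        )
        self.b.grad = grad.sum(axis=(0, 2))
        n, c_in, L = self._in_shape
        L_out = grad.shape[2]
        dx = np.zeros(self._in_shape)
        for j in range(self.kernel):
            dx[:, :, j : j + L_out] += np.einsum(
                "nol,oc->ncl", grad, self.w.value[:, :, j], optimize=True
            )
        return dx


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class BatchNorm1d(Layer):
    """Per-channel batch normalization over (N, L). Input (N, C, L)."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.params = [self.gamma, self.beta]
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mean
            )
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            )
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean[None, :, None]) / self._std[None, :, None]
        return (
            self.gamma.value[None, :, None] * self._xhat
            + self.beta.value[None, :, None]
        )

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.gamma.grad = (grad * self._xhat).sum(axis=(0, 2))
        self.beta.grad = grad.sum(axis=(0, 2))
        m = grad.shape[0] * grad.shape[2]
        g = self.gamma.value[None, :, None] / self._std[None, :, None]
        mean_grad = grad.mean(axis=(0, 2))[None, :, None]
        mean_gx = (grad * self._xhat).mean(axis=(0, 2))[None, :, None]
        return g * (grad - mean_grad - self._xhat * mean_gx)


class MaxPool1d(Layer):
    """Non-overlapping max pooling; a trailing odd element is dropped."""

    def __init__(self, size: int = 2):
        self.size = size

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        n, c, L = x.shape
        L_out = L // self.size
        self._in_shape = x.shape
        windows = x[:, :, : L_out * self.size].reshape(n, c, L_out, self.size)
        self._argmax = windows.argmax(axis=3)
        return windows.max(axis=3)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, L = self._in_shape
        L_out = grad.shape[2]
        dx = np.zeros((n, c, L_out, self.size))
        np.put_along_axis(
            dx, self._argmax[..., None], grad[..., None], axis=3
        )
        out = np.zeros(self._in_shape)
        out[:, :, : L_out * self.size] = dx.reshape(n, c, L_out * self.size)
        return out


class Flatten(Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / d_in)
        self.w = Param(rng.normal(0.0, scale, size=(d_in, d_out)))
        self.b = Param(np.zeros(d_out))
        self.params = [self.w, self.b]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.w.grad = self._x.T @ grad
        self.b.grad = grad.sum(axis=0)
        return grad @ self.w.value.T


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    @property
    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    probs = softmax(logits)
    loss = -np.log(probs[np.arange(n), labels] + 1e-12).mean()
    grad = probs.copy()
    grad[np.arange(n), labels] -= 1.0
    return float(loss), grad / n


class Adam:
    def __init__(
        self,
        params: list[Param],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * p.grad
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * p.grad**2
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class SGD:
    def __init__(
        self, params: list[Param], lr: float = 1e-2, momentum: float = 0.9
    ):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        for i, p in enumerate(self.params):
            self.v[i] = self.momentum * self.v[i] - self.lr * p.grad
            p.value += self.v[i]
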