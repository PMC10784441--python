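"""Minimal NumPy neural-network engine for the degradation-pretext encoder.

Implements exactly the layers the encoder needs — 2x2 'same' convolutions,
1x1 convolutions, batch normalization, ReLU, squeeze-and-excitation channel
attention, 2x2 max pooling, global average pooling, dropout and a dense
head — each with an analytically derived backward pass, plus an Adam
optimizer.  Arrays are channels-first ``(N, C, H, W)`` float64.  Gradient
correctness is verified against central finite differences in the test
suite.
"""

from __future__ import annotations

import numpy as np


class Param:
    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = value
        self.grad = np.zeros_like(value)
        self.name = name


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2x2(Layer):
    """2x2 convolution with bottom/right zero padding (output size = input size)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator, name: str = "conv"):
        scale = np.sqrt(2.0 / (cin * 4))
        self.W = Param(rng.normal(0.0, scale, (cout, cin, 2, 2)), f"{name}.W")
        self.b = Param(np.zeros(cout), f"{name}.b")

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train):
        self._xp = np.pad(x, ((0, 0), (0, 0), (0, 1), (0, 1)))
        n, _, h, w = x.shape
        cout = self.W.value.shape[0]
        out = np.zeros((n, cout, h, w))
        for di in (0, 1):
            for dj in (0, 1):
                sl = self._xp[:, :, di : di + h, dj : dj + w]
                out += np.tensordot(sl, self.W.value[:, :, di, dj], axes=([1], [1])).transpose(
                    0, 3, 1, 2
                )
        out += self.b.value[None, :, None, None]
        self._hw = (h, w)
        return out

    def backward(self, dout):
        h, w = self._hw
        dxp = np.zeros_like(self._xp)
        for di in (0, 1):
            for dj in (0, 1):
                sl = self._xp[:, :, di : di + h, dj : dj + w]
                self.W.grad[:, :, di, dj] += np.tensordot(dout, sl, axes=([0, 2, 3], [0, 2, 3]))
                dxp[:, :, di : di + h, dj : dj + w] += np.tensordot(
                    dout, self.W.value[:, :, di, dj], axes=([1], [0])
                ).transpose(0, 3, 1, 2)
        self.b.grad += dout.sum(axis=(0, 2, 3))
        return dxp[:, :, :h, :w]


class Conv1x1(Layer):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator, name: str = "skip"):
        scale = np.sqrt(2.0 / cin)
        self.W = Param(rng.normal(0.0, scale, (cout, cin)), f"{name}.W")
        self.b = Param(np.zeros(cout), f"{name}.b")

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train):
        self._x = x
        out = np.tensordot(x, self.W.value, axes=([1], [1])).transpose(0, 3, 1, 2)
        return out + self.b.value[None, :, None, None]

    def backward(self, dout):
        self.W.grad += np.tensordot(dout, self._x, axes=([0, 2, 3], [0, 2, 3]))
        self.b.grad += dout.sum(axis=(0, 2, 3))
        return np.tensordot(dout, self.W.value, axes=([1], [0])).transpose(0, 3, 1, 2)


class BatchNorm2d(Layer):
    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5, name: str = "bn"):
        self.gamma = Param(np.ones(c), f"{name}.gamma")
        self.beta = Param(np.zeros(c), f"{name}.beta")
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean[None, :, None, None]) / self._std[None, :, None, None]
        self._train = train
        self._m = x.shape[0] * x.shape[2] * x.shape[3]
        return (
            self.gamma.value[None, :, None, None] * self._xhat
            + self.beta.value[None, :, None, None]
        )

    def backward(self, dout):
        xhat, std, m = self._xhat, self._std, self._m
        self.gamma.grad += (dout * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dout.sum(axis=(0, 2, 3))
        dxhat = dout * self.gamma.value[None, :, None, None]
        if not self._train:
            return dxhat / std[None, :, None, None]
        s1 = dxhat.sum(axis=(0, 2, 3))[None, :, None, None]
        s2 = (dxhat * xhat).sum(axis=(0, 2, 3))[None, :, None, None]
        return (dxhat - s1 / m - xhat * s2 / m) / std[None, :, None, None]


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class SqueezeExcite(Layer):
    """Channel attention: GAP -> dense (reduction) -> ReLU -> dense -> sigmoid -> scale."""

    def __init__(self, c: int, reduction: int = 2, *, rng: np.random.Generator, name: str = "se"):
        cr = max(1, c // reduction)
        self.W1 = Param(rng.normal(0.0, np.sqrt(2.0 / c), (c, cr)), f"{name}.W1")
        self.b1 = Param(np.zeros(cr), f"{name}.b1")
        self.W2 = Param(rng.normal(0.0, np.sqrt(2.0 / cr), (cr, c)), f"{name}.W2")
        self.b2 = Param(np.zeros(c), f"{name}.b2")

    def params(self):
        return [self.W1, self.b1, self.W2, self.b2]

    def forward(self, x, train):
        self._x = x
        self._s = x.mean(axis=(2, 3))  # (N, C)
        self._h = np.maximum(self._s @ self.W1.value + self.b1.value, 0.0)
        self._g = 1.0 / (1.0 + np.exp(-(self._h @ self.W2.value + self.b2.value)))
        return x * self._g[:, :, None, None]

    def backward(self, dout):
        x, s, h, g = self._x, self._s, self._h, self._g
        dx_scale = dout * g[:, :, None, None]
        dg = (dout * x).sum(axis=(2, 3))  # (N, C)
        dz2 = dg * g * (1.0 - g)
        self.W2.grad += h.T @ dz2
        self.b2.grad += dz2.sum(axis=0)
        dh = dz2 @ self.W2.value.T
        dz1 = dh * (h > 0)
        self.W1.grad += s.T @ dz1
        self.b1.grad += dz1.sum(axis=0)
        ds = dz1 @ self.W1.value.T  # (N, C)
        hw = x.shape[2] * x.shape[3]
        return dx_scale + ds[:, :, None, None] / hw


class MaxPool2x2(Layer):
    def forward(self, x, train):
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError("max pooling requires even spatial dimensions")
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        out = xr.max(axis=(3, 5))
        winners = xr == out[:, :, :, None, :, None]
        # break ties toward one winner so gradients are not duplicated
        flat = winners.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
        first = np.argmax(flat, axis=-1)
        tie_free = np.zeros_like(flat, dtype=np.float64)
        np.put_along_axis(tie_free, first[..., None], 1.0, axis=-1)
        self._mask = (
            tie_free.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).astype(bool)
        )
        self._shape = x.shape
        return out

    def backward(self, dout):
        n, c, h, w = self._shape
        dx = np.zeros((n, c, h // 2, 2, w // 2, 2))
        dx += dout[:, :, :, None, :, None] * self._mask
        return dx.reshape(n, c, h, w)


class GlobalAvgPool(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout):
        n, c, h, w = self._shape
        return np.broadcast_to(dout[:, :, None, None], (n, c, h, w)) / (h * w)


class Dropout(Layer):
    def __init__(self, p: float, rng: np.random.Generator):
        self.p = p
        self.rng = rng

    def forward(self, x, train):
        if not train or self.p <= 0:
            self._mask = None
            return x
        self._mask = (self.rng.uniform(size=x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class Dense(Layer):
    """Fully connected layer; W has shape (n_in, n_out) so rows index inputs."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, name: str = "fc"):
        self.W = Param(rng.normal(0.0, np.sqrt(2.0 / n_in), (n_in, n_out)), f"{name}.W")
        self.b = Param(np.zeros(n_out), f"{name}.b")

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dout):
        self.W.grad += self._x.T @ dout
        self.b.grad += dout.sum(axis=0)
        return dout @ self.W.value.T


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(probs: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean categorical cross-entropy and its gradient w.r.t. the logits."""
    n = probs.shape[0]
    loss = float(-np.log(np.clip(probs[np.arange(n), y], 1e-12, None)).mean())
    grad = probs.copy()
    grad[np.arange(n), y] -= 1.0
    return loss, grad / n


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * p.grad
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * p.grad**2
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
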