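"""NumPy layers with explicit forward/backward passes.

Tensors are (N, C, H, W).  Each layer caches what its backward pass needs;
``backward`` consumes the gradient w.r.t. the layer output and returns the
gradient w.r.t. its input, accumulating parameter gradients on
:class:`Param` objects.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    """A named weight array with its gradient and trainability flag."""

    def __init__(self, name: str, value: np.ndarray, trainable: bool = True):
        self.name = name
        self.value = np.asarray(value, dtype=float)
        self.grad = np.zeros_like(self.value)
        self.trainable = trainable

    @property
    def size(self) -> int:
        return self.value.size


class Layer:
    def params(self) -> list:
        return []

    def forward(self, x, train: bool = False):
        raise NotImplementedError

    def backward(self, grad):
        raise NotImplementedError


class Conv2D(Layer):
    """Same-padding stride-1 convolution with bias (He-initialised)."""

    def __init__(self, cin: int, cout: int, kernel: int = 3, name: str = "conv", rng=None):
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / (cin * kernel * kernel))
        self.w = Param(f"{name}.w", rng.normal(0.0, std, (cout, cin, kernel, kernel)))
        self.b = Param(f"{name}.b", np.zeros(cout))
        self.kernel = kernel
        self.pad = kernel // 2

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train: bool = False):
        n, c, h, w = x.shape
        k, p = self.kernel, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        cols = sliding_window_view(xp, (k, k), axis=(2, 3))  # (N, C, H, W, k, k)
        cols = cols.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * k * k)
        self._cols, self._shape = cols, (n, c, h, w)
        cout = self.w.value.shape[0]
        out = cols @ self.w.value.reshape(cout, -1).T + self.b.value
        return out.reshape(n, h, w, cout).transpose(0, 3, 1, 2)

    def backward(self, grad):
        n, c, h, w = self._shape
        k, p = self.kernel, self.pad
        cout = self.w.value.shape[0]
        g = grad.transpose(0, 2, 3, 1).reshape(n * h * w, cout)
        self.w.grad += (g.T @ self._cols).reshape(self.w.value.shape)
        self.b.grad += g.sum(axis=0)
        dcols = (g @ self.w.value.reshape(cout, -1)).reshape(n, h, w, c, k, k)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p))
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + h, j : j + w] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        return dxp[:, :, p : p + h, p : p + w] if p else dxp


class BatchNorm2d(Layer):
    """Per-channel batch normalisation with running statistics."""

    def __init__(self, channels: int, name: str = "bn", momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(f"{name}.gamma", np.ones(channels))
        self.beta = Param(f"{name}.beta", np.zeros(channels))
        self.running_mean = Param(f"{name}.moving_mean", np.zeros(channels), trainable=False)
        self.running_var = Param(f"{name}.moving_var", np.ones(channels), trainable=False)
        self.momentum = momentum
        self.eps = eps

    def params(self):
        return [self.gamma, self.beta, self.running_mean, self.running_var]

    def forward(self, x, train: bool = False):
        axes = (0, 2, 3)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean.value = (
                (1 - self.momentum) * self.running_mean.value + self.momentum * mean
            )
            self.running_var.value = (
                (1 - self.momentum) * self.running_var.value + self.momentum * var
            )
        else:
            mean, var = self.running_mean.value, self.running_var.value
        mean4 = mean[None, :, None, None]
        inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean4) * inv[None, :, None, None]
        self._inv = inv
        self._m = x.shape[0] * x.shape[2] * x.shape[3]
        self._train = train
        return self.gamma.value[None, :, None, None] * self._xhat + self.beta.value[None, :, None, None]

    def backward(self, grad):
        axes = (0, 2, 3)
        self.gamma.grad += (grad * self._xhat).sum(axis=axes)
        self.beta.grad += grad.sum(axis=axes)
        g = grad * self.gamma.value[None, :, None, None]
        if not self._train:
            return g * self._inv[None, :, None, None]
        m = self._m
        sum_g = g.sum(axis=axes, keepdims=True)
        sum_gx = (g * self._xhat).sum(axis=axes, keepdims=True)
        return (
            self._inv[None, :, None, None] / m * (m * g - sum_g - self._xhat * sum_gx)
        )


class ReLU(Layer):
    def forward(self, x, train: bool = False):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad):
        return grad * self._mask


class MaxPool2(Layer):
    """2x2 max pooling (stride 2); ties split the gradient evenly."""

    def forward(self, x, train: bool = False):
        n, c, h, w = x.shape
        x6 = x.reshape(n, c, h // 2, 2, w // 2, 2)
        out = x6.max(axis=(3, 5))
        self._mask = x6 == out[:, :, :, None, :, None]
        self._count = self._mask.sum(axis=(3, 5), keepdims=True)
        self._shape = x.shape
        return out

    def backward(self, grad):
        n, c, h, w = self._shape
        g6 = self._mask * (grad[:, :, :, None, :, None] / self._count)
        return g6.reshape(n, c, h, w)


class UpsampleNearest2(Layer):
    def forward(self, x, train: bool = False):
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, grad):
        n, c, h, w = grad.shape
        return grad.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class Dropout(Layer):
    """Inverted dropout; active only in training mode, seeded via ``rng``."""

    def __init__(self, rate: float):
        self.rate = rate
        self.rng = np.random.default_rng(0)

    def forward(self, x, train: bool = False):
        if not train or self.rate == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Dense(Layer):
    def __init__(self, cin: int, cout: int, name: str = "dense", rng=None):
        rng = rng or np.random.default_rng(0)
        self.w = Param(f"{name}.w", rng.normal(0.0, np.sqrt(2.0 / cin), (cin, cout)))
        self.b = Param(f"{name}.b", np.zeros(cout))

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train: bool = False):
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, grad):
        self.w.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        return grad @ self.w.value.T


class GlobalAvgPool(Layer):
    def forward(self, x, train: bool = False):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad):
        n, c, h, w = self._shape
        return np.broadcast_to(grad[:, :, None, None], self._shape) / (h * w)


class Sigmoid(Layer):
    def forward(self, x, train: bool = False):
        self._y = 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))
        return self._y

    def backward(self, grad):
        return grad * self._y * (1.0 - self._y)


class SoftmaxChannels(Layer):
    """Softmax across the channel axis so output channels sum to 1 per pixel."""

    def forward(self, x, train: bool = False):
        z = x - x.max(axis=1, keepdims=True)
        e = np.exp(z)
        self._p = e / e.sum(axis=1, keepdims=True)
        return self._p

    def backward(self, grad):
        p = self._p
        return p * (grad - (grad * p).sum(axis=1, keepdims=True))
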