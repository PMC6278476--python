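"""A small NumPy engine for 1-D convolutional networks on spectra.

Implements exactly the layer set the spectral classifier needs — 1-D
convolution (kernel 3, stride 1, padding 1), batch normalization, ELU,
max-pooling (kernel 2, stride 2, floor on odd lengths), flatten and dense
layers — with explicit forward/backward passes and an SGD-with-momentum
update. Shapes are (batch, channels, length) for convolutional layers and
(batch, features) after flattening. Weight initialization is He-style and
fully determined by the generator passed in.
"""

from __future__ import annotations

import numpy as np

from .exceptions import InvalidArgumentError

__all__ = [
    "Conv1d",
    "BatchNorm",
    "Elu",
    "MaxPool1d",
    "Flatten",
    "Dense",
    "Sequential",
    "softmax",
    "softmax_cross_entropy_grad",
]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy_grad(logits: np.ndarray, onehot: np.ndarray):
    """Mean cross-entropy of softmax(logits) against one-hot targets and its
    gradient w.r.t. the logits."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = -np.sum(onehot * np.log(np.clip(p, 1e-12, None))) / n
    return loss, (p - onehot) / n


class Layer:
    """Base layer: parameters live in ``params`` as (value, grad, velocity)."""

    def __init__(self) -> None:
        self.params: list[list[np.ndarray]] = []
        self.training = True

    def add_param(self, value: np.ndarray) -> list[np.ndarray]:
        entry = [value, np.zeros_like(value), np.zeros_like(value)]
        self.params.append(entry)
        return entry

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def num_params(self) -> int:
        return sum(p[0].size for p in self.params)


class Conv1d(Layer):
    """1-D convolution, kernel 3, stride 1, zero padding 1 (length preserved)."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int = 3,
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        if kernel % 2 != 1:
            raise InvalidArgumentError("only odd kernels supported")
        rng = rng or np.random.default_rng(0)
        fan_in = in_channels * kernel
        self.kernel = kernel
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.w = self.add_param(
            rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_channels, in_channels * kernel))
        )
        self.b = self.add_param(np.zeros(out_channels))
        self._cols: np.ndarray | None = None

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        # x: (n, c, L) -> (n, L, c*k), zero-padded so length is preserved
        k = self.kernel
        pad = k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
        n, c, Lp = xp.shape
        L = x.shape[2]
        strides = xp.strides
        windows = np.lib.stride_tricks.as_strided(
            xp, shape=(n, c, L, k), strides=(strides[0], strides[1], strides[2], strides[2])
        )
        return windows.transpose(0, 2, 1, 3).reshape(n, L, c * k)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x_shape = x.shape
        cols = self._im2col(x)
        self._cols = cols
        y = cols @ self.w[0].T + self.b[0]  # (n, L, out)
        return y.transpose(0, 2, 1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = grad.transpose(0, 2, 1)  # (n, L, out)
        n, L, _ = g.shape
        cols = self._cols
        self.w[1] += g.reshape(-1, self.out_channels).T @ cols.reshape(-1, cols.shape[2])
        self.b[1] += g.sum(axis=(0, 1))
        gcols = g @ self.w[0]  # (n, L, c*k)
        # col2im: scatter-add back through the padding
        k = self.kernel
        pad = k // 2
        c = self.in_channels
        gx = np.zeros((n, c, L + 2 * pad))
        gcols = gcols.reshape(n, L, c, k)
        for j in range(k):
            gx[:, :, j : j + L] += gcols[:, :, :, j].transpose(0, 2, 1)
        return gx[:, :, pad : pad + L]


class BatchNorm(Layer):
    """Batch normalization over the batch (and length, for conv inputs).

    Accepts (n, c, L) or (n, f); statistics are per channel/feature. Running
    statistics (momentum 0.9) are used in evaluation mode.
    """

    def __init__(self, n_features: int, eps: float = 1e-5, momentum: float = 0.9) -> None:
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = self.add_param(np.ones(n_features))
        self.beta = self.add_param(np.zeros(n_features))
        self.running_mean = np.zeros(n_features)
        self.running_var = np.ones(n_features)

    def _axes(self, x: np.ndarray):
        return (0, 2) if x.ndim == 3 else (0,)

    def _shape(self, x: np.ndarray):
        return (1, -1, 1) if x.ndim == 3 else (1, -1)

    def forward(self, x: np.ndarray) -> np.ndarray:
        axes, shp = self._axes(x), self._shape(x)
        if self.training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean.reshape(shp)) / self._std.reshape(shp)
        return self.gamma[0].reshape(shp) * self._xhat + self.beta[0].reshape(shp)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        axes, shp = self._axes(grad), self._shape(grad)
        xhat = self._xhat
        self.gamma[1] += np.sum(grad * xhat, axis=axes)
        self.beta[1] += np.sum(grad, axis=axes)
        gxhat = grad * self.gamma[0].reshape(shp)
        # standard BN backward through batch statistics
        gx = (
            gxhat
            - np.mean(gxhat, axis=axes).reshape(shp)
            - xhat * np.mean(gxhat * xhat, axis=axes).reshape(shp)
        ) / self._std.reshape(shp)
        return gx


class Elu(Layer):
    """Exponential linear unit: x for x >= 0, alpha(e^x - 1) otherwise."""

    def __init__(self, alpha: float = 1.0) -> None:
        super().__init__()
        if alpha <= 0:
            raise InvalidArgumentError("alpha must be positive")
        self.alpha = alpha

    def forward(self, x: np.ndarray) -> np.ndarray:
        neg = x < 0
        y = np.where(neg, self.alpha * np.expm1(np.minimum(x, 0.0)), x)
        self._y = y
        self._neg = neg
        return y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * np.where(self._neg, self._y + self.alpha, 1.0)


class MaxPool1d(Layer):
    """Max pooling, kernel 2, stride 2; an odd trailing element is dropped."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, L = x.shape
        half = L // 2
        if half < 1:
            raise InvalidArgumentError("sequence too short to pool")
        xt = x[:, :, : 2 * half].reshape(n, c, half, 2)
        self._arg = xt.argmax(axis=3)
        self._in_len = L
        return xt.max(axis=3)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, half = grad.shape
        gx = np.zeros((n, c, self._in_len))
        gt = np.zeros((n, c, half, 2))
        np.put_along_axis(gt, self._arg[..., None], grad[..., None], axis=3)
        gx[:, :, : 2 * half] = gt.reshape(n, c, 2 * half)
        return gx


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.w = self.add_param(
            rng.normal(0.0, np.sqrt(2.0 / in_features), size=(in_features, out_features))
        )
        self.b = self.add_param(np.zeros(out_features))

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w[0] + self.b[0]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.w[1] += self._x.T @ grad
        self.b[1] += grad.sum(axis=0)
        return grad @ self.w[0].T


class Sequential:
    """A feed-forward stack with SGD + momentum training support."""

    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def train_mode(self, flag: bool = True) -> None:
        for layer in self.layers:
            layer.training = flag

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad: np.ndarray) -> None:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def zero_grad(self) -> None:
        for layer in self.layers:
            for p in layer.params:
                p[1][...] = 0.0

    def sgd_step(self, lr: float, momentum: float) -> None:
        for layer in self.layers:
            for p in layer.params:
                p[2][...] = momentum * p[2] - lr * p[1]
                p[0][...] += p[2]

    def num_params(self) -> int:
        return sum(layer.num_params() for layer in self.layers)
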