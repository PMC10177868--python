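"""Minimal 1-D convolutional network engine in NumPy.

Implements exactly the layer set the spectral regression networks need —
valid-padding 1-D convolution, batch normalization, ReLU, 2:1 max pooling,
flatten, dense layers — with explicit reverse-mode gradients and an Adam
optimizer.  Everything is deterministic given a seed, runs on one CPU, and
uses float32 by default (float64 is available for gradient checking).

Tensor layout is (batch, channels, length) for convolutional layers and
(batch, features) after the flatten.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    """Base layer: stateless unless it declares parameters."""

    trainable = True

    def parameters(self) -> dict[str, np.ndarray]:
        return {}

    def gradients(self) -> dict[str, np.ndarray]:
        return {}

    def state(self) -> dict[str, np.ndarray]:
        """All arrays needed to restore the layer (parameters + buffers)."""
        return self.parameters()

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv1d(Layer):
    """Valid-padding 1-D convolution (cross-correlation), stride 1.

    Weights are Kaiming-uniform on fan-in = in_channels * kernel_size, the
    convention spectral CNNs are usually initialized with.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        rng: np.random.Generator,
        dtype=np.float32,
    ) -> None:
        fan_in = in_channels * kernel_size
        bound = 1.0 / np.sqrt(fan_in)
        self.weight = rng.uniform(-bound, bound, (out_channels, in_channels, kernel_size)).astype(dtype)
        self.bias = rng.uniform(-bound, bound, out_channels).astype(dtype)
        self.kernel_size = kernel_size
        self._grads: dict[str, np.ndarray] = {}

    def parameters(self):
        return {"weight": self.weight, "bias": self.bias}

    def gradients(self):
        return self._grads

    def forward(self, x, training):
        self._x = x
        n, c_in, length = x.shape
        k = self.kernel_size
        l_out = length - k + 1
        # (n, c_in, l_out, k) windows -> matmul against (c_out, c_in*k)
        win = sliding_window_view(x, k, axis=2)
        self._win = win.transpose(0, 2, 1, 3).reshape(n * l_out, c_in * k)
        w2 = self.weight.reshape(self.weight.shape[0], c_in * k)
        y = self._win @ w2.T + self.bias
        return np.ascontiguousarray(y.reshape(n, l_out, -1).transpose(0, 2, 1))

    def backward(self, grad):
        n, c_out, l_out = grad.shape
        _, c_in, length = self._x.shape
        k = self.kernel_size
        g2 = grad.transpose(0, 2, 1).reshape(n * l_out, c_out)
        dw = (g2.T @ self._win).reshape(self.weight.shape)
        db = g2.sum(axis=0)
        if not self.trainable:
            self._grads = {}
        else:
            self._grads = {"weight": dw.astype(self.weight.dtype), "bias": db.astype(self.bias.dtype)}
        # dx: full correlation of grad with the flipped kernel
        gpad = np.zeros((n, c_out, l_out + 2 * (k - 1)), dtype=grad.dtype)
        gpad[:, :, k - 1 : k - 1 + l_out] = grad
        gwin = sliding_window_view(gpad, k, axis=2)  # (n, c_out, length, k)
        gwin = gwin.transpose(0, 2, 1, 3).reshape(n * length, c_out * k)
        wflip = self.weight[:, :, ::-1].transpose(1, 0, 2).reshape(c_in, c_out * k)
        dx = (gwin @ wflip.T).reshape(n, length, c_in).transpose(0, 2, 1)
        return np.ascontiguousarray(dx)


class BatchNorm(Layer):
    """Batch normalization over (batch, length) per channel, or per feature
    for 2-D inputs.  Training mode uses in-batch statistics (biased
    variance) and maintains running statistics for evaluation mode."""

    def __init__(self, n_features: int, momentum: float = 0.1, eps: float = 1e-5, dtype=np.float32) -> None:
        self.gamma = np.ones(n_features, dtype=dtype)
        self.beta = np.zeros(n_features, dtype=dtype)
        self.running_mean = np.zeros(n_features, dtype=dtype)
        self.running_var = np.ones(n_features, dtype=dtype)
        self.momentum = momentum
        self.eps = eps
        self._grads: dict[str, np.ndarray] = {}

    def parameters(self):
        return {"gamma": self.gamma, "beta": self.beta}

    def gradients(self):
        return self._grads

    def state(self):
        return {
            "gamma": self.gamma,
            "beta": self.beta,
            "running_mean": self.running_mean,
            "running_var": self.running_var,
        }

    def _shape(self, x):
        return (1, -1, 1) if x.ndim == 3 else (1, -1)

    def forward(self, x, training):
        axes = (0, 2) if x.ndim == 3 else (0,)
        shape = self._shape(x)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps).reshape(shape)
        self._xhat = (x - mean.reshape(shape)) / self._std
        self._training = training
        return self.gamma.reshape(shape) * self._xhat + self.beta.reshape(shape)

    def backward(self, grad):
        axes = (0, 2) if grad.ndim == 3 else (0,)
        shape = self._shape(grad)
        dgamma = (grad * self._xhat).sum(axis=axes)
        dbeta = grad.sum(axis=axes)
        if self.trainable:
            self._grads = {"gamma": dgamma.astype(self.gamma.dtype), "beta": dbeta.astype(self.beta.dtype)}
        else:
            self._grads = {}
        g = grad * self.gamma.reshape(shape)
        if not self._training:
            return g / self._std
        mean_g = g.mean(axis=axes).reshape(shape)
        mean_gx = (g * self._xhat).mean(axis=axes).reshape(shape)
        return (g - mean_g - self._xhat * mean_gx) / self._std


class ReLU(Layer):
    def forward(self, x, training):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class MaxPool1d(Layer):
    """Valid-padding max pooling, kernel 2 / stride 2.

    An odd trailing element is discarded, matching valid-padding pooling;
    this floor behaviour is what the network's shape arithmetic assumes.
    """

    def forward(self, x, training):
        n, c, length = x.shape
        l_out = length // 2
        self._in_length = length
        xv = x[:, :, : 2 * l_out].reshape(n, c, l_out, 2)
        self._argmax = xv.argmax(axis=3)
        return np.take_along_axis(xv, self._argmax[..., None], axis=3)[..., 0]

    def backward(self, grad):
        n, c, l_out = grad.shape
        dx = np.zeros((n, c, self._in_length), dtype=grad.dtype)
        dxv = dx[:, :, : 2 * l_out].reshape(n, c, l_out, 2)
        np.put_along_axis(dxv, self._argmax[..., None], grad[..., None], axis=3)
        return dx


class Flatten(Layer):
    def forward(self, x, training):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator, dtype=np.float32) -> None:
        bound = 1.0 / np.sqrt(in_features)
        self.weight = rng.uniform(-bound, bound, (in_features, out_features)).astype(dtype)
        self.bias = rng.uniform(-bound, bound, out_features).astype(dtype)
        self._grads: dict[str, np.ndarray] = {}

    def parameters(self):
        return {"weight": self.weight, "bias": self.bias}

    def gradients(self):
        return self._grads

    def forward(self, x, training):
        self._x = x
        return x @ self.weight + self.bias

    def backward(self, grad):
        if self.trainable:
            self._grads = {
                "weight": (self._x.T @ grad).astype(self.weight.dtype),
                "bias": grad.sum(axis=0).astype(self.bias.dtype),
            }
        else:
            self._grads = {}
        return grad @ self.weight.T


class Sequential(Layer):
    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def forward(self, x, training):
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


class Adam:
    """Adam with the conventional defaults: betas (0.9, 0.999), eps 1e-8."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 0.005,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8) -> None:
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for key, g in grads.items():
            p = self.params[key]
            m = self.m[key]
            v = self.v[key]
            m += (1.0 - self.b1) * (g - m)
            v += (1.0 - self.b2) * (g * g - v)
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def collect_named(prefix: str, layer: Layer, out: dict[str, tuple[Layer, str]]) -> None:
    """Flatten a layer tree into ``{qualified_name: (layer, array_key)}``."""
    if isinstance(layer, Sequential):
        for i, sub in enumerate(layer.layers):
            collect_named(f"{prefix}.{i}", sub, out)
    else:
        for key in layer.parameters():
            out[f"{prefix}.{key}"] = (layer, key)
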