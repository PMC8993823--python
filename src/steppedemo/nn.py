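"""Minimal seeded neural-network framework (numpy, CPU, deterministic).

Implements exactly the pieces the SNP-image classifier/regressor needs:
1-D convolution over the SNP axis (haplotype rows enter as input channels),
batch normalization, ReLU, max/global-average pooling, dense layers, Adam,
and softmax cross-entropy / mean-squared-error losses with full backprop.
All randomness flows through an explicit ``numpy.random.Generator``, so a
given seed reproduces training bit-for-bit on a fixed BLAS configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Conv1d",
    "BatchNorm1d",
    "ReLU",
    "MaxPool1d",
    "GlobalAvgPool1d",
    "Dense",
    "Sequential",
    "Adam",
    "softmax",
    "softmax_cross_entropy",
    "mse_loss",
    "build_cnn",
]


@dataclass
class Param:
    value: np.ndarray
    grad: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv1d(Layer):
    """Valid cross-correlation along the last axis: (N, C, L) -> (N, F, L-k+1)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * kernel))
        self.w = Param(rng.normal(0.0, scale, size=(c_out, c_in, kernel)).astype(np.float64))
        self.b = Param(np.zeros(c_out))
        self.kernel = kernel

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._xw = np.lib.stride_tricks.sliding_window_view(x, self.kernel, axis=2)
        return np.einsum("nclk,fck->nfl", self._xw, self.w.value, optimize=True) + self.b.value[:, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.w.grad += np.einsum("nclk,nfl->fck", self._xw, grad, optimize=True)
        self.b.grad += grad.sum(axis=(0, 2))
        k = self.kernel
        padded = np.pad(grad, ((0, 0), (0, 0), (k - 1, k - 1)))
        gw = np.lib.stride_tricks.sliding_window_view(padded, k, axis=2)
        return np.einsum("nflk,fck->ncl", gw, self.w.value[:, :, ::-1], optimize=True)


class SummaryChannels(Layer):
    """Append per-column, per-lineage-block summary channels to the image.

    For the rows above and below ``boundary`` (the two lineage blocks) four
    channels are added: fraction of called (non-zero) pixels and derived
    (+1) fraction among called pixels, per block.  This hands the network
    the missingness-normalized allele frequencies that raw three-level
    pixels only encode implicitly through division.  Non-trainable.
    """

    def __init__(self, boundary: int):
        self.boundary = boundary

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._n_rows = x.shape[1]
        extras = []
        for sl in (slice(None, self.boundary), slice(self.boundary, None)):
            block = x[:, sl, :]
            called = (block != 0).sum(axis=1)
            derived = (block == 1).sum(axis=1)
            extras.append(called / block.shape[1])
            extras.append(derived / np.maximum(called, 1))
        return np.concatenate([x] + [e[:, None, :] for e in extras], axis=1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad[:, : self._n_rows, :]


class BatchNorm1d(Layer):
    """Per-channel batch normalization over the (batch, length) axes."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)[None, :, None]
        self._xhat = (x - mean[None, :, None]) / self._std
        return self.gamma.value[None, :, None] * self._xhat + self.beta.value[None, :, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.gamma.grad += (grad * self._xhat).sum(axis=(0, 2))
        self.beta.grad += grad.sum(axis=(0, 2))
        g = grad * self.gamma.value[None, :, None]
        m = grad.shape[0] * grad.shape[2]
        return (
            g - g.mean(axis=(0, 2), keepdims=True)
            - self._xhat * (g * self._xhat).sum(axis=(0, 2), keepdims=True) / m
        ) / self._std


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class MaxPool1d(Layer):
    """Non-overlapping max pooling; a trailing remainder is dropped."""

    def __init__(self, size: int = 2):
        self.size = size

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, length = x.shape
        lp = length // self.size
        self._in_shape = x.shape
        xr = x[:, :, : lp * self.size].reshape(n, c, lp, self.size)
        self._argmax = xr.argmax(axis=3)
        return xr.max(axis=3)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, lp = grad.shape
        out = np.zeros((n, c, lp, self.size))
        np.put_along_axis(out, self._argmax[..., None], grad[..., None], axis=3)
        full = np.zeros(self._in_shape)
        full[:, :, : lp * self.size] = out.reshape(n, c, lp * self.size)
        return full


class GlobalAvgPool1d(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._length = x.shape[2]
        return x.mean(axis=2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.repeat(grad[:, :, None], self._length, axis=2) / self._length


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.w = Param(rng.normal(0.0, scale, size=(n_in, n_out)))
        self.b = Param(np.zeros(n_out))

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.w.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        return grad @ self.w.value.T


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    def state_bytes(self) -> bytes:
        """Concatenated parameter bytes (for reproducibility hashing)."""
        return b"".join(np.ascontiguousarray(p.value).tobytes() for p in self.params())

    def get_state(self) -> list[np.ndarray]:
        """Copies of all parameters and batch-norm running statistics."""
        state = [p.value.copy() for p in self.params()]
        for layer in self.layers:
            if isinstance(layer, BatchNorm1d):
                state += [layer.running_mean.copy(), layer.running_var.copy()]
        return state

    def set_state(self, state: list[np.ndarray]) -> None:
        params = self.params()
        for p, v in zip(params, state[: len(params)]):
            p.value[...] = v
        i = len(params)
        for layer in self.layers:
            if isinstance(layer, BatchNorm1d):
                layer.running_mean[...] = state[i]
                layer.running_var[...] = state[i + 1]
                i += 2


class Adam:
    """Adam with optional decoupled (AdamW-style) weight decay."""

    def __init__(self, params: list[Param], lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * p.grad
            v[...] = b2 * v + (1 - b2) * p.grad**2
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.value -= self.lr * (mhat / (np.sqrt(vhat) + self.eps) + self.weight_decay * p.value)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean NLL and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    p = softmax(logits)
    loss = -np.log(p[np.arange(n), labels] + 1e-300).mean()
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return float(loss), grad / n


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    diff = pred - target
    return float((diff**2).mean()), 2.0 * diff / diff.size


def build_cnn(
    n_channels: int,
    n_out: int,
    rng: np.random.Generator,
    conv_channels: tuple[int, ...] = (32, 32, 32),
    kernels: tuple[int, ...] = (2, 5, 10),
    head: str = "gap",
    width: int | None = None,
    hidden: int = 0,
) -> Sequential:
    """Stacked conv blocks with distinct kernel sizes, each followed by batch
    normalization and pooling, then a dense head.

    The input is (N, H, W) with the H haplotype rows as channels.  With
    ``head="gap"`` the last block ends in global average pooling, accepting
    any width above the receptive-field minimum; ``head="flatten"``
    (requires ``width``) keeps the positional layout of the final feature
    map, which matters when columns are sorted so that position along the
    SNP axis encodes a frequency quantile.  ``hidden`` > 0 inserts one
    intermediate dense+ReLU stage before the output layer.
    """
    if len(conv_channels) != len(kernels):
        raise ValueError("conv_channels and kernels must have equal length")
    if head not in ("gap", "flatten"):
        raise ValueError("head must be 'gap' or 'flatten'")
    layers: list[Layer] = []
    c_in = n_channels
    length = width
    last = len(kernels) - 1
    for i, (c_out, k) in enumerate(zip(conv_channels, kernels)):
        layers += [Conv1d(c_in, c_out, k, rng), BatchNorm1d(c_out), ReLU()]
        if length is not None:
            length -= k - 1
        if i == last and head == "gap":
            layers.append(GlobalAvgPool1d())
        else:
            layers.append(MaxPool1d(2))
            if length is not None:
                length //= 2
        c_in = c_out
    if head == "flatten":
        if width is None:
            raise ValueError("head='flatten' requires the input width")
        layers.append(Flatten())
        c_in = c_in * length
    if hidden > 0:
        layers += [Dense(c_in, hidden, rng), ReLU()]
        c_in = hidden
    layers.append(Dense(c_in, n_out, rng))
    return Sequential(layers)
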