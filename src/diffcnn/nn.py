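"""Minimal NumPy neural-network layers with exact reverse-mode gradients.

The layers cover what the sequence models need: 1-D convolution (optionally
dilated, "same" padding), batch normalisation, ReLU, dropout, max-pooling,
global max/average pooling, dense layers and channel concatenation.  Every
layer implements ``forward(x, train)`` and ``backward(dout) -> dx`` so that
gradients can be propagated all the way to the one-hot input — attribution
methods depend on d(logit)/d(input), not only on parameter gradients.

Arrays are float32 (single precision roughly halves the memory-bandwidth
cost of the convolution and batch-norm passes that dominate CPU training).
Sequence tensors are shaped ``(batch, channels, length)``; feature tensors
``(batch, features)``.  Losses are accumulated in float64.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32

__all__ = [
    "Parameter",
    "Layer",
    "Conv1d",
    "BatchNorm1d",
    "ReLU",
    "Dropout",
    "MaxPool1d",
    "GlobalMaxPool",
    "GlobalAvgPool",
    "GlobalMaxAvgPool",
    "Dense",
    "Flatten",
    "Sequential",
    "Adam",
    "softmax",
    "cross_entropy_grad",
    "mse_grad",
]


class Parameter:
    """A trainable array with an accumulated gradient and a freeze flag."""

    __slots__ = ("data", "grad", "trainable", "name")

    def __init__(self, data: np.ndarray, name: str = "", trainable: bool = True):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad = np.zeros_like(self.data)
        self.trainable = trainable
        self.name = name

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    def params(self) -> list[Parameter]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def freeze(self) -> None:
        for p in self.params():
            p.trainable = False


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv1d(Layer):
    """1-D convolution with 'same' padding and optional dilation.

    Weight shape (out_channels, in_channels, kernel).  The effective span is
    ``(kernel - 1) * dilation + 1``; the output length equals the input length.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 dilation: int = 1, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        self.dilation = dilation
        fan_in = in_channels * kernel
        self.w = Parameter(_he_init(rng, (out_channels, in_channels, kernel), fan_in), "conv.w")
        self.b = Parameter(np.zeros(out_channels), "conv.b")
        self._cache = None

    def params(self) -> list[Parameter]:
        return [self.w, self.b]

    @property
    def span(self) -> int:
        return (self.kernel - 1) * self.dilation + 1

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        B, C, L = x.shape
        span = self.span
        pl = (span - 1) // 2
        pr = span - 1 - pl
        xp = np.pad(x, ((0, 0), (0, 0), (pl, pr)))
        # (B, C*K, L): row c*K+k holds channel c shifted by k*dilation
        cols = np.empty((B, C, self.kernel, L), dtype=DTYPE)
        for k in range(self.kernel):
            off = k * self.dilation
            cols[:, :, k, :] = xp[:, :, off:off + L]
        return cols.reshape(B, C * self.kernel, L)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=DTYPE)
        cols = self._im2col(x)
        W2 = self.w.data.reshape(self.out_channels, -1)
        # batched gemm: (1,O,CK) @ (B,CK,L) -> (B,O,L)
        y = np.matmul(W2[None], cols) + self.b.data[None, :, None]
        self._cache = (x.shape, cols)
        return y

    def backward(self, dout: np.ndarray) -> np.ndarray:
        (B, C, L), cols = self._cache
        dout = np.asarray(dout, dtype=DTYPE)
        dW2 = np.matmul(dout, cols.transpose(0, 2, 1)).sum(axis=0)  # (O, CK)
        self.w.grad += dW2.reshape(self.w.data.shape)
        self.b.grad += dout.sum(axis=(0, 2))
        W2 = self.w.data.reshape(self.out_channels, -1)
        dcols = np.matmul(W2.T[None], dout)  # (B, CK, L)
        dcols = dcols.reshape(B, C, self.kernel, L)
        span = self.span
        pl = (span - 1) // 2
        dxp = np.zeros((B, C, L + span - 1), dtype=DTYPE)
        for k in range(self.kernel):
            off = k * self.dilation
            dxp[:, :, off:off + L] += dcols[:, :, k, :]
        return dxp[:, :, pl:pl + L]


class BatchNorm1d(Layer):
    """Per-channel batch normalisation over (batch, length).

    Training mode normalises by batch statistics and updates running moments;
    evaluation mode applies the affine map implied by the running moments
    (which keeps the evaluated network piecewise-linear in its input).
    """

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(channels), "bn.gamma")
        self.beta = Parameter(np.zeros(channels), "bn.beta")
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)
        self._cache = None

    def params(self) -> list[Parameter]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=DTYPE)
        if train:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mean).astype(DTYPE)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var).astype(DTYPE)
        else:
            mean, var = self.running_mean, self.running_var
        inv = (1.0 / np.sqrt(var + self.eps)).astype(DTYPE)
        xhat = (x - mean[None, :, None]) * inv[None, :, None]
        self._cache = (xhat, inv, train, x.shape)
        return self.gamma.data[None, :, None] * xhat + self.beta.data[None, :, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv, train, shape = self._cache
        self.gamma.grad += (dout * xhat).sum(axis=(0, 2))
        self.beta.grad += dout.sum(axis=(0, 2))
        g = self.gamma.data[None, :, None] * inv[None, :, None]
        if not train:
            return dout * g
        B, C, L = shape
        n = B * L
        dxhat = dout * self.gamma.data[None, :, None]
        # standard batch-norm backward through the batch statistics
        dx = (inv[None, :, None] / n) * (
            n * dxhat
            - dxhat.sum(axis=(0, 2))[None, :, None]
            - xhat * (dxhat * xhat).sum(axis=(0, 2))[None, :, None]
        )
        return dx


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class Dropout(Layer):
    """Inverted dropout; identity at evaluation time."""

    def __init__(self, p: float, rng: np.random.Generator | None = None):
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout probability must be in [0, 1), got {p}")
        self.p = p
        self.rng = rng or np.random.default_rng()
        self._mask = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.p == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = ((self.rng.random(x.shape) < keep) / keep).astype(DTYPE)
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout if self._mask is None else dout * self._mask


class MaxPool1d(Layer):
    """Non-overlapping max pooling; a trailing remainder shorter than the
    window is dropped, so the output length is floor(L / width)."""

    def __init__(self, width: int):
        self.width = width

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        B, C, L = x.shape
        Lo = L // self.width
        xr = x[:, :, :Lo * self.width].reshape(B, C, Lo, self.width)
        self._arg = xr.argmax(axis=3)
        self._shape = (B, C, L, Lo)
        return xr.max(axis=3)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, C, L, Lo = self._shape
        dxr = np.zeros((B, C, Lo, self.width), dtype=DTYPE)
        np.put_along_axis(dxr, self._arg[..., None],
                          np.asarray(dout, dtype=DTYPE)[..., None], axis=3)
        dx = np.zeros((B, C, L), dtype=DTYPE)
        dx[:, :, :Lo * self.width] = dxr.reshape(B, C, Lo * self.width)
        return dx


class GlobalMaxPool(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._arg = x.argmax(axis=2)
        self._shape = x.shape
        return x.max(axis=2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, C, L = self._shape
        dx = np.zeros((B, C, L), dtype=DTYPE)
        np.put_along_axis(dx, self._arg[..., None],
                          np.asarray(dout, dtype=DTYPE)[..., None], axis=2)
        return dx


class GlobalAvgPool(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._L = x.shape[2]
        return x.mean(axis=2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.repeat(dout[:, :, None], self._L, axis=2) / self._L


class GlobalMaxAvgPool(Layer):
    """Concatenation of global max-pool and global average-pool features,
    yielding 2*channels features per example."""

    def __init__(self):
        self.gmp = GlobalMaxPool()
        self.gap = GlobalAvgPool()

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return np.concatenate([self.gmp.forward(x, train), self.gap.forward(x, train)], axis=1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        C = dout.shape[1] // 2
        return self.gmp.backward(dout[:, :C]) + self.gap.backward(dout[:, C:])


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.w = Parameter(_he_init(rng, (in_features, out_features), in_features), "dense.w")
        self.b = Parameter(np.zeros(out_features), "dense.b")

    def params(self) -> list[Parameter]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=DTYPE)
        self._x = x
        return x @ self.w.data + self.b.data

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dout = np.asarray(dout, dtype=DTYPE)
        self.w.grad += self._x.T @ dout
        self.b.grad += dout.sum(axis=0)
        return dout @ self.w.data.T


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = list(layers)

    def params(self) -> list[Parameter]:
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout


class Adam:
    """Adam optimizer; frozen parameters are never updated."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.beta1 ** self.t
        b2t = 1 - self.beta2 ** self.t
        for i, p in enumerate(self.params):
            if not p.trainable:
                continue
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * p.grad
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * p.grad ** 2
            p.data -= self.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


def softmax(logits: np.ndarray) -> np.ndarray:
    z = np.asarray(logits, dtype=np.float64)
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy_grad(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = -np.log(np.clip(p[np.arange(n), labels], 1e-12, None)).mean()
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return float(loss), (grad / n).astype(DTYPE)


def mse_grad(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error (over all entries) and its gradient w.r.t. pred."""
    diff = np.asarray(pred, dtype=np.float64) - target
    loss = float((diff ** 2).mean())
    return loss, (2.0 * diff / diff.size).astype(DTYPE)
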