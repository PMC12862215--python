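"""NumPy neural-network layers with hand-written backpropagation.

Everything operates on activations shaped ``(batch, length, channels)``
in float32.  Convolutions are computed tap-wise — one GEMM per kernel
tap against a zero-padded input — which keeps the whole cost inside
BLAS and supports arbitrary dilation with exact "same" padding (total
padding ``dilation * (kernel - 1)``, floor-half left, ceil-half right,
so even kernels preserve length too).

Each layer caches what its backward pass needs on ``forward`` and
accumulates parameter gradients into ``Param.grad`` on ``backward``.
"""

from __future__ import annotations

from typing import Dict, List

import numpy as np


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Embedding:
    """Token embedding with a frozen all-zero row for the padding token.

    Token 0 (padding and ambiguous N) maps to the zero vector and its
    row receives no gradient, so padded positions contribute nothing to
    learning through the embedding.
    """

    def __init__(self, vocab_size: int, dim: int, rng: np.random.Generator,
                 padding_index: int = 0):
        w = rng.normal(0.0, 1.0 / np.sqrt(dim), size=(vocab_size, dim))
        w[padding_index] = 0.0
        self.W = Param(w)
        self.padding_index = padding_index
        self._tokens = None

    def params(self) -> List[Param]:
        return [self.W]

    def forward(self, tokens: np.ndarray) -> np.ndarray:
        self._tokens = tokens
        return self.W.value[tokens]

    def backward(self, dy: np.ndarray) -> None:
        np.add.at(self.W.grad, self._tokens, dy)
        self.W.grad[self.padding_index] = 0.0

    def state(self) -> Dict[str, np.ndarray]:
        return {"W": self.W.value}

    def load_state(self, state: Dict[str, np.ndarray]) -> None:
        self.W.value[...] = state["W"]


class Conv1d:
    """Length-preserving dilated 1D convolution over (B, L, C) activations."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 dilation: int = 1):
        std = np.sqrt(2.0 / (kernel * c_in))
        self.W = Param(rng.normal(0.0, std, size=(kernel, c_in, c_out)))
        self.b = Param(np.zeros(c_out))
        self.kernel = kernel
        self.dilation = dilation
        total = dilation * (kernel - 1)
        self.pad_left = total // 2
        self.pad_right = total - total // 2
        self._xp = None

    def params(self) -> List[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, L, _ = x.shape
        k, d = self.kernel, self.dilation
        if k == 1:
            self._xp = x
            return x @ self.W.value[0] + self.b.value
        xp = np.zeros((B, L + d * (k - 1), x.shape[2]), dtype=np.float32)
        xp[:, self.pad_left : self.pad_left + L] = x
        self._xp = xp
        y = np.empty((B, L, self.W.value.shape[2]), dtype=np.float32)
        y[...] = self.b.value
        for t in range(k):
            y += xp[:, t * d : t * d + L] @ self.W.value[t]
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, L, c_out = dy.shape
        k, d = self.kernel, self.dilation
        self.b.grad += dy.sum(axis=(0, 1))
        dy2 = dy.reshape(B * L, c_out)
        if k == 1:
            x = self._xp
            self.W.grad[0] += x.reshape(B * L, -1).T @ dy2
            return (dy @ self.W.value[0].T).astype(np.float32, copy=False)
        xp = self._xp
        dxp = np.zeros_like(xp)
        for t in range(k):
            xs = xp[:, t * d : t * d + L].reshape(B * L, -1)
            self.W.grad[t] += xs.T @ dy2
            dxp[:, t * d : t * d + L] += dy @ self.W.value[t].T
        return dxp[:, self.pad_left : self.pad_left + L]

    def state(self) -> Dict[str, np.ndarray]:
        return {"W": self.W.value, "b": self.b.value}

    def load_state(self, state: Dict[str, np.ndarray]) -> None:
        self.W.value[...] = state["W"]
        self.b.value[...] = state["b"]


class BatchNorm:
    """Per-channel batch normalisation over the (batch, length) axes.

    Training batches normalise with their own statistics (padded
    positions included); evaluation uses the running estimates, which is
    what makes evaluation-mode forwards deterministic and
    padding-insensitive.
    """

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def params(self) -> List[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mu = x.mean(axis=(0, 1))
            var = x.var(axis=(0, 1))
            self.running_mean += self.momentum * (mu - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mu, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv_std
        if train:
            self._cache = (xhat, inv_std)
        return (xhat * self.gamma.value + self.beta.value).astype(np.float32, copy=False)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        n = dy.shape[0] * dy.shape[1]
        dxhat_sum = dy.sum(axis=(0, 1))
        dxhat_dot = (dy * xhat).sum(axis=(0, 1))
        self.beta.grad += dxhat_sum
        self.gamma.grad += dxhat_dot
        g = self.gamma.value * inv_std
        return (g * (dy - dxhat_sum / n - xhat * (dxhat_dot / n))).astype(
            np.float32, copy=False
        )

    def state(self) -> Dict[str, np.ndarray]:
        return {
            "gamma": self.gamma.value,
            "beta": self.beta.value,
            "running_mean": self.running_mean,
            "running_var": self.running_var,
        }

    def load_state(self, state: Dict[str, np.ndarray]) -> None:
        self.gamma.value[...] = state["gamma"]
        self.beta.value[...] = state["beta"]
        self.running_mean[...] = state["running_mean"]
        self.running_var[...] = state["running_var"]


class Adam:
    """Adam optimiser over a flat parameter list."""

    def __init__(self, params: List[Param], lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.beta1 ** self.t
        bc2 = 1.0 - self.beta2 ** self.t
        scale = self.lr / bc1
        sq = np.sqrt(bc2)
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m += (1.0 - self.beta1) * (g - m)
            v += (1.0 - self.beta2) * (g * g - v)
            # p -= scale * m / (sqrt(v)/sqrt(bc2) + eps); the gradient
            # buffer doubles as scratch space (it is zeroed next step)
            np.sqrt(v, out=g)
            g /= sq
            g += self.eps
            np.divide(m, g, out=g)
            g *= scale
            p.value -= g
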