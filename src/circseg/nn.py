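"""Minimal 1-D neural-network layers with hand-written backpropagation.

Everything the segmentation model needs — same-padded 1-D convolution,
ReLU, ceil-mode max pooling, dropout, batch normalization, nearest-neighbour
upsampling and a global-average context injection — implemented directly on
NumPy arrays of shape (batch, positions, channels), plus an Adam optimizer.

Each layer caches what its backward pass needs during ``forward`` and
returns the gradient w.r.t. its input from ``backward``; parameter gradients
accumulate on ``Param.grad``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


@dataclass
class Param:
    """A trainable array and its accumulated gradient."""

    name: str
    value: np.ndarray
    grad: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.value = np.asarray(self.value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv1D(Layer):
    """Same-padded cross-correlation along the position axis.

    Weights have shape (k, in_ch, out_ch); He initialization.  The kernel is
    the classic "motif scanner": at the first layer each filter's weight
    slice is directly comparable to a motif's one-hot pattern.
    """

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        kernel_width: int,
        rng: np.random.Generator,
        bias: bool = True,
        name: str = "conv",
    ) -> None:
        if kernel_width < 1:
            raise ValueError("kernel_width must be >= 1")
        scale = math.sqrt(2.0 / (kernel_width * in_ch))
        self.W = Param(f"{name}.W", rng.normal(0.0, scale, (kernel_width, in_ch, out_ch)))
        self.b = Param(f"{name}.b", np.zeros(out_ch)) if bias else None
        self.k = kernel_width
        self._cache: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.W] + ([self.b] if self.b is not None else [])

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        k = self.k
        pl = (k - 1) // 2
        xp = np.pad(x, ((0, 0), (pl, k - 1 - pl), (0, 0)))
        # windows: (B, L, C, k)
        win = sliding_window_view(xp, k, axis=1)
        self._cache = win if training else None
        self._in_shape = x.shape
        out = np.einsum("blck,kco->blo", win, self.W.value, optimize=True)
        if self.b is not None:
            out += self.b.value
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        win = self._cache
        if win is None:
            raise RuntimeError("backward requires a forward pass with training=True")
        self.W.grad += np.einsum("blck,blo->kco", win, dout, optimize=True)
        if self.b is not None:
            self.b.grad += dout.sum(axis=(0, 1))
        B, L, _ = self._in_shape
        k = self.k
        pl = (k - 1) // 2
        dxp = np.zeros((B, L + k - 1, win.shape[2]))
        for ki in range(k):
            # dout (B,L,O) @ W[ki].T (O,C) -> contribution at input offset ki
            dxp[:, ki : ki + L, :] += dout @ self.W.value[ki].T
        return dxp[:, pl : pl + L, :]


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class MaxPool1D(Layer):
    """Ceil-mode max pooling: length L -> ceil(L / factor)."""

    def __init__(self, factor: int) -> None:
        if factor < 1:
            raise ValueError("pool factor must be >= 1")
        self.factor = factor

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        p = self.factor
        if p == 1:
            self._idx = None
            return x
        B, L, C = x.shape
        n_out = -(-L // p)
        if n_out < 1:
            raise ValueError("pooled length would be 0")
        pad = n_out * p - L
        xp = np.pad(x, ((0, 0), (0, pad), (0, 0)), constant_values=-np.inf)
        blocks = xp.reshape(B, n_out, p, C)
        idx = blocks.argmax(axis=2)
        self._idx, self._in_len = idx, L
        return np.take_along_axis(blocks, idx[:, :, None, :], axis=2)[:, :, 0, :]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        p = self.factor
        if p == 1:
            return dout
        B, n_out, C = dout.shape
        dblocks = np.zeros((B, n_out, p, C))
        np.put_along_axis(dblocks, self._idx[:, :, None, :], dout[:, :, None, :], axis=2)
        return dblocks.reshape(B, n_out * p, C)[:, : self._in_len, :]


class Dropout(Layer):
    """Inverted dropout; active only in training, identity in eval."""

    def __init__(self, rate: float, rng: np.random.Generator) -> None:
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate
        self.rng = rng
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if not training or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout if self._mask is None else dout * self._mask


class BatchNorm1D(Layer):
    """Per-channel batch normalization over (batch, positions).

    Batch statistics in training, exponential running averages (momentum 0.1)
    in eval.
    """

    def __init__(self, n_ch: int, momentum: float = 0.1, eps: float = 1e-5,
                 name: str = "bn") -> None:
        self.gamma = Param(f"{name}.gamma", np.ones(n_ch))
        self.beta = Param(f"{name}.beta", np.zeros(n_ch))
        self.running_mean = np.zeros(n_ch)
        self.running_var = np.ones(n_ch)
        self.momentum = momentum
        self.eps = eps

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 1))
            var = x.var(axis=(0, 1))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean) / self._std
        self._training = training
        return self.gamma.value * self._xhat + self.beta.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, std = self._xhat, self._std
        self.gamma.grad += (dout * xhat).sum(axis=(0, 1))
        self.beta.grad += dout.sum(axis=(0, 1))
        dxhat = dout * self.gamma.value
        if not self._training:
            return dxhat / std
        N = xhat.shape[0] * xhat.shape[1]
        return (
            dxhat - dxhat.mean(axis=(0, 1)) - xhat * (dxhat * xhat).mean(axis=(0, 1))
        ) / std


class UpsampleNearest(Layer):
    """Nearest-neighbour upsampling to an explicit target length.

    Repeats each position ceil(target/L) times, then crops to the target —
    the recorded pre-pool length of the mirrored encoder stage, so odd
    lengths (101 -> 51 -> 101) restore exactly.
    """

    def __init__(self, target_length: int) -> None:
        self.target = target_length

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        L = x.shape[1]
        self._in_len = L
        if L == self.target:
            self._factor = 1
            return x
        f = -(-self.target // L)
        self._factor = f
        return np.repeat(x, f, axis=1)[:, : self.target, :]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        f, L = self._factor, self._in_len
        if f == 1 and dout.shape[1] == L:
            return dout
        B, _, C = dout.shape
        full = np.zeros((B, L * f, C))
        full[:, : self.target, :] = dout
        return full.reshape(B, L, f, C).sum(axis=2)


class GlobalContext(Layer):
    """Adds the per-channel global average back to every position.

    A broadcast context injection: out = x + mean_over_positions(x).
    """

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return x + x.mean(axis=1, keepdims=True)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout + dout.mean(axis=1, keepdims=True)


class Adam:
    """Adam with the standard bias correction; zeroes grads after each step."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8) -> None:
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        for i, p in enumerate(self.params):
            self.m[i] = b1 * self.m[i] + (1 - b1) * p.grad
            self.v[i] = b2 * self.v[i] + (1 - b2) * p.grad**2
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0
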