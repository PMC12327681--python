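"""Neural-network building blocks on top of the autograd engine.

The surface deliberately mirrors the conventions of mainstream deep-learning
frameworks (train/eval modes, ``state_dict`` checkpoints, fan-in uniform
initialisation) so the rest of the package reads familiarly.
"""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from .autograd import Tensor

__all__ = [
    "Module", "Parameter", "Sequential", "Linear", "LayerNorm", "BatchNorm1d",
    "ReLU", "Dropout", "Conv1d", "GlobalAvgPool1d", "LSTM",
    "MultiHeadSelfAttention", "TransformerEncoderLayer", "cross_entropy",
]


def Parameter(data: np.ndarray) -> Tensor:
    return Tensor(np.asarray(data, dtype=np.float64), requires_grad=True)


def _fan_in_uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    bound = 1.0 / math.sqrt(fan_in) if fan_in > 0 else 0.0
    return rng.uniform(-bound, bound, size=shape)


class Module:
    """Base class: parameter/buffer registry, modes, checkpoints."""

    def __init__(self) -> None:
        self.training = True
        self._buffers: dict[str, np.ndarray] = {}

    # attribute scan keeps registration implicit, as in the big frameworks
    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for name, value in vars(self).items():
            if isinstance(value, Tensor) and value.requires_grad:
                yield prefix + name, value
            elif isinstance(value, Module):
                yield from value.named_parameters(prefix + name + ".")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{prefix}{name}.{i}.")
                    elif isinstance(item, Tensor) and item.requires_grad:
                        yield f"{prefix}{name}.{i}", item

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def modules(self) -> Iterator["Module"]:
        yield self
        for value in vars(self).values():
            if isinstance(value, Module):
                yield from value.modules()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield from item.modules()

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name, arr in self._buffers.items():
            yield prefix + name, arr
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield from value.named_buffers(prefix + name + ".")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_buffers(f"{prefix}{name}.{i}.")

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            m.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, b in self.named_buffers():
            out["buffer:" + name] = b.copy()
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        for key, value in state.items():
            if key.startswith("buffer:"):
                buffers[key[len("buffer:"):]][...] = value
            else:
                params[key].data[...] = value

    def forward(self, x: Tensor) -> Tensor:  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        self.in_features = in_features
        self.out_features = out_features
        self.weight = Parameter(_fan_in_uniform(rng, (in_features, out_features), in_features))
        self.bias = Parameter(_fan_in_uniform(rng, (out_features,), in_features)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[-1] != self.in_features:
            raise ValueError(
                f"Linear expected last dim {self.in_features}, got {x.shape[-1]}")
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class LayerNorm(Module):
    """Normalisation over the last (feature) axis, per sample."""

    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.dim = dim
        self.eps = eps
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        xhat = xc * (var + self.eps).pow(-0.5)
        return xhat * self.gamma + self.beta


class BatchNorm1d(Module):
    """Normalisation over the channel axis of (B, C, L) tensors.

    Batch statistics in train mode, running statistics in eval mode.
    Train mode requires batch*length > 1 per channel; a batch of one sample
    with L == 1 has undefined variance and raises.
    """

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.channels = channels
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self._buffers["running_mean"] = np.zeros(channels)
        self._buffers["running_var"] = np.ones(channels)

    def forward(self, x: Tensor) -> Tensor:
        if x.ndim != 3 or x.shape[1] != self.channels:
            raise ValueError(
                f"BatchNorm1d expected (B, {self.channels}, L), got {x.shape}")
        if self.training:
            B, _, L = x.shape
            n = B * L
            if B < 2:
                raise ValueError(
                    "BatchNorm1d in train mode needs batch size >= 2 "
                    "(batch variance is undefined for a single sample)")
            mu = x.mean(axis=(0, 2), keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=(0, 2), keepdims=True)
            m = self.momentum
            self._buffers["running_mean"] *= 1 - m
            self._buffers["running_mean"] += m * mu.data.reshape(-1)
            self._buffers["running_var"] *= 1 - m
            self._buffers["running_var"] += m * var.data.reshape(-1) * n / (n - 1)
            xhat = xc * (var + self.eps).pow(-0.5)
        else:
            mu = self._buffers["running_mean"][None, :, None]
            sd = np.sqrt(self._buffers["running_var"][None, :, None] + self.eps)
            xhat = (x - Tensor(mu)) * Tensor(1.0 / sd)
        return xhat * self.gamma.reshape(1, -1, 1) + self.beta.reshape(1, -1, 1)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Dropout(Module):
    """Inverted dropout; identity in eval mode."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout probability must be in [0, 1), got {p}")
        self.p = p
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        keep = 1.0 - self.p
        mask = (self.rng.random(x.shape) < keep) / keep
        return x * Tensor(mask)


class Conv1d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, padding: int = 0, bias: bool = True):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.padding = padding
        fan_in = in_channels * kernel_size
        self.weight = Parameter(
            _fan_in_uniform(rng, (out_channels, in_channels, kernel_size), fan_in))
        self.bias = Parameter(_fan_in_uniform(rng, (out_channels,), fan_in)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        if x.ndim != 3:
            raise ValueError(f"Conv1d expects (B, C, L) input, got shape {x.shape}")
        return x.conv1d(self.weight, self.bias, padding=self.padding)


class GlobalAvgPool1d(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.mean(axis=2)


class LSTM(Module):
    """Single-layer LSTM; returns the final hidden state (B, hidden)."""

    def __init__(self, input_size: int, hidden_size: int, rng: np.random.Generator):
        super().__init__()
        self.input_size = input_size
        self.hidden_size = hidden_size
        h = hidden_size
        self.w_ih = Parameter(_fan_in_uniform(rng, (input_size, 4 * h), h))
        self.w_hh = Parameter(_fan_in_uniform(rng, (h, 4 * h), h))
        self.b = Parameter(_fan_in_uniform(rng, (4 * h,), h))

    def forward(self, x: Tensor) -> Tensor:
        if x.ndim != 3 or x.shape[2] != self.input_size:
            raise ValueError(
                f"LSTM expects (B, T, {self.input_size}), got {x.shape}")
        B, T, _ = x.shape
        h = Tensor(np.zeros((B, self.hidden_size)))
        c = Tensor(np.zeros((B, self.hidden_size)))
        H = self.hidden_size
        for t in range(T):
            gates = x[:, t, :] @ self.w_ih + h @ self.w_hh + self.b
            i = gates[:, :H].sigmoid()
            f = gates[:, H:2 * H].sigmoid()
            g = gates[:, 2 * H:3 * H].tanh()
            o = gates[:, 3 * H:].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
        return h


class MultiHeadSelfAttention(Module):
    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        if dim % n_heads:
            raise ValueError(f"model dim {dim} not divisible by {n_heads} heads")
        self.dim = dim
        self.n_heads = n_heads
        self.head_dim = dim // n_heads
        self.qkv = Linear(dim, 3 * dim, rng)
        self.out = Linear(dim, dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        B, T, _ = x.shape
        qkv = self.qkv(x)  # (B, T, 3*dim)
        qkv = qkv.reshape(B, T, 3, self.n_heads, self.head_dim)
        qkv = qkv.transpose(2, 0, 3, 1, 4)  # (3, B, heads, T, head_dim)
        q, k, v = qkv[0], qkv[1], qkv[2]
        scale = 1.0 / math.sqrt(self.head_dim)
        attn = (q @ k.transpose(0, 1, 3, 2)) * scale
        attn = attn.softmax(axis=-1)
        ctx = attn @ v  # (B, heads, T, head_dim)
        ctx = ctx.transpose(0, 2, 1, 3).reshape(B, T, self.dim)
        return self.out(ctx)


class TransformerEncoderLayer(Module):
    """Post-norm encoder block: attention + feed-forward, residual both."""

    def __init__(self, dim: int, n_heads: int, ff_dim: int, dropout_p: float,
                 rng: np.random.Generator):
        super().__init__()
        self.attn = MultiHeadSelfAttention(dim, n_heads, rng)
        self.norm1 = LayerNorm(dim)
        self.ff1 = Linear(dim, ff_dim, rng)
        self.ff2 = Linear(ff_dim, dim, rng)
        self.norm2 = LayerNorm(dim)
        self.drop = Dropout(dropout_p, rng)

    def forward(self, x: Tensor) -> Tensor:
        x = self.norm1(x + self.drop(self.attn(x)))
        x = self.norm2(x + self.drop(self.ff2(self.ff1(x).relu())))
        return x


def cross_entropy(logits: Tensor, targets: np.ndarray,
                  class_weights: np.ndarray | None = None) -> Tensor:
    """Class-weighted cross-entropy, normalised by the summed sample weights."""
    targets = np.asarray(targets)
    B = logits.shape[0]
    if targets.shape != (B,):
        raise ValueError(f"targets shape {targets.shape} does not match batch {B}")
    lse = logits.logsumexp(axis=1, keepdims=True)
    logp = logits - lse
    picked = logp[np.arange(B), targets]
    if class_weights is None:
        return -picked.mean()
    w = np.asarray(class_weights, dtype=np.float64)[targets]
    return -(picked * Tensor(w)).sum() * (1.0 / w.sum())
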