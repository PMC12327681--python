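"""The multi-channel embedding module.

A batch of single-channel spectrum vectors ``X`` of shape (B, D) is mapped to
a multi-channel representation ``O`` of shape (B, 1+C, d):

1. **Encoder** — two fully connected layers; the first is followed by
   layer normalization (over the hidden features, per sample), ReLU and
   dropout.  Output: the global embedding ``E`` of shape (B, d).
2. **Channel embedding** — ``E`` is reshaped to (B, 1, d) and passed through
   two 1-D convolutions (1 -> C_mid -> C channels, odd kernel, stride 1,
   symmetric padding so the length axis stays ``d``); batch normalization,
   ReLU and dropout sit between them.
3. **Channel concatenation** — ``E`` (as channel 0) is concatenated with the
   C convolutional channels.

All three stages are trainable end to end.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from . import nn
from .nn import Tensor

__all__ = ["MSMCEConfig", "MSMCE", "Encoder", "ChannelEmbedding"]


@dataclass(frozen=True)
class MSMCEConfig:
    """Shapes and regularization knobs of the module."""

    D: int
    hidden: int = 2048
    d: int = 1024
    C: int = 256
    C_mid: int | None = None  # defaults to C // 2
    kernel: int = 3
    dropout_p: float = 0.3

    def __post_init__(self) -> None:
        c_mid = self.C_mid if self.C_mid is not None else max(self.C // 2, 1)
        object.__setattr__(self, "C_mid", c_mid)
        for name in ("D", "hidden", "d", "C", "C_mid"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.kernel % 2 == 0 or self.kernel < 1:
            raise ValueError(f"kernel must be odd and positive, got {self.kernel}")
        if not 0.0 <= self.dropout_p < 1.0:
            raise ValueError(f"dropout_p must be in [0, 1), got {self.dropout_p}")

    @property
    def out_channels(self) -> int:
        return 1 + self.C

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "MSMCEConfig":
        return cls(**d)


class Encoder(nn.Module):
    """(B, D) -> (B, d): Linear, LayerNorm, ReLU, Dropout, Linear."""

    def __init__(self, cfg: MSMCEConfig, rng: np.random.Generator):
        super().__init__()
        self.fc1 = nn.Linear(cfg.D, cfg.hidden, rng)
        self.norm = nn.LayerNorm(cfg.hidden)
        self.drop = nn.Dropout(cfg.dropout_p, rng)
        self.fc2 = nn.Linear(cfg.hidden, cfg.d, rng)

    def forward(self, x: Tensor) -> Tensor:
        h = self.drop(self.norm(self.fc1(x)).relu())
        return self.fc2(h)


class ChannelEmbedding(nn.Module):
    """(B, d) -> (B, C, d): two same-length 1-D convolutions."""

    def __init__(self, cfg: MSMCEConfig, rng: np.random.Generator):
        super().__init__()
        pad = (cfg.kernel - 1) // 2
        self.conv1 = nn.Conv1d(1, cfg.C_mid, cfg.kernel, rng, padding=pad)
        self.bn = nn.BatchNorm1d(cfg.C_mid)
        self.drop = nn.Dropout(cfg.dropout_p, rng)
        self.conv2 = nn.Conv1d(cfg.C_mid, cfg.C, cfg.kernel, rng, padding=pad)

    def forward(self, e: Tensor) -> Tensor:
        if e.ndim != 2:
            raise ValueError(f"expected (B, d) embedding, got shape {e.shape}")
        x = e.reshape(e.shape[0], 1, e.shape[1])
        x = self.bn(self.conv1(x)).relu()
        return self.conv2(self.drop(x))


class MSMCE(nn.Module):
    """End-to-end module: raw instance vectors -> (B, 1+C, d) representation."""

    def __init__(self, cfg: MSMCEConfig, rng: np.random.Generator | int | None = None):
        super().__init__()
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        self.cfg = cfg
        self.encoder = Encoder(cfg, rng)
        self.channel_embedding = ChannelEmbedding(cfg, rng)

    def forward(self, x: Tensor) -> Tensor:
        if x.ndim != 2 or x.shape[1] != self.cfg.D:
            raise ValueError(
                f"expected input of shape (B, {self.cfg.D}), got {x.shape}")
        e = self.encoder(x)
        c2 = self.channel_embedding(e)
        e_chan = e.reshape(e.shape[0], 1, e.shape[1])
        return nn.concat([e_chan, c2], axis=1)
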