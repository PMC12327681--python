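"""Classification heads and their input adaptations.

Three families are provided, each in a baseline form (consuming raw instance
vectors) and a composed form (consuming the multi-channel embedding):

* ``cnn1d`` — a small residual 1-D convolutional stack with global average
  pooling; the baseline treats the raw vector as one channel, the composed
  form widens the stem to ``1 + C`` input channels.
* ``lstm`` — the raw vector is chunked into fixed-length segments forming a
  sequence; classification from the final hidden state.
* ``transformer`` — segments are linearly embedded, a learnable CLS token is
  prepended, learned position embeddings are added, and classification reads
  the CLS position after the encoder stack.

For the sequence families the composed form treats the embedded channels as
the sequence axis and the embedding dimension as the per-element feature
length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .msmce import MSMCE, MSMCEConfig
from .nn import Tensor

__all__ = ["ClassifierSpec", "segment_sequence", "make_classifier", "compose",
           "ComposedModel"]

_FAMILIES = ("cnn1d", "lstm", "transformer")


@dataclass(frozen=True)
class ClassifierSpec:
    family: str
    n_classes: int
    in_channels: int = 1            # cnn1d: channels of the input tensor
    input_len: int | None = None    # cnn1d: length axis (for profiling only)
    segment_len: int = 1024         # sequence baselines: chunk width
    width: int = 32                 # cnn1d: stem channels
    depth: int = 2                  # cnn1d: residual blocks / transformer layers
    hidden: int = 128               # lstm hidden size / transformer model dim
    heads: int = 4                  # transformer attention heads
    dropout_p: float = 0.1

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"family must be one of {_FAMILIES}, got {self.family!r}")
        if self.n_classes < 2:
            raise ValueError(f"n_classes must be >= 2, got {self.n_classes}")
        if self.in_channels < 1 or self.segment_len < 1:
            raise ValueError("in_channels and segment_len must be >= 1")
        if self.family == "transformer" and self.hidden % self.heads:
            raise ValueError(
                f"model dim {self.hidden} not divisible by {self.heads} heads")


def segment_sequence(x: np.ndarray | Tensor, segment_len: int) -> Tensor:
    """Chunk (B, D) row-major into (B, L, segment_len), zero-padding the tail."""
    if segment_len < 1:
        raise ValueError(f"segment_len must be >= 1, got {segment_len}")
    t = x if isinstance(x, Tensor) else Tensor(x)
    B, D = t.shape
    L = -(-D // segment_len)
    pad = L * segment_len - D
    if pad:
        t = _pad_cols(t, pad)
    return t.reshape(B, L, segment_len)


def _pad_cols(t: Tensor, pad: int) -> Tensor:
    zeros = Tensor(np.zeros((t.shape[0], pad)))
    return nn.concat([t, zeros], axis=1)


class ResidualBlock1d(nn.Module):
    """conv-norm-ReLU x2 with identity shortcut (channel count preserved)."""

    def __init__(self, channels: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        pad = (kernel - 1) // 2
        self.conv1 = nn.Conv1d(channels, channels, kernel, rng, padding=pad)
        self.bn1 = nn.BatchNorm1d(channels)
        self.conv2 = nn.Conv1d(channels, channels, kernel, rng, padding=pad)
        self.bn2 = nn.BatchNorm1d(channels)

    def forward(self, x: Tensor) -> Tensor:
        h = self.bn1(self.conv1(x)).relu()
        h = self.bn2(self.conv2(h))
        return (h + x).relu()


class CNN1dClassifier(nn.Module):
    def __init__(self, spec: ClassifierSpec, rng: np.random.Generator):
        super().__init__()
        self.spec = spec
        self.stem = nn.Conv1d(spec.in_channels, spec.width, 3, rng, padding=1)
        self.stem_bn = nn.BatchNorm1d(spec.width)
        self.blocks = [ResidualBlock1d(spec.width, 3, rng) for _ in range(spec.depth)]
        self.pool = nn.GlobalAvgPool1d()
        self.head = nn.Linear(spec.width, spec.n_classes, rng)

    def forward(self, x: Tensor) -> Tensor:
        if x.ndim == 2:  # raw vectors: add the single channel axis
            x = x.reshape(x.shape[0], 1, x.shape[1])
        if x.shape[1] != self.spec.in_channels:
            raise ValueError(
                f"cnn1d expected {self.spec.in_channels} input channels, got {x.shape[1]}")
        h = self.stem_bn(self.stem(x)).relu()
        for blk in self.blocks:
            h = blk(h)
        return self.head(self.pool(h))


class LSTMClassifier(nn.Module):
    def __init__(self, spec: ClassifierSpec, feat_len: int, rng: np.random.Generator,
                 segment_input: bool):
        super().__init__()
        self.spec = spec
        self.segment_input = segment_input
        self.lstm = nn.LSTM(feat_len, spec.hidden, rng)
        self.head = nn.Linear(spec.hidden, spec.n_classes, rng)

    def forward(self, x: Tensor) -> Tensor:
        if self.segment_input and x.ndim == 2:
            x = segment_sequence(x, self.spec.segment_len)
        return self.head(self.lstm(x))


class TransformerClassifier(nn.Module):
    def __init__(self, spec: ClassifierSpec, feat_len: int, rng: np.random.Generator,
                 segment_input: bool, max_len: int = 4096):
        super().__init__()
        self.spec = spec
        self.segment_input = segment_input
        dim = spec.hidden
        self.embed = nn.Linear(feat_len, dim, rng)
        self.cls_token = nn.Parameter(rng.normal(0.0, 0.02, size=(1, 1, dim)))
        self.pos_embed = nn.Parameter(rng.normal(0.0, 0.02, size=(1, max_len, dim)))
        self.layers = [
            nn.TransformerEncoderLayer(dim, spec.heads, 2 * dim, spec.dropout_p, rng)
            for _ in range(spec.depth)
        ]
        self.head = nn.Linear(dim, spec.n_classes, rng)

    def forward(self, x: Tensor) -> Tensor:
        if self.segment_input and x.ndim == 2:
            x = segment_sequence(x, self.spec.segment_len)
        B, L, _ = x.shape
        h = self.embed(x)
        cls = Tensor(np.ones((B, 1, 1))) * self.cls_token
        h = nn.concat([cls, h], axis=1)  # sequence length becomes L + 1
        h = h + self.pos_embed[:, :L + 1, :]
        for layer in self.layers:
            h = layer(h)
        return self.head(h[:, 0, :])


def make_classifier(spec: ClassifierSpec, rng: np.random.Generator | int | None = None,
                    feat_len: int | None = None, segment_input: bool = True) -> nn.Module:
    """Build a classifier; ``feat_len`` is the per-element feature length for
    sequence families (defaults to ``segment_len`` for segmented baselines)."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if spec.family == "cnn1d":
        return CNN1dClassifier(spec, rng)
    if feat_len is None:
        feat_len = spec.segment_len
    if spec.family == "lstm":
        return LSTMClassifier(spec, feat_len, rng, segment_input)
    return TransformerClassifier(spec, feat_len, rng, segment_input)


class ComposedModel(nn.Module):
    """Embedding module + classifier trained under one loss."""

    def __init__(self, embedder: MSMCE, classifier: nn.Module):
        super().__init__()
        self.embedder = embedder
        self.classifier = classifier

    def forward(self, x: Tensor) -> Tensor:
        return self.classifier(self.embedder(x))


def compose(msmce_cfg: MSMCEConfig, spec: ClassifierSpec,
            rng: np.random.Generator | int | None = None) -> ComposedModel:
    """Wire the embedding module in front of a classifier.

    cnn1d heads must declare ``in_channels == 1 + C``; sequence heads consume
    sequence length ``1 + C`` with feature length ``d``.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if spec.family == "cnn1d" and spec.in_channels != msmce_cfg.out_channels:
        raise ValueError(
            f"cnn1d in_channels must equal 1 + C = {msmce_cfg.out_channels}, "
            f"got {spec.in_channels}")
    embedder = MSMCE(msmce_cfg, rng)
    classifier = make_classifier(spec, rng, feat_len=msmce_cfg.d, segment_input=False)
    return ComposedModel(embedder, classifier)
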