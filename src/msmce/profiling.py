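"""Analytic cost accounting for composed models.

MAC counts (multiply–accumulate, reported under the conventional "FLOPs"
label where one MAC = one unit) are derived from closed forms per layer type
rather than measured, so they are exact and hardware-independent.
Normalisations, activations and pooling count as zero, matching the common
profiler convention.  The size estimate assumes 4 bytes per scalar with
parameters stored twice (weights + gradients) plus activations at the stated
batch size.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import singledispatch
from math import prod

from . import nn
from .classifiers import (CNN1dClassifier, ComposedModel, LSTMClassifier,
                          ResidualBlock1d, TransformerClassifier)
from .msmce import MSMCE, ChannelEmbedding, Encoder

__all__ = ["ProfileReport", "count_macs", "count_params", "profile_model",
           "profile_pair"]


@dataclass
class ProfileReport:
    macs: int
    params: int
    est_size_mb: float

    def to_dict(self) -> dict:
        return {"macs": self.macs, "params": self.params,
                "est_size_mb": self.est_size_mb}


@singledispatch
def _profile(module: nn.Module, in_shape: tuple[int, ...]):
    """Return (macs, out_shape, activation_elements) for one sample."""
    raise TypeError(f"unsupported layer for profiling: {type(module).__name__}")


def _chain(layers, in_shape):
    macs, acts, shape = 0, 0, in_shape
    for layer in layers:
        m, shape, a = _profile(layer, shape)
        macs += m
        acts += a
    return macs, shape, acts


@_profile.register
def _(module: nn.Sequential, in_shape):
    return _chain(module.layers, in_shape)


@_profile.register
def _(module: nn.Linear, in_shape):
    if in_shape[-1] != module.in_features:
        raise ValueError(f"Linear expects last dim {module.in_features}, got {in_shape}")
    out_shape = in_shape[:-1] + (module.out_features,)
    macs = prod(in_shape[:-1] + ()) * module.in_features * module.out_features
    return macs, out_shape, prod(out_shape)


@_profile.register
def _(module: nn.Conv1d, in_shape):
    c_in, length = in_shape
    if c_in != module.in_channels:
        raise ValueError(f"Conv1d expects {module.in_channels} channels, got {c_in}")
    l_out = length + 2 * module.padding - module.kernel_size + 1
    macs = l_out * module.out_channels * module.in_channels * module.kernel_size
    out_shape = (module.out_channels, l_out)
    return macs, out_shape, prod(out_shape)


@_profile.register
def _(module: nn.LayerNorm, in_shape):
    return 0, in_shape, prod(in_shape)


@_profile.register
def _(module: nn.BatchNorm1d, in_shape):
    return 0, in_shape, prod(in_shape)


@_profile.register
def _(module: nn.ReLU, in_shape):
    return 0, in_shape, prod(in_shape)


@_profile.register
def _(module: nn.Dropout, in_shape):
    return 0, in_shape, 0


@_profile.register
def _(module: nn.GlobalAvgPool1d, in_shape):
    return 0, in_shape[:-1], prod(in_shape[:-1])


@_profile.register
def _(module: nn.LSTM, in_shape):
    t, feat = in_shape
    h = module.hidden_size
    macs = t * 4 * (feat * h + h * h)
    return macs, (h,), t * 4 * h


@_profile.register
def _(module: nn.MultiHeadSelfAttention, in_shape):
    t, dim = in_shape
    macs = t * dim * 3 * dim           # qkv projection
    macs += 2 * module.n_heads * t * t * module.head_dim  # scores + context
    macs += t * dim * dim              # output projection
    return macs, in_shape, 4 * t * dim + module.n_heads * t * t


@_profile.register
def _(module: nn.TransformerEncoderLayer, in_shape):
    t, dim = in_shape
    macs, acts = 0, 0
    m, _, a = _profile(module.attn, in_shape)
    macs, acts = macs + m, acts + a
    ff = module.ff1.out_features
    macs += t * dim * ff + t * ff * dim
    acts += t * ff + 3 * t * dim
    return macs, in_shape, acts


@_profile.register
def _(module: ResidualBlock1d, in_shape):
    return _chain([module.conv1, module.bn1, module.conv2, module.bn2], in_shape)


@_profile.register
def _(module: CNN1dClassifier, in_shape):
    if len(in_shape) == 1:
        in_shape = (1, in_shape[0])
    macs, shape, acts = _chain(
        [module.stem, module.stem_bn, *module.blocks, module.pool], in_shape)
    m, shape, a = _profile(module.head, shape)
    return macs + m, shape, acts + a


@_profile.register
def _(module: LSTMClassifier, in_shape):
    if len(in_shape) == 1:
        d = in_shape[0]
        seg = module.spec.segment_len
        in_shape = (-(-d // seg), seg)
    return _chain([module.lstm, module.head], in_shape)


@_profile.register
def _(module: TransformerClassifier, in_shape):
    if len(in_shape) == 1:
        d = in_shape[0]
        seg = module.spec.segment_len
        in_shape = (-(-d // seg), seg)
    t, feat = in_shape
    macs, shape, acts = _profile(module.embed, in_shape)
    shape = (t + 1, shape[-1])  # CLS token prepended
    acts += prod(shape)
    m, shape, a = _chain(module.layers, shape)
    macs, acts = macs + m, acts + a
    m, shape, a = _profile(module.head, (shape[-1],))
    return macs + m, shape, acts + a


@_profile.register
def _(module: Encoder, in_shape):
    return _chain([module.fc1, module.norm, module.drop, module.fc2], in_shape)


@_profile.register
def _(module: ChannelEmbedding, in_shape):
    (d,) = in_shape
    return _chain([module.conv1, module.bn, module.drop, module.conv2], (1, d))


@_profile.register
def _(module: MSMCE, in_shape):
    macs, shape, acts = _profile(module.encoder, in_shape)
    m, cshape, a = _profile(module.channel_embedding, shape)
    out_shape = (1 + cshape[0], cshape[1])
    return macs + m, out_shape, acts + a + prod(out_shape)


@_profile.register
def _(module: ComposedModel, in_shape):
    macs, shape, acts = _profile(module.embedder, in_shape)
    m, shape, a = _profile(module.classifier, shape)
    return macs + m, shape, acts + a


def count_macs(model: nn.Module, input_shape: tuple[int, ...]) -> int:
    """Single-sample forward MACs; ``input_shape`` excludes the batch axis."""
    macs, _, _ = _profile(model, tuple(input_shape))
    return int(macs)


def count_params(model: nn.Module) -> int:
    """Exact count of learnable scalars (frozen tensors excluded)."""
    return int(sum(p.data.size for p in model.parameters() if p.requires_grad))


def profile_model(model: nn.Module, input_shape: tuple[int, ...],
                  batch_size: int = 1) -> ProfileReport:
    macs, _, acts = _profile(model, tuple(input_shape))
    params = count_params(model)
    size_bytes = 4.0 * (2 * params + batch_size * (acts + prod(input_shape)))
    return ProfileReport(int(macs), params, size_bytes / 2 ** 20)


def profile_pair(baseline_model: nn.Module, msmce_model: nn.Module,
                 input_shape: tuple[int, ...], batch_size: int = 1) -> dict:
    """Side-by-side MACs/params/size with ratios (composed / baseline)."""
    base = profile_model(baseline_model, input_shape, batch_size)
    comp = profile_model(msmce_model, input_shape, batch_size)
    return {
        "baseline": base.to_dict(),
        "msmce": comp.to_dict(),
        "ratios": {
            "macs": comp.macs / base.macs if base.macs else float("inf"),
            "params": comp.params / base.params if base.params else float("inf"),
            "est_size_mb": (comp.est_size_mb / base.est_size_mb
                            if base.est_size_mb else float("inf")),
        },
    }
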