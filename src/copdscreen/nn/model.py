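"""The respiratory-sound classifier.

A compact ECAPA-style 1-D convolutional network over 80-bin log-Mel frames:
an optional per-band frequency gate, three Conv1D+BN+ReLU stages each followed
by squeeze-and-excitation channel gating, temporal pooling (attentive
statistics by default, plain global averaging as the ablation variant), a
dropout-regularized 192-d embedding and a 2-class linear head. An opt-in
SE-Res2 block style replaces the second and third plain stages with
multi-scale Res2 residual blocks and aggregates their outputs.
"""
from __future__ import annotations

from dataclasses import dataclass, asdict, field

import numpy as np

from .autograd import Module, Tensor, concat, cross_entropy, no_grad
from .layers import (AttentiveStatsPooling, BatchNorm1d, Conv1d, Dropout,
                     FreqGate, GlobalAvgPooling, Linear, Res2Conv, SEBlock)

POOLING_CHOICES = ("ASP", "GlobalAvg")
BLOCK_CHOICES = ("PlainConvSE", "SERes2")


@dataclass
class ModelConfig:
    n_mel: int = 80
    channels: int = 1024
    embedding_dim: int = 192
    dropout_p: float = 0.2
    se_reduction: int = 16
    pooling: str = "ASP"
    block_style: str = "PlainConvSE"
    freq_gate: bool = False
    se_enabled: bool = True        # "w/o SE" ablation switch
    n_classes: int = 2
    seed: int = 0

    def __post_init__(self):
        if min(self.n_mel, self.channels, self.embedding_dim, self.n_classes) <= 0:
            raise ValueError("all dimensions must be positive")
        if not 0.0 <= self.dropout_p < 1.0:
            raise ValueError("dropout_p must be in [0, 1)")
        if self.pooling not in POOLING_CHOICES:
            raise ValueError(f"pooling must be one of {POOLING_CHOICES}")
        if self.block_style not in BLOCK_CHOICES:
            raise ValueError(f"block_style must be one of {BLOCK_CHOICES}")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ForwardOutput:
    logits: Tensor          # (B, 2)
    embedding: Tensor       # (B, embedding_dim)
    frame_features: Tensor  # (B, channels, T), final conv stage (Grad-CAM hook)
    attention: Tensor | None = None  # (B, 1, T) when pooling is ASP


DESK_PRESET = dict(channels=64, embedding_dim=64)


class _Identity(Module):
    def __call__(self, x: Tensor) -> Tensor:
        return x


class _ConvSEStage(Module):
    def __init__(self, in_ch, out_ch, kernel, rng, se_reduction, se_enabled):
        self.conv = Conv1d(in_ch, out_ch, kernel, rng)
        self.bn = BatchNorm1d(out_ch)
        self.se = SEBlock(out_ch, rng, se_reduction) if se_enabled else _Identity()

    def __call__(self, x: Tensor) -> Tensor:
        return self.se(self.bn(self.conv(x)).relu())


class _SERes2Stage(Module):
    """1x1 conv -> Res2 multi-scale conv (dilated) -> 1x1 conv -> SE, with a
    residual connection around the whole block."""

    def __init__(self, n_ch, kernel, dilation, rng, se_reduction, se_enabled):
        self.pre = Conv1d(n_ch, n_ch, 1, rng)
        self.bn1 = BatchNorm1d(n_ch)
        self.res2 = Res2Conv(n_ch, kernel, rng, scales=4, dilation=dilation)
        self.post = Conv1d(n_ch, n_ch, 1, rng)
        self.bn2 = BatchNorm1d(n_ch)
        self.se = SEBlock(n_ch, rng, se_reduction) if se_enabled else _Identity()

    def __call__(self, x: Tensor) -> Tensor:
        h = self.bn1(self.pre(x)).relu()
        h = self.res2(h)
        h = self.se(self.bn2(self.post(h)).relu())
        return h + x


class ECAPAClassifier(Module):
    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        C = config.channels
        self.freq_gate = FreqGate(config.n_mel) if config.freq_gate else None
        self.stage1 = _ConvSEStage(config.n_mel, C, 5, rng,
                                   config.se_reduction, config.se_enabled)
        if config.block_style == "PlainConvSE":
            self.stage2 = _ConvSEStage(C, C, 3, rng, config.se_reduction,
                                       config.se_enabled)
            self.stage3 = _ConvSEStage(C, C, 3, rng, config.se_reduction,
                                       config.se_enabled)
            self.aggregate = None
        else:  # SERes2 variant: two multi-scale residual blocks + aggregation
            self.stage2 = _SERes2Stage(C, 3, 2, rng, config.se_reduction,
                                       config.se_enabled)
            self.stage3 = _SERes2Stage(C, 3, 3, rng, config.se_reduction,
                                       config.se_enabled)
            self.aggregate = Conv1d(2 * C, C, 1, rng)
        if config.pooling == "ASP":
            self.pool = AttentiveStatsPooling(C, rng)
            pooled_dim = 2 * C
        else:
            self.pool = GlobalAvgPooling()
            pooled_dim = C
        self.dropout = Dropout(config.dropout_p, np.random.default_rng(
            [config.seed, 0x5EED]))
        self.fc_embed = Linear(pooled_dim, config.embedding_dim, rng)
        self.fc_class = Linear(config.embedding_dim, config.n_classes, rng)

    # ------------------------------------------------------------------
    def forward(self, x) -> ForwardOutput:
        """x: array or Tensor of shape (B, n_mel, T)."""
        if not isinstance(x, Tensor):
            x = Tensor(x)
        if x.data.ndim != 3 or x.data.shape[1] != self.config.n_mel:
            raise ValueError(
                f"expected input (B, {self.config.n_mel}, T), got {x.data.shape}")
        h = self.freq_gate(x) if self.freq_gate is not None else x
        h = self.stage1(h)
        h2 = self.stage2(h)
        h3 = self.stage3(h2)
        if self.aggregate is not None:
            h3 = self.aggregate(concat([h2, h3], axis=1)).relu()
        pooled, alpha = self.pool(h3)
        emb = self.fc_embed(self.dropout(pooled))
        logits = self.fc_class(emb)
        return ForwardOutput(logits=logits, embedding=emb,
                             frame_features=h3, attention=alpha)

    __call__ = forward

    def predict_proba(self, x) -> np.ndarray:
        """Class probabilities (B, 2) in eval mode without graph building."""
        was_training = self.training
        self.eval()
        try:
            with no_grad():
                logits = self.forward(x).logits.data
        finally:
            if was_training:
                self.train()
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def loss(self, x, labels: np.ndarray, class_weights=None):
        out = self.forward(x)
        return cross_entropy(out.logits, labels, class_weights), out


def build_model(config: ModelConfig | None = None, **overrides) -> ECAPAClassifier:
    """Construct the classifier from a config (or keyword overrides)."""
    if config is None:
        config = ModelConfig(**overrides)
    elif overrides:
        config = ModelConfig(**{**config.to_dict(), **overrides})
    return ECAPAClassifier(config)


def save_checkpoint(model: ECAPAClassifier, path: str) -> str:
    """Persist weights + buffers with the model config embedded as JSON."""
    import json

    state = model.state_dict()
    arrays = {f"arr_{i}": a for i, a in enumerate(state)}
    np.savez_compressed(path, n_arrays=np.array([len(state)]),
                        config=np.array(json.dumps(model.config.to_dict())),
                        **arrays)
    return path if path.endswith(".npz") else path + ".npz"


def load_checkpoint(path: str) -> ECAPAClassifier:
    """Rebuild a classifier from a checkpoint written by save_checkpoint."""
    import json

    with np.load(path, allow_pickle=False) as data:
        config = ModelConfig(**json.loads(str(data["config"])))
        n = int(data["n_arrays"][0])
        state = [data[f"arr_{i}"] for i in range(n)]
    model = ECAPAClassifier(config)
    model.load_state_dict(state)
    model.eval()
    return model
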