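"""Declarative run configuration: nested sections, strict schema (unknown
keys rejected), YAML loading, and named sub-seeds for every stochastic
stage."""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Any, Dict, Tuple

import numpy as np
import yaml

from .nn.model import DESK_PRESET, ModelConfig
from .training import PipelineConfig, TrainConfig


@dataclass
class DataSection:
    input_dir: str = ""
    n_patients_copd: int = 14
    n_patients_healthy: int = 6
    duration_mean_s: float = 20.0
    sample_rate: int = 16000
    clip_len_s: float = 5.0
    split_ratios: Tuple[float, float, float] = (0.7, 0.15, 0.15)


@dataclass
class FeaturesSection:
    n_mels: int = 80
    win_ms: float = 25.0
    hop_ms: float = 10.0
    fmax: float = 8000.0
    spec_augment: bool = True


@dataclass
class LassoSection:
    enabled: bool = True
    n_lambdas: int = 30
    cv_folds: int = 3


@dataclass
class ModelSection:
    channels: int = 1024
    embedding_dim: int = 192
    dropout_p: float = 0.2
    se_reduction: int = 16
    pooling: str = "ASP"
    block_style: str = "PlainConvSE"
    freq_gate: bool = False
    se_enabled: bool = True


@dataclass
class TrainSection:
    learning_rate: float = 5e-4
    batch_size: int = 32
    max_epochs: int = 50
    weight_decay: float = 0.0
    early_stop_patience: int = 3
    imbalance_mode: str = "oversample"
    k_folds: int = 5


@dataclass
class ExplainSection:
    hot_threshold: float = 0.6
    n_overlays: int = 2


@dataclass
class RobustnessSection:
    snr_db: Tuple[float, ...] = (30.0, 20.0, 15.0, 10.0, 5.0, 0.0)


@dataclass
class RunConfig:
    run_id: str = "run"
    seed: int = 0
    output_dir: str = "runs"
    data: DataSection = field(default_factory=DataSection)
    features: FeaturesSection = field(default_factory=FeaturesSection)
    lasso: LassoSection = field(default_factory=LassoSection)
    model: ModelSection = field(default_factory=ModelSection)
    train: TrainSection = field(default_factory=TrainSection)
    explain: ExplainSection = field(default_factory=ExplainSection)
    robustness: RobustnessSection = field(default_factory=RobustnessSection)

    # -- construction ------------------------------------------------------
    @classmethod
    def from_dict(cls, raw: Dict[str, Any]) -> "RunConfig":
        return _build(cls, raw, path="")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    def to_dict(self) -> Dict[str, Any]:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def subseed(self, name: str) -> int:
        """Named substream seed derived from the run seed (stable, < 2^31)."""
        h = hashlib.sha256(f"{self.seed}:{name}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31)

    def apply_preset(self, preset: str) -> "RunConfig":
        if preset == "full":
            return self
        if preset == "desk":
            self.model.channels = DESK_PRESET["channels"]
            self.model.embedding_dim = DESK_PRESET["embedding_dim"]
            self.train.max_epochs = min(self.train.max_epochs, 10)
            return self
        raise ValueError(f"unknown preset {preset!r}")

    # -- adapters ----------------------------------------------------------
    def model_config(self) -> ModelConfig:
        return ModelConfig(n_mel=self.features.n_mels,
                           channels=self.model.channels,
                           embedding_dim=self.model.embedding_dim,
                           dropout_p=self.model.dropout_p,
                           se_reduction=self.model.se_reduction,
                           pooling=self.model.pooling,
                           block_style=self.model.block_style,
                           freq_gate=self.model.freq_gate,
                           se_enabled=self.model.se_enabled,
                           seed=self.subseed("model-init"))

    def pipeline_config(self) -> PipelineConfig:
        return PipelineConfig(
            model=self.model_config(),
            train=TrainConfig(learning_rate=self.train.learning_rate,
                              batch_size=self.train.batch_size,
                              max_epochs=self.train.max_epochs,
                              weight_decay=self.train.weight_decay,
                              early_stop_patience=self.train.early_stop_patience,
                              imbalance_mode=self.train.imbalance_mode,
                              spec_augment=self.features.spec_augment,
                              seed=self.subseed("train")),
            lasso_enabled=self.lasso.enabled,
            lasso_n_lambdas=self.lasso.n_lambdas,
            lasso_cv_folds=self.lasso.cv_folds)


def _build(cls, raw: Dict[str, Any], path: str):
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"config section {path or '<root>'} must be a mapping")
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(raw) - set(fields)
    if unknown:
        raise ValueError(f"unknown config key(s) {sorted(unknown)} "
                         f"in section {path or '<root>'}")
    kwargs = {}
    for name, f in fields.items():
        if name not in raw:
            continue
        val = raw[name]
        if dataclasses.is_dataclass(f.type) or (isinstance(f.default_factory, type)
                                                and dataclasses.is_dataclass(
                                                    f.default_factory)):
            sub_cls = (f.default_factory if isinstance(f.default_factory, type)
                       else f.type)
            kwargs[name] = _build(sub_cls, val, f"{path}{name}.")
        elif isinstance(val, list):
            kwargs[name] = tuple(val)
        else:
            kwargs[name] = val
    return cls(**kwargs)
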