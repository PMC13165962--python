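"""Training loop, imbalance handling, patient-wise cross-validation and the
SNR robustness sweep.

Training follows a fixed recipe: AdamW (lr 5e-4, weight decay 0), batch size
32, up to 50 epochs with early stopping (patience 3) on the validation
F1-score; the returned parameters are those of the best-validation-F1 epoch.
Class imbalance is handled either by train-only minority oversampling
(resampling upstream, unweighted loss) or by inverse-frequency class weights
normalized to mean 1.

Cross-validation is patient-wise and class-stratified: per fold the lasso
mask and all statistics are fit on the training patients only, the held-out
fold serves as the validation set, and fold metrics are aggregated with
Student-t 95% confidence intervals.
"""
from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .features import (LogMelSpec, compute_logmel, noisy_logmel, spec_augment)
from .ingest import (Clip, assert_no_leakage, kfold_patient_splits,
                     normalize_clip, oversample_minority, split_clips)
from .lasso import SpectrogramSelector, T_FIXED
from .metrics import (CVSummary, FoldMetrics, evaluate_predictions,
                      summarize_folds)
from .nn import AdamW, ECAPAClassifier, ModelConfig, build_model, cross_entropy

LABELS = ("Healthy", "COPD")  # index 1 = positive class


@dataclass
class TrainConfig:
    learning_rate: float = 5e-4
    batch_size: int = 32
    max_epochs: int = 50
    weight_decay: float = 0.0
    early_stop_patience: int = 3
    selection_metric: str = "f1"
    imbalance_mode: str = "oversample"   # oversample | class_weight | none
    spec_augment: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.early_stop_patience > self.max_epochs:
            raise ValueError("patience must not exceed max_epochs")
        if self.imbalance_mode not in ("oversample", "class_weight", "none"):
            raise ValueError(f"unknown imbalance_mode {self.imbalance_mode!r}")


class EarlyStopper:
    """Stop after `patience` consecutive epochs without strict improvement;
    remembers the best epoch (1-based).

    Epochs where the selection metric is undefined (e.g. F1 with no positive
    predictions yet) count neither as improvement nor toward patience: there
    is no metric value to have failed to improve, and stopping on them would
    return a degenerate single-class model.
    """

    def __init__(self, patience: int):
        self.patience = patience
        self.best = -np.inf
        self.best_epoch = 0
        self.stale = 0

    def update(self, value: float, epoch: int) -> bool:
        """Returns True if this epoch improved the tracked metric."""
        if not np.isfinite(value):
            return False
        if value > self.best:
            self.best = value
            self.best_epoch = epoch
            self.stale = 0
            return True
        self.stale += 1
        return False

    @property
    def should_stop(self) -> bool:
        return self.stale >= self.patience


def make_loss(imbalance_mode: str,
              class_counts: Dict[str, int] | None = None) -> np.ndarray | None:
    """Per-class loss weights: inverse-frequency normalized to mean 1 for
    'class_weight'; None (unweighted) for 'oversample'/'none'."""
    if imbalance_mode in ("oversample", "none"):
        return None
    if imbalance_mode != "class_weight":
        raise ValueError(f"unknown imbalance_mode {imbalance_mode!r}")
    if class_counts is None:
        raise ValueError("class_weight mode needs class counts")
    counts = np.array([class_counts.get(lab, 0) for lab in LABELS], dtype=float)
    if np.any(counts == 0):
        raise ValueError("class_weight mode requires nonzero counts per class")
    w = 1.0 / counts
    return w / w.mean()


# ---------------------------------------------------------------------------
# clip -> network-input pipeline
# ---------------------------------------------------------------------------

def clips_to_specs(clips: Sequence[Clip]) -> List[LogMelSpec]:
    return [compute_logmel(normalize_clip(c)) for c in clips]


def augment_specs(specs: Sequence[LogMelSpec], seed: int) -> List[LogMelSpec]:
    """Deterministic per-clip SpecAugment (training specs only)."""
    return [spec_augment(s, seed=int(np.random.default_rng([seed, i])
                                     .integers(0, 2**31)))
            for i, s in enumerate(specs)]


def specs_to_batch(specs: Sequence[LogMelSpec],
                   selector: SpectrogramSelector) -> Tuple[np.ndarray, np.ndarray]:
    """(n, 80, T_fixed) float32 inputs + integer labels (1 = COPD)."""
    X = np.stack([selector.transform(s) for s in specs]).astype(np.float32)
    y = np.array([1 if s.label == "COPD" else 0 for s in specs], dtype=np.int64)
    return X, y


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

def _forward_scores(model: ECAPAClassifier, X: np.ndarray,
                    batch_size: int = 64) -> np.ndarray:
    probs = [model.predict_proba(X[i:i + batch_size])
             for i in range(0, len(X), batch_size)]
    return np.concatenate(probs)[:, 1]


def evaluate_model(model: ECAPAClassifier, X: np.ndarray,
                   y: np.ndarray) -> FoldMetrics:
    scores = _forward_scores(model, X)
    y_true = [LABELS[i] for i in y]
    y_pred = [LABELS[int(s >= 0.5)] for s in scores]
    return evaluate_predictions(y_true, y_pred, scores)


def train_model(model: ECAPAClassifier, X_train: np.ndarray, y_train: np.ndarray,
                X_val: np.ndarray, y_val: np.ndarray,
                config: TrainConfig) -> Tuple[ECAPAClassifier, pd.DataFrame]:
    """Fit with early stopping on validation F1; returns the model restored
    to its best-epoch parameters plus a per-epoch history table."""
    if len(np.unique(y_train)) < 2:
        raise ValueError("training data must contain both classes")
    class_counts = {lab: int((y_train == i).sum())
                    for i, lab in enumerate(LABELS)}
    weights = make_loss(config.imbalance_mode, class_counts)
    opt = AdamW(model.parameters(), lr=config.learning_rate,
                weight_decay=config.weight_decay)
    stopper = EarlyStopper(config.early_stop_patience)
    rng = np.random.default_rng(config.seed)
    best_state = model.state_dict()
    history: List[dict] = []
    n = len(X_train)
    for epoch in range(1, config.max_epochs + 1):
        model.train()
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            loss, _ = model.loss(X_train[idx], y_train[idx], weights)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"NaN/inf loss at epoch {epoch}, batch {start // config.batch_size}"
                    f" (lr={config.learning_rate}, batch={len(idx)})")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        model.eval()
        val_metrics = evaluate_model(model, X_val, y_val)
        sel = val_metrics.as_dict()[config.selection_metric]
        if stopper.update(sel, epoch):
            best_state = model.state_dict()
        history.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                        **{f"val_{k}": v for k, v in val_metrics.as_dict().items()}})
        if stopper.should_stop:
            break
    model.load_state_dict(best_state)
    model.eval()
    hist = pd.DataFrame(history)
    hist.attrs["best_epoch"] = stopper.best_epoch
    return model, hist


# ---------------------------------------------------------------------------
# fold pipeline + cross-validation
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    lasso_enabled: bool = True
    lasso_n_lambdas: int = 30
    lasso_cv_folds: int = 3
    t_fixed: int = T_FIXED


def run_fold(train_clips: Sequence[Clip], val_clips: Sequence[Clip],
             cfg: PipelineConfig, seed: int):
    """One complete fold: oversample/weight train only -> fit lasso mask on
    train -> train the network -> evaluate on the held-out clips."""
    train_cfg = TrainConfig(**{**asdict(cfg.train), "seed": seed})
    if train_cfg.imbalance_mode == "oversample":
        train_clips = oversample_minority(train_clips)
    train_specs = clips_to_specs(train_clips)
    if train_cfg.spec_augment:
        train_specs = augment_specs(train_specs, seed)
    val_specs = clips_to_specs(val_clips)

    selector = SpectrogramSelector(t_fixed=cfg.t_fixed,
                                   n_lambdas=cfg.lasso_n_lambdas,
                                   cv_folds=cfg.lasso_cv_folds,
                                   seed=seed, enabled=cfg.lasso_enabled)
    selector.fit(train_specs,
                 [1 if s.label == "COPD" else 0 for s in train_specs],
                 [s.patient_id for s in train_specs])

    X_tr, y_tr = specs_to_batch(train_specs, selector)
    X_va, y_va = specs_to_batch(val_specs, selector)
    model = build_model(cfg.model, seed=seed)
    model, history = train_model(model, X_tr, y_tr, X_va, y_va, train_cfg)
    fold_metrics = evaluate_model(model, X_va, y_va)
    return model, selector, fold_metrics, history


def cross_validate(clips: Sequence[Clip], patient_labels: Dict[str, str],
                   k: int, cfg: PipelineConfig, seed: int = 0) -> CVSummary:
    """Patient-wise k-fold CV of the full pipeline. Every fold asserts the
    no-leakage invariant; fold metrics come from held-out patients only."""
    splits = kfold_patient_splits(patient_labels, k=k, seed=seed)
    per_fold: List[FoldMetrics] = []
    for fold_idx, split in enumerate(splits):
        assert_no_leakage(split, clips)
        parts = split_clips(clips, split)
        train_clips, val_clips = parts.get("train", []), parts.get("val", [])
        val_patients = {c.patient_id for c in val_clips}
        train_patients = {c.patient_id for c in train_clips}
        if val_patients & train_patients:
            raise AssertionError("patient leakage between train and val")
        _, _, fm, _ = run_fold(train_clips, val_clips, cfg,
                               seed=int(np.random.default_rng(
                                   [seed, fold_idx]).integers(0, 2**31)))
        per_fold.append(fm)
    return summarize_folds(per_fold)


# ---------------------------------------------------------------------------
# noise robustness
# ---------------------------------------------------------------------------

DEFAULT_SNR_LIST = (30.0, 20.0, 15.0, 10.0, 5.0, 0.0)


def noise_robustness_curve(model: ECAPAClassifier, selector: SpectrogramSelector,
                           eval_specs: Sequence[LogMelSpec],
                           snr_list: Sequence[float] = DEFAULT_SNR_LIST,
                           seed: int = 0,
                           include_clean: bool = True) -> pd.DataFrame:
    """Accuracy vs SNR: Gaussian noise injected into the log-Mel inputs at
    each level (fixed seed per SNR) before masking and classification.
    A clean reference row (snr_db = inf) is included by default."""
    y = np.array([1 if s.label == "COPD" else 0 for s in eval_specs])
    rows = []
    levels = ([float("inf")] if include_clean else []) + [float(s) for s in snr_list]
    for i, snr in enumerate(levels):
        if np.isinf(snr):
            specs = list(eval_specs)
        else:
            snr_seed = int(np.random.default_rng([seed, i]).integers(0, 2**31))
            specs = [noisy_logmel(s, snr, seed=snr_seed + j)
                     for j, s in enumerate(eval_specs)]
        X, _ = specs_to_batch(specs, selector)
        fm = evaluate_model(model, X, y)
        rows.append({"snr_db": snr, "accuracy": fm.accuracy, "f1": fm.f1})
    return pd.DataFrame(rows)
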