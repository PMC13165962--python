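"""Classification metrics with COPD as the positive class, and the
cross-validation summary arithmetic (Student-t 95% confidence intervals)."""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score

POSITIVE_LABEL = "COPD"


def round_half_up(x: float, decimals: int = 1) -> float:
    """Report-time rounding: half always rounds away from zero."""
    if not np.isfinite(x):
        return x
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class FoldMetrics:
    """Percentages in [0, 100]; undefined ratios are NaN (with a warning at
    computation time), never silently zero."""
    accuracy: float
    precision: float
    recall: float
    f1: float
    specificity: float
    roc_auc: float = float("nan")
    loss: float = float("nan")
    confusion: ConfusionMatrix | None = None

    def as_dict(self) -> Dict[str, float]:
        return {"accuracy": self.accuracy, "precision": self.precision,
                "recall": self.recall, "f1": self.f1,
                "specificity": self.specificity, "roc_auc": self.roc_auc,
                "loss": self.loss}


def _safe_ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting NaN")
        return float("nan")
    return num / den


def metrics_from_confusion(cm: ConfusionMatrix) -> FoldMetrics:
    """Confusion-matrix-derived metrics, as percentages (full precision;
    round only at report time)."""
    acc = _safe_ratio(cm.tp + cm.tn, cm.total, "accuracy") * 100
    prec = _safe_ratio(cm.tp, cm.tp + cm.fp, "precision") * 100
    rec = _safe_ratio(cm.tp, cm.tp + cm.fn, "recall") * 100
    spec = _safe_ratio(cm.tn, cm.tn + cm.fp, "specificity") * 100
    if np.isfinite(prec) and np.isfinite(rec) and (prec + rec) > 0:
        f1 = 2 * prec * rec / (prec + rec)
    else:
        warnings.warn("f1 undefined; reporting NaN")
        f1 = float("nan")
    return FoldMetrics(accuracy=acc, precision=prec, recall=rec, f1=f1,
                       specificity=spec, confusion=cm)


def evaluate_predictions(y_true: Sequence[str], y_pred: Sequence[str],
                         scores: Sequence[float] | None = None,
                         positive: str = POSITIVE_LABEL) -> FoldMetrics:
    """Metrics from label sequences; ``scores`` (positive-class score per
    sample) additionally yields ROC-AUC via the rank statistic."""
    y_true = list(y_true)
    y_pred = list(y_pred)
    if len(y_true) == 0:
        raise ValueError("need at least one sample")
    labels = set(y_true) | set(y_pred)
    if len(labels - {positive}) > 1:
        raise ValueError(f"label vocabulary mismatch for binary task with "
                         f"positive={positive!r}: {sorted(labels)}")
    t = np.array([lab == positive for lab in y_true])
    p = np.array([lab == positive for lab in y_pred])
    cm = ConfusionMatrix(tp=int((t & p).sum()), fp=int((~t & p).sum()),
                         tn=int((~t & ~p).sum()), fn=int((t & ~p).sum()))
    fm = metrics_from_confusion(cm)
    if scores is not None and len(set(t.tolist())) == 2:
        fm.roc_auc = float(roc_auc_score(t.astype(int), np.asarray(scores))) * 100
    return fm


def confidence_interval(mean: float, std: float, k: int) -> Tuple[float, float]:
    """95% CI of a k-fold mean: mean +- t_{0.975, k-1} * std / sqrt(k)."""
    if k < 2:
        raise ValueError("need k >= 2 folds for a confidence interval")
    if std < 0:
        raise ValueError("std must be nonnegative")
    half = stats.t.ppf(0.975, k - 1) * std / np.sqrt(k)
    return (mean - half, mean + half)


@dataclass
class CVSummary:
    per_fold: List[FoldMetrics]
    mean: Dict[str, float] = field(default_factory=dict)
    std: Dict[str, float] = field(default_factory=dict)
    ci95: Dict[str, Tuple[float, float]] = field(default_factory=dict)

    @property
    def k(self) -> int:
        return len(self.per_fold)


def summarize_folds(per_fold: List[FoldMetrics]) -> CVSummary:
    """Aggregate fold metrics: mean, sample std (ddof=1), and t-based 95% CI."""
    summary = CVSummary(per_fold=per_fold)
    k = len(per_fold)
    for key in per_fold[0].as_dict():
        vals = np.array([fm.as_dict()[key] for fm in per_fold])
        vals = vals[np.isfinite(vals)]
        if len(vals) == 0:
            continue
        m = float(vals.mean())
        s = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        summary.mean[key] = m
        summary.std[key] = s
        if len(vals) >= 2:
            summary.ci95[key] = confidence_interval(m, s, len(vals))
    return summary
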