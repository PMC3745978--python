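"""Confusion-matrix metrics and stratified k-fold cross-validation.

The five figures reported for a binary diagnostic classifier are

    accuracy    = (TP + TN) / (TP + FP + FN + TN)
    sensitivity = TP / (TP + FN)          (recall of the positive class)
    specificity = TN / (TN + FP)
    PPV         = TP / (TP + FP)          (positive predictive value)
    NPV         = TN / (TN + FN)

A metric whose denominator is zero is reported as undefined (None) and
flagged — never silently zero.  Cross-validation reports both the mean of
per-fold metrics (the convention used when quoting a single CV accuracy)
and the metrics of the pooled confusion counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold

from .classification import SvmConfig, predict_batch, train_svm
from .data import LabeledMatrix

__all__ = [
    "ConfusionMatrix",
    "Metrics",
    "MetricReport",
    "confusion",
    "metrics",
    "stratified_kfold",
    "cross_validate",
]

METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "ppv", "npv")


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.tp + other.tp,
            self.fp + other.fp,
            self.fn + other.fn,
            self.tn + other.tn,
        )

    def to_dict(self) -> dict:
        return {"tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn}


@dataclass
class Metrics:
    """The five performance figures; None where the denominator was zero,
    with the metric name listed in ``undefined``."""

    accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    undefined: list = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {name: getattr(self, name) for name in METRIC_NAMES}
        d["undefined"] = list(self.undefined)
        return d


def confusion(y_true, y_pred, positive_class, classes: Sequence | None = None) -> ConfusionMatrix:
    """Count TP/FP/FN/TN with the designated positive class."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValueError("y_true and y_pred must be equal-length 1-D label vectors")
    observed = set(y_true.tolist()) | set(y_pred.tolist())
    if classes is not None:
        unknown = observed - set(classes)
        if unknown:
            raise ValueError(f"unknown labels: {sorted(map(str, unknown))}")
        if positive_class not in classes:
            raise ValueError(f"positive_class {positive_class!r} not in classes")
    elif len(observed | {positive_class}) > 2:
        raise ValueError(
            "labels are not binary; pass `classes` to disambiguate"
        )
    tpos = y_true == positive_class
    ppos = y_pred == positive_class
    return ConfusionMatrix(
        tp=int(np.sum(tpos & ppos)),
        fp=int(np.sum(~tpos & ppos)),
        fn=int(np.sum(tpos & ~ppos)),
        tn=int(np.sum(~tpos & ~ppos)),
    )


def _ratio(num: int, den: int, name: str, undefined: list) -> float | None:
    if den == 0:
        undefined.append(name)
        return None
    return num / den


def metrics(cm: ConfusionMatrix) -> Metrics:
    """Derive the five figures from confusion counts (fractions in [0, 1])."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    undefined: list = []
    return Metrics(
        accuracy=(cm.tp + cm.tn) / cm.total,
        sensitivity=_ratio(cm.tp, cm.tp + cm.fn, "sensitivity", undefined),
        specificity=_ratio(cm.tn, cm.tn + cm.fp, "specificity", undefined),
        ppv=_ratio(cm.tp, cm.tp + cm.fp, "ppv", undefined),
        npv=_ratio(cm.tn, cm.tn + cm.fn, "npv", undefined),
        undefined=undefined,
    )


def stratified_kfold(
    data: LabeledMatrix,
    k: int,
    seed: int,
    stratify: bool = True,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """k train/validation index pairs; stratified by default.

    Stratification requires every class to have at least k samples (class
    proportions are then preserved within one sample per fold).  Plain
    shuffled k-fold (``stratify=False``) supports any k up to n, including
    leave-one-out.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if stratify:
        for label, count in data.class_counts().items():
            if count < k:
                raise ValueError(
                    f"class {label!r} has {count} samples, fewer than k={k}"
                )
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(seed))
        pairs = splitter.split(data.features, data.labels.astype(str))
    else:
        if k > data.n_samples:
            raise ValueError("k cannot exceed the number of samples")
        splitter = KFold(n_splits=k, shuffle=True, random_state=int(seed))
        pairs = splitter.split(data.features)
    return [(tr.copy(), va.copy()) for tr, va in pairs]


def _mean_of_folds(per_fold: list[Metrics]) -> Metrics:
    undefined: list = []
    values = {}
    for name in METRIC_NAMES:
        vals = [getattr(m, name) for m in per_fold if getattr(m, name) is not None]
        if not vals:
            undefined.append(name)
            values[name] = None
        else:
            values[name] = float(np.mean(vals))
    return Metrics(undefined=undefined, **values)


@dataclass
class MetricReport:
    folds: int
    positive_class: object
    per_fold: list          # ConfusionMatrix per fold
    per_fold_metrics: list  # Metrics per fold
    mean: Metrics           # mean over folds (the headline CV numbers)
    pooled: Metrics         # metrics of the summed confusion counts

    def to_dict(self) -> dict:
        return {
            "folds": self.folds,
            "positive_class": str(self.positive_class),
            "per_fold": [cm.to_dict() for cm in self.per_fold],
            "per_fold_metrics": [m.to_dict() for m in self.per_fold_metrics],
            "mean": self.mean.to_dict(),
            "pooled": self.pooled.to_dict(),
        }


def cross_validate(
    data: LabeledMatrix,
    subset: Sequence[int],
    k: int,
    svm_config: SvmConfig | None = None,
    seed: int = 0,
    positive_class=None,
    stratify: bool = True,
) -> MetricReport:
    """k-fold CV of the linear SVM on the given feature columns.

    ``positive_class`` defaults to the second entry of ``class_set`` (the
    class the SVM maps to +1).
    """
    if data.n_classes != 2:
        raise ValueError("cross_validate requires a two-class dataset")
    subset = list(subset)
    if positive_class is None:
        positive_class = data.class_set[1]
    if positive_class not in data.class_set:
        raise ValueError(f"positive_class {positive_class!r} not in class_set")
    restricted = data.restrict(subset)
    per_fold: list[ConfusionMatrix] = []
    per_fold_metrics: list[Metrics] = []
    for tr_idx, va_idx in stratified_kfold(restricted, k, seed, stratify=stratify):
        model = train_svm(restricted.take(tr_idx), svm_config)
        pred = predict_batch(model, restricted.features[va_idx])
        cm = confusion(
            restricted.labels[va_idx], pred, positive_class,
            classes=restricted.class_set,
        )
        per_fold.append(cm)
        per_fold_metrics.append(metrics(cm))
    pooled_cm = per_fold[0]
    for cm in per_fold[1:]:
        pooled_cm = pooled_cm + cm
    return MetricReport(
        folds=k,
        positive_class=positive_class,
        per_fold=per_fold,
        per_fold_metrics=per_fold_metrics,
        mean=_mean_of_folds(per_fold_metrics),
        pooled=metrics(pooled_cm),
    )
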