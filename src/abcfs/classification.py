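"""Linear SVM stage behind a narrow train/predict contract.

Training delegates to scikit-learn's ``SVC`` (libsvm's SMO solver for the
dual problem ``max_a sum a_i - 1/2 sum y_i y_j K(x_i,x_j) a_i a_j`` subject
to ``sum y_i a_i = 0``, ``0 <= a_i <= C``).  The two classes are mapped to
-1/+1 by their ``class_set`` order, and prediction is computed here
directly from the extracted hyperplane (w, b): positive side (including
the boundary itself) goes to the +1 class.

Defaults follow the standard SMO configuration for this pipeline: linear
kernel, KKT tolerance 1e-3, iteration cap 15000, 5000 MB kernel cache, and
cost C = 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.svm import SVC

from .data import LabeledMatrix

__all__ = ["SvmConfig", "TrainedSvm", "train_svm", "predict", "predict_batch"]


@dataclass(frozen=True)
class SvmConfig:
    kernel: str = "linear"
    kkt_tolerance: float = 1.0e-3
    max_iterations: int = 15000
    cache_limit: int = 5000
    cost_C: float = 1.0

    def __post_init__(self) -> None:
        if self.kernel != "linear":
            raise ValueError("only the linear kernel is supported")
        if self.cost_C <= 0:
            raise ValueError("cost_C must be positive")


@dataclass
class TrainedSvm:
    """Hyperplane (w, b) plus the -1/+1 class mapping and diagnostics."""

    weight_vector: np.ndarray
    bias: float
    negative_class: object  # mapped to -1 (first in class_set)
    positive_class: object  # mapped to +1 (second in class_set)
    support_info: dict = field(default_factory=dict)


def train_svm(train: LabeledMatrix, config: SvmConfig | None = None) -> TrainedSvm:
    """Fit a linear SVM on a two-class LabeledMatrix.

    The first class in ``class_set`` maps to -1, the second to +1.
    Non-convergence within the iteration cap is recorded in
    ``support_info["warnings"]`` rather than raised.
    """
    if config is None:
        config = SvmConfig()
    if train.n_classes != 2:
        raise ValueError(
            f"linear SVM stage supports exactly 2 classes, got {train.n_classes}"
        )
    neg, pos = train.class_set
    y = np.where(train.labels == pos, 1.0, -1.0)
    clf = SVC(
        kernel="linear",
        C=config.cost_C,
        tol=config.kkt_tolerance,
        max_iter=config.max_iterations,
        cache_size=config.cache_limit,
    )
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        clf.fit(train.features, y)
    # dual_coef_ holds y_i * alpha_i for the support vectors
    alpha_y = clf.dual_coef_[0]
    info = {
        "n_support": clf.n_support_.tolist(),
        "support_indices": clf.support_.tolist(),
        "alpha_times_y": alpha_y,
        "dual_equality_gap": float(abs(alpha_y.sum())),
        "C": config.cost_C,
        "warnings": [str(w.message) for w in caught],
    }
    return TrainedSvm(
        weight_vector=clf.coef_[0].copy(),
        bias=float(clf.intercept_[0]),
        negative_class=neg,
        positive_class=pos,
        support_info=info,
    )


def decision_values(model: TrainedSvm, X: np.ndarray) -> np.ndarray:
    """Signed distances-proportional values ``w . x + b`` for rows of X."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.weight_vector.shape[0]:
        raise ValueError(
            f"expected {model.weight_vector.shape[0]} features, got {X.shape[1]}"
        )
    return X @ model.weight_vector + model.bias


def predict(model: TrainedSvm, x: np.ndarray):
    """Class of a single pattern: sign of ``w . x + b``; the boundary
    itself (exactly zero) is assigned to the positive class."""
    val = decision_values(model, np.atleast_2d(np.asarray(x, dtype=float)))[0]
    return model.positive_class if val >= 0 else model.negative_class


def predict_batch(model: TrainedSvm, X: np.ndarray) -> np.ndarray:
    vals = decision_values(model, X)
    out = np.where(vals >= 0, model.positive_class, model.negative_class)
    return out.astype(object)
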