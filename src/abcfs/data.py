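"""Shared in-memory container for labeled tabular data.

Every stage of the pipeline (imputation, scaling, feature selection,
clustering, SVM evaluation) operates on a :class:`LabeledMatrix`: a dense
float feature matrix, one label per row, and an ordered set of distinct
class labels.  The class order is semantically meaningful — it fixes
tie-breaks in nearest-center classification and the -1/+1 mapping for the
SVM — so it travels with the data instead of being re-derived.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["LabeledMatrix"]


def _ordered_unique(labels: np.ndarray) -> list:
    seen: dict = {}
    for lab in labels.tolist():
        if lab not in seen:
            seen[lab] = None
    return list(seen)


@dataclass
class LabeledMatrix:
    """N x d feature matrix with per-row class labels.

    Parameters
    ----------
    features : ndarray of shape (n_samples, n_features)
        Dense float matrix.  May contain NaN only for not-yet-imputed data.
    labels : ndarray of shape (n_samples,)
        Class label per row.  Any hashable values.
    class_set : list, optional
        Ordered distinct labels.  Defaults to order of first appearance in
        ``labels``.  Order determines classification tie-breaks.
    feature_names : list of str, optional
        Column names; generated as ``f0..f{d-1}`` if omitted.
    """

    features: np.ndarray
    labels: np.ndarray
    class_set: list = field(default=None)  # type: ignore[assignment]
    feature_names: list = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.features = np.atleast_2d(np.asarray(self.features, dtype=float))
        self.labels = np.asarray(self.labels)
        if self.features.shape[0] != self.labels.shape[0]:
            raise ValueError(
                f"feature rows ({self.features.shape[0]}) != labels "
                f"({self.labels.shape[0]})"
            )
        if self.class_set is None:
            self.class_set = _ordered_unique(self.labels)
        else:
            self.class_set = list(self.class_set)
            present = set(self.labels.tolist())
            missing = present - set(self.class_set)
            if missing:
                raise ValueError(f"labels not in class_set: {sorted(map(str, missing))}")
        if self.feature_names is None:
            self.feature_names = [f"f{j}" for j in range(self.features.shape[1])]
        elif len(self.feature_names) != self.features.shape[1]:
            raise ValueError("feature_names length != number of feature columns")

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def n_classes(self) -> int:
        return len(self.class_set)

    def class_indices(self, label) -> np.ndarray:
        """Row indices belonging to ``label``."""
        return np.flatnonzero(self.labels == label)

    def class_counts(self) -> dict:
        return {c: int((self.labels == c).sum()) for c in self.class_set}

    def restrict(self, subset: Sequence[int]) -> "LabeledMatrix":
        """View of the data on a subset of feature columns (order kept)."""
        subset = list(subset)
        return LabeledMatrix(
            features=self.features[:, subset],
            labels=self.labels,
            class_set=self.class_set,
            feature_names=[self.feature_names[j] for j in subset],
        )

    def take(self, idx: Sequence[int]) -> "LabeledMatrix":
        """Row subset preserving class_set order."""
        idx = np.asarray(idx, dtype=int)
        return LabeledMatrix(
            features=self.features[idx],
            labels=self.labels[idx],
            class_set=self.class_set,
            feature_names=self.feature_names,
        )
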