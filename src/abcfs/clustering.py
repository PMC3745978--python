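"""Supervised clustering with ABC-trained class centers.

Training is per class: the class's samples (restricted to the active
feature subset) define both the search box (their per-dimension min/max)
and the cost — the mean Euclidean distance from a candidate center to the
class's training samples:

    f(z) = (1 / D_train) * sum_j d(x_j, z)

The 1/D_train factor normalizes the cost so colonies trained on classes of
different sizes are comparable; its exact minimizer is the geometric
median of the class.  All SN food sources surviving the ABC run are kept
as that class's prototype set, and test points take the label of the
single nearest prototype across classes (ties go to the earlier class in
``class_set`` order).

``kmeans_objective`` and ``class_mean`` implement the classical
squared-distance clustering objective and the cluster mean; they are
diagnostics/reference quantities, not on the training path.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .abc_core import AbcConfig, SearchSpace, run_abc
from .data import LabeledMatrix

__all__ = [
    "ClassCenterModel",
    "within_class_cost",
    "kmeans_objective",
    "class_mean",
    "train_class_centers",
    "classify_nearest_food",
]


@dataclass
class ClassCenterModel:
    """Per-class prototype centers living in a feature subspace.

    ``centers_by_class[label]`` is an (n_centers, d) array with
    d == len(feature_indices); ``class_set`` fixes the tie-break order.
    """

    centers_by_class: dict
    feature_indices: list
    class_set: list

    def __post_init__(self) -> None:
        d = len(self.feature_indices)
        for label, centers in self.centers_by_class.items():
            centers = np.atleast_2d(np.asarray(centers, dtype=float))
            if centers.shape[0] < 1 or centers.shape[1] != d:
                raise ValueError(
                    f"class {label!r}: centers must be (n>=1, {d}), "
                    f"got {centers.shape}"
                )
            self.centers_by_class[label] = centers

    @property
    def best_center_by_class(self) -> dict:
        """First stored center per class (the ABC best, by construction)."""
        return {c: arr[0] for c, arr in self.centers_by_class.items()}


def within_class_cost(center: np.ndarray, samples: np.ndarray) -> float:
    """Mean Euclidean distance from ``center`` to each row of ``samples``.

    This is the (normalized) cost handed to the ABC optimizer for one
    class; its true minimizer is the geometric median of the rows.
    """
    center = np.atleast_1d(np.asarray(center, dtype=float))
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    if samples.shape[0] == 0:
        raise ValueError("samples must be nonempty")
    if samples.shape[1] != center.shape[0]:
        raise ValueError(
            f"dimension mismatch: center has {center.shape[0]}, "
            f"samples have {samples.shape[1]}"
        )
    return float(np.linalg.norm(samples - center, axis=1).mean())


def batch_within_class_cost(centers: np.ndarray, samples: np.ndarray) -> np.ndarray:
    """`within_class_cost` for many candidate centers at once: (m, d) -> (m,)."""
    return cdist(np.atleast_2d(centers), samples).mean(axis=1)


def kmeans_objective(
    assignments: np.ndarray, features: np.ndarray, centers: np.ndarray
) -> float:
    """Classical clustering objective: sum of squared distances to the
    assigned center, ``sum_i sum_j w_ij ||x_i - z_j||^2``.

    ``assignments`` is an (N, K) 0/1 matrix with exactly one 1 per row.
    """
    w = np.asarray(assignments, dtype=float)
    x = np.atleast_2d(np.asarray(features, dtype=float))
    z = np.atleast_2d(np.asarray(centers, dtype=float))
    if w.ndim != 2 or w.shape != (x.shape[0], z.shape[0]):
        raise ValueError("assignments must be (n_samples, n_centers)")
    if not np.allclose(w.sum(axis=1), 1.0):
        raise ValueError("every assignment row must sum to 1")
    sq = cdist(x, z, metric="sqeuclidean")
    return float((w * sq).sum())


def class_mean(samples: np.ndarray) -> np.ndarray:
    """Arithmetic mean of the rows (the squared-distance-optimal center)."""
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    if samples.shape[0] == 0:
        raise ValueError("samples must be nonempty")
    return samples.mean(axis=0)


def _class_space(samples: np.ndarray) -> SearchSpace:
    return SearchSpace(samples.min(axis=0), samples.max(axis=0))


def train_class_centers(
    train: LabeledMatrix,
    subset: Sequence[int],
    abc_config: AbcConfig,
) -> ClassCenterModel:
    """Run one ABC optimization per class and keep all SN final foods.

    Each class c gets an independent colony seeded ``abc_config.seed +
    class_index``, searching the box spanned by that class's training
    samples on the ``subset`` columns.  Centers are stored best-first.
    """
    subset = list(subset)
    centers_by_class: dict = {}
    for ci, label in enumerate(train.class_set):
        rows = train.class_indices(label)
        if rows.size == 0:
            raise ValueError(f"class {label!r} has no training samples")
        samples = train.features[np.ix_(rows, subset)]
        result = run_abc(
            lambda c, s=samples: batch_within_class_cost(c, s),
            _class_space(samples),
            abc_config.with_seed(abc_config.seed + ci),
            batched=True,
        )
        order = np.argsort([f.cost for f in result.final_foods], kind="stable")
        centers_by_class[label] = np.array(
            [result.final_foods[i].position for i in order]
        )
    return ClassCenterModel(
        centers_by_class=centers_by_class,
        feature_indices=subset,
        class_set=list(train.class_set),
    )


def classify_nearest_food(model: ClassCenterModel, x: np.ndarray):
    """Label of the nearest center across all classes (single vector or
    (n, d) matrix; ties go to the earlier class in ``class_set``)."""
    X = np.asarray(x, dtype=float)
    single = X.ndim == 1
    X = np.atleast_2d(X)
    d = len(model.feature_indices)
    if X.shape[1] != d:
        raise ValueError(f"expected {d}-dimensional input, got {X.shape[1]}")
    # per class: distance to the nearest of its centers
    per_class = np.stack(
        [
            cdist(X, model.centers_by_class[c]).min(axis=1)
            for c in model.class_set
        ],
        axis=1,
    )
    idx = per_class.argmin(axis=1)  # argmin takes the first min: class order
    labels = np.array(model.class_set, dtype=object)[idx]
    return labels[0] if single else labels
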