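"""ABCFS: sequential forward selection scored by ABC clustering.

Candidate feature subsets are scored by how well the ABC-trained
nearest-center classifier predicts held-out data: each evaluation draws a
stratified 75/25 train/test split, trains per-class centers on the train
part, classifies the test part, and records the accuracy.  The evaluation
is repeated ``runs`` times with fresh splits and colony seeds and the mean
accuracy is the subset's score.

The search itself is plain greedy forward selection: start from the empty
set, at each step score every unselected feature appended to the current
subset, accept the argmax (ties to the lowest feature index), and stop as
soon as the step-best mean score drops below the previous step's score —
the declining feature is not kept.  ``scorer`` is pluggable so the greedy
loop can be exercised against deterministic oracles.

Seeding: each (step, candidate) evaluation derives an independent seed
from the base seed via ``derive_seed`` (SeedSequence mixing), so candidate
scores are not coupled through shared splits; the ``runs`` repetitions of
one evaluation are evolved as a batched colony ensemble from a single
generator, which keeps the whole selection deterministic under the base
seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .abc_core import AbcConfig, _evolve
from .data import LabeledMatrix

__all__ = [
    "SelectionStep",
    "SelectionTrace",
    "SelectionResult",
    "derive_seed",
    "stratified_split",
    "score_subset",
    "abcfs_select",
    "SCORE_DECLINED",
    "MAX_FEATURES_REACHED",
    "ALL_FEATURES_USED",
]

SCORE_DECLINED = "score_declined"
MAX_FEATURES_REACHED = "max_features_reached"
ALL_FEATURES_USED = "all_features_used"


def derive_seed(*keys: int) -> int:
    """Mix integer keys into a seed below 2**31 (stable across platforms)."""
    entropy = [int(k) & 0xFFFFFFFF for k in keys]
    return int(np.random.SeedSequence(entropy).generate_state(1)[0] % (1 << 31))


@dataclass
class SelectionStep:
    subset_before: tuple
    candidate_scores: dict  # feature index -> mean accuracy
    candidate_stds: dict    # feature index -> accuracy std over runs
    chosen_feature: int
    mean_score: float
    score_std: float

    def to_dict(self) -> dict:
        return {
            "subset_before": list(self.subset_before),
            "candidate_scores": {str(k): v for k, v in self.candidate_scores.items()},
            "candidate_stds": {str(k): v for k, v in self.candidate_stds.items()},
            "chosen_feature": self.chosen_feature,
            "mean_score": self.mean_score,
            "score_std": self.score_std,
        }


@dataclass
class SelectionTrace:
    steps: list = field(default_factory=list)
    runs_per_evaluation: int = 1
    rejected_step: SelectionStep | None = None  # the declining evaluation

    def to_dict(self) -> dict:
        return {
            "runs_per_evaluation": self.runs_per_evaluation,
            "steps": [s.to_dict() for s in self.steps],
            "rejected_step": (
                None if self.rejected_step is None else self.rejected_step.to_dict()
            ),
        }


@dataclass
class SelectionResult:
    selected_features: list
    trace: SelectionTrace
    stop_reason: str

    def to_dict(self) -> dict:
        return {
            "selected_features": list(self.selected_features),
            "stop_reason": self.stop_reason,
            "trace": self.trace.to_dict(),
        }


def stratified_split(
    data: LabeledMatrix,
    train_fraction: float,
    rng: np.random.Generator | int,
) -> tuple[LabeledMatrix, LabeledMatrix]:
    """Per-class split: floor(train_fraction * n_class) rows to train.

    Preserves per-class proportions within one sample; raises if any class
    would land entirely on one side.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    train_idx: list[np.ndarray] = []
    test_idx: list[np.ndarray] = []
    for label in data.class_set:
        idx = data.class_indices(label)
        if idx.size < 2:
            raise ValueError(f"class {label!r} has fewer than 2 samples")
        n_tr = math.floor(train_fraction * idx.size)
        if n_tr < 1 or n_tr >= idx.size:
            raise ValueError(
                f"class {label!r}: split {train_fraction} leaves an empty side "
                f"(n={idx.size})"
            )
        perm = rng.permutation(idx)
        train_idx.append(perm[:n_tr])
        test_idx.append(perm[n_tr:])
    return data.take(np.concatenate(train_idx)), data.take(np.concatenate(test_idx))


def _ensemble_centers(
    class_arrays: np.ndarray,
    n_foods: int,
    max_cycles: int,
    limit: int,
    seed: int,
) -> np.ndarray:
    """Evolve R parallel colonies, one per run, on one class's samples.

    class_arrays: (R, S, d) training samples; returns centers (R, SN, d).
    """
    samples = np.asarray(class_arrays, dtype=float)
    lower = samples.min(axis=1)
    upper = samples.max(axis=1)
    samp_sq = (samples * samples).sum(axis=2)  # (R, S)

    def eval_fn(cand: np.ndarray) -> np.ndarray:
        # mean_s ||cand[r, i] - samples[r, s]|| via the expanded square
        cand_sq = (cand * cand).sum(axis=2)
        cross = cand @ samples.transpose(0, 2, 1)  # (R, m, S)
        d2 = cand_sq[:, :, None] + samp_sq[:, None, :] - 2.0 * cross
        return np.sqrt(np.maximum(d2, 0.0)).mean(axis=2)

    rng = np.random.default_rng(seed)
    pos, _, _, _, _, _, _ = _evolve(
        rng, lower, upper, eval_fn, n_foods, max_cycles, limit
    )
    return pos


def score_subset(
    data: LabeledMatrix,
    subset: Sequence[int],
    runs: int,
    abc_config: AbcConfig,
    train_fraction: float = 0.75,
    fixed_split: bool = False,
) -> tuple[float, float]:
    """Mean and std of held-out nearest-center accuracy over ``runs``
    repeated stratified splits.

    With ``fixed_split`` the 75/25 split is drawn once and reused; colony
    seeds still differ per run.
    """
    subset = list(subset)
    if not subset:
        raise ValueError("subset must be nonempty")
    if runs < 1:
        raise ValueError("runs must be >= 1")
    base = abc_config.seed
    K = len(data.class_set)
    class_to_idx = {c: i for i, c in enumerate(data.class_set)}

    train_by_class: list[list[np.ndarray]] = [[] for _ in range(K)]
    test_feats: list[np.ndarray] = []
    test_labels: list[np.ndarray] = []
    for r in range(runs):
        split_seed = derive_seed(base, 7, 0 if fixed_split else r)
        train, test = stratified_split(
            data, train_fraction, np.random.default_rng(split_seed)
        )
        for ci, label in enumerate(data.class_set):
            rows = train.class_indices(label)
            train_by_class[ci].append(train.features[np.ix_(rows, subset)])
        test_feats.append(test.features[:, subset])
        test_labels.append(
            np.array([class_to_idx[l] for l in test.labels.tolist()])
        )

    X_test = np.stack(test_feats)               # (R, T, d)
    y_test = np.stack(test_labels)              # (R, T)
    R, T, d = X_test.shape

    # per class: nearest-center distance of every test point, per run
    per_class = np.empty((K, R, T))
    for ci in range(K):
        centers = _ensemble_centers(
            np.stack(train_by_class[ci]),
            abc_config.n_foods,
            abc_config.max_cycles,
            abc_config.limit,
            derive_seed(base, 11, ci),
        )                                        # (R, SN, d)
        for r in range(R):
            per_class[ci, r] = cdist(X_test[r], centers[r]).min(axis=1)

    pred = per_class.argmin(axis=0)              # (R, T); ties -> earlier class
    acc = (pred == y_test).mean(axis=1)          # (R,)
    return float(acc.mean()), float(acc.std())


def abcfs_select(
    data: LabeledMatrix,
    max_features: int | None = None,
    runs: int = 100,
    abc_config: AbcConfig | None = None,
    scorer: Callable[[Sequence[int]], tuple[float, float]] | None = None,
    min_improvement: float = 0.0,
    train_fraction: float = 0.75,
    fixed_split: bool = False,
) -> SelectionResult:
    """Greedy forward selection with the ABC-clustering scorer.

    Parameters
    ----------
    max_features
        Upper bound on the subset size; defaults to all features.
    runs
        Repetitions per subset evaluation (averaged).
    scorer
        Optional replacement for the default scorer; called with a feature
        index list, must return (mean_score, std).  When given, ``runs``
        and ``abc_config`` only annotate the trace.
    min_improvement
        Selection stops when the step-best mean score is below the previous
        step's score plus this margin (0 = stop on strict decline).
    """
    if abc_config is None:
        abc_config = AbcConfig()
    n = data.n_features
    if max_features is None:
        max_features = n
    if not 1 <= max_features <= n:
        raise ValueError("max_features must be in [1, n_features]")

    selected: list[int] = []
    remaining = list(range(n))
    trace = SelectionTrace(runs_per_evaluation=runs)
    last_score = -math.inf
    stop_reason = ALL_FEATURES_USED

    while remaining:
        step = len(selected)
        cand_scores: dict[int, float] = {}
        cand_stds: dict[int, float] = {}
        for c in remaining:
            if scorer is not None:
                mean, std = scorer(selected + [c])
            else:
                cfg = abc_config.with_seed(derive_seed(abc_config.seed, step, c))
                mean, std = score_subset(
                    data, selected + [c], runs, cfg,
                    train_fraction=train_fraction, fixed_split=fixed_split,
                )
            cand_scores[c] = float(mean)
            cand_stds[c] = float(std)
        best_c = max(cand_scores, key=lambda c: (cand_scores[c], -c))
        record = SelectionStep(
            subset_before=tuple(selected),
            candidate_scores=cand_scores,
            candidate_stds=cand_stds,
            chosen_feature=best_c,
            mean_score=cand_scores[best_c],
            score_std=cand_stds[best_c],
        )
        if selected and cand_scores[best_c] < last_score + min_improvement:
            trace.rejected_step = record
            stop_reason = SCORE_DECLINED
            break
        trace.steps.append(record)
        selected.append(best_c)
        remaining.remove(best_c)
        last_score = cand_scores[best_c]
        if len(selected) >= max_features:
            stop_reason = MAX_FEATURES_REACHED if remaining else ALL_FEATURES_USED
            break

    return SelectionResult(
        selected_features=selected, trace=trace, stop_reason=stop_reason
    )
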