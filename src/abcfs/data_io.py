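"""Readers for delimited tabular datasets (UCI dialect), imputation, scaling.

Handles the common shape of public medical classification tables: numeric
and coded-binary columns, one label column, and ``?`` as the missing-value
marker.  Missing cells are imputed by the most frequent observed value of
the same feature *within the sample's own class*; ties break to the
smaller value.  Optional min-max scaling maps each feature to [0, 1] using
parameters learned on one dataset and re-applicable (with clipping) to
held-out data.

Schemas for the three classic UCI liver/diabetes tables (hepatitis, BUPA
liver disorders, Pima diabetes) ship with the package and declare per
column: kind (continuous / discrete / binary), the documented valid range,
and for binary columns the tokens coding each level.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .data import LabeledMatrix

__all__ = [
    "DatasetSchema",
    "ColumnSpec",
    "ScalingParams",
    "load_schema",
    "read_table",
    "read_csv_simple",
    "impute_mode_per_class",
    "impute_mean_per_class",
    "minmax_scale",
    "apply_scaling",
    "inverse_scaling",
    "write_clean_csv",
]

KINDS = ("continuous", "discrete", "binary")


@dataclass(frozen=True)
class ColumnSpec:
    name: str
    kind: str = "continuous"
    valid_range: tuple | None = None
    # binary columns: levels[0] = tokens mapping to 0, levels[1] = tokens to 1
    levels: tuple = ()

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown column kind {self.kind!r}")
        if self.kind == "binary" and len(self.levels) != 2:
            raise ValueError(f"binary column {self.name!r} needs 2 level token lists")


@dataclass(frozen=True)
class DatasetSchema:
    name: str
    columns: tuple          # ColumnSpec per feature, in file order
    label_column: str
    label_values: tuple     # ordered class labels (fixes class_set order)
    label_position: int = 0  # index of the label column in the file
    has_header: bool = False
    positive_class: str | None = None

    @property
    def feature_names(self) -> list:
        return [c.name for c in self.columns]


def load_schema(name_or_path: str | Path) -> DatasetSchema:
    """Load a packaged schema by name (``hepatitis``, ``liver_disorders``,
    ``diabetes``) or any schema JSON file by path."""
    path = Path(name_or_path)
    if path.suffix == ".json" and path.exists():
        payload = json.loads(path.read_text())
    else:
        ref = resources.files("abcfs.schemas").joinpath(f"{name_or_path}.json")
        try:
            payload = json.loads(ref.read_text())
        except FileNotFoundError:
            raise FileNotFoundError(
                f"no packaged schema named {name_or_path!r} and no such file"
            ) from None
    cols = tuple(
        ColumnSpec(
            name=c["name"],
            kind=c.get("kind", "continuous"),
            valid_range=tuple(c["range"]) if c.get("range") else None,
            levels=tuple(tuple(str(t) for t in lv) for lv in c.get("levels", [])),
        )
        for c in payload["columns"]
    )
    return DatasetSchema(
        name=payload["name"],
        columns=cols,
        label_column=payload["label"]["column"],
        label_values=tuple(str(v) for v in payload["label"]["values"]),
        label_position=int(payload["label"].get("position", 0)),
        has_header=bool(payload.get("has_header", False)),
        positive_class=payload["label"].get("positive"),
    )


def _parse_binary(token: str, spec: ColumnSpec, row: int) -> float:
    t = token.strip().lower()
    for value, tokens in enumerate(spec.levels):
        if t in (s.lower() for s in tokens):
            return float(value)
    raise ValueError(
        f"row {row}: column {spec.name!r} has unrecognized binary token {token!r}"
    )


def read_table(
    path: str | Path,
    schema: DatasetSchema,
    missing_marker: str = "?",
) -> tuple[LabeledMatrix, np.ndarray]:
    """Parse a delimited file against a schema.

    Returns the LabeledMatrix (missing cells as NaN) and the boolean
    missing mask.  Values outside a column's documented range trigger a
    warning but are kept.
    """
    n_cols = len(schema.columns) + 1
    df = pd.read_csv(
        path,
        header=0 if schema.has_header else None,
        dtype=str,
        skipinitialspace=True,
        skip_blank_lines=True,
    )
    if df.shape[1] != n_cols:
        bad = _find_bad_row(path, n_cols)
        raise ValueError(
            f"{path}: expected {n_cols} columns, found {df.shape[1]}"
            + (f" (first offending row: {bad})" if bad is not None else "")
        )
    values = df.to_numpy(dtype=object)
    label_tokens = values[:, schema.label_position]
    feat_tokens = np.delete(values, schema.label_position, axis=1)

    labels = np.empty(len(label_tokens), dtype=object)
    for i, tok in enumerate(label_tokens):
        t = str(tok).strip()
        if t not in schema.label_values:
            raise ValueError(
                f"row {i}: unknown label {t!r} (expected one of {schema.label_values})"
            )
        labels[i] = t

    n, d = feat_tokens.shape
    feats = np.full((n, d), np.nan)
    mask = np.zeros((n, d), dtype=bool)
    for j, spec in enumerate(schema.columns):
        for i in range(n):
            tok = str(feat_tokens[i, j]).strip()
            if tok == missing_marker or tok == "" or tok.lower() == "nan":
                mask[i, j] = True
                continue
            if spec.kind == "binary":
                try:
                    feats[i, j] = _parse_binary(tok, spec, i)
                    continue
                except ValueError:
                    pass  # fall through to numeric parse for 0/1-coded files
            try:
                feats[i, j] = float(tok)
            except ValueError:
                raise ValueError(
                    f"row {i}: column {spec.name!r} has unparseable value {tok!r}"
                ) from None
        if spec.valid_range is not None:
            lo, hi = spec.valid_range
            col = feats[:, j]
            bad = np.flatnonzero((col < lo) | (col > hi))
            if bad.size:
                warnings.warn(
                    f"column {spec.name!r}: {bad.size} value(s) outside the "
                    f"documented range [{lo}, {hi}] (e.g. {col[bad[0]]} at row "
                    f"{bad[0]}); values kept",
                    stacklevel=2,
                )
    data = LabeledMatrix(
        features=feats,
        labels=labels,
        class_set=[v for v in schema.label_values if v in set(labels.tolist())]
        or list(schema.label_values),
        feature_names=schema.feature_names,
    )
    return data, mask


def _find_bad_row(path, n_cols):
    try:
        with open(path) as fh:
            for i, line in enumerate(fh):
                if line.strip() and len(line.split(",")) != n_cols:
                    return i
    except OSError:
        pass
    return None


def read_csv_simple(
    path: str | Path,
    label_column: str,
    missing_marker: str = "?",
    class_order: list | None = None,
) -> tuple[LabeledMatrix, np.ndarray]:
    """Schema-less reader for a headered CSV: every non-label column is a
    numeric feature."""
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    if label_column not in df.columns:
        raise ValueError(f"{path}: no column named {label_column!r}")
    labels = df[label_column].astype(str).to_numpy(dtype=object)
    feat_df = df.drop(columns=[label_column])
    raw = feat_df.to_numpy(dtype=object)
    mask = np.zeros(raw.shape, dtype=bool)
    feats = np.full(raw.shape, np.nan)
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            tok = str(raw[i, j]).strip()
            if tok == missing_marker or tok == "" or tok.lower() == "nan":
                mask[i, j] = True
            else:
                try:
                    feats[i, j] = float(tok)
                except ValueError:
                    raise ValueError(
                        f"row {i}: column {feat_df.columns[j]!r} has "
                        f"unparseable value {tok!r}"
                    ) from None
    data = LabeledMatrix(
        features=feats,
        labels=labels,
        class_set=[str(c) for c in class_order] if class_order else None,
        feature_names=list(feat_df.columns),
    )
    return data, mask


def _column_mode(values: np.ndarray) -> float:
    """Most frequent value; ties broken by the smaller value."""
    uniq, counts = np.unique(values, return_counts=True)
    return float(uniq[np.argmax(counts)])  # np.unique sorts -> first max is smallest


def impute_mode_per_class(data: LabeledMatrix, mask: np.ndarray) -> LabeledMatrix:
    """Replace each missing cell by the most frequent observed value of
    that feature within the sample's own class."""
    return _impute(data, mask, _column_mode)


def impute_mean_per_class(data: LabeledMatrix, mask: np.ndarray) -> LabeledMatrix:
    """Per-class mean imputation (alternative policy for continuous data)."""
    return _impute(data, mask, lambda v: float(v.mean()))


def _impute(data: LabeledMatrix, mask: np.ndarray, stat) -> LabeledMatrix:
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != data.features.shape:
        raise ValueError("mask shape must match the feature matrix")
    feats = data.features.copy()
    for label in data.class_set:
        rows = data.class_indices(label)
        for j in range(data.n_features):
            miss = rows[mask[rows, j]]
            if miss.size == 0:
                continue
            obs = feats[rows[~mask[rows, j]], j]
            if obs.size == 0:
                raise ValueError(
                    f"cannot impute: class {label!r}, feature "
                    f"{data.feature_names[j]!r} has no observed values"
                )
            feats[miss, j] = stat(obs)
    return LabeledMatrix(
        features=feats,
        labels=data.labels,
        class_set=data.class_set,
        feature_names=data.feature_names,
    )


@dataclass(frozen=True)
class ScalingParams:
    minima: np.ndarray
    maxima: np.ndarray

    @property
    def spans(self) -> np.ndarray:
        return self.maxima - self.minima


def minmax_scale(data: LabeledMatrix) -> tuple[LabeledMatrix, ScalingParams]:
    """Map each feature to [0, 1] by its min/max; constant features map to 0.

    Requires complete (imputed) data.  Returns the parameters needed to
    apply the identical transform to held-out rows.
    """
    if np.isnan(data.features).any():
        raise ValueError("impute missing values before scaling")
    mins = data.features.min(axis=0)
    maxs = data.features.max(axis=0)
    params = ScalingParams(minima=mins, maxima=maxs)
    scaled, _ = apply_scaling(params, data.features)
    return (
        LabeledMatrix(
            features=scaled,
            labels=data.labels,
            class_set=data.class_set,
            feature_names=data.feature_names,
        ),
        params,
    )


def apply_scaling(params: ScalingParams, features: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Apply stored min/max scaling; out-of-range values are clipped into
    [0, 1] and flagged in the returned boolean mask."""
    X = np.atleast_2d(np.asarray(features, dtype=float))
    span = params.spans.copy()
    constant = span == 0
    span[constant] = 1.0
    scaled = (X - params.minima) / span
    scaled[:, constant] = 0.0
    clipped = (scaled < 0.0) | (scaled > 1.0)
    return np.clip(scaled, 0.0, 1.0), clipped


def inverse_scaling(params: ScalingParams, scaled: np.ndarray) -> np.ndarray:
    """Undo ``apply_scaling`` for in-range values (constant features
    recover their single value)."""
    X = np.atleast_2d(np.asarray(scaled, dtype=float))
    return params.minima + X * params.spans


def write_clean_csv(path: str | Path, data: LabeledMatrix, label_column: str = "label") -> None:
    df = pd.DataFrame(data.features, columns=data.feature_names)
    df[label_column] = data.labels
    df.to_csv(path, index=False)
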