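"""End-to-end two-phase run: ABCFS feature selection, then SVM + k-fold CV.

``run_pipeline`` wires the stages together: load (or simulate) the data,
impute and optionally scale it, run greedy forward selection with the ABC
clustering scorer, cross-validate the linear SVM on the selected columns,
and write the artifacts — selection trace, metric report, a log of every
seed and parameter, and a MANIFEST recording which artifacts are complete.
All randomness is derived from the single ``seed`` field, and artifacts
contain no timestamps, so identical configs produce byte-identical output.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import data_io
from .abc_core import AbcConfig
from .classification import SvmConfig
from .data import LabeledMatrix
from .evaluation import cross_validate
from .feature_selection import abcfs_select, derive_seed
from .synthetic_data import SynthSpec, generate

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    pass


@dataclass(frozen=True)
class RunConfig:
    """Full configuration of one pipeline run; JSON round-trippable."""

    # data source: either an input file or a synthetic spec
    input: str | None = None
    schema: str | None = None
    label_column: str = "label"
    missing_marker: str = "?"
    synth: dict | None = None
    impute: str = "mode"          # mode | mean | none
    scale: bool = False
    # colony
    colony_size: int = 20
    max_cycles: int = 300
    limit: int = 200
    # selection
    max_features: int | None = None
    runs: int = 100
    min_improvement: float = 0.0
    train_fraction: float = 0.75
    fixed_split: bool = False
    # cross-validation / SVM
    folds: int = 10
    stratify: bool = True
    positive_class: str | None = None
    kkt_tolerance: float = 1.0e-3
    max_iterations: int = 15000
    cache_limit: int = 5000
    cost_C: float = 1.0
    # global
    seed: int = 0

    def to_dict(self) -> dict:
        # canonical JSON form (tuples become lists) so round-trips compare equal
        return json.loads(json.dumps(dataclasses.asdict(self)))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def abc_config(self) -> AbcConfig:
        return AbcConfig(
            colony_size=self.colony_size,
            max_cycles=self.max_cycles,
            limit=self.limit,
            seed=self.seed,
        )

    def svm_config(self) -> SvmConfig:
        return SvmConfig(
            kkt_tolerance=self.kkt_tolerance,
            max_iterations=self.max_iterations,
            cache_limit=self.cache_limit,
            cost_C=self.cost_C,
        )


def _json_dump(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def load_input(config: RunConfig) -> tuple[LabeledMatrix, np.ndarray]:
    """Read or simulate the dataset named by the config (pre-imputation)."""
    if config.input is not None:
        path = Path(config.input)
        if not path.exists():
            raise PipelineError(f"input file not found: {path}")
        if config.schema:
            schema = data_io.load_schema(config.schema)
            return data_io.read_table(path, schema, config.missing_marker)
        return data_io.read_csv_simple(
            path, config.label_column, config.missing_marker
        )
    if config.synth is not None:
        data, _, mask = generate(SynthSpec.from_dict(config.synth))
        return data, mask
    raise PipelineError("config must provide either `input` or `synth`")


def prepare(config: RunConfig) -> LabeledMatrix:
    """Load, impute, and optionally scale the dataset."""
    data, mask = load_input(config)
    if mask.any():
        if config.impute == "mode":
            data = data_io.impute_mode_per_class(data, mask)
        elif config.impute == "mean":
            data = data_io.impute_mean_per_class(data, mask)
        elif config.impute != "none":
            raise PipelineError(f"unknown impute policy {config.impute!r}")
        else:
            raise PipelineError(
                "data contains missing values but imputation is disabled"
            )
    if config.scale:
        data, _ = data_io.minmax_scale(data)
    return data


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Execute both phases and write artifacts into ``outdir``.

    Returns the MANIFEST dict.  On failure, partial artifacts stay on disk
    with the MANIFEST marking the run incomplete, and the error is raised.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "complete": False,
        "stage": "start",
        "artifacts": {},
        "error": None,
    }

    def checkpoint(stage: str) -> None:
        manifest["stage"] = stage
        _json_dump(outdir / "MANIFEST.json", manifest)

    log_lines = [
        "abcfs pipeline run",
        "config:",
        json.dumps(config.to_dict(), indent=2, sort_keys=True),
    ]
    try:
        _json_dump(outdir / "config.json", config.to_dict())
        manifest["artifacts"]["config"] = "config.json"
        checkpoint("load")

        data = prepare(config)
        log_lines.append(
            f"data: {data.n_samples} samples x {data.n_features} features, "
            f"classes {[str(c) for c in data.class_set]} "
            f"{list(data.class_counts().values())}"
        )
        checkpoint("select")

        selection = abcfs_select(
            data,
            max_features=config.max_features,
            runs=config.runs,
            abc_config=config.abc_config(),
            min_improvement=config.min_improvement,
            train_fraction=config.train_fraction,
            fixed_split=config.fixed_split,
        )
        _json_dump(outdir / "selection_trace.json", selection.to_dict())
        manifest["artifacts"]["selection_trace"] = "selection_trace.json"
        names = [data.feature_names[j] for j in selection.selected_features]
        log_lines.append(f"selection seed: {config.seed}")
        log_lines.append(
            f"selected features (selection order): "
            f"{selection.selected_features} {names}"
        )
        log_lines.append(f"stop reason: {selection.stop_reason}")
        for s in selection.trace.steps:
            log_lines.append(
                f"  step {len(s.subset_before) + 1}: chose {s.chosen_feature} "
                f"mean={s.mean_score:.4f} std={s.score_std:.4f}"
            )
        checkpoint("cross_validate")

        cv_seed = derive_seed(config.seed, 997)
        report = cross_validate(
            data,
            selection.selected_features,
            k=config.folds,
            svm_config=config.svm_config(),
            seed=cv_seed,
            positive_class=config.positive_class,
            stratify=config.stratify,
        )
        payload = report.to_dict()
        payload["selected_features"] = selection.selected_features
        payload["selected_feature_names"] = names
        _json_dump(outdir / "report.json", payload)
        manifest["artifacts"]["report"] = "report.json"
        log_lines.append(f"cv seed: {cv_seed} folds: {config.folds}")
        mean = report.mean
        log_lines.append(
            "cv mean-of-folds: "
            + " ".join(
                f"{name}={getattr(mean, name):.4f}"
                if getattr(mean, name) is not None
                else f"{name}=undefined"
                for name in ("accuracy", "sensitivity", "specificity", "ppv", "npv")
            )
        )
        manifest["complete"] = True
        checkpoint("done")
        return manifest
    except Exception as exc:
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        checkpoint(manifest["stage"])
        raise
    finally:
        (outdir / "run_log.txt").write_text("\n".join(log_lines) + "\n")
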