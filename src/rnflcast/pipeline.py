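"""End-to-end orchestration: simulate → preprocess → split → triplets →
train → predict → evaluate → report, driven by one structured config.

Every stage writes its artifacts into a run directory so the final report
can be regenerated from the stored manifests alone, and every random draw
traces to a named seed in the config. Re-running with the same config
reproduces the report (exactly for LR/GBR/carry-forward; to floating
tolerance for the CNN).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import io as rcio
from .evaluation import render_figures, stratified_report
from .models import RNFLForecastModel, RNFLForecastResults, triplets_to_arrays
from .profiles import preprocess_cohort
from .synthetic import CohortConfig, generate_cohort
from .triplets import (
    GAP_WINDOW_DAYS,
    build_test_triplets,
    build_training_triplets,
    make_split,
    triplets_to_frame,
)

logger = logging.getLogger(__name__)


@dataclass
class ModelSpec:
    method: str
    target_mode: str = "vector768"
    hyperparams: dict = field(default_factory=dict)
    seed: int = 0


@dataclass
class RunConfig:
    """Full pipeline configuration; nested blocks mirror the stage inputs."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    gap_window_days: tuple[int, int] = GAP_WINDOW_DAYS
    train_fraction: float = 0.8
    split_seed: int = 0
    test_scan_seed: int = 0
    models: dict[str, ModelSpec] = field(
        default_factory=lambda: {
            "carry_forward": ModelSpec(method="carry_forward"),
            "lr": ModelSpec(method="lr"),
        }
    )
    n_boot: int = 200
    n_perm: int = 2000
    eval_seed: int = 0
    with_comparisons: bool = True
    figures: bool = True

    def validate(self) -> None:
        self.cohort.validate()
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be strictly between 0 and 1")
        modes = {m.target_mode for m in self.models.values()}
        if len(modes) > 1:
            raise ValueError("all models in one run must share a target_mode")
        for name, m in self.models.items():
            if m.method not in ("lr", "svr", "gbr", "cnn", "carry_forward"):
                raise ValueError(f"model {name!r}: unknown method {m.method!r}")

    @property
    def target_mode(self) -> str:
        return next(iter(self.models.values())).target_mode

    def to_dict(self) -> dict:
        d = asdict(self)
        d["gap_window_days"] = list(self.gap_window_days)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "cohort" in d:
            d["cohort"] = CohortConfig.from_dict(d["cohort"])
        if "gap_window_days" in d:
            d["gap_window_days"] = tuple(d["gap_window_days"])
        if "models" in d:
            d["models"] = {k: ModelSpec(**v) if isinstance(v, dict) else v for k, v in d["models"].items()}
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: RunConfig, outdir: str | Path) -> Path:
    """Execute the full pipeline into ``outdir`` and return it.

    Stage failures abort with the stage name; artifacts written by earlier
    stages are left in place.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    from . import __version__

    config.to_yaml(outdir / "config.yaml")
    (outdir / "provenance.json").write_text(json.dumps({
        "package_version": __version__,
        "seeds": {
            "cohort": config.cohort.seed,
            "split": config.split_seed,
            "test_scan": config.test_scan_seed,
            "eval": config.eval_seed,
            "models": {k: m.seed for k, m in config.models.items()},
        },
    }, indent=2))

    def stage(name, fn):
        logger.info("stage %s ...", name)
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise StageError(name, exc) from exc

    cohort, truth = stage("simulate", lambda: generate_cohort(config.cohort))
    stage("simulate.write", lambda: (
        rcio.write_cohort_csv(cohort, outdir / "profiles.csv", outdir / "metadata.csv"),
        truth.write_csv(outdir / "ground_truth.csv"),
    ))
    pre = stage("preprocess", lambda: preprocess_cohort(cohort))
    split = stage("split", lambda: make_split(pre, config.train_fraction, config.split_seed))
    stage("split.write", lambda: split.to_frame().to_csv(outdir / "split.csv", index=False))
    train = stage("triplets.train", lambda: build_training_triplets(
        split.select(pre, "train_val"), config.gap_window_days))
    test = stage("triplets.test", lambda: build_test_triplets(
        split.select(pre, "test"), config.test_scan_seed, config.gap_window_days))
    stage("triplets.write", lambda: (
        triplets_to_frame(train, "train_val").to_csv(outdir / "triplets_train.csv", index=False),
        triplets_to_frame(test, "test").to_csv(outdir / "triplets_test.csv", index=False),
    ))

    results: dict[str, RNFLForecastResults] = {}
    predictions: dict[str, np.ndarray] = {}
    target_mode = config.target_mode
    _, _, y = triplets_to_arrays(test, target_mode)
    for name, spec in config.models.items():
        def train_one(name=name, spec=spec):
            model = RNFLForecastModel(
                [] if spec.method == "carry_forward" else train,
                method=spec.method,
                target_mode=spec.target_mode,
                hyperparams=spec.hyperparams,
            )
            res = model.fit(seed=spec.seed)
            res.save(outdir / "models" / name)
            return res
        results[name] = stage(f"train.{name}", train_one)
        predictions[name] = stage(f"predict.{name}", lambda name=name: results[name].predict_triplets(test))
        stage(f"predict.{name}.write", lambda name=name: _write_predictions(
            outdir / f"predictions_{name}.csv", test, predictions[name], target_mode))

    report = stage("evaluate", lambda: stratified_report(
        predictions, y, test, pre, target_mode=target_mode,
        n_boot=config.n_boot, n_perm=config.n_perm, seed=config.eval_seed,
        with_comparisons=config.with_comparisons,
    ))
    stage("report.write", lambda: (
        report.to_json(outdir / "report.json"),
        report.write_csv(outdir / "report_cells.csv", outdir / "report_comparisons.csv"),
    ))
    if config.figures:
        stage("figures", lambda: render_figures(
            predictions, y, test, pre, outdir / "figures", target_mode=target_mode))
    logger.info("run complete: %s", outdir)
    return outdir


def _write_predictions(path: Path, test, pred: np.ndarray, target_mode: str) -> None:
    import pandas as pd

    cols = [f"y{i}" for i in range(768)] if target_mode == "vector768" else \
        ["g", "t", "ts", "ti", "n", "ns", "ni"]
    meta = pd.DataFrame({
        "eye_id": [t.eye_id for t in test],
        "target_visit_time_days": [t.target.visit_time for t in test],
        "target_scan_index": [t.target.scan_index_within_visit for t in test],
    })
    frame = pd.concat([meta, pd.DataFrame(np.asarray(pred), columns=cols)], axis=1)
    frame.to_csv(path, index=False)
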