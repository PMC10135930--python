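"""End-to-end experiment orchestration.

``run_experiment`` chains simulate -> preprocess -> extract -> tune ->
evaluate for a list of classifiers, writes every artifact (feature
matrix, tuned-model bundles, metric reports, convergence traces,
improvement table) under an output directory, and records a manifest
with every derived seed so any stage can be rerun in isolation.

Seed discipline: the single experiment seed feeds a
``numpy.random.SeedSequence``; its first four children provide the
simulation, split, optimizer and model seeds (in that order).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluation, features, io, mpa, tuning
from .synthetic import AnnotatedRecord, SimConfig, generate_record

logger = logging.getLogger("ecgmpa")

STAGE_SEEDS = ("simulation", "split", "mpa", "model")


def derive_seeds(experiment_seed: int) -> dict[str, int]:
    """Stage seeds derived deterministically from one experiment seed."""
    children = np.random.SeedSequence(experiment_seed).spawn(len(STAGE_SEEDS))
    return {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(STAGE_SEEDS, children)
    }


@dataclass
class ExperimentConfig:
    """Everything one experiment needs.

    Exactly one of ``sim_config`` or ``record_path`` supplies the input
    record; ``record_format`` is ``"csv"`` or ``"wfdb"``.
    """

    seed: int = 0
    classifiers: tuple[str, ...] = ("svm", "gbdt", "rf", "knn")
    sim_config: SimConfig | None = None
    record_path: str | None = None
    record_format: str = "csv"
    mpa_params: mpa.MPAParams | None = None
    output_dir: str = "ecgmpa-output"

    def __post_init__(self) -> None:
        for name in self.classifiers:
            tuning.spec_for(name)  # raises on unknown names
        if self.record_path is not None and not Path(
            self.record_path
        ).with_suffix(".csv" if self.record_format == "csv" else ".hea").exists():
            raise FileNotFoundError(f"record not found: {self.record_path}")


def load_record(config: ExperimentConfig, seeds: dict[str, int]) -> AnnotatedRecord:
    if config.record_path is not None:
        if config.record_format == "wfdb":
            return io.read_wfdb_record(config.record_path)
        return io.read_csv_record(config.record_path)
    sim = config.sim_config or SimConfig()
    sim = SimConfig(**{**sim.__dict__, "seed": seeds["simulation"]})
    return generate_record(sim)


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    seeds: dict[str, int]
    feature_matrix: pd.DataFrame
    tuned: dict[str, tuning.TunedModel]
    reports: dict[str, pd.DataFrame]
    default_reports: dict[str, pd.DataFrame]
    improvement: pd.DataFrame
    output_dir: Path


def _evaluate_model(model, X_val, y_val) -> pd.DataFrame:
    pred = model.predict(X_val)
    return evaluation.evaluate(y_val, pred, classes=sorted(set(y_val)))


def compare_default_vs_tuned(
    tuned: tuning.TunedModel,
    classifier: str,
    X: np.ndarray,
    y: np.ndarray,
    split_seed: int,
    model_seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Default and tuned metric reports on the identical split, plus the
    improvement rows (optimized - default, percentage points)."""
    split = tuning.split_holdout(X, y, seed=split_seed)
    scaler = tuned.scaler
    X_train = scaler.transform(split.X_train) if scaler is not None else split.X_train
    X_val = scaler.transform(split.X_val) if scaler is not None else split.X_val

    from sklearn.preprocessing import LabelEncoder

    enc = LabelEncoder().fit(y)
    default_model = tuning.build_classifier(classifier, None, model_seed=model_seed)
    default_model.fit(X_train, enc.transform(split.y_train))
    default_pred = enc.inverse_transform(default_model.predict(X_val))
    default_report = evaluation.evaluate(split.y_val, default_pred)
    tuned_pred = tuned.predict(split.X_val)
    tuned_report = evaluation.evaluate(split.y_val, tuned_pred)

    rows = []
    for metric in evaluation.METRICS:
        d = default_report.loc["Average", metric] * 100
        o = tuned_report.loc["Average", metric] * 100
        rows.append(
            {
                "classifier": classifier,
                "metric": metric,
                "default": d,
                "optimized": o,
                "improvement": o - d,
            }
        )
    return default_report, tuned_report, pd.DataFrame(rows)


def run_experiment(config: ExperimentConfig) -> ExperimentResult:
    """Run the full pipeline and write all artifacts to ``output_dir``."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = derive_seeds(config.seed)
    logger.info("stage=seeds event=derived values=%s", seeds)

    record = load_record(config, seeds)
    logger.info(
        "stage=input event=loaded record=%s beats=%d fs=%g",
        record.record_id,
        record.n_beats,
        record.fs,
    )
    matrix = features.extract_all(record)
    features.write_features(matrix, out / "features.csv")
    logger.info("stage=features event=extracted shape=%s", matrix.shape)

    X = matrix.drop(columns="label").to_numpy()
    y = matrix["label"].to_numpy()
    mpa_params = config.mpa_params or mpa.MPAParams(n=10, tmax=15)
    mpa_params = mpa.MPAParams(**{**mpa_params.__dict__, "seed": seeds["mpa"]})

    tuned: dict[str, tuning.TunedModel] = {}
    reports: dict[str, pd.DataFrame] = {}
    default_reports: dict[str, pd.DataFrame] = {}
    improvement_rows = []
    for name in config.classifiers:
        try:
            model = tuning.tune(
                name,
                X,
                y,
                mpa_params=mpa_params,
                split_seed=seeds["split"],
                model_seed=seeds["model"],
            )
        except Exception:
            logger.exception("stage=tune classifier=%s event=failed", name)
            raise
        tuned[name] = model
        default_rep, tuned_rep, improv = compare_default_vs_tuned(
            model, name, X, y, seeds["split"], seeds["model"]
        )
        reports[name] = tuned_rep
        default_reports[name] = default_rep
        improvement_rows.append(improv)
        evaluation.write_report(tuned_rep, out / f"report_{name}.csv")
        evaluation.write_report(default_rep, out / f"report_{name}_default.csv")
        pd.DataFrame(
            {"iteration": np.arange(len(model.result.trace)), "best_fitness": model.result.trace}
        ).to_csv(out / f"trace_{name}.csv", index=False)
        bundle = {
            "classifier": name,
            "best_params": model.params,
            "holdout_accuracy": model.holdout_accuracy,
            "evaluations": model.result.evaluations,
            "distinct_configurations": len(model.evaluation_log),
            "split_seed": model.split_seed,
        }
        (out / f"tuned_{name}.json").write_text(json.dumps(bundle, indent=2, default=float))
        logger.info(
            "stage=tune classifier=%s event=done accuracy=%.4f params=%s",
            name,
            model.holdout_accuracy,
            model.params,
        )

    improvement = pd.concat(improvement_rows, ignore_index=True)
    improvement.to_csv(out / "improvement.csv", index=False, float_format="%.4f")

    manifest = {
        "experiment_seed": config.seed,
        "stage_seeds": seeds,
        "classifiers": list(config.classifiers),
        "mpa": {k: v for k, v in mpa_params.__dict__.items()},
        "n_beats": record.n_beats,
        "fs": record.fs,
        "record_id": record.record_id,
        "n_features": int(matrix.shape[1] - 1),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=float))
    return ExperimentResult(
        config=config,
        seeds=seeds,
        feature_matrix=matrix,
        tuned=tuned,
        reports=reports,
        default_reports=default_reports,
        improvement=improvement,
        output_dir=out,
    )
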