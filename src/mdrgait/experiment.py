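"""End-to-end experiment runner: simulate -> features -> SVM -> report.

Mirrors the study protocol: a large simulated cohort provides the 70/30
train/validation pool for hyperparameter selection, and an independent
(simulated) cohort of 14 fallers / 19 non-fallers plays the role of the
test set.  Everything is reproducible from (config, master seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .classify import (
    DEFAULT_C_GRID,
    DEFAULT_GAMMA_GRID,
    ConfusionMatrix,
    SVMModelSpec,
    confusion_and_metrics,
    predict,
    split_train_validation,
    train_svm,
)
from .config import REFERENCE_GROUP_STATS, RadarConfig
from .envelopes import extract_envelopes
from .features import compute_parameters, steady_state_window
from .io import write_feature_table
from .iq import IQSignal
from .processing import highpass_filter, stft_spectrogram
from .simulate import _child_seed, generate_cohort

__all__ = [
    "ExperimentConfig",
    "process_signal",
    "extract_feature_table",
    "run_experiment",
    "verify_printed_tables",
    "REFERENCE_CONFUSION_TABLES",
]

logger = logging.getLogger("mdrgait")

#: Published test confusion matrices (fallers positive) and the metric values
#: printed alongside them, used by :func:`verify_printed_tables`.
REFERENCE_CONFUSION_TABLES = {
    "accuracy_tuned": {
        "counts": {"tp": 9, "fn": 5, "fp": 2, "tn": 17},
        "printed": {"accuracy_pct": 78.8, "sensitivity_pct": 64.3},
    },
    "sensitivity_tuned": {
        "counts": {"tp": 10, "fn": 4, "fp": 5, "tn": 14},
        "printed": {"accuracy_pct": 72.7, "sensitivity_pct": 71.4},
    },
}


@dataclass
class ExperimentConfig:
    """All knobs of one experiment, serializable to a single YAML file."""

    radar: RadarConfig = field(default_factory=RadarConfig)
    calibration: dict = field(
        default_factory=lambda: {
            g: dict(v) for g, v in REFERENCE_GROUP_STATS.items()
        }
    )
    n_train_fallers: int = 240
    n_train_nonfallers: int = 240
    n_test_fallers: int = 14
    n_test_nonfallers: int = 19
    cutoff_hz: float = 20.0
    filter_order: int = 4
    window_length: int = 128
    overlap: int = 127
    threshold_db: float = -20.0
    min_velocity: float = 0.125
    trim_seconds: float = 1.0
    c_grid: tuple = DEFAULT_C_GRID
    gamma_grid: tuple = DEFAULT_GAMMA_GRID
    objective: str = "accuracy"
    train_fraction: float = 0.7
    seed: int = 0
    out_dir: str | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["radar"] = dataclasses.asdict(self.radar)
        d["c_grid"] = list(self.c_grid)
        d["gamma_grid"] = list(self.gamma_grid)
        d["calibration"] = {
            g: {k: list(v) for k, v in stats.items()}
            for g, stats in self.calibration.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "radar" in d:
            d["radar"] = RadarConfig(**d["radar"])
        if "c_grid" in d:
            d["c_grid"] = tuple(d["c_grid"])
        if "gamma_grid" in d:
            d["gamma_grid"] = tuple(d["gamma_grid"])
        if "calibration" in d:
            d["calibration"] = {
                g: {k: tuple(v) for k, v in stats.items()}
                for g, stats in d["calibration"].items()
            }
        return cls(**d)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def process_signal(
    signal: IQSignal,
    carrier_frequency: float = 24e9,
    cutoff_hz: float = 20.0,
    filter_order: int = 4,
    window_length: int = 128,
    overlap: int = 127,
    threshold_db: float = -20.0,
    min_velocity: float = 0.125,
    trim_seconds: float = 1.0,
):
    """Run one record through filter -> spectrogram -> envelopes -> features."""
    sid = signal.subject_id
    stage = "highpass_filter"
    try:
        filtered = highpass_filter(signal, cutoff=cutoff_hz, order=filter_order)
        stage = "stft_spectrogram"
        spec = stft_spectrogram(
            filtered,
            window_length=window_length,
            overlap=overlap,
            carrier_frequency=carrier_frequency,
        )
        stage = "extract_envelopes"
        env = extract_envelopes(
            spec, threshold_db=threshold_db, min_velocity=min_velocity
        )
        stage = "steady_state_window"
        env = steady_state_window(env, trim_seconds=trim_seconds)
        stage = "compute_parameters"
        return compute_parameters(env, subject_id=sid, label=signal.label)
    except Exception as exc:
        raise RuntimeError(
            f"stage '{stage}' failed for subject {sid or '<unnamed>'}: {exc}"
        ) from exc


def extract_feature_table(signals: list[IQSignal], config: ExperimentConfig) -> pd.DataFrame:
    """Feature table (subject_id, label, four parameters) for a cohort."""
    rows = [
        process_signal(
            s,
            carrier_frequency=config.radar.carrier_frequency,
            cutoff_hz=config.cutoff_hz,
            filter_order=config.filter_order,
            window_length=config.window_length,
            overlap=config.overlap,
            threshold_db=config.threshold_db,
            min_velocity=config.min_velocity,
            trim_seconds=config.trim_seconds,
        ).as_dict()
        for s in signals
    ]
    return pd.DataFrame(
        rows, columns=["subject_id", "label", "v_m_mean", "v_u_mean", "v_u_std", "v_l_std"]
    )


def run_experiment(config: ExperimentConfig) -> dict:
    """Execute the full pipeline and return (and optionally write) a report."""
    train_seed = _child_seed(config.seed, 0)
    test_seed = _child_seed(config.seed, 1)
    split_seed = _child_seed(config.seed, 2)

    logger.info(
        "simulating cohorts: train %d/%d, test %d/%d (seed %d)",
        config.n_train_fallers, config.n_train_nonfallers,
        config.n_test_fallers, config.n_test_nonfallers, config.seed,
    )
    train_signals = generate_cohort(
        config.n_train_fallers, config.n_train_nonfallers, config.radar,
        train_seed, calibration=config.calibration, id_prefix="train",
    )
    test_signals = generate_cohort(
        config.n_test_fallers, config.n_test_nonfallers, config.radar,
        test_seed, calibration=config.calibration, id_prefix="test",
    )

    logger.info("extracting gait features (%d + %d records)",
                len(train_signals), len(test_signals))
    features_pool = extract_feature_table(train_signals, config)
    features_test = extract_feature_table(test_signals, config)

    train_df, val_df = split_train_validation(
        features_pool, train_fraction=config.train_fraction, rng_seed=split_seed
    )
    logger.info("training SVM (objective=%s, grid %dx%d)",
                config.objective, len(config.c_grid), len(config.gamma_grid))
    model = train_svm(
        train_df, val_df,
        objective=config.objective,
        c_grid=config.c_grid,
        gamma_grid=config.gamma_grid,
    )

    y_pred = predict(model, features_test)
    cm, metrics = confusion_and_metrics(features_test["label"], y_pred)
    report = {
        "seed": config.seed,
        "objective": config.objective,
        "model": {"C": model.C, "gamma": model.gamma},
        "n_train": len(train_df),
        "n_validation": len(val_df),
        "n_test": len(features_test),
        "validation_metrics": model.validation_metrics,
        "confusion": cm.as_dict(),
        "metrics": metrics.as_dict(),
        "metrics_pct": metrics.as_percent_dict(),
    }

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_feature_table(features_pool, out / "features_train_pool.csv")
        write_feature_table(features_test, out / "features_test.csv")
        model.to_json(out / "model.json")
        (out / "report.json").write_text(json.dumps(report, sort_keys=True, indent=2))
        config.to_yaml(out / "config.yaml")
    return report


def verify_printed_tables(tables: dict | None = None) -> dict:
    """Recompute metrics from the embedded confusion-matrix fixtures.

    For each fixture, reconstructs the 2x2 matrix through
    :func:`confusion_and_metrics` and compares accuracy and sensitivity (in
    percent, one decimal) against the printed values.  Returns a report with
    per-table pass/fail flags and an overall ``ok``.
    """
    from .config import FALLER, NON_FALLER

    tables = tables if tables is not None else REFERENCE_CONFUSION_TABLES
    report: dict = {"tables": {}, "ok": True}
    for name, fixture in tables.items():
        c = fixture["counts"]
        y_true = [FALLER] * (c["tp"] + c["fn"]) + [NON_FALLER] * (c["fp"] + c["tn"])
        y_pred = (
            [FALLER] * c["tp"] + [NON_FALLER] * c["fn"]
            + [FALLER] * c["fp"] + [NON_FALLER] * c["tn"]
        )
        cm, metrics = confusion_and_metrics(y_true, y_pred)
        pct = metrics.as_percent_dict()
        checks = {
            "accuracy": pct["accuracy"] == fixture["printed"]["accuracy_pct"],
            "sensitivity": pct["sensitivity"] == fixture["printed"]["sensitivity_pct"],
        }
        report["tables"][name] = {
            "counts": cm.as_dict(),
            "computed_pct": pct,
            "printed_pct": dict(fixture["printed"]),
            "checks": checks,
        }
        report["ok"] = report["ok"] and all(checks.values())
    return report
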