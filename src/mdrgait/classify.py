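"""Gaussian-kernel soft-margin SVM for faller/non-faller gait features.

Hyperparameters (penalty C, kernel width gamma) are chosen by grid search
on a held-out validation split, maximizing either validation accuracy or
validation sensitivity.  Fallers form the positive class throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .config import FALLER, GROUPS, NON_FALLER
from .features import FEATURE_COLUMNS

__all__ = [
    "ConfusionMatrix",
    "Metrics",
    "SVMModelSpec",
    "DEFAULT_C_GRID",
    "DEFAULT_GAMMA_GRID",
    "split_train_validation",
    "train_svm",
    "predict",
    "confusion_and_metrics",
]

#: Logarithmic default grids, one point per decade.
DEFAULT_C_GRID = tuple(10.0 ** k for k in range(-2, 4))
DEFAULT_GAMMA_GRID = tuple(10.0 ** k for k in range(-3, 3))


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 counts with fallers as the positive class."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "fp", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    def as_dict(self) -> dict:
        return {"tp": self.tp, "fn": self.fn, "fp": self.fp, "tn": self.tn}


@dataclass(frozen=True)
class Metrics:
    """Proportion-valued summary statistics of a confusion matrix."""

    accuracy: float
    sensitivity: float
    specificity: float
    precision: float

    def __post_init__(self) -> None:
        for name in ("accuracy", "sensitivity", "specificity", "precision"):
            v = getattr(self, name)
            if not (np.isnan(v) or 0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
        }

    def as_percent_dict(self, decimals: int = 1) -> dict:
        return {k: round(100.0 * v, decimals) for k, v in self.as_dict().items()}


def confusion_and_metrics(y_true, y_pred) -> tuple[ConfusionMatrix, Metrics]:
    """Count the 2x2 confusion matrix and derive the four metrics."""
    y_true = list(y_true)
    y_pred = list(y_pred)
    if len(y_true) == 0:
        raise ValueError("empty input")
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must have equal length")
    for lab in (*y_true, *y_pred):
        if lab not in GROUPS:
            raise ValueError(f"unknown label {lab!r}; expected one of {GROUPS}")
    tp = sum(1 for t, p in zip(y_true, y_pred) if t == FALLER and p == FALLER)
    fn = sum(1 for t, p in zip(y_true, y_pred) if t == FALLER and p == NON_FALLER)
    fp = sum(1 for t, p in zip(y_true, y_pred) if t == NON_FALLER and p == FALLER)
    tn = sum(1 for t, p in zip(y_true, y_pred) if t == NON_FALLER and p == NON_FALLER)
    cm = ConfusionMatrix(tp=tp, fn=fn, fp=fp, tn=tn)

    def _ratio(num: int, den: int) -> float:
        return num / den if den > 0 else float("nan")

    metrics = Metrics(
        accuracy=_ratio(tp + tn, cm.total),
        sensitivity=_ratio(tp, tp + fn),
        specificity=_ratio(tn, tn + fp),
        precision=_ratio(tp, tp + fp),
    )
    return cm, metrics


def split_train_validation(
    features: pd.DataFrame, train_fraction: float = 0.7, rng_seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Deterministic stratified split of a labeled feature table."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    if "label" not in features.columns:
        raise KeyError("feature table must have a 'label' column")
    rng = np.random.default_rng(rng_seed)
    train_idx: list[int] = []
    val_idx: list[int] = []
    labels = features["label"].to_numpy()
    for group in GROUPS:
        idx = np.flatnonzero(labels == group)
        if len(idx) > 0 and len(idx) < 2:
            raise ValueError(f"class {group!r} has fewer than 2 samples")
        if len(idx) == 0:
            continue
        perm = rng.permutation(idx)
        n_train = int(round(train_fraction * len(idx)))
        n_train = min(max(n_train, 1), len(idx) - 1)
        train_idx.extend(perm[:n_train])
        val_idx.extend(perm[n_train:])
    train = features.iloc[sorted(train_idx)].reset_index(drop=True)
    val = features.iloc[sorted(val_idx)].reset_index(drop=True)
    return train, val


@dataclass
class SVMModelSpec:
    """A trained RBF-kernel SVM plus the training-set standardization.

    Prediction is self-contained (support vectors, dual coefficients,
    intercept), so a serialized model reproduces decisions bit-for-bit
    without refitting.
    """

    C: float
    gamma: float
    feature_names: list[str]
    scale_mean: np.ndarray
    scale_std: np.ndarray
    support_vectors: np.ndarray
    dual_coef: np.ndarray
    intercept: float
    objective: str = "accuracy"
    validation_metrics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.C <= 0 or self.gamma <= 0:
            raise ValueError("C and gamma must be positive")
        self.scale_mean = np.asarray(self.scale_mean, dtype=float)
        self.scale_std = np.asarray(self.scale_std, dtype=float)
        if np.any(self.scale_std <= 0):
            raise ValueError("standardization SDs must be positive")
        self.support_vectors = np.asarray(self.support_vectors, dtype=float)
        self.dual_coef = np.asarray(self.dual_coef, dtype=float).ravel()

    def _design_matrix(self, features: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.feature_names if c not in features.columns]
        if missing:
            raise KeyError(f"missing feature column(s): {missing}")
        X = features[self.feature_names].to_numpy(dtype=float)
        return (X - self.scale_mean) / self.scale_std

    def decision_function(self, features: pd.DataFrame) -> np.ndarray:
        Z = self._design_matrix(features)
        # RBF kernel against the stored support vectors
        sq = (
            np.sum(Z**2, axis=1)[:, None]
            + np.sum(self.support_vectors**2, axis=1)[None, :]
            - 2.0 * Z @ self.support_vectors.T
        )
        K = np.exp(-self.gamma * np.maximum(sq, 0.0))
        return K @ self.dual_coef + self.intercept

    def predict(self, features: pd.DataFrame) -> list[str]:
        d = self.decision_function(features)
        return [FALLER if v > 0 else NON_FALLER for v in d]

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "C": self.C,
            "gamma": self.gamma,
            "feature_names": self.feature_names,
            "scale_mean": self.scale_mean.tolist(),
            "scale_std": self.scale_std.tolist(),
            "support_vectors": self.support_vectors.tolist(),
            "dual_coef": self.dual_coef.tolist(),
            "intercept": self.intercept,
            "objective": self.objective,
            "validation_metrics": self.validation_metrics,
        }
        text = json.dumps(payload, sort_keys=True, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "SVMModelSpec":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        payload = json.loads(text)
        return cls(
            C=payload["C"],
            gamma=payload["gamma"],
            feature_names=payload["feature_names"],
            scale_mean=np.asarray(payload["scale_mean"]),
            scale_std=np.asarray(payload["scale_std"]),
            support_vectors=np.asarray(payload["support_vectors"]),
            dual_coef=np.asarray(payload["dual_coef"]),
            intercept=payload["intercept"],
            objective=payload.get("objective", "accuracy"),
            validation_metrics=payload.get("validation_metrics", {}),
        )


def _objective_score(metrics: Metrics, objective: str) -> float:
    if objective == "accuracy":
        return metrics.accuracy
    if objective == "sensitivity":
        return metrics.sensitivity
    raise ValueError("objective must be 'accuracy' or 'sensitivity'")


def train_svm(
    train: pd.DataFrame,
    validation: pd.DataFrame,
    objective: str = "accuracy",
    c_grid=DEFAULT_C_GRID,
    gamma_grid=DEFAULT_GAMMA_GRID,
) -> SVMModelSpec:
    """Grid-search a soft-margin RBF SVM on (train, validation) splits.

    Features are z-scored with training-set statistics only.  Ties between
    grid points are broken toward the smallest C, then the smallest gamma
    (smoother models preferred).
    """
    _objective_score(Metrics(0, 0, 0, 0), objective)  # validate objective early
    if len(train) == 0 or len(validation) == 0:
        raise ValueError("train and validation sets must be non-empty")
    if len(c_grid) == 0 or len(gamma_grid) == 0:
        raise ValueError("hyperparameter grids must be non-empty")
    y_train = train["label"].to_numpy()
    if len(set(y_train)) < 2:
        raise ValueError("training set must contain both classes")

    X_train = train[FEATURE_COLUMNS].to_numpy(dtype=float)
    mu = X_train.mean(axis=0)
    sd = X_train.std(axis=0, ddof=0)
    if np.any(sd <= 0):
        raise ValueError("a feature has zero variance on the training set")
    Z_train = (X_train - mu) / sd
    # encode faller as +1 so a positive decision value means "faller"
    y_enc = np.where(y_train == FALLER, 1, -1)
    y_val = validation["label"].to_numpy()
    Z_val = (validation[FEATURE_COLUMNS].to_numpy(dtype=float) - mu) / sd

    best: tuple[float, float, float] | None = None  # (score, C, gamma)
    best_fit = None
    best_metrics = None
    for C in sorted(c_grid):
        for gamma in sorted(gamma_grid):
            clf = SVC(C=C, gamma=gamma, kernel="rbf")
            clf.fit(Z_train, y_enc)
            pred = np.where(clf.decision_function(Z_val) > 0, FALLER, NON_FALLER)
            _, metrics = confusion_and_metrics(y_val, pred)
            score = _objective_score(metrics, objective)
            if np.isnan(score):
                score = -np.inf
            if best is None or score > best[0]:
                best = (score, C, gamma)
                best_fit = clf
                best_metrics = metrics
    assert best is not None and best_fit is not None
    _, C, gamma = best
    return SVMModelSpec(
        C=C,
        gamma=gamma,
        feature_names=list(FEATURE_COLUMNS),
        scale_mean=mu,
        scale_std=sd,
        support_vectors=best_fit.support_vectors_,
        dual_coef=best_fit.dual_coef_.ravel(),
        intercept=float(best_fit.intercept_[0]),
        objective=objective,
        validation_metrics=best_metrics.as_dict() if best_metrics else {},
    )


def predict(model: SVMModelSpec, features: pd.DataFrame) -> list[str]:
    """Predict one label per row of ``features``."""
    return model.predict(features)
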