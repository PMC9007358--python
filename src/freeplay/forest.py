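"""Random-forest activity classification with subject-aware evaluation.

A forest of 500 trees, three features sampled per split, grown to full
depth on bootstrap samples — the standard configuration for free-living
activity classification from 15 s epoch features.  Evaluation is always
subject-aware: leave-one-subject-out cross-validation on the training
cohort, and a single train-once hold-out pass for the method comparison.
One model is fitted per placement; hip and wrist data are never pooled.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .labels import ACTIVITY_CLASSES

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ForestConfig:
    n_trees: int = 500
    features_per_split: int = 3
    seed: int = 0
    labels: tuple[str, ...] = ACTIVITY_CLASSES

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if not (1 <= self.features_per_split <= 25):
            raise ValueError("features_per_split must lie in [1, 25]")


@dataclass
class ForestModel:
    """A fitted forest together with its feature schema and config."""

    estimator: RandomForestClassifier
    feature_names: tuple[str, ...]
    config: ForestConfig

    def save(self, path: str) -> None:
        joblib.dump(
            {
                "estimator": self.estimator,
                "feature_names": self.feature_names,
                "config": self.config,
            },
            path,
        )

    @classmethod
    def load(cls, path: str) -> "ForestModel":
        d = joblib.load(path)
        return cls(d["estimator"], tuple(d["feature_names"]), d["config"])


def train_forest(
    features: pd.DataFrame, labels: pd.Series | np.ndarray, cfg: ForestConfig
) -> ForestModel:
    """Fit the forest; rejects single-class or incomplete training data."""
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("training set contains a single class")
    if features.isna().any().any():
        bad = features.columns[features.isna().any()].tolist()
        raise ValueError(f"missing feature values in columns {bad}")
    est = RandomForestClassifier(
        n_estimators=cfg.n_trees,
        max_features=cfg.features_per_split,
        criterion="gini",
        bootstrap=True,
        max_depth=None,
        random_state=cfg.seed,
        n_jobs=1,
    )
    est.fit(features.to_numpy(), y)
    log.info(
        "forest trained: %d trees, %d features/split, %d rows",
        cfg.n_trees, cfg.features_per_split, len(features),
    )
    return ForestModel(est, tuple(features.columns), cfg)


def predict(model: ForestModel, features: pd.DataFrame) -> np.ndarray:
    """Majority-vote class predictions; the feature schema must match
    training (same names, same order)."""
    if tuple(features.columns) != model.feature_names:
        for got, want in zip(features.columns, model.feature_names):
            if got != want:
                raise ValueError(
                    f"feature schema mismatch: got {got!r}, expected {want!r}"
                )
        raise ValueError(
            f"feature schema mismatch: expected {len(model.feature_names)} "
            f"columns, got {len(features.columns)}"
        )
    if len(features) == 0:
        return np.array([], dtype=object)
    return model.estimator.predict(features.to_numpy())


def loso_cv(
    table: pd.DataFrame,
    feature_names: list[str],
    cfg: ForestConfig,
    label_col: str = "true_class",
    subject_col: str = "subject_id",
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Leave-one-subject-out cross-validation.

    Returns a prediction table (one row per epoch: subject, truth,
    prediction, fold) and per-fold accuracies.  Subjects with no valid
    epochs are skipped with a warning.
    """
    subjects = sorted(table[subject_col].unique())
    if len(subjects) < 2:
        raise ValueError("LOSO requires at least 2 subjects")
    rows = []
    fold_acc: dict[str, float] = {}
    for sid in subjects:
        test = table[table[subject_col] == sid]
        train = table[table[subject_col] != sid]
        if len(test) == 0:
            warnings.warn(f"subject {sid} has no valid epochs; fold skipped")
            continue
        model = train_forest(train[feature_names], train[label_col], cfg)
        pred = predict(model, test[feature_names])
        fold_acc[sid] = float((pred == test[label_col].to_numpy()).mean())
        rows.append(
            pd.DataFrame(
                {
                    subject_col: test[subject_col].to_numpy(),
                    "true_class": test[label_col].to_numpy(),
                    "predicted_class": pred,
                    "fold": sid,
                }
            )
        )
    predictions = pd.concat(rows, ignore_index=True)
    return predictions, fold_acc


def pooled_accuracy(predictions: pd.DataFrame) -> float:
    """Fraction of epochs correctly classified, pooled over folds."""
    return float(
        (predictions["true_class"] == predictions["predicted_class"]).mean()
    )
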