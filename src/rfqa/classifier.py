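"""Random-forest fold classification with confidence tiers, plus regression.

The classifier is trained on the 58-column feature scheme to predict whether
a model is in the correct fold (TM-score >= 0.5). Its score is the fraction
of trees voting "correct"; scores are banded into confidence tiers:
high (> 0.5), medium (0.3, 0.5], low (0.1, 0.3], failed (<= 0.1) —
boundaries belong to the lower tier. A regression variant predicts the
TM-score itself, with predicted TM >= 0.5 usable as a success cutoff.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.metrics import roc_auc_score

from .featurization import FEATURE_NAMES

_FORMAT_VERSION = 1


class Tier(enum.Enum):
    FAILED = "failed"
    LOW = "low"
    MEDIUM = "medium"
    HIGH = "high"

    @property
    def rank(self) -> int:
        return _TIER_RANK[self]


_TIER_RANK = {Tier.FAILED: 0, Tier.LOW: 1, Tier.MEDIUM: 2, Tier.HIGH: 3}


def tier_of(score: float) -> Tier:
    """Total, deterministic map from a score in [0, 1] to a confidence tier."""
    if score > 0.5:
        return Tier.HIGH
    if score > 0.3:
        return Tier.MEDIUM
    if score > 0.1:
        return Tier.LOW
    return Tier.FAILED


@dataclass(frozen=True)
class ForestConfig:
    n_trees: int = 500
    max_features: int = 7
    seed: int = 0
    task: str = "classify"

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if not (1 <= self.max_features <= len(FEATURE_NAMES)):
            raise ValueError("max_features out of range")
        if self.task not in ("classify", "regress"):
            raise ValueError("task must be 'classify' or 'regress'")


@dataclass
class TrainedForest:
    """Fitted forest plus the frozen feature manifest and training medians."""

    forest: object
    config: ForestConfig
    manifest: tuple = FEATURE_NAMES
    train_medians: dict = field(default_factory=dict)


def _design_matrix(features: pd.DataFrame, manifest,
                   medians: dict | None = None) -> np.ndarray:
    missing = [c for c in manifest if c not in features.columns]
    if missing:
        raise ValueError(f"feature table lacks manifest columns: {missing}")
    X = features.loc[:, list(manifest)].to_numpy(dtype=float)
    if medians is not None:
        for c, col in enumerate(manifest):
            nan = np.isnan(X[:, c])
            if nan.any():
                X[nan, c] = medians[col]
    return X


def train(features: pd.DataFrame, labels,
          config: ForestConfig = ForestConfig()) -> TrainedForest:
    """Fit the correct/incorrect fold classifier; deterministic per seed.

    ``labels`` is boolean per row (TM >= 0.5). Requires models from at least
    two targets and both classes present. Residual NaNs (columns missing for
    an entire target) are imputed with training-set medians, which are
    persisted for prediction.
    """
    y = np.asarray(labels, dtype=bool)
    if len(y) != len(features):
        raise ValueError("labels and features lengths differ")
    if features["target_id"].nunique() < 2:
        raise ValueError("training requires models from at least 2 targets")
    if y.all() or not y.any():
        raise ValueError("training requires both classes")
    X = _design_matrix(features, FEATURE_NAMES)
    medians = {c: float(np.nanmedian(X[:, i])) for i, c in enumerate(FEATURE_NAMES)}
    for i, c in enumerate(FEATURE_NAMES):
        nan = np.isnan(X[:, i])
        if nan.any():
            X[nan, i] = medians[c]
    forest = RandomForestClassifier(
        n_estimators=config.n_trees, max_features=config.max_features,
        random_state=config.seed, n_jobs=1,
    )
    forest.fit(X, y)
    return TrainedForest(forest=forest, config=config, train_medians=medians)


def train_regression(features: pd.DataFrame, tm_labels,
                     config: ForestConfig = ForestConfig(task="regress")
                     ) -> TrainedForest:
    """Fit the TM-score regression variant of the forest."""
    if config.task != "regress":
        config = ForestConfig(config.n_trees, config.max_features,
                              config.seed, "regress")
    y = np.asarray(tm_labels, dtype=float)
    if len(y) != len(features):
        raise ValueError("labels and features lengths differ")
    if features["target_id"].nunique() < 2:
        raise ValueError("training requires models from at least 2 targets")
    X = _design_matrix(features, FEATURE_NAMES)
    medians = {c: float(np.nanmedian(X[:, i])) for i, c in enumerate(FEATURE_NAMES)}
    for i, c in enumerate(FEATURE_NAMES):
        nan = np.isnan(X[:, i])
        if nan.any():
            X[nan, i] = medians[c]
    forest = RandomForestRegressor(
        n_estimators=config.n_trees, max_features=config.max_features,
        random_state=config.seed, n_jobs=1,
    )
    forest.fit(X, y)
    return TrainedForest(forest=forest, config=config, train_medians=medians)


def predict(model: TrainedForest, features: pd.DataFrame) -> pd.DataFrame:
    """Score each model; classification scores are per-tree vote fractions.

    Returns a frame with target_id, model_id, rfqa_score, and (for the
    classifier) the confidence tier.
    """
    X = _design_matrix(features, model.manifest, model.train_medians)
    out = features.loc[:, ["target_id", "model_id"]].copy()
    if model.config.task == "classify":
        votes = np.zeros(len(X))
        classes = model.forest.classes_
        for tree in model.forest.estimators_:
            votes += classes[tree.predict(X).astype(int)] == True  # noqa: E712
        score = votes / len(model.forest.estimators_)
        out["rfqa_score"] = score
        out["tier"] = [tier_of(s).value for s in score]
    else:
        out["rfqa_score"] = model.forest.predict(X)
    return out


def assign_folds(targets, folds: int, seed: int) -> dict:
    """Deterministic per-target fold assignment (whole targets per fold)."""
    uniq = sorted(set(targets))
    if len(uniq) < folds:
        raise ValueError("fewer targets than folds")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(uniq))
    return {t: k % folds for k, t in enumerate(order)}


def cross_validate(features: pd.DataFrame, labels, folds: int = 5,
                   seed: int = 0,
                   config: ForestConfig = ForestConfig()) -> pd.DataFrame:
    """Per-target k-fold cross-validation; returns per-fold AUC.

    Splitting is per target: all models of a target land in exactly one fold,
    so no target contributes to both the train and test side of any split.
    """
    y = np.asarray(labels, dtype=bool)
    fold_of = assign_folds(features["target_id"], folds, seed)
    fold_idx = features["target_id"].map(fold_of).to_numpy()
    records = []
    for k in range(folds):
        test = fold_idx == k
        sub_cfg = ForestConfig(config.n_trees, config.max_features,
                               config.seed, config.task)
        fitted = train(features.loc[~test], y[~test], sub_cfg)
        preds = predict(fitted, features.loc[test])
        auc = float("nan")
        if 0 < y[test].sum() < test.sum():
            auc = roc_auc_score(y[test], preds["rfqa_score"])
        records.append({"fold": k, "n_test": int(test.sum()),
                        "n_targets_test": features.loc[test, "target_id"].nunique(),
                        "auc": auc})
    return pd.DataFrame(records)


def save_model(model: TrainedForest, path) -> None:
    joblib.dump({"format_version": _FORMAT_VERSION, "forest": model.forest,
                 "config": model.config, "manifest": model.manifest,
                 "train_medians": model.train_medians}, path)


def load_model(path) -> TrainedForest:
    blob = joblib.load(path)
    if blob.get("format_version") != _FORMAT_VERSION:
        raise ValueError("unsupported model file version")
    if tuple(blob["manifest"]) != FEATURE_NAMES:
        raise ValueError("model manifest does not match this feature scheme")
    return TrainedForest(forest=blob["forest"], config=blob["config"],
                         manifest=tuple(blob["manifest"]),
                         train_medians=blob["train_medians"])
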