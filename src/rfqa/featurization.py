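"""Assembly of the 58-column feature scheme: 3 target + 12 model + 43 ensemble.

The ensemble block carries, for 10 of the 12 model features, their maximum,
minimum, median, and spread (maximum minus median) across all models of the
target (40 columns), plus the per-target maxima of the map-alignment hit
length, the contact PPV, and the absolute satisfied-contact count
(3 columns). The satisfied-contact count is bookkept as an auxiliary
thirteenth quantity: only its ensemble maximum enters the feature vector.
Features are never normalised — the downstream forest does not need scaling.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TARGET_FEATURES: tuple = ("length", "beff", "n_predicted_contacts")

MODEL_FEATURES: tuple = (
    "saint2", "proq2d", "proq3d", "proqroscend", "proqrosfad",
    "pcons", "pcombc", "saint2_contact", "ppv",
    "eigen_score", "mapalign_score", "mapalign_length",
)

#: model features summarised with the full 4-stat block
ENSEMBLE_STAT_FEATURES: tuple = tuple(
    f for f in MODEL_FEATURES if f not in ("ppv", "mapalign_length")
)

ENSEMBLE_FEATURES: tuple = tuple(
    f"{f}_{s}" for f in ENSEMBLE_STAT_FEATURES
    for s in ("max", "min", "median", "spread")
) + ("mapalign_length_max", "ppv_max", "n_satisfied_max")

#: frozen 58-column manifest; order is part of the trained-model contract
FEATURE_NAMES: tuple = TARGET_FEATURES + MODEL_FEATURES + ENSEMBLE_FEATURES

ID_COLUMNS = ("target_id", "model_id")


@dataclass(frozen=True)
class TargetFeatures:
    """Sequence-level features shared by every model of a target."""

    target_id: str
    length: int
    beff: float
    n_predicted_contacts: int

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("length must be >= 1")
        if self.beff < 1:
            raise ValueError("beff must be >= 1")
        if self.n_predicted_contacts < 0:
            raise ValueError("n_predicted_contacts must be >= 0")


@dataclass
class ModelFeatures:
    """The 12 per-model features plus the auxiliary satisfied-contact count.

    External scores that were not supplied are NaN; they stay explicitly
    missing until imputation at assembly/training time.
    """

    model_id: str
    values: dict = field(default_factory=dict)
    n_satisfied: float = math.nan

    def __post_init__(self) -> None:
        unknown = set(self.values) - set(MODEL_FEATURES)
        if unknown:
            raise ValueError(f"unknown model features: {sorted(unknown)}")
        for name in MODEL_FEATURES:
            self.values.setdefault(name, math.nan)
        ppv = self.values["ppv"]
        if not math.isnan(ppv) and not (0.0 <= ppv <= 1.0):
            raise ValueError("ppv must lie in [0, 1]")
        ml = self.values["mapalign_length"]
        if not math.isnan(ml) and (ml < 0 or ml != int(ml)):
            raise ValueError("mapalign_length must be a non-negative integer")


def compute_beff(msa: list, identity_threshold: float = 0.8) -> float:
    """Effective sequence count of an alignment under identity clustering.

    Each sequence contributes 1 / (number of sequences at >= the identity
    threshold to it, itself included). Identity is the fraction of matching
    positions among columns where both sequences are ungapped.
    """
    if not msa:
        raise ValueError("empty alignment")
    L = len(msa[0])
    if any(len(s) != L for s in msa):
        raise ValueError("ragged alignment")
    arr = np.array([list(s.upper()) for s in msa])
    gap = (arr == "-") | (arr == ".")
    n = len(msa)
    beff = 0.0
    for i in range(n):
        both = ~gap[i] & ~gap
        matches = ((arr == arr[i]) & both).sum(axis=1)
        denom = both.sum(axis=1)
        ident = np.where(denom > 0, matches / np.maximum(denom, 1), 0.0)
        beff += 1.0 / max(int((ident >= identity_threshold).sum()), 1)
    return float(beff)


def ensemble_stats(values) -> tuple:
    """(max, min, median, spread) of the available (non-NaN) values."""
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise ValueError("no available values for ensemble statistics")
    mx = float(arr.max())
    med = float(np.median(arr))
    return mx, float(arr.min()), med, mx - med


def assemble_features(target: TargetFeatures,
                      models: list) -> pd.DataFrame:
    """One 58-column row per model; the ensemble block is target-wide.

    Per-model NaNs in a column are imputed with the target's ensemble median
    of that column (logged); columns with no values at all stay NaN and are
    resolved against training-set medians inside the classifier.
    """
    if not models:
        raise ValueError("at least one model is required")
    rows = {name: [m.values[name] for m in models] for name in MODEL_FEATURES}
    rows["n_satisfied"] = [m.n_satisfied for m in models]

    imputed = {}
    for name, col in rows.items():
        arr = np.asarray(col, dtype=float)
        if np.isnan(arr).any() and not np.isnan(arr).all():
            med = float(np.nanmedian(arr))
            logger.info("imputing %d missing %r values with ensemble median %.4g",
                        int(np.isnan(arr).sum()), name, med)
            arr = np.where(np.isnan(arr), med, arr)
        imputed[name] = arr

    ens: dict = {}
    for name in ENSEMBLE_STAT_FEATURES:
        arr = imputed[name]
        if np.isnan(arr).all():
            stats = (math.nan,) * 4
        else:
            stats = ensemble_stats(arr)
        for stat, val in zip(("max", "min", "median", "spread"), stats):
            ens[f"{name}_{stat}"] = val
    for name in ("mapalign_length", "ppv", "n_satisfied"):
        arr = imputed[name]
        ens[f"{name}_max"] = math.nan if np.isnan(arr).all() else float(np.nanmax(arr))

    data = {
        "target_id": [target.target_id] * len(models),
        "model_id": [m.model_id for m in models],
        "length": float(target.length),
        "beff": float(target.beff),
        "n_predicted_contacts": float(target.n_predicted_contacts),
    }
    for name in MODEL_FEATURES:
        data[name] = imputed[name]
    for name in ENSEMBLE_FEATURES:
        data[name] = ens[name]
    df = pd.DataFrame(data, columns=list(ID_COLUMNS) + list(FEATURE_NAMES))
    assert list(df.columns[2:]) == list(FEATURE_NAMES) and len(FEATURE_NAMES) == 58
    return df
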