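"""Model quality measures: TM-score, contact satisfaction, consensus, PcombC.

A model is labelled *correct* when its TM-score against the reference is at
least 0.5, the conventional same-fold threshold. TM-score here is computed
for equal-length decoys with a fixed residue correspondence, maximised over
rigid superpositions by an iterative fragment-seeded search.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._kernels import tm_kernel
from .structure_io import ContactMap, PredictedContactMap, StructureModel

CORRECT_TM = 0.5
#: Smallest d0 used; the unfloored formula goes non-positive for short chains.
D0_FLOOR = 0.5


@dataclass(frozen=True)
class QualityLabel:
    tm_score: float
    correct: bool

    def __post_init__(self) -> None:
        if not (0.0 < self.tm_score <= 1.0):
            raise ValueError("tm_score must lie in (0, 1]")
        if self.correct != (self.tm_score >= CORRECT_TM):
            raise ValueError("correct flag inconsistent with tm_score")

    @classmethod
    def from_tm(cls, tm: float) -> "QualityLabel":
        return cls(tm_score=tm, correct=tm >= CORRECT_TM)


def tm_d0(length: int) -> float:
    """Length-dependent normalisation distance d0, floored at 0.5 Å."""
    return max(1.24 * (length - 15) ** (1.0 / 3.0) - 1.8, D0_FLOOR)


def tm_from_distances(distances, length: int | None = None) -> float:
    """TM-score of a fixed superposition from its per-residue deviations."""
    d = np.asarray(distances, dtype=float)
    L = len(d) if length is None else length
    d0 = tm_d0(L)
    return float(np.sum(1.0 / (1.0 + (d / d0) ** 2)) / L)


def tm_score_fixed(model: StructureModel, reference: StructureModel,
                   stride: int = 4, max_iter: int = 20) -> float:
    """TM-score between equal-length models sharing a residue correspondence.

    Superpositions are seeded from all fragments of lengths {L, L/2, L/4} at
    the given stride; each seed is refined by alternating least-squares
    superposition with reselection of residues deviating by less than d0.
    """
    if model.length != reference.length:
        raise ValueError("model and reference lengths differ")
    if not np.array_equal(model.indices, reference.indices):
        raise ValueError("model and reference residue indexing differ")
    L = model.length
    if L < 16:
        raise ValueError("TM-score requires chains of at least 16 residues")
    A = np.ascontiguousarray(model.coords, dtype=np.float64)
    B = np.ascontiguousarray(reference.coords, dtype=np.float64)
    return float(tm_kernel(A, B, tm_d0(L), stride, max_iter))


def _thresholded(predicted: PredictedContactMap, p_threshold: float) -> set:
    return predicted.pairs_above(p_threshold)


def _check_lengths(map_model: ContactMap, predicted: PredictedContactMap) -> None:
    if map_model.length != predicted.length:
        raise ValueError("contact map lengths differ")


def satisfied_count(map_model: ContactMap, predicted: PredictedContactMap,
                    p_threshold: float = 0.5) -> int:
    """Number of thresholded predicted contacts realised in the model."""
    _check_lengths(map_model, predicted)
    return len(_thresholded(predicted, p_threshold) & map_model.contacts)


def contact_ppv(map_model: ContactMap, predicted: PredictedContactMap,
                p_threshold: float = 0.5) -> float:
    """Fraction of predicted contacts (p > threshold) satisfied in the model.

    A predicted contact is satisfied when its residues' representative atoms
    are within the model map's distance cutoff. Returns 0 with a warning if
    nothing is predicted above the threshold.
    """
    _check_lengths(map_model, predicted)
    pred = _thresholded(predicted, p_threshold)
    if not pred:
        warnings.warn("no predicted contacts above threshold; PPV set to 0",
                      stacklevel=2)
        return 0.0
    return len(pred & map_model.contacts) / len(pred)


def contact_potential(map_model: ContactMap, predicted: PredictedContactMap,
                      unsatisfied_weight: float = 0.0) -> float:
    """Probability-weighted contact satisfaction potential.

    Sum of p over satisfied predicted pairs, minus ``unsatisfied_weight``
    times the probability mass of unsatisfied pairs. With the default weight
    of 0 this is monotone in the satisfied set.
    """
    _check_lengths(map_model, predicted)
    sat = 0.0
    unsat = 0.0
    for i, j, p in predicted.entries:
        if (i, j) in map_model.contacts:
            sat += p
        else:
            unsat += p
    return sat - unsatisfied_weight * unsat


def pairwise_tm_matrix(models: list[StructureModel]) -> np.ndarray:
    """Symmetric matrix of pairwise TM-scores (diagonal 1)."""
    n = len(models)
    tm = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            tm[i, j] = tm[j, i] = tm_score_fixed(models[i], models[j])
    return tm


def consensus_scores(ensemble: list[StructureModel],
                     tm: np.ndarray | None = None) -> np.ndarray:
    """Pcons-style consensus: each model's mean pairwise TM to the others.

    ``tm`` may carry a precomputed pairwise TM matrix to avoid recomputation.
    """
    n = len(ensemble)
    if n < 2:
        raise ValueError("consensus requires at least 2 models")
    if tm is None:
        tm = pairwise_tm_matrix(ensemble)
    out = (tm.sum(axis=1) - np.diag(tm)) / (n - 1)
    return out


def pcombc(proq3d: float, pcons: float, ppv: float,
           weights: tuple = (0.2, 0.5, 0.3)) -> float:
    """Weighted sum of ProQ3D, consensus, and contact PPV.

    The combination weights are not canonical; the defaults favour the
    consensus term and are fully configurable. Missing (NaN) inputs
    propagate to a NaN result.
    """
    w1, w2, w3 = weights
    return w1 * proq3d + w2 * pcons + w3 * ppv


def mean_pairwise_top10(models: list[StructureModel], scores,
                        tm: np.ndarray | None = None, k: int = 10) -> float:
    """Mean pairwise TM-score of the k models ranked highest by ``scores``.

    Ties are broken by model_id so selection is deterministic. Used by the
    convergence baseline with its 0.65 correctness cutoff.
    """
    n = len(models)
    if n < k:
        raise ValueError(f"need at least {k} models")
    scores = np.asarray(scores, dtype=float)
    order = sorted(range(n), key=lambda r: (-scores[r], models[r].model_id))
    top = order[:k]
    if tm is None:
        vals = [tm_score_fixed(models[i], models[j])
                for ii, i in enumerate(top) for j in top[ii + 1:]]
    else:
        vals = [tm[i, j] for ii, i in enumerate(top) for j in top[ii + 1:]]
    return float(np.mean(vals))
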