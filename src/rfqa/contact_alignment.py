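"""Contact-map alignment: local dynamic-programming and spectral methods.

Both aligners score the agreement between an observed (binary) contact map
and a predicted (probabilistic) contact map without requiring the two
structures to share an indexing, returning a monotone partial residue
correspondence.

The local aligner optimises a quadratic objective — the summed weight of
pairs of aligned contacts, discounted for mismatched sequence separations,
minus affine gap costs — through iterated double dynamic programming:
residue-pair seed similarities are refreshed from the current mapping and
realigned until the mapping stops changing. The spectral aligner compares
eigenvector profiles of the two maps (scaled by the square roots of the
absolute eigenvalues) with a global affine-gap alignment; its score is
invariant to the sign indeterminacy of eigenvectors by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._kernels import (gotoh_align, mapping_objective, overlap_seed,
                       refine_run, refine_seed)
from .structure_io import ContactMap, PredictedContactMap

DEFAULT_GAP_OPEN = -1.0
DEFAULT_GAP_EXTEND = -0.1
DEFAULT_SEP_TOLERANCE = 10.0


@dataclass(frozen=True)
class AlignmentResult:
    """Score and monotone partial residue correspondence of an alignment."""

    score: float
    aligned_length: int
    mapping: tuple  # of (i, a) 1-based pairs, strictly increasing in both

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError("alignment score must be non-negative")
        if self.aligned_length != len(self.mapping):
            raise ValueError("aligned_length must equal |mapping|")
        prev = (0, 0)
        for i, a in self.mapping:
            if i <= prev[0] or a <= prev[1]:
                raise ValueError("mapping must be strictly increasing in both coordinates")
            prev = (i, a)


def _as_matrix(cmap) -> np.ndarray:
    if isinstance(cmap, (ContactMap, PredictedContactMap)):
        return cmap.to_matrix()
    raise TypeError(f"expected a contact map, got {type(cmap)!r}")


def _check_penalties(gap_open: float, gap_extend: float) -> None:
    if gap_open > 0 or gap_extend > 0:
        raise ValueError("gap penalties must be non-positive")


def _result(score: float, ai: np.ndarray, bi: np.ndarray) -> AlignmentResult:
    mapping = tuple((int(i) + 1, int(a) + 1) for i, a in zip(ai, bi))
    return AlignmentResult(score=max(float(score), 0.0),
                           aligned_length=len(mapping), mapping=mapping)


def _weight(sep_a: int, sep_b: int, p: float, sep_tolerance: float) -> float:
    return p / (1.0 + abs(sep_a - sep_b) / sep_tolerance)


def align_local(map_obs, map_pred, gap_open: float = DEFAULT_GAP_OPEN,
                gap_extend: float = DEFAULT_GAP_EXTEND,
                refinement_iterations: int = 20,
                sep_tolerance: float = DEFAULT_SEP_TOLERANCE,
                anchor_restarts: int = 32,
                anchor_iterations: int = 4) -> AlignmentResult:
    """Local contact-map alignment by iterated double dynamic programming.

    The search runs the refinement loop from neighbourhood-overlap, degree
    and flat seed matrices under a few gap-parameter variants, then from
    anchored seeds that pin one observed contact onto one predicted contact
    (the ``anchor_restarts`` highest-weight such pinnings), which lets it
    escape basins where pure self-consistent refinement stalls.

    Deterministic for fixed inputs and parameters. The reported score is the
    quadratic objective of the best mapping encountered, not the final DP
    score (the DP similarity matrix is only a search device).
    """
    _check_penalties(gap_open, gap_extend)
    O = _as_matrix(map_obs)
    P = _as_matrix(map_pred)
    if O.shape[0] < 1 or P.shape[0] < 1:
        raise ValueError("zero-length contact map")
    empty = AlignmentResult(0.0, 0, ())
    if O.sum() == 0 or P.sum() == 0:
        return empty

    state = {"score": 0.0, "best": empty}

    def run(M0, go, ge, iters):
        true, ai, bi = refine_run(O, P, np.ascontiguousarray(M0), go, ge,
                                  gap_open, gap_extend, sep_tolerance,
                                  max(iters, 1))
        if true > state["score"] + 1e-12:
            state["score"] = float(true)
            state["best"] = _result(true, ai, bi)

    base = overlap_seed(O, P, sep_tolerance)
    deg_o = O.sum(axis=1)
    deg_p = P.sum(axis=1)
    seeds = [
        base,
        np.outer(deg_o, deg_p) / max(deg_o.max() * deg_p.max(), 1e-12),
        np.full((O.shape[0], P.shape[0]), 0.25),
    ]
    gap_variants = ((gap_open, gap_extend), (0.5 * gap_open, gap_extend),
                    (2.0 * gap_open, gap_extend))
    for seed in seeds:
        for go, ge in gap_variants:
            run(seed, go, ge, refinement_iterations)

    if anchor_restarts > 0:
        obs_pairs = [(i, j) for i in range(O.shape[0]) for j in range(i + 1, O.shape[0])
                     if O[i, j] > 0]
        pred_pairs = [(a, b) for a in range(P.shape[0]) for b in range(a + 1, P.shape[0])
                      if P[a, b] > 0]
        anchors = [
            (_weight(j - i, b - a, P[a, b] * O[i, j], sep_tolerance), i, j, a, b)
            for i, j in obs_pairs for a, b in pred_pairs
        ]
        anchors.sort(key=lambda x: (-x[0], x[1:]))
        bonus = max(float(base.max()), 1.0) * 4.0
        for _, i, j, a, b in anchors[:anchor_restarts]:
            M = base.copy()
            M[i, a] += bonus
            M[j, b] += bonus
            run(M, gap_open, gap_extend, anchor_iterations)
    return state["best"]


def _eigen_profile(matrix: np.ndarray, k: int) -> np.ndarray:
    """Leading-k eigenvectors scaled by sqrt(|eigenvalue|), signs fixed.

    Eigenvectors are ordered by |eigenvalue| descending; each is flipped so
    its largest-magnitude entry (first such, on ties) is positive.
    """
    vals, vecs = np.linalg.eigh(matrix)
    order = np.argsort(-np.abs(vals), kind="stable")[:k]
    prof = vecs[:, order] * np.sqrt(np.abs(vals[order]))
    for c in range(prof.shape[1]):
        col = prof[:, c]
        lead = np.argmax(np.abs(col))
        if col[lead] < 0:
            prof[:, c] = -col
    return prof


def align_spectral(map_obs, map_pred, k: int = 15,
                   gap_open: float = DEFAULT_GAP_OPEN,
                   gap_extend: float = DEFAULT_GAP_EXTEND) -> AlignmentResult:
    """Global alignment of eigenvector profiles of the two contact maps.

    Residue-pair similarity is S(i, j) = sum_k |u_k(i) * v_k(j)|, which makes
    the score invariant under independent sign flips of any eigenvector.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    _check_penalties(gap_open, gap_extend)
    A = _as_matrix(map_obs)
    B = _as_matrix(map_pred)
    if A.shape[0] < 1 or B.shape[0] < 1:
        raise ValueError("zero-length contact map")
    if A.sum() == 0 or B.sum() == 0:
        return AlignmentResult(0.0, 0, ())
    kk = min(k, A.shape[0], B.shape[0])
    if kk < k:
        warnings.warn(f"k={k} exceeds map length; clamped to {kk}", stacklevel=2)
    U = _eigen_profile(A, kk)
    V = _eigen_profile(B, kk)
    S = np.abs(U) @ np.abs(V).T
    score, ai, bi = gotoh_align(np.ascontiguousarray(S), gap_open, gap_extend, False)
    return _result(score, ai, bi)


def brute_force_align(map_a, map_b, max_length: int = 10,
                      gap_open: float = DEFAULT_GAP_OPEN,
                      gap_extend: float = DEFAULT_GAP_EXTEND,
                      sep_tolerance: float = DEFAULT_SEP_TOLERANCE) -> AlignmentResult:
    """Exact optimum of the local-alignment objective by exhaustive search.

    Enumerates every monotone partial correspondence; a testing oracle, kept
    free of the DP machinery it validates. Refuses maps longer than
    ``max_length`` residues.
    """
    O = _as_matrix(map_a)
    P = _as_matrix(map_b)
    LA, LB = O.shape[0], P.shape[0]
    if LA > max_length or LB > max_length:
        raise ValueError(f"maps larger than max_length={max_length}")

    best = [0.0, ()]

    def gap_cost(g: int) -> float:
        return gap_open + (g - 1) * gap_extend if g > 0 else 0.0

    def extend(mi, ma, score, last_i, last_a):
        if score > best[0]:
            best[0] = score
            best[1] = tuple(zip(mi, ma))
        for i in range(last_i + 1, LA):
            for a in range(last_a + 1, LB):
                add = 0.0
                for r in range(len(mi)):
                    o = O[i, mi[r]]
                    if o > 0.0:
                        p = P[a, ma[r]]
                        if p > 0.0:
                            add += o * p / (1.0 + abs((i - mi[r]) - (a - ma[r])) / sep_tolerance)
                if mi:
                    add += gap_cost(i - last_i - 1) + gap_cost(a - last_a - 1)
                mi.append(i)
                ma.append(a)
                extend(mi, ma, score + add, i, a)
                mi.pop()
                ma.pop()

    extend([], [], 0.0, -1, -1)
    mapping = tuple((i + 1, a + 1) for i, a in best[1])
    return AlignmentResult(score=best[0], aligned_length=len(mapping), mapping=mapping)
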