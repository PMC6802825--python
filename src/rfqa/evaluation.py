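"""Evaluation surfaces: ranking, tier reports, ROC/AUC, and the two baselines.

Targets are categorised by the confidence tier of their highest-ranking
model; Top1 asks whether that model is correct, Top5 whether the best of the
five highest-ranked models is. Precisions are reported both to one decimal
place and as integer percentages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

from .classifier import Tier, tier_of
from .quality_scores import CORRECT_TM, mean_pairwise_top10

TIER_ORDER = (Tier.HIGH, Tier.MEDIUM, Tier.LOW, Tier.FAILED)


def rank_and_select(scores: dict, k: int) -> list:
    """Top-k model ids by descending score, ties broken lexicographically."""
    if not scores:
        raise ValueError("no models to rank")
    order = sorted(scores, key=lambda m: (-scores[m], m))
    return order[:k]


def _per_target(predictions: pd.DataFrame, labels: dict) -> pd.DataFrame:
    rows = []
    for target, grp in predictions.groupby("target_id", sort=True):
        scores = dict(zip(grp["model_id"], grp["rfqa_score"]))
        ranked = rank_and_select(scores, len(scores))
        tms = np.array([labels[(target, m)] for m in ranked])
        rows.append({
            "target_id": target,
            "tier": tier_of(scores[ranked[0]]).value,
            "top1_score": scores[ranked[0]],
            "top1_tm": tms[0],
            "top1_correct": tms[0] >= CORRECT_TM,
            "top5_correct": bool((tms[:5] >= CORRECT_TM).any()),
            "has_correct": bool((tms >= CORRECT_TM).any()),
        })
    return pd.DataFrame(rows)


def tier_report(predictions: pd.DataFrame, labels: dict) -> pd.DataFrame:
    """Per-confidence-tier target counts and Top1/Top5 precisions.

    ``predictions`` carries target_id, model_id, rfqa_score; ``labels`` maps
    (target_id, model_id) to TM-score. Count identities
    (top1 <= top5 <= max <= total, totals summing to the target count) are
    asserted on every input.
    """
    missing = [
        (t, m) for t, m in zip(predictions["target_id"], predictions["model_id"])
        if (t, m) not in labels
    ]
    if missing:
        raise ValueError(f"missing TM labels for {len(missing)} models")
    per_target = _per_target(predictions, labels)
    rows = []
    for tier in TIER_ORDER:
        sub = per_target[per_target["tier"] == tier.value]
        total = len(sub)
        top1 = int(sub["top1_correct"].sum())
        top5 = int(sub["top5_correct"].sum())
        mx = int(sub["has_correct"].sum())
        assert top1 <= top5 <= mx <= total
        rows.append({
            "tier": tier.value, "total": total, "max": mx,
            "top1": top1, "top5": top5,
            "top1_precision": round(100.0 * top1 / total, 1) if total else 0.0,
            "top5_precision": round(100.0 * top5 / total, 1) if total else 0.0,
            "top1_precision_pct": round(100.0 * top1 / total) if total else 0,
            "top5_precision_pct": round(100.0 * top5 / total) if total else 0,
        })
    report = pd.DataFrame(rows).set_index("tier")
    assert report["total"].sum() == per_target["target_id"].nunique()
    return report


def combined_precision(report: pd.DataFrame, tiers=("high", "medium"),
                       top: str = "top1") -> float:
    """Pooled Top1/Top5 precision (integer %) over a set of tiers."""
    sub = report.loc[list(tiers)]
    total = sub["total"].sum()
    if total == 0:
        return 0.0
    return round(100.0 * sub[top].sum() / total)


def roc_auc(scores, labels) -> float:
    """AUC of correct/incorrect classification (rank / Mann-Whitney statistic)."""
    y = np.asarray(labels, dtype=bool)
    if y.all() or not y.any():
        raise ValueError("AUC requires both classes")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def tp_vs_fpr_curve(top1_scores, top1_labels) -> pd.DataFrame:
    """True-positive target counts against false positive rate.

    Inputs are per-target: the score of the highest-ranking model and
    whether that model is correct. Evaluated at every distinct score.
    """
    y = np.asarray(top1_labels, dtype=bool)
    s = np.asarray(top1_scores, dtype=float)
    if y.all() or not y.any():
        raise ValueError("curve requires both classes")
    fpr, tpr, thresholds = roc_curve(y, s, drop_intermediate=False)
    return pd.DataFrame({
        "threshold": thresholds, "fpr": fpr,
        "true_positives": np.round(tpr * y.sum()).astype(int),
    })


def fpr_threshold_baseline(scores, labels, fpr_target: float):
    """Score cutoff achieving maximal recall at an FPR bound.

    Returns (threshold, predicted_positive): the smallest threshold, drawn
    from the observed scores (positives predicted at score > threshold),
    whose empirical FPR does not exceed ``fpr_target``.
    """
    y = np.asarray(labels, dtype=bool)
    s = np.asarray(scores, dtype=float)
    if y.all() or not y.any():
        raise ValueError("FPR thresholding requires both classes")
    n_neg = (~y).sum()
    best_t = None
    for t in sorted(set(s.tolist())):
        fp = ((s > t) & ~y).sum()
        if fp / n_neg <= fpr_target:
            best_t = t
            break
    if best_t is None:  # unattainable even with no positives predicted
        raise ValueError(f"FPR {fpr_target} unattainable")
    return float(best_t), s > best_t


def convergence_baseline(ensembles: dict, cutoff: float = 0.65) -> dict:
    """Top-10 mean-pairwise-TM convergence test, per target.

    ``ensembles`` maps target_id to (models, scores[, tm_matrix]); a target
    is predicted correct when the mean pairwise TM-score of its ten
    highest-scoring models is strictly above the cutoff.
    """
    out = {}
    for target, bundle in ensembles.items():
        models, scores = bundle[0], bundle[1]
        tm = bundle[2] if len(bundle) > 2 else None
        out[target] = mean_pairwise_top10(models, scores, tm=tm) > cutoff
    return out
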