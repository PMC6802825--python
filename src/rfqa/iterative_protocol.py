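"""Generate-and-assess loop: grow an ensemble in batches until confident.

Models are requested from a generator in fixed-size batches (default 500)
up to a ceiling (default 10,000). After every batch the ensemble block of
the feature scheme is recomputed over the full accumulated ensemble —
ensemble statistics change as models accumulate — every model is re-scored,
and the loop stops as soon as the best model reaches the stop tier.
Cached model-specific features are reused; only the ensemble block and the
forest scores are refreshed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .classifier import Tier, TrainedForest, predict, tier_of
from .evaluation import rank_and_select
from .featurization import TargetFeatures, assemble_features
from .quality_scores import CORRECT_TM

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ProtocolStep:
    ensemble_size: int
    best_score: float
    best_tier: Tier
    best_model_id: str
    top5_best_tm: float | None = None


@dataclass
class ProtocolTrace:
    target_id: str
    steps: list = field(default_factory=list)
    status: str = "exhausted"  # or "stopped_high"

    def __post_init__(self) -> None:
        if self.status not in ("stopped_high", "exhausted"):
            raise ValueError("invalid terminal status")

    @property
    def final_size(self) -> int:
        return self.steps[-1].ensemble_size if self.steps else 0


def run_protocol(generator, model: TrainedForest, target: TargetFeatures,
                 batch_size: int = 500, max_models: int = 10000,
                 stop_tier: Tier = Tier.HIGH,
                 tm_labels: dict | None = None) -> ProtocolTrace:
    """Drive the iterative assessment loop for one target.

    ``generator(n)`` returns up to n :class:`~rfqa.featurization.ModelFeatures`
    (a short batch means the generator is exhausted; the partial batch is
    still assessed). ``tm_labels`` (model_id -> TM) enables the
    best-of-top-5 TM bookkeeping of each step.
    """
    if batch_size < 1 or max_models < batch_size:
        raise ValueError("need 1 <= batch_size <= max_models")
    ensemble: list = []
    trace = ProtocolTrace(target_id=target.target_id)
    while len(ensemble) < max_models:
        want = min(batch_size, max_models - len(ensemble))
        batch = generator(want)
        if not batch:
            logger.warning("generator exhausted at %d models", len(ensemble))
            break
        if len(batch) < want:
            logger.warning("partial batch of %d models (wanted %d)",
                           len(batch), want)
        ensemble.extend(batch)
        features = assemble_features(target, ensemble)
        preds = predict(model, features)
        scores = dict(zip(preds["model_id"], preds["rfqa_score"]))
        ranked = rank_and_select(scores, 5)
        best_id = ranked[0]
        best_score = float(scores[best_id])
        top5_tm = None
        if tm_labels is not None:
            top5_tm = float(max(tm_labels[m] for m in ranked))
        best_tier = tier_of(best_score)
        trace.steps.append(ProtocolStep(
            ensemble_size=len(ensemble), best_score=best_score,
            best_tier=best_tier, best_model_id=best_id, top5_best_tm=top5_tm))
        if best_tier.rank >= stop_tier.rank:
            trace.status = "stopped_high"
            break
        if len(batch) < want:
            break
    return trace


def summarize_protocols(traces: list) -> dict:
    """Cross-target protocol summary, including the median model count."""
    sizes = [t.final_size for t in traces]
    stopped = [t for t in traces if t.status == "stopped_high"]
    out = {
        "n_targets": len(traces),
        "n_stopped_confident": len(stopped),
        "median_models": float(np.median(sizes)) if sizes else 0.0,
        "total_models": int(np.sum(sizes)) if sizes else 0,
    }
    tm_final = [t.steps[-1].top5_best_tm for t in traces
                if t.steps and t.steps[-1].top5_best_tm is not None]
    if tm_final:
        out["n_top5_correct_final"] = int(
            np.sum([tm >= CORRECT_TM for tm in tm_final]))
    return out
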