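"""End-to-end plumbing: turn model ensembles into feature tables and studies.

This is the glue the CLI, the acceptance study, and the tests share: given
an ensemble of models, a predicted contact map, and (optionally) external
score columns, produce the 58-column feature table; given two benchmarks,
train on one and evaluate on the other.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from . import classifier as clf
from . import evaluation
from .contact_alignment import align_local, align_spectral
from .featurization import (ModelFeatures, TargetFeatures, assemble_features,
                            compute_beff)
from .quality_scores import (consensus_scores, contact_potential, contact_ppv,
                             pairwise_tm_matrix, pcombc, satisfied_count)
from .structure_io import observed_contact_map
from .synthetic_fixtures import Benchmark, TargetBundle

logger = logging.getLogger(__name__)


def featurize_ensemble(models, predicted, external: pd.DataFrame | None,
                       beff: float, target_id: str,
                       p_threshold: float = 0.5,
                       pcombc_weights: tuple = (0.2, 0.5, 0.3),
                       tm: np.ndarray | None = None) -> pd.DataFrame:
    """Feature table (58 columns + ids) for one target's model ensemble.

    ``external`` supplies the five external QA score columns keyed by
    model_id; absent columns stay missing and are imputed downstream.
    ``tm`` may carry a precomputed pairwise TM matrix for the consensus term.
    """
    length = models[0].length
    n_pred = len(predicted.pairs_above(p_threshold))
    target = TargetFeatures(target_id=target_id, length=length, beff=beff,
                            n_predicted_contacts=n_pred)
    if tm is None:
        tm = pairwise_tm_matrix(models)
    pcons = consensus_scores(models, tm=tm)
    ext = {}
    if external is not None:
        ext = external.set_index("model_id").to_dict(orient="index")

    feats = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # empty-PPV warnings on poor maps
        for k, model in enumerate(models):
            omap = observed_contact_map(model)
            ppv = contact_ppv(omap, predicted, p_threshold)
            nsat = satisfied_count(omap, predicted, p_threshold)
            local = align_local(omap, predicted)
            spectral = align_spectral(omap, predicted)
            row = ext.get(model.model_id, {})
            proq3d = float(row.get("proq3d", np.nan))
            values = {
                "saint2": float(row.get("saint2", np.nan)),
                "proq2d": float(row.get("proq2d", np.nan)),
                "proq3d": proq3d,
                "proqroscend": float(row.get("proqroscend", np.nan)),
                "proqrosfad": float(row.get("proqrosfad", np.nan)),
                "pcons": float(pcons[k]),
                "pcombc": pcombc(proq3d, float(pcons[k]), ppv, pcombc_weights),
                "saint2_contact": contact_potential(omap, predicted),
                "ppv": ppv,
                "eigen_score": spectral.score,
                "mapalign_score": local.score,
                "mapalign_length": float(local.aligned_length),
            }
            feats.append(ModelFeatures(model_id=model.model_id, values=values,
                                       n_satisfied=float(nsat)))
    return assemble_features(target, feats)


def featurize_bundle(bundle: TargetBundle) -> pd.DataFrame:
    """Feature table for one synthetic-benchmark target."""
    beff = compute_beff(bundle.msa)
    return featurize_ensemble(bundle.models, bundle.predicted,
                              bundle.external, beff, bundle.target_id)


def featurize_benchmark(bench: Benchmark) -> tuple:
    """(features, tms): stacked feature table and TM labels for a benchmark."""
    frames, tms = [], []
    for bundle in bench.targets:
        frames.append(featurize_bundle(bundle))
        tms.append(bundle.tms)
    return (pd.concat(frames, ignore_index=True), np.concatenate(tms))


def labels_dict(bench: Benchmark) -> dict:
    """(target_id, model_id) -> TM lookup for evaluation."""
    return {(b.target_id, m.model_id): tm
            for b in bench.targets for m, tm in zip(b.models, b.tms)}


def run_study(train_bench: Benchmark, test_bench: Benchmark,
              config: clf.ForestConfig = clf.ForestConfig()) -> dict:
    """Train on one benchmark, evaluate on a disjoint one.

    Returns the fitted model, feature tables, per-model AUC, the tier
    report, and per-target Top1 counts.
    """
    train_X, train_tm = featurize_benchmark(train_bench)
    test_X, test_tm = featurize_benchmark(test_bench)
    model = clf.train(train_X, train_tm >= 0.5, config)
    preds = clf.predict(model, test_X)
    auc = evaluation.roc_auc(preds["rfqa_score"], test_tm >= 0.5)
    report = evaluation.tier_report(preds, labels_dict(test_bench))
    return {"model": model, "train_features": train_X, "train_tm": train_tm,
            "test_features": test_X, "test_tm": test_tm,
            "predictions": preds, "auc": auc, "tier_report": report}
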