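"""Ranking, tier reports, ROC/AUC oracles, and the two baseline classifiers."""

import copy

import numpy as np
import pandas as pd
import pytest

from rfqa import evaluation
from rfqa.quality_scores import pairwise_tm_matrix
from rfqa.synthetic_fixtures import synth_decoys, synth_native


def tier_fixture(tier_specs):
    """Build per-model predictions/labels realising given per-tier counts.

    tier_specs: list of (top_score, total, max_, top1, top5). Each target
    gets six models; correctness is planted at rank 1 (Top1), rank 3
    (Top5-only), or rank 6 (Max-only).
    """
    rows = []
    labels = {}
    t = 0
    for top_score, total, max_, top1, top5 in tier_specs:
        kinds = (["top1"] * top1 + ["top5"] * (top5 - top1)
                 + ["max"] * (max_ - top5) + ["none"] * (total - max_))
        for kind in kinds:
            target = f"T{t:04d}"
            t += 1
            correct_rank = {"top1": 1, "top5": 3, "max": 6}.get(kind)
            for rank in range(1, 7):
                score = top_score if rank == 1 else max(top_score - 0.01 * rank, 0.0)
                tm = 0.7 if rank == correct_rank else 0.2
                model_id = f"m{rank}"
                rows.append({"target_id": target, "model_id": model_id,
                             "rfqa_score": score})
                labels[(target, model_id)] = tm
    return pd.DataFrame(rows), labels


class TestRankAndSelect:
    def test_argmax_first(self):
        assert evaluation.rank_and_select({"a": 0.1, "b": 0.9, "c": 0.5}, 2) == ["b", "c"]

    def test_ties_broken_lexicographically(self):
        assert evaluation.rank_and_select({"c": 0.5, "a": 0.5, "b": 0.5}, 2) == ["a", "b"]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            evaluation.rank_and_select({}, 1)


class TestTierReport:
    def test_three_target_hand_tally(self):
        preds, labels = tier_fixture([(0.8, 1, 1, 1, 1), (0.4, 1, 1, 0, 1),
                                      (0.05, 1, 0, 0, 0)])
        report = evaluation.tier_report(preds, labels)
        assert report.loc["high", ["total", "max", "top1", "top5"]].tolist() == [1, 1, 1, 1]
        assert report.loc["medium", ["total", "top1", "top5"]].tolist() == [1, 0, 1]
        assert report.loc["failed", "total"] == 1
        assert report.loc["low", "total"] == 0

    def test_all_models_correct(self):
        preds = pd.DataFrame({"target_id": ["T1"] * 3, "model_id": list("abc"),
                              "rfqa_score": [0.9, 0.8, 0.7]})
        labels = {("T1", m): 0.8 for m in "abc"}
        report = evaluation.tier_report(preds, labels)
        assert report.loc["high", "top1_precision"] == 100.0

    def test_count_identities_hold(self):
        rng = np.random.default_rng(0)
        rows, labels = [], {}
        for t in range(30):
            for m in range(8):
                rows.append({"target_id": f"T{t}", "model_id": f"m{m}",
                             "rfqa_score": float(rng.random())})
                labels[(f"T{t}", f"m{m}")] = float(rng.random())
        report = evaluation.tier_report(pd.DataFrame(rows), labels)
        assert report["total"].sum() == 30
        assert (report["top1"] <= report["top5"]).all()
        assert (report["top5"] <= report["max"]).all()
        assert (report["max"] <= report["total"]).all()

    def test_missing_labels_rejected(self):
        preds = pd.DataFrame({"target_id": ["T1"], "model_id": ["a"],
                              "rfqa_score": [0.9]})
        with pytest.raises(ValueError, match="labels"):
            evaluation.tier_report(preds, {})

    def test_raising_high_boundary_never_adds_high_targets(self):
        """Tier-count monotonicity in the confidence boundary."""
        rng = np.random.default_rng(1)
        top_scores = rng.random(50)
        counts = [(top_scores > thr).sum() for thr in (0.3, 0.5, 0.7)]
        assert counts == sorted(counts, reverse=True)


class TestRocAuc:
    def test_perfect_separation(self):
        assert evaluation.roc_auc([0.9, 0.8, 0.2, 0.1],
                                  [True, True, False, False]) == 1.0

    def test_label_independent_scores_near_half(self):
        rng = np.random.default_rng(2)
        scores = rng.random(4000)
        labels = rng.random(4000) < 0.5
        assert abs(evaluation.roc_auc(scores, labels) - 0.5) < 0.05

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_equals_concordant_pair_fraction(self, seed):
        """AUC equals brute-force pair counting (ties count half)."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 50))
        scores = np.round(rng.random(n), 1)  # coarse grid forces ties
        labels = rng.random(n) < 0.5
        if labels.all() or not labels.any():
            labels[0] = not labels[0]
        pos = scores[labels]
        neg = scores[~labels]
        pairs = [(1.0 if p > q else 0.5 if p == q else 0.0)
                 for p in pos for q in neg]
        assert evaluation.roc_auc(scores, labels) == pytest.approx(np.mean(pairs))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            evaluation.roc_auc([0.4, 0.6], [True, True])


class TestTpVsFprCurve:
    def test_perfect_separation_curve(self):
        curve = evaluation.tp_vs_fpr_curve([0.9, 0.8, 0.2, 0.1],
                                           [True, True, False, False])
        at_zero = curve[curve["fpr"] == 0.0]["true_positives"].max()
        assert at_zero == 2
        assert curve["true_positives"].max() == 2

    def test_tp_counts_monotone_in_fpr(self):
        rng = np.random.default_rng(3)
        scores = rng.random(40)
        labels = rng.random(40) < 0.4
        labels[0] = True
        labels[1] = False
        curve = evaluation.tp_vs_fpr_curve(scores, labels)
        ordered = curve.sort_values("fpr")["true_positives"]
        assert (np.diff(ordered) >= 0).all()


class TestFprThresholdBaseline:
    def test_perfectly_separated(self):
        thr, pred = evaluation.fpr_threshold_baseline(
            [0.9, 0.8, 0.2, 0.1], [True, True, False, False], 0.01)
        assert thr == 0.2
        assert pred.tolist() == [True, True, False, False]

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(4)
        scores = rng.random(30)
        labels = rng.random(30) < 0.5
        labels[:2] = [True, False]
        for target in (0.01, 0.1, 0.3):
            thr, _ = evaluation.fpr_threshold_baseline(scores, labels, target)
            neg = scores[~labels]
            candidates = [t for t in sorted(set(scores))
                          if (neg > t).mean() <= target]
            assert thr == pytest.approx(min(candidates))

    def test_zero_fpr_with_overlap(self):
        scores = [0.9, 0.55, 0.6, 0.2]
        labels = [True, True, False, False]
        thr, pred = evaluation.fpr_threshold_baseline(scores, labels, 0.0)
        assert thr == 0.6  # just above every negative
        assert pred.tolist() == [True, False, False, False]


class TestConvergenceBaseline:
    def test_identical_ensemble_predicted_correct(self):
        native = synth_native(30, seed=20)
        clones = [copy.deepcopy(native) for _ in range(10)]
        for k, c in enumerate(clones):
            c.model_id = f"m{k}"
        out = evaluation.convergence_baseline({"T1": (clones, np.ones(10))})
        assert out == {"T1": True}

    def test_cutoff_is_strictly_above(self):
        native = synth_native(40, seed=21)
        models, _ = synth_decoys(native, [1.0], 10, seed=22)
        tm = pairwise_tm_matrix(models)
        mean_tm = float(np.mean(tm[np.triu_indices(10, 1)]))
        out = evaluation.convergence_baseline(
            {"T1": (models, np.ones(10), tm)}, cutoff=mean_tm)
        assert out == {"T1": False}  # exactly at the cutoff is not above it
        out = evaluation.convergence_baseline(
            {"T1": (models, np.ones(10), tm)}, cutoff=mean_tm - 1e-9)
        assert out == {"T1": True}

    def test_toy_ensemble_hand_decision(self):
        native = synth_native(40, seed=23)
        good, _ = synth_decoys(native, [0.8], 10, seed=24)
        bad, _ = synth_decoys(native, [8.0], 10, seed=25)
        scores = np.concatenate([np.ones(10), np.zeros(10)])
        out = evaluation.convergence_baseline(
            {"T1": (good + bad, scores)}, cutoff=0.65)
        assert out["T1"]  # top-10 selection picks the converged good models
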