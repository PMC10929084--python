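"""Metric formulas, rank AUC, curves, and the five-fold CV protocol."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

import rpifusion as rf
from rpifusion.classifier import ModelConfig, ScoredPrediction
from rpifusion.errors import SingleClassError, TooFewSamples
from rpifusion.evaluate import rank_auc


def preds_from(labels, scores):
    return [
        ScoredPrediction(rf.InteractionPair(f"r{i}", f"p{i}", int(l)), float(s))
        for i, (l, s) in enumerate(zip(labels, scores))
    ]


class TestConfusion:
    def test_all_correct(self):
        preds = preds_from([1, 1, 0, 0], [0.9, 0.8, 0.1, 0.2])
        c = rf.confusion(preds)
        assert (c.TP, c.TN, c.FP, c.FN) == (2, 2, 0, 0)

    def test_mixed_counts(self):
        preds = preds_from([1, 1, 0, 0], [0.9, 0.2, 0.1, 0.8])
        c = rf.confusion(preds)
        assert (c.TP, c.FN, c.TN, c.FP) == (1, 1, 1, 1)
        assert c.n == 4


class TestMetrics:
    def test_perfect_classifier(self):
        preds = preds_from([1] * 10 + [0] * 10, [0.9] * 10 + [0.1] * 10)
        r = rf.metrics(rf.confusion(preds), preds)
        for name in ("ACC", "SEN", "SPE", "PRE", "F1", "MCC", "AUC"):
            assert getattr(r, name) == pytest.approx(1.0)

    def test_direct_formula_oracle(self):
        from rpifusion.evaluate import ConfusionCounts

        c = ConfusionCounts(TP=50, FN=10, TN=30, FP=10)
        r = rf.metrics(c)
        tp, tn, fp, fn = 50, 30, 10, 10
        assert r.ACC == pytest.approx((tp + tn) / 100)
        assert r.SEN == pytest.approx(tp / (tp + fn))
        assert r.SPE == pytest.approx(tn / (tn + fp))
        assert r.PRE == pytest.approx(tp / (tp + fp))
        pre, sen = tp / (tp + fp), tp / (tp + fn)
        assert r.F1 == pytest.approx(2 * pre * sen / (pre + sen))
        mcc = (tp * tn - fp * fn) / np.sqrt(
            float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
        )
        assert r.MCC == pytest.approx(mcc)

    def test_zero_denominator_flagged(self):
        from rpifusion.evaluate import ConfusionCounts

        r = rf.metrics(ConfusionCounts(TP=0, FN=0, TN=5, FP=0))
        assert r.SEN == 0.0 and "SEN" in r.degenerate

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(40)
        labels = rng.integers(0, 2, size=200)
        scores = rng.random(200)
        preds = preds_from(labels, scores)
        swapped = preds_from(1 - labels, 1 - scores)
        r1 = rf.metrics(rf.confusion(preds), preds)
        r2 = rf.metrics(rf.confusion(swapped), swapped)
        assert r1.SEN == pytest.approx(r2.SPE)
        assert r1.SPE == pytest.approx(r2.SEN)
        # swapping labels alone flips discrimination
        label_only = preds_from(1 - labels, scores)
        r3 = rf.metrics(rf.confusion(label_only), label_only)
        assert r3.AUC == pytest.approx(1 - r1.AUC)


class TestRankAuc:
    def test_separated_scores(self):
        assert rank_auc(
            np.array([0.9, 0.8, 0.7, 0.1]), np.array([1, 1, 0, 0])
        ) == pytest.approx(1.0)

    def test_rank_formula_equals_trapezoid_and_sklearn(self):
        rng = np.random.default_rng(41)
        for _ in range(100):
            n = int(rng.integers(10, 60))
            labels = np.r_[np.ones(5, int), rng.integers(0, 2, n)]
            labels[:5] = 1
            labels[-3:] = 0
            scores = np.round(rng.random(labels.size), 2)  # forces ties
            preds = preds_from(labels, scores)
            _, _, trap_auc, _ = rf.curves(preds)
            got = rank_auc(scores, labels)
            assert got == pytest.approx(trap_auc, abs=1e-9)
            assert got == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(SingleClassError):
            rank_auc(np.array([0.5, 0.6]), np.array([1, 1]))


class TestCurves:
    def test_perfect_separation(self):
        preds = preds_from([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1])
        roc, pr, auc, aupr = rf.curves(preds)
        assert auc == pytest.approx(1.0)
        assert aupr == pytest.approx(1.0)
        assert roc[0].tolist() == [0.0, 0.0] and roc[-1].tolist() == [1.0, 1.0]

    def test_random_scores_auc_near_half(self):
        rng = np.random.default_rng(42)
        labels = np.repeat([0, 1], 5000)
        scores = rng.random(10000)
        preds = preds_from(labels, scores)
        _, _, auc, _ = rf.curves(preds)
        assert auc == pytest.approx(0.5, abs=0.02)


class TestFiveFoldCv:
    def test_protocol_invariants(self, small_blocks):
        blocks, labels, pairs = small_blocks
        cfg = ModelConfig(epochs=4, early_stopping_patience=0, seed=0)
        reports, mean = rf.five_fold_cv(
            pairs, blocks, labels, cfg, seed=0, n_trees=30
        )
        assert len(reports) == 5
        n = labels.size
        sizes = []
        for r in reports:
            assert 0.0 <= r.ACC <= 1.0
        # mean is the arithmetic mean of fold metrics
        assert mean.ACC == pytest.approx(
            np.mean([r.ACC for r in reports]), abs=1e-12
        )
        assert mean.AUC == pytest.approx(
            np.mean([r.AUC for r in reports]), abs=1e-12
        )

    def test_fold_partition_arithmetic(self):
        from sklearn.model_selection import StratifiedKFold

        labels = np.repeat([0, 1], 61)
        skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=0)
        test_folds = [te for _, te in skf.split(np.zeros(122), labels)]
        sizes = [len(te) for te in test_folds]
        assert max(sizes) - min(sizes) <= 1
        all_idx = np.sort(np.concatenate(test_folds))
        assert np.array_equal(all_idx, np.arange(122))

    def test_too_few_samples(self, small_blocks):
        blocks, labels, pairs = small_blocks
        tiny = {k: v[:6] for k, v in blocks.items()}
        with pytest.raises(TooFewSamples):
            rf.five_fold_cv(
                pairs[:6], tiny, labels[:6], ModelConfig(seed=0), seed=0
            )
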