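"""Evaluation: confusion-based metrics, rank AUC, curves, five-fold CV.

Metrics follow the standard confusion-table definitions — ACC, SEN
(recall of positives), SPE (recall of negatives), PRE (positive predictive
value), F1, and MCC — with a zero value and a degenerate flag whenever a
denominator vanishes (small folds can produce empty confusion cells). AUC
is computed by the rank (Mann-Whitney) formula over positive-class scores,
with average ranks under ties:

    AUC = (sum of positive ranks - |P|(|P|+1)/2) / (|P| * |N|).

Cross-validation stratifies by label into five disjoint folds; selection
masks and the model are refit on the four training folds of each split,
and the summary report is the arithmetic mean of the fold metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from .classifier import (
    ModelConfig,
    ScoredPrediction,
    StackingClassifier,
    build_model,
    train,
)
from .errors import SingleClassError, TooFewSamples
from .selection import DEFAULT_N_TREES, fit_selection_masks


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def n(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class MetricReport:
    ACC: float
    SEN: float
    SPE: float
    PRE: float
    F1: float
    MCC: float
    AUC: float
    fold: int | str = "all"
    degenerate: list[str] = field(default_factory=list)

    def as_dict(self) -> dict[str, float]:
        return {
            f.name: getattr(self, f.name)
            for f in fields(self)
            if f.name not in ("fold", "degenerate")
        }


def confusion(preds: list[ScoredPrediction]) -> ConfusionCounts:
    """Count (true label, thresholded class) agreement over predictions."""
    if not preds:
        raise ValueError("no predictions to evaluate")
    tp = sum(1 for p in preds if p.pair.label == 1 and p.predicted == 1)
    tn = sum(1 for p in preds if p.pair.label == 0 and p.predicted == 0)
    fp = sum(1 for p in preds if p.pair.label == 0 and p.predicted == 1)
    fn = sum(1 for p in preds if p.pair.label == 1 and p.predicted == 0)
    return ConfusionCounts(TP=tp, TN=tn, FP=fp, FN=fn)


def rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC from score ranks (average ranks under ties)."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise SingleClassError("AUC needs both classes present")
    ranks = rankdata(scores, method="average")
    pos_rank_sum = ranks[labels == 1].sum()
    return float((pos_rank_sum - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def _safe_div(num: float, den: float, flag: str, degenerate: list[str]) -> float:
    if den == 0:
        degenerate.append(flag)
        return 0.0
    return num / den


def metrics(
    c: ConfusionCounts, preds: list[ScoredPrediction] | None = None
) -> MetricReport:
    """Full metric report from confusion counts (+ scores for AUC)."""
    degenerate: list[str] = []
    tp, tn, fp, fn = c.TP, c.TN, c.FP, c.FN
    acc = _safe_div(tp + tn, c.n, "ACC", degenerate)
    sen = _safe_div(tp, tp + fn, "SEN", degenerate)
    spe = _safe_div(tn, tn + fp, "SPE", degenerate)
    pre = _safe_div(tp, tp + fp, "PRE", degenerate)
    f1 = _safe_div(2 * pre * sen, pre + sen, "F1", degenerate)
    mcc_den = np.sqrt(
        float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    )
    mcc = _safe_div(tp * tn - fp * fn, mcc_den, "MCC", degenerate)
    auc = 0.0
    if preds is not None:
        scores = np.array([p.score for p in preds])
        labels = np.array([p.pair.label for p in preds])
        try:
            auc = rank_auc(scores, labels)
        except SingleClassError:
            degenerate.append("AUC")
    else:
        degenerate.append("AUC")
    return MetricReport(
        ACC=acc, SEN=sen, SPE=spe, PRE=pre, F1=f1, MCC=float(mcc), AUC=auc,
        degenerate=degenerate,
    )


def curves(
    preds: list[ScoredPrediction],
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """ROC points, PR points, trapezoidal AUC, and step-interpolated AUPR.

    Points come from a threshold sweep over the unique scores; the
    trapezoidal ROC area agrees with the rank AUC to numerical precision.
    """
    scores = np.array([p.score for p in preds])
    labels = np.array([p.pair.label for p in preds])
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise SingleClassError("curves need both classes present")
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_labels = labels[order]
    tps = np.cumsum(sorted_labels == 1)
    fps = np.cumsum(sorted_labels == 0)
    # collapse ties: keep the last index of each distinct score
    distinct = np.r_[np.flatnonzero(np.diff(sorted_scores)), scores.size - 1]
    tps, fps = tps[distinct], fps[distinct]
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    roc = np.column_stack([fpr, tpr])
    auc = float(np.trapezoid(tpr, fpr))
    precision = tps / (tps + fps)
    recall = tps / n_pos
    pr = np.column_stack([np.r_[0.0, recall], np.r_[1.0, precision]])
    # step-wise interpolation: area under precision as a function of recall
    aupr = float(np.sum(np.diff(np.r_[0.0, recall]) * precision))
    return roc, pr, auc, aupr


def five_fold_cv(
    pairs: list,
    blocks: dict[str, np.ndarray],
    labels: np.ndarray,
    config: ModelConfig,
    seed: int = 0,
    retain_fractions: dict[str, float] | float = 0.8,
    n_trees: int = DEFAULT_N_TREES,
    n_folds: int = 5,
) -> tuple[list[MetricReport], MetricReport]:
    """Stratified five-fold cross-validation of the full pipeline.

    For each fold the selection masks and the classifier are fit on the
    other four folds only (no selection leakage); the mean report is the
    arithmetic mean of the fold metrics.
    """
    labels = np.asarray(labels, dtype=np.int64)
    for cls in (0, 1):
        if (labels == cls).sum() < n_folds:
            raise TooFewSamples(
                f"need >= {n_folds} samples of class {cls} for {n_folds}-fold CV"
            )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    reports = []
    for fold, (tr, te) in enumerate(skf.split(np.zeros(labels.size), labels)):
        masks = fit_selection_masks(
            {k: np.asarray(v)[tr] for k, v in blocks.items()},
            labels[tr],
            retain_fractions=retain_fractions,
            n_trees=n_trees,
            seed=seed + fold,
        )
        kept_train = {k: m.apply(np.asarray(blocks[k])[tr]) for k, m in masks.items()}
        kept_test = {k: m.apply(np.asarray(blocks[k])[te]) for k, m in masks.items()}
        cfg = replace(config, seed=config.seed + fold)
        model = build_model(cfg, {k: m.n_kept for k, m in masks.items()})
        if isinstance(model, StackingClassifier):
            model.fit(kept_train, labels[tr])
        else:
            train(model, kept_train, labels[tr], cfg)
        probs = model.predict_proba(kept_test)
        preds = [
            ScoredPrediction(pair=pairs[j], score=float(probs[i, 1]))
            for i, j in enumerate(te)
        ]
        report = metrics(confusion(preds), preds)
        report.fold = fold
        reports.append(report)
    mean_vals = {
        k: float(np.mean([r.as_dict()[k] for r in reports]))
        for k in reports[0].as_dict()
    }
    mean_report = MetricReport(**mean_vals, fold="mean")
    return reports, mean_report
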