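"""Threshold metrics (Sn, Sp, Acc, MCC), ROC/AUC, and cross-validation.

Sensitivity Sn = TP/(TP+FN), specificity Sp = TN/(TN+FP), accuracy
Acc = (TP+TN)/n and the Matthews correlation coefficient

    MCC = (TP*TN - FP*FN) / sqrt((TP+FN)(TN+FP)(TP+FP)(TN+FN))

summarize a binary confusion matrix; when any marginal is zero the MCC is
reported as 0 with a degeneracy flag (the standard convention).  The AUC is
the area under the ROC curve, equal to the probability that a random
positive outscores a random negative (ties counted half).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass(frozen=True)
class MetricsReport:
    Sn: float
    Sp: float
    Acc: float
    MCC: float
    AUC: float | None
    counts: ConfusionCounts
    threshold: float
    n_folds: int | None = None
    degenerate_mcc: bool = False

    def to_dict(self) -> dict:
        return {
            "Sn": self.Sn,
            "Sp": self.Sp,
            "Acc": self.Acc,
            "MCC": self.MCC,
            "AUC": self.AUC,
            "TP": self.counts.TP,
            "FP": self.counts.FP,
            "TN": self.counts.TN,
            "FN": self.counts.FN,
            "threshold": self.threshold,
        }


@dataclass(frozen=True)
class ROCCurve:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def confusion(
    scores: Sequence[float], y: Sequence[int], threshold: float
) -> ConfusionCounts:
    """Count TP/FP/TN/FN at a threshold; a score equal to it is positive."""
    s = np.asarray(scores, dtype=float)
    t = np.asarray(y, dtype=int)
    if s.shape != t.shape or s.size == 0:
        raise ValueError("scores and labels must be same-length and non-empty")
    pred = s >= threshold
    return ConfusionCounts(
        TP=int(np.sum(pred & (t == 1))),
        FP=int(np.sum(pred & (t == 0))),
        TN=int(np.sum(~pred & (t == 0))),
        FN=int(np.sum(~pred & (t == 1))),
    )


def metrics_from_counts(
    c: ConfusionCounts,
    auc: float | None = None,
    threshold: float = 0.5,
    n_folds: int | None = None,
) -> MetricsReport:
    """Exact evaluation of the four confusion-matrix formulas."""
    sn = c.TP / (c.TP + c.FN) if (c.TP + c.FN) else 0.0
    sp = c.TN / (c.TN + c.FP) if (c.TN + c.FP) else 0.0
    acc = (c.TP + c.TN) / c.n if c.n else 0.0
    denom = (
        (c.TP + c.FN) * (c.TN + c.FP) * (c.TP + c.FP) * (c.TN + c.FN)
    )
    degenerate = denom == 0
    mcc = 0.0 if degenerate else (c.TP * c.TN - c.FP * c.FN) / math.sqrt(denom)
    return MetricsReport(
        Sn=sn, Sp=sp, Acc=acc, MCC=mcc, AUC=auc, counts=c,
        threshold=threshold, n_folds=n_folds, degenerate_mcc=degenerate,
    )


def roc_auc(scores: Sequence[float], y: Sequence[int]) -> ROCCurve:
    """ROC curve with AUC by trapezoidal integration."""
    s = np.asarray(scores, dtype=float)
    t = np.asarray(y, dtype=int)
    if len(np.unique(t)) < 2:
        raise ValueError("both classes required for ROC")
    fpr, tpr, thresholds = roc_curve(t, s)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=auc)


def pairwise_auc(scores: Sequence[float], y: Sequence[int]) -> float:
    """AUC as the Mann-Whitney statistic P(pos > neg) + P(tie)/2.

    Rank-based O(n log n) route, independent of the ROC-curve integration.
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(y, dtype=int)
    if len(np.unique(t)) < 2:
        raise ValueError("both classes required for AUC")
    n_pos = int(np.sum(t == 1))
    n_neg = t.size - n_pos
    ranks = rankdata(s)  # average ranks handle ties as half-wins
    u = float(np.sum(ranks[t == 1])) - n_pos * (n_pos + 1) / 2
    return u / (n_pos * n_neg)


def threshold_at_specificity(
    scores: Sequence[float], y: Sequence[int], target_sp: float = 0.80
) -> float:
    """Smallest threshold whose specificity reaches the target.

    Tables of this predictor family pin specificity near 0.80; this picks the
    operating point that maximizes sensitivity subject to Sp >= target.
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(y, dtype=int)
    neg = np.sort(s[t == 0])
    if neg.size == 0:
        raise ValueError("no negatives to calibrate specificity on")
    candidates = np.unique(np.concatenate([s, [np.inf]]))
    for thr in candidates:  # ascending: first hit maximizes Sn
        sp = np.mean(neg < thr)
        if sp >= target_sp:
            return float(thr)
    return float(candidates[-1])


def evaluate_scores(
    scores: Sequence[float],
    y: Sequence[int],
    threshold: float = 0.5,
    threshold_mode: str = "fixed",
    target_sp: float = 0.80,
) -> MetricsReport:
    """Full report at a fixed threshold or at the fixed-specificity point."""
    if threshold_mode == "specificity":
        threshold = threshold_at_specificity(scores, y, target_sp)
    elif threshold_mode != "fixed":
        raise ValueError(f"unknown threshold_mode {threshold_mode!r}")
    auc = roc_auc(scores, y).auc if len(np.unique(y)) == 2 else None
    return metrics_from_counts(
        confusion(scores, y, threshold), auc=auc, threshold=threshold
    )


def stratified_folds(
    y: Sequence[int], n_folds: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    y = np.asarray(y)
    if n_folds < 2:
        raise ValueError("folds must be >= 2")
    counts = np.bincount(y, minlength=2)
    if counts.min() < n_folds:
        raise ValueError("each class needs at least one sample per fold")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(y)), y))


def cross_validate_scores(
    score_fn: Callable[[np.ndarray, np.ndarray, np.ndarray], np.ndarray],
    y: Sequence[int],
    n_folds: int = 5,
    seed: int = 0,
    threshold: float = 0.5,
    threshold_mode: str = "fixed",
) -> tuple[list[MetricsReport], pd.DataFrame, np.ndarray]:
    """Generic stratified CV driver.

    score_fn(train_idx, test_idx, y) returns scores for the test rows after
    fitting on the training rows only.  Returns per-fold reports, a mean/SE
    summary table, and the out-of-fold score vector.
    """
    y = np.asarray(y, dtype=int)
    folds = stratified_folds(y, n_folds, seed)
    reports: list[MetricsReport] = []
    oof = np.full(len(y), np.nan)
    for train_idx, test_idx in folds:
        scores = np.asarray(score_fn(train_idx, test_idx, y))
        oof[test_idx] = scores
        reports.append(
            evaluate_scores(
                scores, y[test_idx], threshold=threshold,
                threshold_mode=threshold_mode,
            )
        )
    return reports, summarize_folds(reports), oof


def cross_validate_windows(
    windows: Sequence,
    make_estimator: Callable[[], object],
    n_folds: int = 5,
    seed: int = 0,
    threshold: float = 0.5,
    threshold_mode: str = "fixed",
) -> tuple[list[MetricsReport], pd.DataFrame, np.ndarray]:
    """Stratified CV of a window classifier; selection/training per fold.

    ``make_estimator`` builds a fresh unfitted estimator (e.g. PredNTS) for
    every fold, so feature selection and training never see the test fold.
    Every window is scored exactly once; returns per-fold reports, the
    mean/SE summary, and out-of-fold scores.
    """
    from .sequence_io import labels_array

    windows = list(windows)
    y = labels_array(windows)

    def score_fn(train_idx, test_idx, y_all):
        est = make_estimator()
        est.fit([windows[i] for i in train_idx], y_all[train_idx])
        return est.predict_proba([windows[i] for i in test_idx])[:, 1]

    return cross_validate_scores(
        score_fn, y, n_folds=n_folds, seed=seed,
        threshold=threshold, threshold_mode=threshold_mode,
    )


def summarize_folds(reports: Sequence[MetricsReport]) -> pd.DataFrame:
    """Mean and standard error of each metric across folds."""
    rows = pd.DataFrame([r.to_dict() for r in reports])
    metrics = ["Sn", "Sp", "Acc", "MCC", "AUC"]
    mean = rows[metrics].mean()
    se = rows[metrics].std(ddof=1) / np.sqrt(len(reports))
    return pd.DataFrame({"mean": mean, "se": se})
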