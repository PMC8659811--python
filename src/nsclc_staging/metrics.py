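"""Evaluation: confusion counts, sensitivity/specificity/accuracy, AUC,
stratified k-fold cross-validation, and per-stage reporting."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import KFold, StratifiedKFold

from .records import STAGES

__all__ = [
    "ConfusionCounts",
    "confusion",
    "sensitivity",
    "specificity",
    "accuracy",
    "auc",
    "kfold_cv",
    "stagewise_report",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(predictions: Sequence[int], truths: Sequence[int]) -> ConfusionCounts:
    """Standard 2x2 tally of binary predictions against binary truths."""
    p = np.asarray(predictions, dtype=int)
    t = np.asarray(truths, dtype=int)
    if p.shape != t.shape:
        raise ValueError("predictions and truths differ in length")
    return ConfusionCounts(
        tp=int(((p == 1) & (t == 1)).sum()),
        fp=int(((p == 1) & (t == 0)).sum()),
        tn=int(((p == 0) & (t == 0)).sum()),
        fn=int(((p == 0) & (t == 1)).sum()),
    )


def sensitivity(c: ConfusionCounts) -> float:
    """TP / (TP + FN); NaN when no positives were evaluated."""
    denom = c.tp + c.fn
    return c.tp / denom if denom else math.nan


def specificity(c: ConfusionCounts) -> float:
    """TN / (TN + FP); NaN when no negatives were evaluated."""
    denom = c.tn + c.fp
    return c.tn / denom if denom else math.nan


def accuracy(c: ConfusionCounts) -> float:
    """(TP + TN) / total; NaN on an empty tally."""
    return (c.tp + c.tn) / c.total if c.total else math.nan


def auc(scores: Sequence[float], truths: Sequence[int]) -> float:
    """Rank-based (Mann-Whitney) area under the ROC curve.

    Equals the probability that a random positive is scored above a random
    negative, with ties counted one half. Requires both classes present.
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(truths, dtype=int)
    if s.shape != t.shape:
        raise ValueError("scores and truths differ in length")
    n_pos = int((t == 1).sum())
    n_neg = int((t == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(s)
    return float((ranks[t == 1].sum() - n_pos * (n_pos + 1) / 2.0)
                 / (n_pos * n_neg))


def _fold_metrics(c: ConfusionCounts, scores, truths) -> dict:
    row = {
        "sensitivity": sensitivity(c),
        "specificity": specificity(c),
        "accuracy": accuracy(c),
    }
    try:
        row["auc"] = auc(scores, truths)
    except ValueError:
        row["auc"] = math.nan
    return row


def kfold_cv(
    X: np.ndarray,
    y: Sequence[int],
    trainer: Callable[[np.ndarray, np.ndarray], object],
    k: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Seeded stratified k-fold cross-validation of a binary trainer.

    ``trainer(X_train, y_train)`` must return a fitted object exposing
    ``predict_proba`` (positive class in column 1). Folds are stratified
    whenever each class has at least k members (plain shuffled folds
    otherwise). Returns one row per fold plus a ``mean`` row.
    """
    X = np.asarray(X)
    y = np.asarray(y, dtype=int)
    if len(X) < k:
        raise ValueError(f"dataset of {len(X)} samples cannot be split into {k} folds")
    counts = np.bincount(y, minlength=2)
    if counts.min() >= k:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    rows = []
    for fold, (tr, te) in enumerate(splitter.split(X, y)):
        model = trainer(X[tr], y[tr])
        scores = np.asarray(model.predict_proba(X[te]))[:, 1]
        preds = (scores >= 0.5).astype(int)
        row = {"fold": fold, **_fold_metrics(confusion(preds, y[te]), scores, y[te])}
        rows.append(row)
    df = pd.DataFrame(rows).set_index("fold")
    df.loc["mean"] = df.mean()
    return df


def stagewise_report(
    confidences: pd.DataFrame,
    label_sets: Sequence[set],
    labels: Sequence[str] = STAGES,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """One-vs-rest metric row per stage (sensitivity, specificity,
    accuracy, AUC) from per-stage confidences and true label sets."""
    rows = []
    for li in labels:
        scores = confidences[li].to_numpy()
        truths = np.array([int(li in y) for y in label_sets])
        preds = (scores >= threshold).astype(int)
        c = confusion(preds, truths)
        rows.append({"stage": li, **_fold_metrics(c, scores, truths)})
    return pd.DataFrame(rows).set_index("stage")
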