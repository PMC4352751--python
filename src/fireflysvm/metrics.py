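"""Classification metrics and the stratified 5-fold protocol.

Everything is computed from binary confusion counts (TP/TN/FP/FN): the
correct-classification ratio (CCR, %), the Matthews correlation
coefficient (MCC, in [-1, 1]), and the diagnostic panel of sensitivity,
specificity, false-negative rate, accuracy, Youden's index and F-score,
all reported in percent to match clinical-reporting convention.
"""

from __future__ import annotations

import math
from typing import Callable

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .types import ConfusionCounts, Dataset

__all__ = [
    "confusion_counts",
    "ccr",
    "mcc",
    "binary_panel",
    "youden_index",
    "stratified_kfold",
    "cross_validate",
]


def confusion_counts(y_true: np.ndarray, y_pred: np.ndarray, positive=1) -> ConfusionCounts:
    """Tally TP/TN/FP/FN treating ``positive`` as the positive label."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors differ in length")
    pos_t = y_true == positive
    pos_p = y_pred == positive
    return ConfusionCounts(
        tp=int(np.sum(pos_t & pos_p)),
        tn=int(np.sum(~pos_t & ~pos_p)),
        fp=int(np.sum(~pos_t & pos_p)),
        fn=int(np.sum(pos_t & ~pos_p)),
    )


def ccr(y_true, y_pred=None) -> float:
    """Correct classification ratio in percent.

    Accepts either a pair of label vectors or a ConfusionCounts.
    """
    if isinstance(y_true, ConfusionCounts):
        counts = y_true
        if counts.total == 0:
            raise ValueError("empty confusion counts")
        return 100.0 * (counts.tp + counts.tn) / counts.total
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise ValueError("need at least one sample")
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors differ in length")
    return 100.0 * float(np.mean(y_true == y_pred))


def mcc(counts: ConfusionCounts) -> float:
    """Matthews correlation coefficient in [-1, 1].

    +1 is perfect prediction, 0 no better than chance, -1 total
    disagreement.  Any zero factor in the denominator yields 0 by
    convention.
    """
    if counts.total == 0:
        raise ValueError("empty confusion counts")
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def youden_index(sensitivity: float, specificity: float) -> float:
    """Youden's index in percentage points: sensitivity + specificity - 100."""
    return sensitivity + specificity - 100.0


def binary_panel(counts: ConfusionCounts) -> dict[str, float | None]:
    """The diagnostic panel (all in percent).

    A rate whose denominator is zero is reported as None (undefined)
    rather than raising.
    """
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    sens = 100.0 * tp / (tp + fn) if tp + fn > 0 else None
    spec = 100.0 * tn / (tn + fp) if tn + fp > 0 else None
    fnr = 100.0 * fn / (tp + fn) if tp + fn > 0 else None
    acc = 100.0 * (tp + tn) / counts.total if counts.total > 0 else None
    prec = 100.0 * tp / (tp + fp) if tp + fp > 0 else None
    youden = youden_index(sens, spec) if sens is not None and spec is not None else None
    if prec is not None and sens is not None and prec + sens > 0:
        f_score = 2.0 * prec * sens / (prec + sens)
    else:
        f_score = None
    return {
        "sensitivity": sens,
        "specificity": spec,
        "fnr": fnr,
        "accuracy": acc,
        "youden": youden,
        "f_score": f_score,
    }


def stratified_kfold(data: Dataset, k: int = 5, seed: int = 0) -> np.ndarray:
    """Stratified fold assignment: returns fold indices in {1..k}, one per
    sample; per-class counts across folds differ by at most one."""
    classes, counts = np.unique(data.y, return_counts=True)
    if counts.min() < k:
        raise ValueError(
            f"every class needs at least k={k} samples; smallest has {counts.min()}"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.zeros(data.n, dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(data.X, data.y), start=1):
        assignment[test_idx] = fold
    return assignment


def cross_validate(
    trainer: Callable[[Dataset], Callable[[np.ndarray], np.ndarray]],
    data: Dataset,
    folds: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """k-fold cross-validation of an arbitrary trainer.

    ``trainer`` maps a training Dataset to a predict function (features ->
    labels).  Returns one row per fold (fold, n_test, ccr) plus a summary
    row with the mean and the across-fold sample standard deviation
    (ddof=1) of the fold CCRs.
    """
    assignment = stratified_kfold(data, k=folds, seed=seed)
    rows = []
    for fold in range(1, folds + 1):
        test = assignment == fold
        train = ~test
        predict_fn = trainer(Dataset(data.X[train], data.y[train], scaled=data.scaled))
        pred = np.asarray(predict_fn(data.X[test]))
        rows.append(
            {"fold": fold, "n_test": int(test.sum()),
             "ccr": ccr(data.y[test], pred)}
        )
    fold_ccrs = np.array([r["ccr"] for r in rows])
    rows.append(
        {"fold": "mean±sd", "n_test": data.n,
         "ccr": float(fold_ccrs.mean()),
         "ccr_sd": float(fold_ccrs.std(ddof=1))}
    )
    return pd.DataFrame(rows)
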