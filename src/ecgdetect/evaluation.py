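"""Stratified cross-validation, confusion matrices and the metric suite.

Metrics per confusion matrix: overall accuracy (OA), error rate (ER),
good detection ratio (GDR), F1 score and Matthews correlation
coefficient (MCC), with OA/ER/GDR/F1 reported as percentages rounded
half-up to two decimals and MCC to four; the arrhythmia class is always
the positive class.  Mean squared error (MSE) monitors training against
0/1-coded targets.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
import math

import numpy as np
from sklearn.model_selection import StratifiedKFold


@dataclass
class FoldPlan:
    K: int
    test_indices: list[np.ndarray]
    seed: int


@dataclass
class ConfusionMatrix:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        for name in ("TP", "TN", "FP", "FN"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"{name} must be a non-negative integer, got {v}")
            setattr(self, name, int(v))

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.TP + other.TP, self.TN + other.TN,
            self.FP + other.FP, self.FN + other.FN,
        )


@dataclass
class MetricsRecord:
    OA: float
    ER: float
    GDR: float
    F1: float
    MCC: float
    MSE: float | None = None
    mcc_degenerate: bool = False

    def as_dict(self) -> dict:
        d = {"OA": self.OA, "ER": self.ER, "GDR": self.GDR,
             "F1": self.F1, "MCC": self.MCC}
        if self.MSE is not None:
            d["MSE"] = self.MSE
        return d


def make_folds(labels, K: int = 10, seed: int = 0) -> FoldPlan:
    """Stratified K-fold partition: epochs of each class are spread
    across folds as evenly as possible (per-class counts differ by at
    most one between folds)."""
    y = np.asarray(labels)
    if K < 2:
        raise ValueError("K must be >= 2")
    if K == len(y):
        # degenerate stratification: leave-one-out
        return FoldPlan(K=K, test_indices=[np.array([i]) for i in range(K)],
                        seed=seed)
    classes, counts = np.unique(y, return_counts=True)
    small = classes[counts < K]
    if len(small):
        raise ValueError(
            f"classes {small.tolist()} have fewer than K={K} members; "
            "stratified folding is impossible"
        )
    skf = StratifiedKFold(n_splits=K, shuffle=True, random_state=seed)
    test_indices = [test for _, test in skf.split(np.zeros(len(y)), y)]
    return FoldPlan(K=K, test_indices=test_indices, seed=seed)


def mse(observed, target) -> float:
    """(1/M) * sum (G_k - S_l)^2 between observed and target sequences."""
    g = np.asarray(observed, dtype=float).ravel()
    s = np.asarray(target, dtype=float).ravel()
    if len(g) != len(s):
        raise ValueError(f"length mismatch: {len(g)} observed vs {len(s)} target")
    if len(g) == 0:
        raise ValueError("sequences must be non-empty")
    return float(np.mean((g - s) ** 2))


def confusion(true_labels, predicted_labels, positive_class=1) -> ConfusionMatrix:
    """2x2 confusion counts with the arrhythmia class as positive."""
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if len(t) != len(p):
        raise ValueError("label sequences differ in length")
    seen = set(np.unique(t)) | set(np.unique(p))
    allowed = {positive_class} | (seen - {positive_class})
    if len(allowed - {positive_class}) > 1:
        raise ValueError(f"labels are not binary: {sorted(map(str, seen))}")
    tp = int(np.sum((t == positive_class) & (p == positive_class)))
    tn = int(np.sum((t != positive_class) & (p != positive_class)))
    fp = int(np.sum((t != positive_class) & (p == positive_class)))
    fn = int(np.sum((t == positive_class) & (p != positive_class)))
    return ConfusionMatrix(tp, tn, fp, fn)


def _round_half_up(value: Fraction | float, places: int) -> float:
    if isinstance(value, Fraction):
        dec = Decimal(value.numerator) / Decimal(value.denominator)
    else:
        dec = Decimal(repr(float(value)))
    q = Decimal(1).scaleb(-places)
    return float(dec.quantize(q, rounding=ROUND_HALF_UP))


def metrics_from_confusion(cm: ConfusionMatrix) -> MetricsRecord:
    """OA, ER, GDR, F1 (percent, 2 decimals) and MCC (4 decimals) from a
    confusion matrix, computed in exact rational arithmetic before the
    final rounding.

    OA  = (TP+TN)/(TP+TN+FP+FN) * 100
    ER  = (FP+FN)/(TP+TN+FP+FN) * 100
    GDR = ((TP+TN)-FP)/((TP+TN)+FN) * 100
    F1  = 2TP/(2TP+FP+FN) * 100
    MCC = (TP*TN - FP*FN)/sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

    A zero MCC denominator is reported as MCC 0 with the degenerate flag.
    """
    tp, tn, fp, fn = cm.TP, cm.TN, cm.FP, cm.FN
    total = cm.total
    if total == 0:
        raise ValueError("empty confusion matrix")
    oa = Fraction(100 * (tp + tn), total)
    er = Fraction(100 * (fp + fn), total)
    gdr_den = (tp + tn) + fn
    gdr = Fraction(100 * ((tp + tn) - fp), gdr_den) if gdr_den else Fraction(0)
    f1 = Fraction(200 * tp, 2 * tp + fp + fn) if (2 * tp + fp + fn) else Fraction(0)
    den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    degenerate = den == 0
    if degenerate:
        mcc_val = 0.0
    else:
        mcc_val = (tp * tn - fp * fn) / math.sqrt(den)
    return MetricsRecord(
        OA=_round_half_up(oa, 2),
        ER=_round_half_up(er, 2),
        GDR=_round_half_up(gdr, 2),
        F1=_round_half_up(f1, 2),
        MCC=_round_half_up(mcc_val, 4),
        mcc_degenerate=degenerate,
    )


def cross_validated_error(fitter, data, labels, K: int = 10, seed: int = 0) -> float:
    """Pooled misclassification rate of ``fitter(x_train, y_train)``
    over a stratified K-fold plan."""
    x = np.asarray(data, dtype=float)
    y = np.asarray(labels).astype(int)
    plan = make_folds(y, K, seed)
    wrong = 0
    for test in plan.test_indices:
        mask = np.zeros(len(y), dtype=bool)
        mask[test] = True
        model = fitter(x[~mask], y[~mask])
        _, pred = model.predict(x[mask])
        wrong += int(np.sum(pred != y[mask]))
    return wrong / len(y)


@dataclass
class EvaluationResult:
    fold_confusions: list[ConfusionMatrix]
    pooled: ConfusionMatrix
    averaged: ConfusionMatrix
    metrics: MetricsRecord
    mse_value: float


def evaluate_classifier(
    fitter, data, labels, K: int = 10, seed: int = 0
) -> EvaluationResult:
    """K-fold evaluation of one classifier family.

    Per fold: train on K-1 parts, predict the held-out part.  The pooled
    confusion over all folds drives the metric suite; the fold-averaged
    matrix (rounded half-up to integers) is also reported, and MSE
    compares the pooled continuous scores against the 0/1-coded labels.
    """
    x = np.asarray(data, dtype=float)
    y = np.asarray(labels).astype(int)
    plan = make_folds(y, K, seed)
    folds = []
    scores = np.empty(len(y))
    preds = np.empty(len(y), dtype=int)
    for test in plan.test_indices:
        mask = np.zeros(len(y), dtype=bool)
        mask[test] = True
        model = fitter(x[~mask], y[~mask])
        s, p = model.predict(x[mask])
        scores[mask], preds[mask] = s, p
        folds.append(confusion(y[mask], p))
    pooled = folds[0]
    for cm in folds[1:]:
        pooled = pooled + cm
    averaged = ConfusionMatrix(
        *(
            int(_round_half_up(sum(getattr(c, f) for c in folds) / len(folds), 0))
            for f in ("TP", "TN", "FP", "FN")
        )
    )
    rec = metrics_from_confusion(pooled)
    # scores are mapped through the hard decision for MSE comparability
    rec.MSE = mse(preds, y)
    return EvaluationResult(folds, pooled, averaged, rec, rec.MSE)
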