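"""Classification metrics, ROC/AUC and the shared cross-validation protocol.

Threshold metrics are computed from confusion counts with the standard
formulas:

    F1  = 2*TP / (2*TP + FP + FN)
    Sn  = TP / (TP + FN)            (sensitivity / recall)
    Sp  = TN / (TN + FP)            (specificity)
    ACC = (TP + TN) / n
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

A metric whose denominator vanishes is reported as 0 and flagged. AUC is the
area under the ROC curve by trapezoidal integration, equivalent to the
normalized Mann-Whitney U statistic (ties get half credit).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionCounts":
        y_true = np.asarray(y_true, dtype=int)
        y_pred = np.asarray(y_pred, dtype=int)
        return cls(
            tp=int(np.sum((y_true == 1) & (y_pred == 1))),
            fp=int(np.sum((y_true == 0) & (y_pred == 1))),
            tn=int(np.sum((y_true == 0) & (y_pred == 0))),
            fn=int(np.sum((y_true == 1) & (y_pred == 0))),
        )


@dataclass
class MetricsReport:
    F1: float
    Sn: float
    Sp: float
    MCC: float
    ACC: float
    AUC: float = float("nan")
    roc_points: list[tuple[float, float]] = field(default_factory=list)
    undefined: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        out = {k: getattr(self, k) for k in ("ACC", "Sn", "Sp", "MCC", "AUC", "F1")}
        if self.undefined:
            out["undefined"] = list(self.undefined)
        return out


def _safe_div(num: float, den: float, name: str, flags: list[str]) -> float:
    if den == 0:
        flags.append(name)
        return 0.0
    return num / den


def metrics(counts: ConfusionCounts) -> MetricsReport:
    """Threshold metrics from confusion counts (AUC left NaN here)."""
    if counts.n == 0:
        raise ValueError("cannot compute metrics on zero evaluated samples")
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    flags: list[str] = []
    f1 = _safe_div(2 * tp, 2 * tp + fp + fn, "F1", flags)
    sn = _safe_div(tp, tp + fn, "Sn", flags)
    sp = _safe_div(tn, tn + fp, "Sp", flags)
    acc = (tp + tn) / counts.n
    mcc_den = math.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = _safe_div(tp * tn - fp * fn, mcc_den, "MCC", flags)
    return MetricsReport(F1=f1, Sn=sn, Sp=sp, MCC=mcc, ACC=acc, undefined=flags)


def auc(scores, labels) -> tuple[float, list[tuple[float, float]]]:
    """ROC AUC via trapezoidal integration over all score thresholds."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(set(labels.tolist())) < 2:
        raise ValueError("AUC undefined: only one class present")
    fpr, tpr, _ = roc_curve(labels, scores)
    return float(np.trapezoid(tpr, fpr)), list(zip(fpr.tolist(), tpr.tolist()))


def evaluate(y_true, scores, threshold: float = 0.5) -> MetricsReport:
    """Full report: threshold metrics at p >= threshold plus AUC.

    Ties at the threshold are classed positive.
    """
    scores = np.asarray(scores, dtype=float)
    y_pred = (scores >= threshold).astype(int)
    report = metrics(ConfusionCounts.from_predictions(y_true, y_pred))
    try:
        report.AUC, report.roc_points = auc(scores, y_true)
    except ValueError:
        report.undefined.append("AUC")
        report.AUC = 0.0
    return report


def stratified_folds(y, k: int, seed: int) -> list[np.ndarray]:
    """Seeded stratified fold assignment, shared across compared models.

    Returns a list of test-index arrays; refolds once with a perturbed seed
    if any fold lacks a class, then raises.
    """
    y = np.asarray(y, dtype=int)
    if k < 2:
        raise ValueError("need at least 2 folds")
    for attempt_seed in (seed, seed + 1):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=attempt_seed)
        folds = [test for _train, test in skf.split(np.zeros(len(y)), y)]
        if all(len(set(y[f].tolist())) == 2 for f in folds):
            return folds
    raise ValueError("stratified folding left a fold without both classes")


def cross_validate(fit_predict, X, y, k: int = 10, seed: int = 42,
                   threshold: float = 0.5) -> dict:
    """k-fold CV of an arbitrary fit/score callable.

    ``fit_predict(X_train, y_train, X_test) -> scores`` is called once per
    fold. Pooled metrics come from summed confusion counts plus AUC over the
    pooled out-of-fold scores (micro); per-fold reports are also returned.
    """
    y = np.asarray(y, dtype=int)
    folds = stratified_folds(y, k, seed)
    all_idx = np.arange(len(y))
    oof_scores = np.full(len(y), np.nan)
    fold_reports = []
    for test_idx in folds:
        train_idx = np.setdiff1d(all_idx, test_idx)
        scores = np.asarray(fit_predict(_take(X, train_idx), y[train_idx], _take(X, test_idx)))
        oof_scores[test_idx] = scores
        fold_reports.append(evaluate(y[test_idx], scores, threshold))
    pooled = evaluate(y, oof_scores, threshold)
    mean_report = {
        k_: float(np.mean([getattr(r, k_) for r in fold_reports]))
        for k_ in ("ACC", "Sn", "Sp", "MCC", "AUC", "F1")
    }
    return {
        "pooled": pooled,
        "per_fold": fold_reports,
        "fold_mean": mean_report,
        "oof_scores": oof_scores,
        "folds": folds,
    }


def _take(X, idx):
    if hasattr(X, "iloc"):
        return X.iloc[idx]
    return np.asarray(X)[idx]


def comparison_table(reports: dict[str, MetricsReport]):
    """Model-by-metric table (rows = models; ACC, Sn, Sp, MCC, AUC, F1)."""
    import pandas as pd

    return pd.DataFrame(
        {name: rep.to_dict() for name, rep in reports.items()}
    ).T[["ACC", "Sn", "Sp", "MCC", "AUC", "F1"]]
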