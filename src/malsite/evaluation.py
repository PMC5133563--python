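"""Cross-validation protocols, confusion-matrix metrics, and ROC/AUC.

The evaluation protocol mirrors common practice in PTM site prediction:
leave-one-out (LOO) validation and stratified k-fold cross-validation (k =
6, 8, 10) repeated with reshuffled folds, averaging over repeats.  For every
held-out sample the *entire* pipeline — constant-feature mask, mRMR
selection, optional scaler, SVM — is refit on the remaining data, so no
selection leakage inflates the scores.

Metrics are the four confusion-matrix measures standard in the field
(sensitivity Sn, specificity Sp, accuracy Ac, Matthews correlation
coefficient MCC) plus the ROC curve and its area.  AUC is computed by
trapezoidal integration of the threshold-sweep ROC, which equals the
rank-based Mann-Whitney statistic (ties counted 1/2); both routes are
implemented and kept in agreement.

Per repeat, fold scores are pooled into a single ROC/AUC; the mean of
per-fold AUCs is also reported.  Repeat-averaged ROC curves use vertical
averaging on a fixed 101-point FPR grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import KFold, StratifiedKFold

from .model import Pipeline


# ---------------------------------------------------------------------------
# Confusion counts and closed-form metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN counts of a binary evaluation."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricSet:
    """Sn/Sp/Ac/MCC with explicit undefined markers.

    A metric whose denominator is zero is NaN and listed in ``undefined``;
    exception: MCC is reported as 0.0 (with the annotation) by the common
    convention for degenerate tables.
    """

    sn: float
    sp: float
    ac: float
    mcc: float
    undefined: tuple[str, ...] = ()
    auc: float | None = None
    roc: tuple[np.ndarray, np.ndarray] | None = None


def confusion_from_scores(
    scores: np.ndarray, labels: np.ndarray, theta: float = 0.5
) -> ConfusionCounts:
    """Count TP/TN/FP/FN calling positive iff score > theta."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    calls = scores > theta
    pos = labels == 1
    return ConfusionCounts(
        tp=int((calls & pos).sum()),
        tn=int((~calls & ~pos).sum()),
        fp=int((calls & ~pos).sum()),
        fn=int((~calls & pos).sum()),
    )


def compute_metrics(counts: ConfusionCounts) -> MetricSet:
    """Sn, Sp, Ac, MCC from the closed forms.

    Sn = TP/(TP+FN); Sp = TN/(TN+FP); Ac = (TP+TN)/total;
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)).
    """
    if counts.total == 0:
        raise ValueError("cannot compute metrics on zero samples")
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    undefined: list[str] = []

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            undefined.append(name)
            return float("nan")
        return num / den

    sn = ratio(tp, tp + fn, "sn")
    sp = ratio(tn, tn + fp, "sp")
    ac = (tp + tn) / counts.total
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        undefined.append("mcc")
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / math.sqrt(denom)
    return MetricSet(sn=sn, sp=sp, ac=ac, mcc=mcc, undefined=tuple(undefined))


# ---------------------------------------------------------------------------
# ROC and AUC
# ---------------------------------------------------------------------------

def _check_two_classes(labels: np.ndarray) -> None:
    labels = np.asarray(labels)
    if not ((labels == 1).any() and (labels == 0).any()):
        raise ValueError("ROC/AUC requires both classes to be present")


def roc_points(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """ROC curve by threshold sweep over the unique scores.

    Returns (fpr, tpr) arrays running from (0, 0) to (1, 1).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    _check_two_classes(labels)
    order = np.argsort(-scores, kind="stable")
    s, l = scores[order], labels[order]
    n_pos, n_neg = int((l == 1).sum()), int((l == 0).sum())
    tp = np.cumsum(l == 1)
    fp = np.cumsum(l == 0)
    # keep the last point of each tied-score run
    last_of_run = np.append(s[1:] != s[:-1], True)
    tpr = np.concatenate([[0.0], tp[last_of_run] / n_pos])
    fpr = np.concatenate([[0.0], fp[last_of_run] / n_neg])
    return fpr, tpr


def auc_trapezoid(fpr: np.ndarray, tpr: np.ndarray) -> float:
    return float(np.trapezoid(tpr, fpr))


def auc_rank(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the normalized Mann-Whitney statistic (ties counted 1/2)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    _check_two_classes(labels)
    n_pos = int((labels == 1).sum())
    n_neg = labels.size - n_pos
    ranks = rankdata(scores)  # average ranks on ties
    rank_sum = ranks[labels == 1].sum()
    return float((rank_sum - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> tuple[tuple[np.ndarray, np.ndarray], float]:
    """Threshold-sweep ROC and its trapezoidal AUC."""
    fpr, tpr = roc_points(scores, labels)
    return (fpr, tpr), auc_trapezoid(fpr, tpr)


def vertical_average_roc(
    curves: Sequence[tuple[np.ndarray, np.ndarray]], n_grid: int = 101
) -> tuple[np.ndarray, np.ndarray]:
    """Average ROC curves by interpolating TPR on a fixed FPR grid."""
    grid = np.linspace(0, 1, n_grid)
    tprs = [np.interp(grid, fpr, tpr) for fpr, tpr in curves]
    return grid, np.mean(tprs, axis=0)


# ---------------------------------------------------------------------------
# Cross-validation protocols
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CVPlan:
    """Scheme and seeding of a cross-validation run."""

    scheme: str = "k-fold"  # "loo" or "k-fold"
    k: int = 6
    repeats: int = 30
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scheme not in ("loo", "k-fold"):
            raise ValueError(f"unknown CV scheme {self.scheme!r}")
        if self.scheme == "k-fold" and self.k < 2:
            raise ValueError("k must be >= 2")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


PipelineFactory = Callable[[int], Pipeline]


def _derived_seeds(master: int, n: int) -> list[int]:
    """Deterministic per-repeat seeds below 2**31 derived from one master."""
    state = np.random.SeedSequence(master).generate_state(n)
    return [int(s % (2**31)) for s in state]


@dataclass
class LOOResult:
    scores: np.ndarray
    labels: np.ndarray
    metrics: MetricSet


def run_loo(
    factory: PipelineFactory,
    X: np.ndarray,
    y: np.ndarray,
    theta: float = 0.5,
    seed: int = 0,
) -> LOOResult:
    """Leave-one-out validation with the full chain refit per held-out sample.

    The n held-out probabilities are pooled into one ROC/AUC and thresholded
    at ``theta`` for the confusion metrics.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if y.size < 2 or len(np.unique(y)) < 2:
        raise ValueError("LOO requires >= 2 samples with both classes")
    scores = np.empty(y.size)
    idx = np.arange(y.size)
    for i in range(y.size):
        train_idx = idx != i
        pipe = factory(seed).fit(X[train_idx], y[train_idx])
        scores[i] = pipe.predict_probability(X[i : i + 1])[0]
    roc, auc = roc_auc(scores, y)
    metrics = compute_metrics(confusion_from_scores(scores, y, theta))
    metrics = MetricSet(**{**metrics.__dict__, "auc": auc, "roc": roc})
    return LOOResult(scores=scores, labels=y, metrics=metrics)


@dataclass
class KFoldResult:
    plan: CVPlan
    pooled_aucs: list[float]          # one pooled AUC per repeat
    per_fold_aucs: list[list[float]]  # fold AUCs per repeat
    mean_metrics: MetricSet           # averaged over repeats (pooled per repeat)
    mean_roc: tuple[np.ndarray, np.ndarray]

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.pooled_aucs))

    @property
    def std_auc(self) -> float:
        return float(np.std(self.pooled_aucs))

    @property
    def mean_per_fold_auc(self) -> float:
        return float(np.mean([a for rep in self.per_fold_aucs for a in rep]))


def run_kfold(
    factory: PipelineFactory,
    X: np.ndarray,
    y: np.ndarray,
    plan: CVPlan,
    theta: float = 0.5,
) -> KFoldResult:
    """Repeated stratified k-fold cross-validation.

    Per repeat: folds are reshuffled with a derived seed, scores are pooled
    across folds into one AUC and one confusion table at ``theta``.  Means
    and standard deviations are taken over repeats; per-fold AUCs are also
    recorded (the repeat average of both is reported because protocols in
    the literature differ on which is meant by "average AUC").
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if plan.k > y.size:
        raise ValueError(f"k={plan.k} exceeds the number of samples {y.size}")
    pooled_aucs: list[float] = []
    per_fold: list[list[float]] = []
    metric_rows: list[MetricSet] = []
    curves: list[tuple[np.ndarray, np.ndarray]] = []
    for rep_seed in _derived_seeds(plan.seed, plan.repeats):
        if plan.stratified:
            skf = StratifiedKFold(n_splits=plan.k, shuffle=True, random_state=rep_seed)
        else:
            skf = KFold(n_splits=plan.k, shuffle=True, random_state=rep_seed)
        scores = np.empty(y.size)
        fold_aucs: list[float] = []
        for train_idx, test_idx in skf.split(X, y):
            pipe = factory(rep_seed).fit(X[train_idx], y[train_idx])
            fold_scores = pipe.predict_probability(X[test_idx])
            scores[test_idx] = fold_scores
            if len(np.unique(y[test_idx])) == 2:
                fold_aucs.append(auc_rank(fold_scores, y[test_idx]))
        roc, auc = roc_auc(scores, y)
        pooled_aucs.append(auc)
        per_fold.append(fold_aucs)
        curves.append(roc)
        metric_rows.append(compute_metrics(confusion_from_scores(scores, y, theta)))

    def _mean(attr: str) -> float:
        vals = [getattr(m, attr) for m in metric_rows]
        return float(np.nanmean(vals)) if not all(np.isnan(v) for v in vals) else float("nan")

    undefined = tuple(sorted({u for m in metric_rows for u in m.undefined}))
    mean_metrics = MetricSet(
        sn=_mean("sn"),
        sp=_mean("sp"),
        ac=_mean("ac"),
        mcc=_mean("mcc"),
        undefined=undefined,
        auc=float(np.mean(pooled_aucs)),
        roc=vertical_average_roc(curves),
    )
    return KFoldResult(
        plan=plan,
        pooled_aucs=pooled_aucs,
        per_fold_aucs=per_fold,
        mean_metrics=mean_metrics,
        mean_roc=mean_metrics.roc,
    )


def metrics_to_dict(m: MetricSet) -> dict:
    """JSON-able summary of a MetricSet (ROC points omitted)."""
    out = {
        "sn": None if math.isnan(m.sn) else round(m.sn, 6),
        "sp": None if math.isnan(m.sp) else round(m.sp, 6),
        "ac": None if math.isnan(m.ac) else round(m.ac, 6),
        "mcc": round(m.mcc, 6),
        "undefined": list(m.undefined),
    }
    if m.auc is not None:
        out["auc"] = round(m.auc, 6)
    return out
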