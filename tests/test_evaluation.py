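"""Confusion metrics, ROC/AUC, and cross-validation protocols."""

import math

import numpy as np
import pytest
from sklearn.metrics import matthews_corrcoef, roc_auc_score
from sklearn.model_selection import StratifiedKFold

import malsite as ms
from malsite.evaluation import _derived_seeds


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def test_perfect_prediction_metrics():
    m = ms.compute_metrics(ms.ConfusionCounts(tp=50, tn=50, fp=0, fn=0))
    assert (m.sn, m.sp, m.ac, m.mcc) == (1.0, 1.0, 1.0, 1.0)
    assert not m.undefined


def test_all_positive_calls_on_balanced_set():
    m = ms.compute_metrics(ms.ConfusionCounts(tp=10, tn=0, fp=10, fn=0))
    assert m.sn == 1.0 and m.sp == 0.0 and m.ac == 0.5
    assert m.mcc == 0.0 and "mcc" in m.undefined


def test_hand_evaluated_table():
    m = ms.compute_metrics(ms.ConfusionCounts(tp=3, fn=1, tn=2, fp=2))
    assert m.sn == pytest.approx(0.75)
    assert m.sp == pytest.approx(0.5)
    assert m.ac == pytest.approx(0.625)
    assert m.mcc == pytest.approx(4 / math.sqrt(5 * 4 * 4 * 3), abs=1e-10)


def test_negative_counts_rejected():
    with pytest.raises(ValueError):
        ms.ConfusionCounts(tp=-1, tn=0, fp=0, fn=0)


def test_metrics_against_sklearn_on_random_tables():
    rng = np.random.default_rng(17)
    for _ in range(1000):
        tp, tn, fp, fn = (int(v) for v in rng.integers(0, 30, size=4))
        if tp + tn + fp + fn == 0:
            continue
        m = ms.compute_metrics(ms.ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn))
        y_true = [1] * tp + [0] * tn + [0] * fp + [1] * fn
        y_pred = [1] * tp + [0] * tn + [1] * fp + [0] * fn
        assert m.ac == pytest.approx(np.mean(np.array(y_true) == np.array(y_pred)))
        if "mcc" not in m.undefined:
            assert m.mcc == pytest.approx(matthews_corrcoef(y_true, y_pred), abs=1e-10)
        if tp + fn:
            assert m.sn == pytest.approx(tp / (tp + fn))
        if tn + fp:
            assert m.sp == pytest.approx(tn / (tn + fp))


def test_confusion_from_scores_tie_is_negative():
    counts = ms.confusion_from_scores(np.array([0.5, 0.6]), np.array([1, 1]), theta=0.5)
    assert counts.tp == 1 and counts.fn == 1


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

def test_auc_examples():
    assert ms.roc_auc(np.array([0.9, 0.8, 0.1, 0.2]), np.array([1, 1, 0, 0]))[1] == 1.0
    assert ms.roc_auc(np.array([0.5] * 6), np.array([1, 0, 1, 0, 1, 0]))[1] == 0.5
    _, auc = ms.roc_auc(np.array([0.9, 0.8, 0.4, 0.3]), np.array([1, 0, 1, 0]))
    assert auc == pytest.approx(0.75)


def test_auc_sweep_equals_rank_statistic():
    rng = np.random.default_rng(23)
    for _ in range(50):
        n = int(rng.integers(4, 200))
        scores = np.round(rng.random(n), 2)  # rounding forces ties
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            continue
        _, sweep = ms.roc_auc(scores, labels)
        rank = ms.auc_rank(scores, labels)
        assert abs(sweep - rank) < 1e-12
        assert sweep == pytest.approx(roc_auc_score(labels, scores), abs=1e-10)


def test_roc_endpoints_and_one_class_error():
    fpr, tpr = ms.roc_points(np.array([0.2, 0.9]), np.array([0, 1]))
    assert fpr[0] == tpr[0] == 0.0 and fpr[-1] == tpr[-1] == 1.0
    with pytest.raises(ValueError):
        ms.roc_auc(np.array([0.1, 0.2]), np.array([1, 1]))


def test_vertical_average_roc_grid():
    curves = [
        (np.array([0.0, 1.0]), np.array([0.0, 1.0])),
        (np.array([0.0, 0.0, 1.0]), np.array([0.0, 1.0, 1.0])),
    ]
    grid, mean_tpr = ms.vertical_average_roc(curves, n_grid=11)
    assert grid.shape == mean_tpr.shape == (11,)
    assert mean_tpr[0] == pytest.approx(0.5)  # (0 + 1) / 2 at FPR 0


# ---------------------------------------------------------------------------
# cross-validation protocols
# ---------------------------------------------------------------------------

def test_loo_produces_one_score_per_sample(fast_factory):
    ds = ms.generate_windows(ms.SyntheticSpec(n_positive=8, n_negative=16, seed=9))
    X = ms.encode_matrix(ds.windows)
    y = np.array([w.label for w in ds.windows])
    res = ms.run_loo(fast_factory, X, y)
    assert res.scores.shape == (24,)
    assert res.metrics.auc is not None


def test_kfold_with_k_equal_n_covers_like_loo(fast_factory):
    ds = ms.generate_windows(ms.SyntheticSpec(n_positive=6, n_negative=6, seed=9))
    X = ms.encode_matrix(ds.windows)
    y = np.array([w.label for w in ds.windows])
    plan = ms.CVPlan(scheme="k-fold", k=12, repeats=1, stratified=False, seed=0)
    res = ms.run_kfold(fast_factory, X, y, plan)
    assert len(res.pooled_aucs) == 1  # every sample held out exactly once


def test_fold_partitions_are_exact_and_stratified(small_dataset):
    _, X, y = small_dataset
    for seed in _derived_seeds(3, 2):
        skf = StratifiedKFold(n_splits=6, shuffle=True, random_state=seed)
        seen = np.zeros(y.size, dtype=int)
        ratios = []
        for _, test_idx in skf.split(X, y):
            seen[test_idx] += 1
            ratios.append(y[test_idx].sum())
        assert np.all(seen == 1)
        assert max(ratios) - min(ratios) <= 1  # class balance within +/- 1


def test_derived_seeds_deterministic_and_bounded():
    a = _derived_seeds(42, 5)
    assert a == _derived_seeds(42, 5)
    assert all(0 <= s < 2**31 for s in a)
    assert a != _derived_seeds(43, 5)


def test_kfold_repeats_reduce_spread(fast_factory, small_dataset):
    _, X, y = small_dataset
    plan1 = ms.CVPlan(scheme="k-fold", k=6, repeats=4, seed=7)
    res = ms.run_kfold(fast_factory, X, y, plan1)
    singles = np.array(res.pooled_aucs)
    # the mean over repeats is less variable than individual repeats by
    # construction; check the repeat AUCs actually differ (reshuffling works)
    assert len(set(np.round(singles, 6))) > 1
    assert res.std_auc < (singles.max() - singles.min() + 1e-9)


def test_kfold_rejects_k_larger_than_n(fast_factory):
    X = np.zeros((4, 3))
    y = np.array([0, 1, 0, 1])
    with pytest.raises(ValueError):
        ms.run_kfold(fast_factory, X, y, ms.CVPlan(k=5, repeats=1))


def test_metrics_to_dict_serializable(small_dataset, fast_factory):
    _, X, y = small_dataset
    res = ms.run_kfold(fast_factory, X, y, ms.CVPlan(k=4, repeats=1, seed=0))
    d = ms.evaluation.metrics_to_dict(res.mean_metrics)
    assert set(d) >= {"sn", "sp", "ac", "mcc", "auc"}
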