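"""Mutual information, discretization, and greedy mRMR selection."""

import math

import numpy as np
import pytest
from sklearn.metrics import mutual_info_score

import malsite as ms
from malsite.mrmr import DiscretizationScheme, discretize, discretize_matrix


def naive_mrmr(X, y, n, scheme="MID"):
    """Independent brute-force greedy reference implementation."""
    Xd = discretize_matrix(np.asarray(X, dtype=float))
    yd = np.unique(y, return_inverse=True)[1]
    f = Xd.shape[1]
    rel = [ms.mutual_information(Xd[:, j], yd) for j in range(f)]
    selected: list[int] = []
    while len(selected) < n:
        best, best_score = None, -math.inf
        for j in range(f):
            if j in selected:
                continue
            if not selected:
                score = rel[j]
            else:
                red = np.mean([ms.mutual_information(Xd[:, j], Xd[:, k]) for k in selected])
                score = rel[j] - red if scheme == "MID" else rel[j] / max(red, 1e-12)
            if score > best_score + 1e-12:  # strict improvement -> lowest index on ties
                best, best_score = j, score
        selected.append(best)
    return selected


# ---------------------------------------------------------------------------
# discretization
# ---------------------------------------------------------------------------

def test_discretize_constant_column():
    assert set(discretize(np.array([3.5] * 7))) == {0}


def test_discretize_three_state_example():
    # mean 0, population sigma sqrt(200/3) ~ 8.165; alpha=0.5 -> thresholds -/+4.08
    labels = discretize(np.array([-10.0, 0.0, 10.0]), DiscretizationScheme(alpha=0.5))
    assert labels.tolist() == [0, 1, 2]


def test_discretize_integer_passthrough():
    codes = np.array([1.0, 21.0, 9.0, 9.0])
    assert discretize(codes).tolist() == [1, 21, 9, 9]


def test_discretize_equal_frequency():
    x = np.linspace(0, 1, 30) + 0.001 * np.sin(np.arange(30))
    labels = discretize(x, DiscretizationScheme(method="equal-frequency", bins=3))
    assert sorted(np.bincount(labels)) == [10, 10, 10]


# ---------------------------------------------------------------------------
# mutual information
# ---------------------------------------------------------------------------

def test_mi_constant_is_zero():
    x = np.zeros(20, dtype=int)
    y = np.arange(20) % 2
    assert ms.mutual_information(x, y) == 0.0


def test_mi_identical_binary_is_log2():
    y = np.array([0, 1] * 10)
    assert ms.mutual_information(y, y) == pytest.approx(math.log(2), abs=1e-12)


def test_mi_two_by_two_table():
    x = np.array([0, 0, 1, 1])
    y = np.array([0, 0, 1, 1])
    assert ms.mutual_information(x, y) == pytest.approx(math.log(2), abs=1e-12)


def test_mi_symmetry_and_oracle():
    rng = np.random.default_rng(4)
    for _ in range(20):
        x = rng.integers(0, 4, size=60)
        y = rng.integers(0, 3, size=60)
        ours = ms.mutual_information(x, y)
        assert ours == pytest.approx(ms.mutual_information(y, x), abs=1e-12)
        assert ours == pytest.approx(mutual_info_score(x, y), abs=1e-10)
        assert ours >= 0


def test_mi_length_mismatch():
    with pytest.raises(ValueError):
        ms.mutual_information(np.zeros(3), np.zeros(4))


# ---------------------------------------------------------------------------
# mRMR selection
# ---------------------------------------------------------------------------

def test_informative_feature_selected_first():
    y = np.array([0, 1] * 20)
    X = np.zeros((40, 5))
    X[:, 3] = y  # single informative feature among constants
    sel = ms.mrmr_select(X, y, n=2)
    assert sel.indices[0] == 3


def test_duplicate_feature_penalized():
    # two equally noisy, independent copies of the label plus an exact
    # duplicate of the first: after the first is selected, the duplicate's
    # MID score I(f;y) - I(f;f) is strongly negative, so the equally
    # relevant independent feature must be preferred.
    rng = np.random.default_rng(7)
    y = rng.integers(0, 2, size=200)
    noisy1 = np.where(rng.random(200) < 0.1, 1 - y, y).astype(float)
    noisy2 = np.where(rng.random(200) < 0.1, 1 - y, y).astype(float)
    X = np.column_stack([noisy1, noisy1.copy(), noisy2])
    sel = ms.mrmr_select(X, y, n=2, scheme="MID")
    assert sel.indices[0] in (0, 2)
    assert sel.indices[1] != 1  # exact duplicate is never preferred
    assert set(sel.indices) == {0, 2}


@pytest.mark.parametrize("scheme", ["MID", "MIQ"])
def test_matches_bruteforce_oracle(scheme):
    rng = np.random.default_rng(12)
    for _ in range(8):
        n_samp = int(rng.integers(20, 51))
        n_feat = int(rng.integers(3, 9))
        X = rng.integers(0, 3, size=(n_samp, n_feat)).astype(float)
        y = rng.integers(0, 2, size=n_samp)
        n_sel = min(5, n_feat)
        assert ms.mrmr_select(X, y, n_sel, scheme=scheme).indices == naive_mrmr(
            X, y, n_sel, scheme
        )


def test_selection_deterministic(small_dataset):
    _, X, y = small_dataset
    s1 = ms.mrmr_select(X[:, :100], y, n=10)
    s2 = ms.mrmr_select(X[:, :100], y, n=10)
    assert s1.indices == s2.indices and s1.scores == s2.scores


def test_permutation_equivariance():
    rng = np.random.default_rng(3)
    X = rng.integers(0, 3, size=(40, 6)).astype(float)
    y = rng.integers(0, 2, size=40)
    base = ms.mrmr_select(X, y, n=4).indices
    perm = rng.permutation(6)
    permuted = ms.mrmr_select(X[:, perm], y, n=4).indices
    assert [perm[j] for j in permuted] == base


def test_n_larger_than_features_selects_all():
    X = np.random.default_rng(0).integers(0, 2, size=(30, 4)).astype(float)
    y = np.arange(30) % 2
    sel = ms.mrmr_select(X, y, n=10)
    assert sorted(sel.indices) == [0, 1, 2, 3]


def test_selection_report_shape(small_dataset):
    _, X, y = small_dataset
    sel = ms.mrmr_select(X[:, :50], y, n=5)
    report = ms.selection_report(sel, [f"f{i}" for i in range(50)])
    assert list(report.columns) == [
        "rank", "feature_index", "feature", "relevance", "redundancy", "score",
    ]
    assert len(report) == 5 and report["rank"].tolist() == [1, 2, 3, 4, 5]
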