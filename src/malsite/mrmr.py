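"""Minimum-Redundancy-Maximum-Relevance feature selection.

mRMR greedily builds an ordered feature subset: the first feature maximizes
the mutual information I(f; y) with the class label (relevance); each later
step picks the candidate maximizing

* MID (difference form):  I(f; y) - mean_{s in S} I(f; s)
* MIQ (quotient form):    I(f; y) / mean_{s in S} I(f; s)

where S is the already-selected set (redundancy term).  Mutual information
is the plug-in estimate on empirical joint distributions, in nats, which
requires discrete features: integer-valued columns (k-gram counts, position
codes) pass through unchanged, and real-valued columns (physicochemical
values) are discretized to three states at mean +/- alpha * sigma — the
conventional default of the original mRMR program for continuous data.

Ties are broken toward the lowest feature index, making selection fully
deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

log = logging.getLogger("malsite")


@dataclass(frozen=True)
class DiscretizationScheme:
    """How real-valued columns are made discrete before MI estimation.

    ``three-state-mean-sigma``: values below mean - alpha*sigma -> 0, above
    mean + alpha*sigma -> 2, else 1 (population sigma).  ``equal-frequency``:
    quantile bins.  ``none``: values must already be integer-valued.
    Integer-valued columns always pass through unchanged.
    """

    method: str = "three-state-mean-sigma"
    alpha: float = 1.0
    bins: int = 3

    def __post_init__(self) -> None:
        if self.method not in ("three-state-mean-sigma", "equal-frequency", "none"):
            raise ValueError(f"unknown discretization method {self.method!r}")
        if self.alpha <= 0 or self.bins < 2:
            raise ValueError("alpha must be > 0 and bins >= 2")


def _is_label_like(x: np.ndarray) -> bool:
    """Non-negative integer-valued columns (counts, codes) are already discrete."""
    return bool(np.allclose(x, np.round(x)) and x.min() >= 0)


def discretize(x: np.ndarray, scheme: DiscretizationScheme = DiscretizationScheme()) -> np.ndarray:
    """Discretize one column to small non-negative integer labels.

    Deterministic given the data; a zero-variance column maps to a single
    label (valid — its MI with anything is 0).
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("cannot discretize an empty column")
    if _is_label_like(x):
        return x.astype(np.int64)
    if scheme.method == "none":
        raise ValueError("scheme 'none' requires non-negative integer-valued input")
    if scheme.method == "three-state-mean-sigma":
        mu, sigma = x.mean(), x.std()
        if sigma == 0:
            return np.zeros(x.size, dtype=np.int64)
        labels = np.ones(x.size, dtype=np.int64)
        labels[x < mu - scheme.alpha * sigma] = 0
        labels[x > mu + scheme.alpha * sigma] = 2
        return labels
    # equal-frequency
    edges = np.quantile(x, np.linspace(0, 1, scheme.bins + 1)[1:-1])
    return np.searchsorted(edges, x, side="right").astype(np.int64)


def _relabel(x: np.ndarray) -> np.ndarray:
    """Map arbitrary integer labels to consecutive 0..k-1."""
    _, inv = np.unique(x, return_inverse=True)
    return inv.astype(np.int64)


def mutual_information(x: np.ndarray, y: np.ndarray) -> float:
    """Plug-in mutual information (nats) between two discrete label vectors.

    I(x; y) = sum_ab p(a,b) log[p(a,b) / (p(a) p(b))] over the empirical
    joint distribution; non-negative and symmetric.
    """
    x, y = np.asarray(x), np.asarray(y)
    if x.shape != y.shape:
        raise ValueError("mutual information requires equal-length vectors")
    xi, yi = _relabel(x), _relabel(y)
    kx, ky = xi.max() + 1, yi.max() + 1
    joint = np.bincount(xi * ky + yi, minlength=kx * ky).reshape(kx, ky) / x.size
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = joint * (np.log(joint) - np.log(px) - np.log(py))
    return float(max(np.nansum(terms), 0.0))


def _mi_against_all(Xd: np.ndarray, s: np.ndarray) -> np.ndarray:
    """MI (nats) of one label vector ``s`` against every column of ``Xd``.

    ``Xd`` must hold consecutive labels per column.  Vectorized as a single
    flat histogram over (column, x-label, s-label) triples.
    """
    n, f = Xd.shape
    kx = int(Xd.max()) + 1
    ks = int(s.max()) + 1
    codes = (np.arange(f, dtype=np.int64) * (kx * ks))[None, :] + Xd * ks + s[:, None]
    counts = np.bincount(codes.ravel(), minlength=f * kx * ks).astype(float)
    joint = counts.reshape(f, kx, ks) / n
    px = joint.sum(axis=2, keepdims=True)
    ps = joint.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = joint * (np.log(joint) - np.log(px) - np.log(ps))
    return np.maximum(np.nansum(terms, axis=(1, 2)), 0.0)


def discretize_matrix(
    X: np.ndarray, scheme: DiscretizationScheme = DiscretizationScheme()
) -> np.ndarray:
    """Column-wise discretization to consecutive small integer labels."""
    X = np.asarray(X, dtype=float)
    out = np.empty(X.shape, dtype=np.int64)
    for j in range(X.shape[1]):
        out[:, j] = _relabel(discretize(X[:, j], scheme))
    return out


@dataclass(frozen=True)
class FeatureSelection:
    """Ordered mRMR output: indices plus per-step diagnostics."""

    indices: list[int]
    relevance: list[float]   # I(f; y) of each selected feature
    redundancy: list[float]  # mean MI with previously selected at pick time
    scores: list[float]      # the criterion value at pick time
    scheme: str = "MID"
    n_requested: int = 50

    def __post_init__(self) -> None:
        if len(set(self.indices)) != len(self.indices):
            raise ValueError("selected indices must be unique")


def mrmr_select(
    X: np.ndarray,
    y: np.ndarray,
    n: int = 50,
    scheme: str = "MID",
    discretization: DiscretizationScheme = DiscretizationScheme(),
) -> FeatureSelection:
    """Greedy mRMR selection of ``n`` features from matrix ``X``.

    Returns the ordered selection with per-step relevance, redundancy and
    criterion scores.  If ``n`` exceeds the number of features, all features
    are selected (with a warning).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("X must be a non-empty matrix")
    if n < 1:
        raise ValueError("n must be >= 1")
    if scheme not in ("MID", "MIQ"):
        raise ValueError(f"unknown mRMR scheme {scheme!r}")
    n_feat = X.shape[1]
    if n > n_feat:
        log.warning("mRMR: requested %d features but only %d exist; selecting all", n, n_feat)
        n = n_feat

    Xd = discretize_matrix(X, discretization)
    yd = _relabel(np.asarray(y))
    relevance = _mi_against_all(Xd, yd)

    indices: list[int] = []
    rel_out: list[float] = []
    red_out: list[float] = []
    score_out: list[float] = []
    red_sum = np.zeros(n_feat)
    available = np.ones(n_feat, dtype=bool)

    for step in range(n):
        if step == 0:
            scores = relevance.copy()
            redundancy = np.zeros(n_feat)
        else:
            red_sum += _mi_against_all(Xd, Xd[:, indices[-1]])
            redundancy = red_sum / len(indices)
            if scheme == "MID":
                scores = relevance - redundancy
            else:  # MIQ; guard zero redundancy
                scores = relevance / np.maximum(redundancy, 1e-12)
        masked = np.where(available, scores, -np.inf)
        pick = int(np.argmax(masked))  # argmax returns lowest index on ties
        indices.append(pick)
        rel_out.append(float(relevance[pick]))
        red_out.append(float(redundancy[pick]))
        score_out.append(float(masked[pick]))
        available[pick] = False

    return FeatureSelection(
        indices=indices,
        relevance=rel_out,
        redundancy=red_out,
        scores=score_out,
        scheme=scheme,
        n_requested=n,
    )


def selection_report(selection: FeatureSelection, names: list[str] | None = None):
    """Tabular report of the selection: rank, feature, relevance, redundancy, score."""
    import pandas as pd

    rows = []
    for rank, (i, rel, red, sc) in enumerate(
        zip(selection.indices, selection.relevance, selection.redundancy, selection.scores),
        start=1,
    ):
        rows.append(
            {
                "rank": rank,
                "feature_index": i,
                "feature": names[i] if names else str(i),
                "relevance": round(rel, 6),
                "redundancy": round(red, 6),
                "score": round(sc, 6),
            }
        )
    return pd.DataFrame(rows)
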