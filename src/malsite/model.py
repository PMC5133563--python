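"""Probability-output RBF-SVM classifier and the full prediction pipeline.

The classifier is a soft-margin SVM with an RBF kernel (width gamma = 0.0125
by default, the published value) whose decision values are mapped to class
probabilities by Platt sigmoid calibration, as in LIBSVM.  A window P is
called positive when Pr(y=1 | P) > theta (default 0.5); a probability exactly
equal to theta is classified negative — the conservative convention for
positive calls.

The soft-margin cost C is not fixed by the reference protocol; the default is
C = 1.0, recorded in the trained model, with :func:`grid_search_c` provided
to tune it explicitly.

A :class:`TrainedModel` bundles the fitted SVM with the exact preprocessing
chain used at training time (constant-feature mask, optional min-max scaler,
mRMR selection, property table), so prediction on raw windows is always
consistent with training.
"""

from __future__ import annotations

import pickle
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.svm import SVC

from . import features as F
from .mrmr import DiscretizationScheme, FeatureSelection, mrmr_select
from .properties import PropertyTable, default_property_table
from .windows import PeptideWindow, WindowConfig


@dataclass(frozen=True)
class SVMConfig:
    """RBF-SVM hyperparameters and the probability decision threshold."""

    gamma: float = 0.0125
    C: float = 1.0
    theta: float = 0.5

    def __post_init__(self) -> None:
        if self.gamma <= 0 or self.C <= 0:
            raise ValueError("gamma and C must be positive")
        if not 0 < self.theta < 1:
            raise ValueError("theta must be in (0, 1)")


@dataclass(frozen=True)
class MRMRConfig:
    """How many features to select and with which mRMR variant."""

    n_features: int = 50
    scheme: str = "MID"
    discretization: DiscretizationScheme = field(default_factory=DiscretizationScheme)


def _fit_svc(X: np.ndarray, y: np.ndarray, config: SVMConfig, seed: int) -> SVC:
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training requires at least one sample of each class")
    svc = SVC(
        kernel="rbf",
        gamma=config.gamma,
        C=config.C,
        probability=True,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        svc.fit(np.asarray(X, dtype=float), y)
    return svc


@dataclass
class FittedSVM:
    """A fitted probability SVM on an already-preprocessed matrix."""

    svc: SVC
    config: SVMConfig
    seed: int
    n_features: int

    def predict_probability(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"expected {self.n_features} features, got {X.shape[1]}"
            )
        pos_col = int(np.flatnonzero(self.svc.classes_ == 1)[0])
        return self.svc.predict_proba(X)[:, pos_col]


def train(X: np.ndarray, y: np.ndarray, config: SVMConfig = SVMConfig(), seed: int = 0) -> FittedSVM:
    """Train the probability RBF-SVM on a reduced+selected feature matrix."""
    X = np.asarray(X, dtype=float)
    return FittedSVM(_fit_svc(X, y, config, seed), config, seed, X.shape[1])


class Pipeline:
    """Constant-feature mask -> mRMR -> min-max scaling -> SVM.

    Fitted on a raw (n, 687) feature matrix; every stage is fitted on the
    training data only, so the pipeline can be refit per cross-validation
    fold without selection leakage.

    Scaling happens after selection and only feeds the SVM: mRMR's
    discretization sees the natural integer-valued k-gram and position-code
    columns, while the kernel sees features on a common [0, 1] range.  The
    raw blocks span four orders of magnitude (counts 0-16 vs molecular
    weights ~200), which at the default RBF width gamma = 0.0125 would
    collapse the kernel to near-zero off the diagonal; min-max scaling is
    therefore on by default and recorded in the model.
    """

    def __init__(
        self,
        svm: SVMConfig = SVMConfig(),
        mrmr: MRMRConfig = MRMRConfig(),
        scale: bool = True,
        seed: int = 0,
    ):
        self.svm_config = svm
        self.mrmr_config = mrmr
        self.scale = scale
        self.seed = seed
        self.mask: F.ReductionMask | None = None
        self.selection: FeatureSelection | None = None
        self.scaler_min: np.ndarray | None = None
        self.scaler_range: np.ndarray | None = None
        self.fitted: FittedSVM | None = None
        self.class_counts: dict[int, int] | None = None

    def _preprocess(self, X: np.ndarray) -> np.ndarray:
        assert self.mask is not None and self.selection is not None
        X = F.apply_reduction(np.atleast_2d(np.asarray(X, dtype=float)), self.mask)
        X = X[:, self.selection.indices]
        if self.scale:
            X = (X - self.scaler_min) / self.scaler_range
        return X

    def fit(self, X: np.ndarray, y: np.ndarray) -> "Pipeline":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(int)
        self.mask = F.fit_reduction_mask(X)
        Xr = F.apply_reduction(X, self.mask)
        self.selection = mrmr_select(
            Xr,
            y,
            n=self.mrmr_config.n_features,
            scheme=self.mrmr_config.scheme,
            discretization=self.mrmr_config.discretization,
        )
        Xs = Xr[:, self.selection.indices]
        if self.scale:
            self.scaler_min = Xs.min(axis=0)
            rng = Xs.max(axis=0) - self.scaler_min
            self.scaler_range = np.where(rng == 0, 1.0, rng)
            Xs = (Xs - self.scaler_min) / self.scaler_range
        self.fitted = train(Xs, y, self.svm_config, self.seed)
        self.class_counts = {int(c): int((y == c).sum()) for c in np.unique(y)}
        return self

    def predict_probability(self, X: np.ndarray) -> np.ndarray:
        if self.fitted is None:
            raise RuntimeError("pipeline is not fitted")
        return self.fitted.predict_probability(self._preprocess(X))


@dataclass
class TrainedModel:
    """A trained pipeline plus everything needed to reproduce predictions."""

    pipeline: Pipeline
    window_config: WindowConfig
    property_table: PropertyTable
    binary_kgrams: bool = False
    metadata: dict = field(default_factory=dict)

    @property
    def theta(self) -> float:
        return self.pipeline.svm_config.theta

    def _encode(self, w: PeptideWindow) -> np.ndarray:
        return F.encode(w, self.property_table, self.window_config, self.binary_kgrams)

    def predict_probability(
        self, item: PeptideWindow | np.ndarray | Sequence[PeptideWindow]
    ) -> float | np.ndarray:
        """Pr(y=1 | P) for a window, a raw feature vector, or a window list."""
        if isinstance(item, PeptideWindow):
            return float(self.pipeline.predict_probability(self._encode(item))[0])
        if isinstance(item, np.ndarray):
            p = self.pipeline.predict_probability(item)
            return float(p[0]) if item.ndim == 1 else p
        X = np.array([self._encode(w) for w in item])
        return self.pipeline.predict_probability(X)

    def classify(
        self,
        item: PeptideWindow | np.ndarray,
        theta: float | None = None,
    ) -> tuple[int, float]:
        """(call, probability); positive (1) iff probability > theta.

        A probability exactly equal to theta is classified negative.
        """
        theta = self.theta if theta is None else theta
        p = self.predict_probability(item)
        p = float(p if np.isscalar(p) else np.asarray(p).ravel()[0])
        return (1 if p > theta else 0), p

    def save(self, path: str | Path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path: str | Path) -> "TrainedModel":
        with open(path, "rb") as fh:
            model = pickle.load(fh)
        if not isinstance(model, TrainedModel):
            raise TypeError(f"{path} does not contain a TrainedModel")
        return model


def train_model(
    windows: Sequence[PeptideWindow],
    svm: SVMConfig = SVMConfig(),
    mrmr: MRMRConfig = MRMRConfig(),
    window_config: WindowConfig = WindowConfig(),
    property_table: PropertyTable | None = None,
    scale: bool = True,
    binary_kgrams: bool = False,
    seed: int = 0,
) -> TrainedModel:
    """Encode labeled windows and fit the full pipeline."""
    if property_table is None:
        property_table = default_property_table()
    labels = [w.label for w in windows]
    if any(l is None for l in labels):
        raise ValueError("all training windows must be labeled")
    X = F.encode_matrix(windows, property_table, window_config, binary_kgrams)
    y = np.asarray(labels, dtype=int)
    pipe = Pipeline(svm=svm, mrmr=mrmr, scale=scale, seed=seed).fit(X, y)
    return TrainedModel(
        pipeline=pipe,
        window_config=window_config,
        property_table=property_table,
        binary_kgrams=binary_kgrams,
        metadata={
            "seed": seed,
            "class_counts": pipe.class_counts,
            "property_table_checksum": property_table.checksum(),
        },
    )


def grid_search_c(
    X: np.ndarray,
    y: np.ndarray,
    candidates: Sequence[float] = (0.125, 0.5, 1.0, 2.0, 8.0, 32.0),
    svm: SVMConfig = SVMConfig(),
    k: int = 5,
    seed: int = 0,
) -> tuple[float, dict[float, float]]:
    """Pick C by stratified k-fold AUC on a preprocessed matrix.

    Returns the best C and the per-candidate mean AUC.  Provided as an
    explicit helper because the reference protocol fixes gamma but not C.
    """
    from sklearn.model_selection import StratifiedKFold

    from .evaluation import roc_auc

    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    results: dict[float, float] = {}
    for c in candidates:
        cfg = SVMConfig(gamma=svm.gamma, C=c, theta=svm.theta)
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        scores = np.empty(len(y))
        for train_idx, test_idx in skf.split(X, y):
            fitted = train(X[train_idx], y[train_idx], cfg, seed)
            scores[test_idx] = fitted.predict_probability(X[test_idx])
        _, auc = roc_auc(scores, y)
        results[c] = auc
    best = max(results, key=lambda c: (results[c], -c))
    return best, results
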