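"""Classifier families used throughout the benchmark.

Three families are compared on every trait: a 1-nearest-neighbour rule on a
chosen distance matrix (phylogenetic, 16S Hamming, or gene-content L1), a
random forest in which every tree may consider all genes at every split, and
an L1-regularized logistic regression. All of them emit a
:class:`FitResult` so evaluation code never needs to know which model ran.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression

from .dataio import DistanceMatrix
from .partitioning import Partition

__all__ = [
    "FitResult",
    "ImportanceProfile",
    "nn_predict",
    "rf_fit_predict",
    "logreg_l1_fit_predict",
    "aggregate_importance",
]


@dataclass
class FitResult:
    """Predictions of one fitted model on one test set."""

    test_ids: list[str]
    predictions: np.ndarray
    model: str
    gene_ids: list[str] | None = None
    importances: np.ndarray | None = None
    partition: Partition | None = None

    def __post_init__(self) -> None:
        self.predictions = np.asarray(self.predictions, dtype=int)
        if self.predictions.shape != (len(self.test_ids),):
            raise ValueError("one prediction per test strain required")
        if not np.isin(self.predictions, (0, 1)).all():
            raise ValueError("predictions must be binary")
        if self.importances is not None:
            self.importances = np.asarray(self.importances, dtype=float)
            if (self.importances < 0).any():
                raise ValueError("importance scores must be non-negative")


@dataclass
class ImportanceProfile:
    """Per-gene importance averaged over partitions."""

    gene_ids: list[str]
    mean_importance: np.ndarray
    n_partitions: int

    def top(self, k: int) -> list[str]:
        order = np.argsort(-self.mean_importance, kind="stable")
        return [self.gene_ids[i] for i in order[:k]]


def nn_predict(
    dist: DistanceMatrix,
    train_ids: Sequence[str],
    train_labels: Sequence[int],
    test_ids: Sequence[str],
    exclude_self: bool = False,
) -> FitResult:
    """Predict each test strain's trait from its closest training strain.

    Distance ties resolve to the lexicographically smallest training ID. With
    ``exclude_self`` a test strain that also appears in the training set
    ignores its own zero self-distance (the self-match is only meaningful as
    a diagnostic).
    """
    train_ids = list(train_ids)
    test_ids = list(test_ids)
    if not train_ids:
        raise ValueError("empty training set")
    labels = np.asarray(train_labels, dtype=int)
    if labels.shape != (len(train_ids),):
        raise ValueError("one label per training strain required")
    order = np.argsort(np.array(train_ids, dtype=object))
    sorted_train = [train_ids[i] for i in order]
    sorted_labels = labels[order]
    d = dist.between(test_ids, sorted_train).copy()
    if exclude_self:
        for i, t in enumerate(test_ids):
            if t in sorted_train:
                d[i, sorted_train.index(t)] = np.inf
    nearest = np.argmin(d, axis=1)  # first minimum = smallest ID on ties
    return FitResult(
        test_ids=test_ids,
        predictions=sorted_labels[nearest],
        model=f"1nn_{dist.metric}",
    )


def rf_fit_predict(
    X_train: np.ndarray,
    y_train: Sequence[int],
    X_test: np.ndarray,
    test_ids: Sequence[str] | None = None,
    gene_ids: Sequence[str] | None = None,
    config: dict | None = None,
    rng_seed: int | None = None,
) -> FitResult:
    """Random forest with every feature available to every split.

    Defaults: 100 trees, unbounded depth, ``max_features=None`` so no tree
    drops a key predictor by feature subsampling; importances are the
    normalized mean impurity decrease. ``config`` may override
    ``n_estimators``, ``max_depth`` and ``max_features`` (for hyperparameter
    sweeps). Exact 50/50 ensemble votes resolve to class 0 (the lower class
    index).
    """
    y = np.asarray(y_train, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    cfg = {"n_estimators": 100, "max_features": None, "max_depth": None}
    cfg.update(config or {})
    rf = RandomForestClassifier(
        n_estimators=cfg["n_estimators"],
        max_features=cfg["max_features"],
        max_depth=cfg["max_depth"],
        random_state=None if rng_seed is None else int(rng_seed),
        n_jobs=1,
    )
    rf.fit(np.asarray(X_train, dtype=np.float32), y)
    preds = rf.predict(np.asarray(X_test, dtype=np.float32))
    imp = rf.feature_importances_
    if test_ids is None:
        test_ids = [f"t{i}" for i in range(len(preds))]
    return FitResult(
        test_ids=list(test_ids),
        predictions=preds,
        model="random_forest",
        gene_ids=list(gene_ids) if gene_ids is not None else None,
        importances=imp,
    )


def logreg_l1_fit_predict(
    X_train: np.ndarray,
    y_train: Sequence[int],
    X_test: np.ndarray,
    test_ids: Sequence[str] | None = None,
    gene_ids: Sequence[str] | None = None,
    penalty_strength: float = 1.0,
) -> FitResult:
    """L1-regularized logistic regression (liblinear, C = ``penalty_strength``).

    Predictions threshold the fitted probability at 0.5. Importances are the
    normalized absolute coefficients (all zero coefficients -> no profile).
    """
    if penalty_strength <= 0:
        raise ValueError("penalty_strength must be positive")
    y = np.asarray(y_train, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    # l1_ratio=1.0 selects the pure L1 penalty under liblinear
    clf = LogisticRegression(C=penalty_strength, solver="liblinear", l1_ratio=1.0)
    clf.fit(np.asarray(X_train, dtype=float), y)
    preds = clf.predict(np.asarray(X_test, dtype=float))
    coefs = np.abs(clf.coef_.ravel())
    imp = coefs / coefs.sum() if coefs.sum() > 0 else None
    if test_ids is None:
        test_ids = [f"t{i}" for i in range(len(preds))]
    return FitResult(
        test_ids=list(test_ids),
        predictions=preds,
        model="logreg_l1",
        gene_ids=list(gene_ids) if gene_ids is not None else None,
        importances=imp,
    )


def aggregate_importance(fit_results: Sequence[FitResult]) -> ImportanceProfile:
    """Arithmetic mean of per-gene importances across partitions."""
    results = [r for r in fit_results]
    if not results:
        raise ValueError("no fit results to aggregate")
    gene_ids = results[0].gene_ids
    if gene_ids is None:
        raise ValueError("fit results carry no gene IDs")
    stack = []
    for r in results:
        if r.gene_ids != gene_ids:
            raise ValueError("fit results disagree on gene IDs")
        if r.importances is None:
            raise ValueError("fit result without importances")
        stack.append(r.importances)
    return ImportanceProfile(
        gene_ids=list(gene_ids),
        mean_importance=np.mean(stack, axis=0),
        n_partitions=len(results),
    )
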