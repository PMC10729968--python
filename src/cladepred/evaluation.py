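"""Null models, accuracy metrics and the significance protocol.

Raw accuracy is inflated for unbalanced traits, so a model only counts as
successful when its accuracy distribution over data partitions is
significantly higher than BOTH of two baselines evaluated on the same
partitions:

* Bernoulli null — predict 1 with the training-set frequency of 1s;
* identity null — always predict the training-set majority phenotype.

Comparisons use a two-sided permutation t-test, with Holm-Sidak correction
across all traits evaluated in a run. Fixed external prediction vectors
(e.g. from constraint-based metabolic models) are scored against an
empirical null-accuracy distribution built over random partitions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EvaluationRecord",
    "ComparisonResult",
    "Score",
    "bernoulli_null_predict",
    "identity_null_predict",
    "score",
    "permutation_t_test",
    "holm_sidak",
    "compare_to_nulls",
    "empirical_pvalue",
    "fixed_prediction_pvalue",
]


@dataclass
class EvaluationRecord:
    """Per-partition accuracies of one model on one trait."""

    trait_id: str
    model: str
    regime: str
    accuracies: list[float]
    balanced_accuracies: list[float]

    def __post_init__(self) -> None:
        for a in list(self.accuracies) + list(self.balanced_accuracies):
            if not (np.isnan(a) or 0.0 <= a <= 1.0):
                raise ValueError(f"accuracy {a} outside [0, 1]")

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracies))


@dataclass
class ComparisonResult:
    trait_id: str
    model: str
    p_vs_bernoulli: float
    p_vs_identity: float
    p_vs_bernoulli_corrected: float
    p_vs_identity_corrected: float
    significant: bool


def bernoulli_null_predict(train_labels: Sequence[int], n_test: int,
                           rng_seed: int | None = None) -> np.ndarray:
    """Predict 1 i.i.d. with the training-set frequency of 1s."""
    y = np.asarray(train_labels, dtype=int)
    if y.size == 0:
        raise ValueError("empty training labels")
    p = y.mean()
    rng = np.random.default_rng(rng_seed)
    return (rng.random(n_test) < p).astype(int)


def identity_null_predict(train_labels: Sequence[int], n_test: int) -> np.ndarray:
    """Always predict the training-set majority phenotype (ties -> 1)."""
    y = np.asarray(train_labels, dtype=int)
    if y.size == 0:
        raise ValueError("empty training labels")
    majority = 1 if y.mean() >= 0.5 else 0
    return np.full(n_test, majority, dtype=int)


@dataclass
class Score:
    accuracy: float
    balanced_accuracy: float
    balanced_defined: bool


def score(predictions: Sequence[int], labels: Sequence[int]) -> Score:
    """Accuracy and balanced accuracy (mean of sensitivity and specificity).

    When the test labels contain a single class balanced accuracy is
    undefined; plain accuracy is reported in its place with
    ``balanced_defined=False``.
    """
    pred = np.asarray(predictions, dtype=int)
    lab = np.asarray(labels, dtype=int)
    if pred.size == 0 or pred.shape != lab.shape:
        raise ValueError("predictions and labels must be equal-length, non-empty")
    acc = float((pred == lab).mean())
    pos = lab == 1
    if pos.all() or (~pos).all():
        return Score(acc, acc, balanced_defined=False)
    sens = float((pred[pos] == 1).mean())
    spec = float((pred[~pos] == 0).mean())
    return Score(acc, (sens + spec) / 2.0, balanced_defined=True)


def _abs_t(sum_a, sumsq_a, n_a, total, totalsq, n):
    """|t| (pooled, equal-variance) from group-a sufficient statistics."""
    n_b = n - n_a
    m_a = sum_a / n_a
    m_b = (total - sum_a) / n_b
    ss_a = sumsq_a - n_a * m_a**2
    ss_b = (totalsq - sumsq_a) - n_b * m_b**2
    sp2 = (ss_a + ss_b) / (n - 2)
    denom = np.sqrt(sp2 * (1.0 / n_a + 1.0 / n_b))
    diff = np.abs(m_a - m_b)
    scale = max(1.0, float(np.max(np.abs([total / n, 1.0]))))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / denom
    # zero within-group variance: equal means -> t = 0, else t = +inf
    t = np.where(denom <= 1e-12 * scale,
                 np.where(diff <= 1e-12 * scale, 0.0, np.inf), t)
    return t


def permutation_t_test(sample_a: Sequence[float], sample_b: Sequence[float],
                       n_permutations: int = 100_000,
                       rng_seed: int | None = None) -> float:
    """Two-sided permutation test on the pooled t statistic.

    All group assignments are enumerated exactly when their number does not
    exceed ``n_permutations`` (the identity assignment counts, so the
    smallest attainable p is 1/total); otherwise ``n_permutations`` random
    assignments are drawn and the (count+1)/(B+1) estimator is used.
    Degenerate assignments with zero within-group variance get |t| = 0 when
    the group means agree and |t| = +inf when they differ.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 values")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    x = np.concatenate([a, b])
    n, n_a = x.size, a.size
    total, totalsq = x.sum(), (x**2).sum()
    t_obs = float(_abs_t(a.sum(), (a**2).sum(), n_a, total, totalsq, n))
    thresh = t_obs - 1e-12 * max(1.0, t_obs if np.isfinite(t_obs) else 1.0)
    n_exact = math.comb(n, n_a)
    if n_exact <= n_permutations:
        idx = np.array(list(combinations(range(n), n_a)))
        sum_a = x[idx].sum(axis=1)
        sumsq_a = (x[idx] ** 2).sum(axis=1)
        t_perm = _abs_t(sum_a, sumsq_a, n_a, total, totalsq, n)
        return float(np.count_nonzero(t_perm >= thresh) / n_exact)
    rng = np.random.default_rng(rng_seed)
    B = int(n_permutations)
    # each row: a uniformly random subset of size n_a
    order = np.argsort(rng.random((B, n)), axis=1)[:, :n_a]
    xa = x[order]
    t_perm = _abs_t(xa.sum(axis=1), (xa**2).sum(axis=1), n_a, total, totalsq, n)
    return float((np.count_nonzero(t_perm >= thresh) + 1) / (B + 1))


def holm_sidak(p_values: Sequence[float]) -> np.ndarray:
    """Step-down Sidak (Holm-Sidak) adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    with np.errstate(divide="ignore"):  # log1p(-1) for exact zeros
        return multipletests(p, method="holm-sidak")[1]


def compare_to_nulls(
    model_records: Sequence[EvaluationRecord],
    bernoulli_records: Sequence[EvaluationRecord],
    identity_records: Sequence[EvaluationRecord],
    alpha: float = 0.05,
    n_permutations: int = 100_000,
    rng_seed: int | None = None,
) -> list[ComparisonResult]:
    """Test every trait's model accuracies against both nulls.

    The three record lists are aligned by trait and must share partition
    counts. Holm-Sidak correction is applied across the traits of this call,
    separately for each null family. A trait is significant when both
    corrected p-values fall below ``alpha`` AND the model's mean accuracy
    exceeds both null means (the permutation test itself is two-sided).
    """
    if not (len(model_records) == len(bernoulli_records) == len(identity_records)):
        raise ValueError("record lists must be aligned by trait")
    p_bern, p_ident = [], []
    rng = np.random.default_rng(rng_seed)
    for m, b, i in zip(model_records, bernoulli_records, identity_records):
        if not (len(m.accuracies) == len(b.accuracies) == len(i.accuracies)):
            raise ValueError(f"partition counts differ for trait {m.trait_id!r}")
        p_bern.append(permutation_t_test(
            m.accuracies, b.accuracies, n_permutations,
            rng_seed=int(rng.integers(2**31))))
        p_ident.append(permutation_t_test(
            m.accuracies, i.accuracies, n_permutations,
            rng_seed=int(rng.integers(2**31))))
    p_bern_c = holm_sidak(p_bern)
    p_ident_c = holm_sidak(p_ident)
    out = []
    for k, (m, b, i) in enumerate(
            zip(model_records, bernoulli_records, identity_records)):
        sig = (
            p_bern_c[k] < alpha and p_ident_c[k] < alpha
            and m.mean_accuracy > b.mean_accuracy
            and m.mean_accuracy > i.mean_accuracy
        )
        out.append(ComparisonResult(
            trait_id=m.trait_id, model=m.model,
            p_vs_bernoulli=p_bern[k], p_vs_identity=p_ident[k],
            p_vs_bernoulli_corrected=float(p_bern_c[k]),
            p_vs_identity_corrected=float(p_ident_c[k]),
            significant=bool(sig),
        ))
    return out


def fixed_prediction_pvalue(
    observed_accuracy: float,
    null_kind: str,
    trait_labels: Sequence[int],
    n_partitions: int = 100_000,
    test_fraction: float = 0.20,
    rng_seed: int | None = None,
    plus_one: bool = False,
) -> float:
    """Empirical p-value of a single fixed prediction accuracy.

    Builds a distribution of null-model accuracies over ``n_partitions``
    random train/test partitions of the labelled strains and returns the
    fraction of null accuracies strictly greater than ``observed_accuracy``
    (``plus_one`` adds the usual +1 small-sample guard to numerator and
    denominator).
    """
    if not 0.0 <= observed_accuracy <= 1.0:
        raise ValueError("observed_accuracy must lie in [0, 1]")
    if null_kind not in ("bernoulli", "identity"):
        raise ValueError(f"unknown null kind {null_kind!r}")
    y = np.asarray(trait_labels, dtype=int)
    n = y.size
    if n < 2:
        raise ValueError("need at least 2 labelled strains")
    m = max(1, round(test_fraction * n))
    rng = np.random.default_rng(rng_seed)
    B = int(n_partitions)
    accs = np.empty(B)
    chunk = max(1, min(B, 20_000_000 // max(n, 1)))
    done = 0
    total_ones = y.sum()
    while done < B:
        k = min(chunk, B - done)
        order = np.argsort(rng.random((k, n)), axis=1)
        test_lab = y[order[:, :m]]
        train_ones = total_ones - test_lab.sum(axis=1)
        p_train = train_ones / (n - m)
        if null_kind == "bernoulli":
            preds = rng.random((k, m)) < p_train[:, None]
        else:
            preds = np.broadcast_to((p_train >= 0.5)[:, None], (k, m))
        accs[done:done + k] = (preds == test_lab).mean(axis=1)
        done += k
    return empirical_pvalue(observed_accuracy, accs, plus_one=plus_one)


def empirical_pvalue(observed: float, null_values: Sequence[float],
                     plus_one: bool = False) -> float:
    """Fraction of null values strictly greater than the observed one."""
    null = np.asarray(null_values, dtype=float)
    if null.size == 0:
        raise ValueError("empty null distribution")
    higher = int(np.count_nonzero(null > observed))
    if plus_one:
        return (higher + 1) / (null.size + 1)
    return higher / null.size
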