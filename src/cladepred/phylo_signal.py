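"""Phylogeny-trait correlation and the nearest-neighbour mimicry diagnostic.

Closely related strains tend to share metabolic traits up to some
evolutionary distance. The *correlation length* of a binary trait is the
largest tree distance at which strain pairs inside a sliding distance
window are still significantly more likely to share the trait than pairs
outside it (chi-square on the 2x2 window x same/different contingency
table). The mimicry statistic asks whether an arbitrary trained classifier
behaves like a 1-nearest-neighbour rule on gene-content (L1) distance: for
each test strain, compare the model's prediction with its prediction for
the strain's nearest training neighbour.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .dataio import DistanceMatrix
from .evaluation import permutation_t_test
from .partitioning import Partition

__all__ = [
    "CorrelationLengthResult",
    "MimicryResult",
    "TraitDifferenceCurve",
    "trait_difference_curve",
    "correlation_length",
    "nn_mimicry",
]


def _align_trait(dist: DistanceMatrix, trait) -> tuple[DistanceMatrix, np.ndarray]:
    """Restrict the distance matrix to strains with a non-missing label."""
    if isinstance(trait, pd.Series):
        trait = trait.dropna()
        ids = [s for s in dist.strain_ids if s in trait.index]
        y = trait.loc[ids].to_numpy(dtype=int)
    else:
        y = np.asarray(trait, dtype=float)
        if y.shape != (len(dist.strain_ids),):
            raise ValueError("trait vector must align with dist.strain_ids")
        keep = ~np.isnan(y)
        ids = [s for s, k in zip(dist.strain_ids, keep) if k]
        y = y[keep].astype(int)
    if not np.isin(y, (0, 1)).all():
        raise ValueError("trait values must be binary")
    return dist.submatrix(ids), y


def _default_grid(dmax: float, window_width: float) -> np.ndarray:
    n_steps = max(1, int(np.ceil((dmax - window_width) / (window_width / 2))) + 1)
    return window_width + (window_width / 2) * np.arange(n_steps)


@dataclass
class TraitDifferenceCurve:
    d_grid: np.ndarray
    mean_difference: np.ndarray  # NaN where no pair is within reach
    null_mean: np.ndarray
    null_std: np.ndarray


def trait_difference_curve(
    dist: DistanceMatrix,
    trait,
    d_grid: Sequence[float] | None = None,
    n_bootstrap: int = 100,
    rng_seed: int | None = None,
) -> TraitDifferenceCurve:
    """Mean |y_a - y_b| over strain pairs with distance <= d, for each d.

    The null band is the mean and standard deviation of the same curve under
    ``n_bootstrap`` uniform shuffles of the trait labels over strains.
    """
    if n_bootstrap < 1:
        raise ValueError("n_bootstrap must be >= 1")
    sub, y = _align_trait(dist, trait)
    iu, ju, d = sub.condensed_pairs()
    if d_grid is None:
        d_grid = _default_grid(float(d.max()), 0.1) if d.size else np.array([0.1])
    d_grid = np.asarray(d_grid, dtype=float)
    order = np.argsort(d)
    d_sorted = d[order]
    counts = np.searchsorted(d_sorted, d_grid, side="right")

    def curve_for(labels: np.ndarray) -> np.ndarray:
        diff = np.abs(labels[iu] - labels[ju]).astype(float)[order]
        csum = np.concatenate([[0.0], np.cumsum(diff)])
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(counts > 0, csum[counts] / counts, np.nan)

    rng = np.random.default_rng(rng_seed)
    null_curves = np.array([
        curve_for(rng.permutation(y)) for _ in range(n_bootstrap)
    ])
    return TraitDifferenceCurve(
        d_grid=d_grid,
        mean_difference=curve_for(y),
        null_mean=np.nanmean(null_curves, axis=0),
        null_std=np.nanstd(null_curves, axis=0),
    )


@dataclass
class CorrelationLengthResult:
    trait_id: str | None
    d_grid: np.ndarray
    chi2: np.ndarray          # NaN for degenerate (skipped) windows
    p_values: np.ndarray      # NaN for degenerate windows
    same_excess: np.ndarray   # True where same-trait pairs are enriched inside
    correlation_length: float


def correlation_length(
    dist: DistanceMatrix,
    trait,
    window_width: float = 0.1,
    d_grid: Sequence[float] | None = None,
    alpha: float = 0.05,
    continuity_correction: bool = True,
    trait_id: str | None = None,
) -> CorrelationLengthResult:
    """Phylogeny-trait correlation length via sliding-window chi-square.

    For each grid value ``d``, pairs with distance in ``[d - window_width,
    d)`` form the in-window group; the 2x2 table counts in/out x
    same/different trait and is tested with Pearson chi-square. Windows with
    a degenerate table (an empty row or column) are skipped. The length is
    the largest ``d`` whose window is significant (p < alpha) with an excess
    of same-trait pairs inside; it is 0 when the smallest non-degenerate
    window is not significant in that direction — i.e. no correlation is
    detected at short range.
    """
    if window_width <= 0:
        raise ValueError("window_width must be positive")
    sub, y = _align_trait(dist, trait)
    iu, ju, d = sub.condensed_pairs()
    same = (y[iu] == y[ju])
    if d_grid is None:
        d_grid = _default_grid(float(d.max()) if d.size else window_width,
                               window_width)
    d_grid = np.asarray(d_grid, dtype=float)
    chi2 = np.full(d_grid.size, np.nan)
    pvals = np.full(d_grid.size, np.nan)
    excess = np.zeros(d_grid.size, dtype=bool)
    for k, dk in enumerate(d_grid):
        inside = (d >= dk - window_width) & (d < dk)
        table = np.array([
            [np.count_nonzero(same & inside), np.count_nonzero(~same & inside)],
            [np.count_nonzero(same & ~inside), np.count_nonzero(~same & ~inside)],
        ])
        if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
            continue  # degenerate window: treated as non-significant
        res = chi2_contingency(table, correction=continuity_correction)
        chi2[k] = res.statistic
        pvals[k] = res.pvalue
        expected_same_inside = table[0].sum() * (table[:, 0].sum() / table.sum())
        excess[k] = table[0, 0] > expected_same_inside
    valid = ~np.isnan(pvals)
    significant = valid & (pvals < alpha) & excess
    length = 0.0
    if valid.any():
        first = int(np.argmax(valid))
        if significant[first]:
            length = float(d_grid[significant].max())
    return CorrelationLengthResult(
        trait_id=trait_id, d_grid=d_grid, chi2=chi2, p_values=pvals,
        same_excess=excess, correlation_length=length,
    )


@dataclass
class MimicryResult:
    model: str
    regime: str
    mu: np.ndarray
    mu_rand: np.ndarray
    p_value: float


def nn_mimicry(
    model_runner: Callable[[Partition], Callable[[Sequence[str]], np.ndarray]],
    dist_for_nn: DistanceMatrix,
    partitions: Sequence[Partition],
    rng_seed: int | None = None,
    model_tag: str = "model",
) -> MimicryResult:
    """Does a trained classifier mimic 1-NN on gene-content distance?

    ``model_runner(partition)`` trains the classifier on the partition's
    training strains and returns a prediction function over strain IDs. Per
    partition, ``mu`` is the mean |f(test) - f(nearest train strain)| where
    the neighbour lookup always uses ``dist_for_nn`` (L1 gene-content
    distance in the original construction); ``mu_rand`` replaces the
    neighbour with a uniformly random training strain. An exact 1-NN
    classifier on the same distance gives mu = 0 in every partition. The
    p-value compares the two distributions across partitions with the
    permutation t-test.
    """
    if not partitions:
        raise ValueError("no partitions supplied")
    rng = np.random.default_rng(rng_seed)
    mus, mus_rand = [], []
    regime = partitions[0].regime
    for part in partitions:
        if not part.test_ids:
            raise ValueError("partition with empty test set")
        predict = model_runner(part)
        # lexicographic training order makes distance ties deterministic
        train_sorted = sorted(part.train_ids)
        d = dist_for_nn.between(part.test_ids, train_sorted)
        nn_ids = [train_sorted[j] for j in np.argmin(d, axis=1)]
        rand_ids = [train_sorted[j]
                    for j in rng.integers(len(train_sorted), size=len(part.test_ids))]
        f_test = np.asarray(predict(part.test_ids), dtype=int)
        f_nn = np.asarray(predict(nn_ids), dtype=int)
        f_rand = np.asarray(predict(rand_ids), dtype=int)
        mus.append(float(np.abs(f_test - f_nn).mean()))
        mus_rand.append(float(np.abs(f_test - f_rand).mean()))
    mu = np.array(mus)
    mu_rand = np.array(mus_rand)
    if len(partitions) < 2:
        p = float("nan")  # a single partition cannot be tested
    elif np.allclose(mu, mu_rand):
        p = 1.0
    else:
        p = permutation_t_test(mu, mu_rand, n_permutations=10_000,
                               rng_seed=None if rng_seed is None
                               else int(rng.integers(2**31)))
    return MimicryResult(model=model_tag, regime=regime,
                         mu=mu, mu_rand=mu_rand, p_value=p)
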