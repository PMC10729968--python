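"""End-to-end benchmark orchestration.

``run_benchmark`` wires the whole protocol together for a set of binary
traits: per trait, drop strains with missing labels, draw ``n_partitions``
train/test splits per regime (random and/or out-of-clade), fit every
requested model plus both null models on identical partitions, score
accuracies, and test each model's accuracy distribution against both nulls
with Holm-Sidak correction across traits. Random-forest importance profiles
are averaged across partitions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import dataio
from .dataio import GenotypeMatrix, PhyloTree, TraitTable, distance_matrix, filter_traits
from .evaluation import (
    EvaluationRecord,
    bernoulli_null_predict,
    compare_to_nulls,
    identity_null_predict,
    score,
)
from .models import aggregate_importance, logreg_l1_fit_predict, nn_predict, rf_fit_predict
from .partitioning import enumerate_clade_testsets, out_of_clade_partition, random_partition

logger = logging.getLogger(__name__)

__all__ = ["BenchmarkConfig", "run_benchmark", "summarize"]

KNOWN_MODELS = ("random_forest", "nn_l1", "logreg_l1")


@dataclass
class BenchmarkConfig:
    """Configuration of one benchmark run (YAML-loadable)."""

    genotype_path: str | None = None
    trait_path: str | None = None
    tree_path: str | None = None
    models: tuple[str, ...] = ("random_forest",)
    regimes: tuple[str, ...] = ("random", "out_of_clade")
    n_partitions: int = 100
    test_fraction: float = 0.20
    min_fraction: float = 0.10
    max_fraction: float = 0.30
    min_per_class: int = 10
    alpha: float = 0.05
    n_permutations: int = 100_000
    seed: int = 0
    rf_config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_partitions < 2:
            raise ValueError("n_partitions must be >= 2")
        unknown = set(self.models) - set(KNOWN_MODELS)
        if unknown:
            raise ValueError(f"unknown models {sorted(unknown)}")
        unknown = set(self.regimes) - {"random", "out_of_clade"}
        if unknown:
            raise ValueError(f"unknown regimes {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "BenchmarkConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("models", "regimes"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _fit_model(model: str, genotypes: GenotypeMatrix, l1_dist, y, part, cfg,
               seed: int):
    """Train one model on a partition; returns (predictions, importances)."""
    y_train = y.loc[part.train_ids].to_numpy()
    if len(np.unique(y_train)) < 2:
        # a clade hold-out can leave a one-class training set; fall back to
        # the constant classifier that single class implies
        const = int(y_train[0])
        logger.info("single-class training set (%s): constant prediction", model)
        return np.full(len(part.test_ids), const), None
    if model == "nn_l1":
        fit = nn_predict(l1_dist, part.train_ids, y_train, part.test_ids)
        return fit.predictions, None
    X_train = genotypes.rows(part.train_ids)
    X_test = genotypes.rows(part.test_ids)
    if model == "random_forest":
        fit = rf_fit_predict(X_train, y_train, X_test, test_ids=part.test_ids,
                             gene_ids=genotypes.gene_ids, config=cfg.rf_config,
                             rng_seed=seed)
        return fit.predictions, fit.importances
    if model == "logreg_l1":
        fit = logreg_l1_fit_predict(X_train, y_train, X_test,
                                    test_ids=part.test_ids,
                                    gene_ids=genotypes.gene_ids)
        return fit.predictions, fit.importances
    raise ValueError(f"unknown model {model!r}")


def run_benchmark(
    config: BenchmarkConfig,
    genotypes: GenotypeMatrix | None = None,
    traits: TraitTable | None = None,
    tree: PhyloTree | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Run the full evaluation protocol; returns (summary table, detail).

    Data may be passed in memory or loaded from the paths in ``config``.
    The summary has one row per trait x model x regime with mean accuracies,
    null means, corrected p-values and the significance flag; ``detail``
    holds per-partition accuracies, partition compositions and mean
    random-forest importance profiles, all JSON-serializable.
    """
    if genotypes is None:
        genotypes = dataio.load_genotype_matrix(config.genotype_path)
    if traits is None:
        traits = dataio.load_trait_table(config.trait_path)
    if tree is None and config.tree_path:
        tree = dataio.load_tree(config.tree_path)
    if "out_of_clade" in config.regimes and tree is None:
        raise ValueError("out-of-clade partitioning requires a tree")

    kept = filter_traits(traits, config.min_per_class)
    skipped = sorted(set(traits.trait_ids) - set(kept.trait_ids))
    for t in skipped:
        logger.info("trait %s skipped: fewer than %d strains per class",
                    t, config.min_per_class)
    l1_dist = (distance_matrix(genotypes, "l1")
               if "nn_l1" in config.models else None)
    root_rng = np.random.default_rng(config.seed)
    logger.info("benchmark seed=%d traits=%d models=%s regimes=%s",
                config.seed, len(kept.trait_ids), config.models, config.regimes)

    records: dict[tuple[str, str, str], EvaluationRecord] = {}
    detail: dict = {"skipped_traits": skipped, "traits": {},
                    "importance": {}, "seed": config.seed}

    for trait_id in kept.trait_ids:
        y = kept.trait(trait_id)
        usable = list(y.index)
        trait_detail: dict = {"n_usable": len(usable), "partitions": {}}
        for regime in config.regimes:
            candidates = None
            if regime == "out_of_clade":
                candidates = enumerate_clade_testsets(
                    tree, config.min_fraction, config.max_fraction,
                    restrict_to=usable)
            parts = []
            for _ in range(config.n_partitions):
                seed = int(root_rng.integers(2**31))
                if regime == "random":
                    parts.append(random_partition(
                        usable, config.test_fraction, rng_seed=seed))
                else:
                    parts.append(out_of_clade_partition(
                        tree, config.min_fraction, config.max_fraction,
                        rng_seed=seed, restrict_to=usable,
                        candidates=candidates))
            trait_detail["partitions"][regime] = [
                {"seed": p.seed, "n_test": len(p.test_ids),
                 "test_ids": list(p.test_ids)} for p in parts]
            accs: dict[str, list[float]] = {m: [] for m in config.models}
            bals: dict[str, list[float]] = {m: [] for m in config.models}
            null_accs = {"bernoulli": [], "identity": []}
            null_bals = {"bernoulli": [], "identity": []}
            importances = []
            for part in parts:
                y_train = y.loc[part.train_ids].to_numpy()
                y_test = y.loc[part.test_ids].to_numpy()
                for model in config.models:
                    seed = int(root_rng.integers(2**31))
                    preds, imp = _fit_model(model, genotypes, l1_dist, y,
                                            part, config, seed)
                    sc = score(preds, y_test)
                    accs[model].append(sc.accuracy)
                    bals[model].append(sc.balanced_accuracy)
                    if model == "random_forest" and imp is not None:
                        importances.append(imp)
                bp = bernoulli_null_predict(
                    y_train, len(y_test),
                    rng_seed=int(root_rng.integers(2**31)))
                ip = identity_null_predict(y_train, len(y_test))
                for name, preds in (("bernoulli", bp), ("identity", ip)):
                    sc = score(preds, y_test)
                    null_accs[name].append(sc.accuracy)
                    null_bals[name].append(sc.balanced_accuracy)
            for model in config.models:
                records[(trait_id, model, regime)] = EvaluationRecord(
                    trait_id, model, regime, accs[model], bals[model])
            for name in ("bernoulli", "identity"):
                records[(trait_id, name, regime)] = EvaluationRecord(
                    trait_id, name, regime, null_accs[name], null_bals[name])
            if importances:
                profile = aggregate_importance([
                    _ImpCarrier(genotypes.gene_ids, imp)
                    for imp in importances])
                detail["importance"][f"{trait_id}|{regime}"] = {
                    "gene_ids": profile.gene_ids,
                    "mean_importance": profile.mean_importance.tolist(),
                    "n_partitions": profile.n_partitions,
                }
        detail["traits"][trait_id] = trait_detail

    rows = []
    for model in config.models:
        for regime in config.regimes:
            trait_ids = kept.trait_ids
            model_recs = [records[(t, model, regime)] for t in trait_ids]
            bern_recs = [records[(t, "bernoulli", regime)] for t in trait_ids]
            ident_recs = [records[(t, "identity", regime)] for t in trait_ids]
            comps = compare_to_nulls(
                model_recs, bern_recs, ident_recs, alpha=config.alpha,
                n_permutations=config.n_permutations,
                rng_seed=int(root_rng.integers(2**31)))
            for rec, brec, irec, comp in zip(model_recs, bern_recs,
                                             ident_recs, comps):
                rows.append({
                    "trait": rec.trait_id, "model": model, "regime": regime,
                    "mean_accuracy": rec.mean_accuracy,
                    "mean_balanced_accuracy": float(np.mean(rec.balanced_accuracies)),
                    "bernoulli_mean": brec.mean_accuracy,
                    "identity_mean": irec.mean_accuracy,
                    "p_vs_bernoulli": comp.p_vs_bernoulli_corrected,
                    "p_vs_identity": comp.p_vs_identity_corrected,
                    "significant": comp.significant,
                })
    summary = pd.DataFrame(rows, columns=[
        "trait", "model", "regime", "mean_accuracy",
        "mean_balanced_accuracy", "bernoulli_mean", "identity_mean",
        "p_vs_bernoulli", "p_vs_identity", "significant"])
    detail["records"] = {
        "|".join(k): {"accuracies": v.accuracies,
                      "balanced_accuracies": v.balanced_accuracies}
        for k, v in records.items()}
    return summary, detail


class _ImpCarrier:
    """Minimal adapter so importance vectors can be averaged uniformly."""

    def __init__(self, gene_ids, importances):
        self.gene_ids = list(gene_ids)
        self.importances = np.asarray(importances)


def summarize(summary: pd.DataFrame) -> pd.DataFrame:
    """One row per trait, one significance column per model x regime.

    The DataFrame's ``attrs["significant_counts"]`` holds the number of
    significant traits per model/regime column.
    """
    columns = ["trait"]
    if summary.empty:
        out = pd.DataFrame(columns=columns)
        out.attrs["significant_counts"] = {}
        return out
    wide = summary.pivot_table(
        index="trait",
        columns=["model", "regime"],
        values=["mean_accuracy", "significant"],
        aggfunc="first",
    )
    wide.columns = [f"{val}|{model}|{regime}"
                    for val, model, regime in wide.columns]
    wide = wide.reset_index()
    counts = {
        c.split("|", 1)[1]: int(wide[c].sum())
        for c in wide.columns if c.startswith("significant|")
    }
    wide.attrs["significant_counts"] = counts
    return wide
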