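"""cladepred: phylogeny-aware benchmarking of genotype-to-trait prediction.

Predicting binary microbial phenotypes (e.g. growth on a carbon source)
from gene presence/absence looks easy under random cross-validation because
close relatives share both genes and traits. This package implements the
evaluation protocol that separates phylogenetic interpolation from genuine
mechanistic prediction: out-of-clade hold-outs, dual null-model
significance testing, phylogeny-trait correlation lengths, a
nearest-neighbour mimicry diagnostic, three feature-selection procedures,
and a synthetic boolean-trait simulator for power studies.
"""

from importlib import resources

from .dataio import (
    DistanceMatrix,
    GenotypeMatrix,
    PhyloTree,
    TraitTable,
    binarize_growth,
    distance_matrix,
    filter_traits,
    load_genotype_matrix,
    load_trait_table,
    load_tree,
)
from .evaluation import (
    bernoulli_null_predict,
    compare_to_nulls,
    fixed_prediction_pvalue,
    holm_sidak,
    identity_null_predict,
    permutation_t_test,
    score,
)
from .feature_selection import (
    FeatureSet,
    ReactionGraph,
    conditional_entropy,
    greedy_entropy_select,
    kegg_select,
    meta_learning_select,
)
from .models import (
    FitResult,
    ImportanceProfile,
    aggregate_importance,
    logreg_l1_fit_predict,
    nn_predict,
    rf_fit_predict,
)
from .partitioning import (
    Partition,
    enumerate_clade_testsets,
    out_of_clade_partition,
    random_partition,
)
from .experiments import scaled_sample_size_study
from .phylo_signal import correlation_length, nn_mimicry, trait_difference_curve
from .pipeline import BenchmarkConfig, run_benchmark, summarize
from .synthetic_data import (
    LogicTrait,
    SyntheticDataset,
    evaluate_logic_trait,
    generate_benchmark,
    random_logic_trait,
    simulate_gene_content,
    simulate_tree,
)

__version__ = "0.1.0"


def fixture_reaction_graph_path():
    """Path to the bundled hand-curated example reaction graph (JSON)."""
    return resources.files("cladepred").joinpath(
        "data/fixture_reaction_graph.json")


def fixture_reaction_graph_expected_path():
    """Path to the hand-derived gene selections for the bundled graph."""
    return resources.files("cladepred").joinpath(
        "data/fixture_reaction_graph_expected.json")
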