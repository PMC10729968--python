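import numpy as np
import pytest

import cladepred as cp


@pytest.fixture(scope="session")
def small_dataset():
    """64-strain simulated dataset with phylogenetically structured genes."""
    tree = cp.simulate_tree(64, rng_seed=11)
    genotypes = cp.simulate_gene_content(tree, 120, rng_seed=12)
    return tree, genotypes


@pytest.fixture(scope="session")
def fixture_graph():
    return cp.ReactionGraph.from_json(cp.fixture_reaction_graph_path())


@pytest.fixture
def rng():
    return np.random.default_rng(0)
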