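import numpy as np
import pytest

from mogt import SimGraphConfig, SplitSpec, simulate_gene_graph
from mogt.training import single_fold_masks


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_graph():
    """A compact separable graph for fast model/training tests."""
    graph, truth = simulate_gene_graph(
        SimGraphConfig(n_genes=80, n_features=10, seed=7)
    )
    return graph, truth


@pytest.fixture(scope="session")
def masked_graph(small_graph):
    """Same graph with train/val/test masks for one fold assigned."""
    graph, truth = small_graph
    g = type(graph)(
        node_ids=graph.node_ids,
        features=graph.features,
        edges=graph.edges,
        labels=graph.labels,
        masks=single_fold_masks(graph, SplitSpec(n_folds=4, seed=7)),
        raw_features=graph.raw_features,
    )
    return g, truth
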