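import networkx as nx
import numpy as np
import pytest

from netpipe.interactome import GeneList, Interactome


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_interactome(rng, n_nodes=50, n_edges=100, prefix="N"):
    """Random simple graph over synthetic symbols (helper, not a fixture)."""
    names = [f"{prefix}{i:04d}" for i in range(n_nodes)]
    g = nx.gnm_random_graph(n_nodes, n_edges, seed=int(rng.integers(2**31)))
    g = nx.relabel_nodes(g, dict(enumerate(names)))
    return Interactome(graph=g, provenance="random")


def random_gene_list(rng, g, k, label="list"):
    nodes = np.array(sorted(g.nodes))
    return GeneList(list(rng.choice(nodes, size=k, replace=False)), label=label)
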