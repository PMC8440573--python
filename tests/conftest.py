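import networkx as nx
import numpy as np
import pandas as pd
import pytest

from soilweb.synth import ScenarioConfig, generate_scenario


@pytest.fixture(scope="session")
def small_config():
    return ScenarioConfig(n_taxa=60, n_groups=3, seed=7)


@pytest.fixture(scope="session")
def small_scenario(small_config):
    return generate_scenario(small_config)


@pytest.fixture
def chain_web():
    """A -> B -> C -> D resource-to-consumer chain."""
    g = nx.DiGraph()
    g.add_edges_from(
        [("A", "B"), ("B", "C"), ("C", "D")], type="predation", weight=1.0)
    return g


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_digraph(rng, n, p, parasitic_frac=0.0):
    """Random directed graph without self-loops, optionally typed edges."""
    g = nx.DiGraph()
    g.add_nodes_from(range(n))
    mask = rng.random((n, n)) < p
    np.fill_diagonal(mask, False)
    for i, j in zip(*np.nonzero(mask)):
        etype = "parasitism" if rng.random() < parasitic_frac else "predation"
        g.add_edge(int(i), int(j), type=etype, weight=1.0)
    return g


def planted_adjacency(rng, n, Q, p_in, p_out):
    """Directed planted-partition adjacency and its labels."""
    z = np.repeat(np.arange(Q), n // Q)
    z = np.concatenate([z, rng.integers(0, Q, n - len(z))])
    P = np.where(z[:, None] == z[None, :], p_in, p_out)
    np.fill_diagonal(P, 0.0)
    A = (rng.random((n, n)) < P).astype(float)
    return A, z


@pytest.fixture
def kb_frame():
    def make(rows):
        return pd.DataFrame(
            rows, columns=["resource", "consumer", "type", "evidence_rank",
                           "source"])
    return make
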