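import networkx as nx
import numpy as np
import pandas as pd
import pytest

import coexpnet as cx

CANONICAL_SEED = 0


@pytest.fixture(scope="session")
def toy_matrix() -> pd.DataFrame:
    """4 genes x 5 samples with known relationships (fixed by hand)."""
    return pd.DataFrame(
        [
            [1.0, 2.0, 3.0, 4.0, 5.0],   # gA
            [3.0, 5.0, 7.0, 9.0, 11.0],  # gB = 2*gA + 1
            [5.0, 4.0, 4.5, 2.0, 1.0],   # gC roughly anti-monotone with gA
            [2.0, 2.5, 1.0, 6.0, 3.5],   # gD scrambled
        ],
        index=["gA", "gB", "gC", "gD"],
        columns=[f"s{i}" for i in range(5)],
    )


@pytest.fixture(scope="session")
def rare_scenario():
    return cx.rare_cluster_scenario(CANONICAL_SEED)


@pytest.fixture(scope="session")
def compendium():
    return cx.simulate_compendium(cx.default_compendium_config(CANONICAL_SEED))


@pytest.fixture(scope="session")
def compendium_scaled(compendium):
    matrix, _ = compendium
    scaled = cx.scale_to_cross_experiment_trimmed_mean(matrix)
    usable, dropped = cx.drop_zero_variance(scaled)
    assert not dropped
    return usable


@pytest.fixture(scope="session")
def compendium_networks(compendium_scaled):
    nets = cx.build_mr_networks(compendium_scaled)
    nets["SCC"] = cx.build_scc_network(compendium_scaled)
    return nets


@pytest.fixture(scope="session")
def compendium_modules(compendium_networks):
    return {
        name: cx.detect_modules(net)
        for name, net in compendium_networks.items()
        if name != "SCC"
    }


def make_clique_pair() -> nx.Graph:
    """Two unit-weight 5-cliques joined by a single light (0.05) edge."""
    g = nx.Graph(name="cliques")
    a = [f"a{i}" for i in range(5)]
    b = [f"b{i}" for i in range(5)]
    for grp in (a, b):
        for i in range(5):
            for j in range(i + 1, 5):
                g.add_edge(grp[i], grp[j], weight=1.0)
    g.add_edge("a0", "b0", weight=0.05)
    return g


@pytest.fixture(scope="session")
def clique_pair() -> nx.Graph:
    return make_clique_pair()
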