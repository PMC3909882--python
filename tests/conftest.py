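import networkx as nx
import numpy as np
import pytest

import bcgrn


@pytest.fixture(scope="session")
def planted():
    """Small planted dataset shared across modules: scale-free truth,
    expression with edge-wise correlation, annotations with planted
    modules, chromosome catalog, census set."""
    net = bcgrn.generate_network(100, model="scale-free", mean_degree=1.5,
                                 seed=11)
    truth = bcgrn.PlantedTruth(network=net, edge_strength=0.8)
    expr = bcgrn.simulate_expression(truth, n_samples=300, seed=12)
    annotations = bcgrn.generate_annotations(truth, n_terms=40, n_planted=5,
                                             seed=13)
    catalog = bcgrn.generate_catalog(net.nodes(), seed=14)
    census = bcgrn.generate_census(
        net.nodes(), 15, bias_term=annotations.terms[truth.module_terms[0]],
        seed=15)
    return {"truth": truth, "network": net, "expr": expr,
            "annotations": annotations, "catalog": catalog, "census": census}


@pytest.fixture()
def path5():
    """5-node path graph A-B-C-D-E with string labels."""
    g = nx.path_graph(5)
    return nx.relabel_nodes(g, {i: "ABCDE"[i] for i in range(5)})


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
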