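import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import idrw

settings.register_profile(
    "suite", deadline=None, max_examples=25, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_matrix(values, layer="expression", genes=None, samples=None,
                value_kind="continuous"):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    genes = genes or [f"G{i + 1}" for i in range(values.shape[0])]
    samples = samples or [f"S{j + 1}" for j in range(values.shape[1])]
    return idrw.OmicsMatrix(layer, pd.DataFrame(values, index=genes, columns=samples),
                            value_kind)


def make_labels(groups, samples=None):
    samples = samples or [f"S{j + 1}" for j in range(len(groups))]
    return idrw.PhenotypeLabels(list(samples), np.array(groups, dtype=object))


@pytest.fixture(scope="session")
def small_cohort():
    """A reusable synthetic cohort with two planted pathways of eight."""
    pathdb, base = idrw.generate_pathway_graph(
        n_genes=160, n_pathways=8, size_range=(12, 18), edge_density=0.2, seed=7)
    expr, meth, labels, truth = idrw.generate_cohort(
        pathdb, base, n_samples=80, planted=2, expr_lfc=1.5, meth_shift=1.0, seed=7)
    return {"pathdb": pathdb, "base": base, "expr": expr, "meth": meth,
            "labels": labels, "truth": truth}


@pytest.fixture(scope="session")
def small_pipeline(small_cohort):
    """Statistics, graph, walk and activity computed once on the small cohort."""
    c = small_cohort
    stats = (idrw.nb_wald_test(c["expr"], c["labels"])
             + idrw.welch_t_test(c["meth"], c["labels"]))
    graph = idrw.build_integrated_graph(c["base"], c["expr"], c["meth"], mode="all")
    transition = idrw.row_normalize(graph)
    w0 = idrw.initial_weights(stats, graph)
    winf = idrw.random_walk(transition, w0)
    zmats = {"expression": idrw.zscore(c["expr"]),
             "methylation": idrw.zscore(c["meth"])}
    act = idrw.build_activity_matrix(c["pathdb"], stats, winf, zmats)
    return {**c, "stats": stats, "graph": graph, "transition": transition,
            "w0": w0, "winf": winf, "zmats": zmats, "activity": act}


def random_transition(n, rng, edge_prob=0.15, ensure_dangling=False):
    """A random directed graph's transition matrix plus a random restart vector."""
    import networkx as nx
    adj = rng.random((n, n)) < edge_prob
    np.fill_diagonal(adj, False)
    if ensure_dangling:
        adj[n - 1, :] = False
    base = nx.from_numpy_array(adj, create_using=nx.DiGraph)
    base = nx.relabel_nodes(base, {i: f"G{i}" for i in range(n)})
    nodes = [(f"G{i}", "expression") for i in range(n)]
    node_index = {node: i for i, node in enumerate(nodes)}
    from scipy import sparse
    graph = idrw.IntegratedGraph(nodes, node_index,
                                 sparse.csr_matrix(adj.astype(float)))
    w0_raw = rng.random(n) + 1e-3
    w0 = idrw.NodeWeights(nodes, w0_raw / w0_raw.sum(), "initial")
    return idrw.row_normalize(graph), w0
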