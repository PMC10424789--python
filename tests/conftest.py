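"""Shared fixtures: tiny literal tables, small graphs, and the published
reference values used by the worked-example consistency tests.

The reference numbers describe eight soil bacterial networks (two soils,
a control CK and three herbicide dose levels L/M/H): node/link counts
with the reported average degree, shared-node counts between control and
each dose network, and the 2x2 node-membership cells of the reported
preserved module pairs.  They are inputs to arithmetic consistency
checks, not outputs of this package.
"""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from cooccurnet import AbundanceTable, CoNetwork

# (soil, treatment) -> (total nodes, total links, reported average degree)
REFERENCE_INDICES = {
    ("JSJ", "CK"): (520, 1585, 6.096),
    ("JSJ", "L"): (393, 756, 3.847),
    ("JSJ", "M"): (511, 937, 3.667),
    ("JSJ", "H"): (430, 822, 3.823),
    ("LF", "CK"): (621, 1083, 3.488),
    ("LF", "L"): (237, 330, 2.785),
    ("LF", "M"): (339, 413, 2.437),
    ("LF", "H"): (393, 416, 2.117),
}

# (soil, dose) -> shared nodes between the control and the dose network
REFERENCE_SHARED_NODES = {
    ("JSJ", "L"): 196,
    ("JSJ", "M"): 260,
    ("JSJ", "H"): 194,
    ("LF", "L"): 131,
    ("LF", "M"): 151,
    ("LF", "H"): 171,
}

# reported preserved-module rows: (soil, dose, a, b, c, d) where a..d are
# overlapping / only-module-1 / only-module-2 / absent-from-both counts
REFERENCE_PRESERVED_ROWS = [
    ("JSJ", "L", 13, 67, 23, 614),
    ("JSJ", "L", 13, 54, 29, 621),
    ("JSJ", "L", 27, 53, 16, 621),
    ("JSJ", "L", 11, 69, 11, 626),
    ("JSJ", "L", 5, 9, 2, 701),
    ("JSJ", "M", 17, 50, 41, 663),
    ("JSJ", "M", 36, 44, 21, 670),
    ("JSJ", "M", 6, 8, 41, 716),
    ("JSJ", "M", 13, 63, 31, 664),
    ("JSJ", "M", 9, 8, 35, 719),
    ("JSJ", "M", 12, 55, 29, 675),
    ("JSJ", "M", 15, 61, 20, 675),
    ("JSJ", "H", 16, 64, 26, 650),
    ("JSJ", "H", 16, 64, 40, 636),
    ("JSJ", "H", 14, 53, 22, 667),
    ("JSJ", "H", 6, 8, 1, 741),
    ("JSJ", "H", 8, 50, 10, 688),
    ("JSJ", "H", 4, 72, 1, 679),
    ("LF", "L", 7, 42, 13, 665),
    ("LF", "L", 11, 47, 13, 656),
    ("LF", "M", 11, 60, 26, 712),
    ("LF", "M", 23, 35, 23, 728),
    ("LF", "M", 10, 61, 9, 729),
    ("LF", "H", 13, 45, 18, 767),
    ("LF", "H", 6, 35, 12, 790),
]


@pytest.fixture
def reference_index_frame() -> pd.DataFrame:
    rows = [
        dict(soil=soil, treatment=treatment, total_nodes=nodes,
             total_links=links, average_degree=degree)
        for (soil, treatment), (nodes, links, degree) in REFERENCE_INDICES.items()
    ]
    return pd.DataFrame(rows)


def make_table(values: np.ndarray, taxa=None, samples=None,
               treatment="CK") -> AbundanceTable:
    values = np.asarray(values, dtype=float)
    n_taxa, n_samples = values.shape
    taxa = taxa or [f"t{i}" for i in range(n_taxa)]
    samples = samples or [f"s{j}" for j in range(n_samples)]
    metadata = pd.DataFrame(
        dict(soil="synthetic", treatment=treatment,
             day=list(range(1, n_samples + 1)),
             replicate=[1] * n_samples),
        index=pd.Index(samples, name="sample_id"),
    )
    frame = pd.DataFrame(values, index=pd.Index(taxa, name="taxon_id"),
                         columns=samples)
    return AbundanceTable(frame, metadata)


def network_from_edges(edges, r=0.95) -> CoNetwork:
    graph = nx.Graph()
    for edge in edges:
        if len(edge) == 3:
            a, b, weight = edge
        else:
            (a, b), weight = edge, r
        graph.add_edge(a, b, r=weight)
    return CoNetwork(graph)


@pytest.fixture
def tiny_table() -> AbundanceTable:
    return make_table([[1, 2, 3, 4], [2, 4, 6, 8], [5, 1, 4, 2]])


@pytest.fixture
def triangle() -> CoNetwork:
    return network_from_edges([("a", "b"), ("b", "c"), ("c", "a")])


@pytest.fixture
def two_cliques() -> CoNetwork:
    """Two disjoint 5-cliques."""
    graph = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(5))
    nx.set_edge_attributes(graph, 0.95, "r")
    return CoNetwork(graph)


def complete_network(n: int) -> CoNetwork:
    graph = nx.complete_graph(n)
    nx.set_edge_attributes(graph, 0.95, "r")
    return CoNetwork(graph)


def path_network(n: int) -> CoNetwork:
    graph = nx.path_graph(n)
    nx.set_edge_attributes(graph, 0.95, "r")
    return CoNetwork(graph)


def star_network(n_leaves: int) -> CoNetwork:
    graph = nx.star_graph(n_leaves)
    nx.set_edge_attributes(graph, 0.95, "r")
    return CoNetwork(graph)
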