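"""Topological indices, module detection, Zi-Pi node roles, keystones.

The node-role scheme follows Guimera & Amaral's cartographic analysis:
within-module connectivity Zi (z-score of a node's within-module degree
against its module) and among-module connectivity Pi
(1 - sum_s (k_is / k_i)^2 over modules s).  Thresholds Zi >= 2.5 and
Pi >= 0.62 split nodes into peripherals, module hubs, connectors and
network hubs; every non-peripheral node is a keystone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .containers import OTHERS, PREDOMINANT_PHYLA, CoNetwork, phylum_of
from .errors import CoverageWarning, EmptyNetworkWarning, PartitionError

ZI_THRESHOLD = 2.5
PI_THRESHOLD = 0.62
BIG_MODULE_SIZE = 5

ROLE_PERIPHERAL = "peripheral"
ROLE_MODULE_HUB = "module hub"
ROLE_CONNECTOR = "connector"
ROLE_NETWORK_HUB = "network hub"


@dataclass
class ModulePartition:
    """Node -> module-id map with dense 1-based ids, largest module first."""

    membership: dict  # node -> int module id

    @property
    def module_ids(self) -> list:
        return sorted(set(self.membership.values()))

    @property
    def sizes(self) -> dict:
        sizes: dict = {}
        for module in self.membership.values():
            sizes[module] = sizes.get(module, 0) + 1
        return sizes

    def members(self, module_id: int) -> set:
        return {n for n, m in self.membership.items() if m == module_id}

    def big_modules(self, min_size: int = BIG_MODULE_SIZE) -> list:
        return [m for m, s in sorted(self.sizes.items()) if s >= min_size]

    @property
    def nodes(self) -> set:
        return set(self.membership)


def topological_indices(net: CoNetwork) -> dict:
    """Node/link counts, average degree, and path statistics.

    Average path distance is the mean shortest-path length over connected
    node pairs of the largest connected component (these sparse networks
    are practically never connected as a whole); the component's diameter
    is reported alongside.  An empty network yields an all-zero record
    with a warning.
    """
    n, links = net.n_nodes, net.n_links
    if n == 0:
        warnings.warn("empty network: all indices zero", EmptyNetworkWarning,
                      stacklevel=2)
        return dict(total_nodes=0, total_links=0, average_degree=0.0,
                    average_path_distance=0.0, diameter=0)
    components = list(nx.connected_components(net.graph))
    giant = net.graph.subgraph(max(components, key=len))
    if giant.number_of_nodes() > 1:
        path_distance = nx.average_shortest_path_length(giant)
        diameter = nx.diameter(giant)
    else:
        path_distance, diameter = 0.0, 0
    return dict(
        total_nodes=n,
        total_links=links,
        average_degree=2.0 * links / n,
        average_path_distance=path_distance,
        diameter=diameter,
    )


def average_degree(total_nodes: int, total_links: int) -> float:
    """2L/N — exposed separately for checks against published index tables."""
    if total_nodes == 0:
        return 0.0
    return 2.0 * total_links / total_nodes


def detect_modules(
    net: CoNetwork, algorithm: str = "louvain", seed: int = 0
) -> ModulePartition:
    """Modularity-based module detection (Louvain or greedy agglomerative).

    Detection runs on the unweighted graph: correlation signs would break
    modularity's weight assumptions and edge magnitudes are all near the
    threshold anyway.  Communities are split by connected component (two
    components never share a module) and renumbered 1..K by decreasing
    size, ties broken by smallest member label, so ids are deterministic.
    """
    if net.n_nodes == 0:
        raise ValueError("cannot detect modules of an empty network")
    if algorithm == "louvain":
        communities = nx.community.louvain_communities(
            net.graph, weight=None, seed=seed
        )
    elif algorithm == "greedy_modularity":
        communities = nx.community.greedy_modularity_communities(
            net.graph, weight=None
        )
    else:
        raise ValueError(f"unknown module algorithm: {algorithm!r}")

    pieces = []
    for community in communities:
        sub = net.graph.subgraph(community)
        for component in nx.connected_components(sub):
            pieces.append(set(component))
    pieces.sort(key=lambda c: (-len(c), min(str(n) for n in c)))
    membership = {}
    for module_id, piece in enumerate(pieces, start=1):
        for node in piece:
            membership[node] = module_id
    return ModulePartition(membership)


def zipi(net: CoNetwork, part: ModulePartition) -> pd.DataFrame:
    """Per-node connectivity table: ki, ki_in, Zi, Pi.

    Zi uses the population standard deviation of within-module degrees
    over the node's module; a module whose members all have the same
    within-module degree carries no hub signal, so its Zi is 0 by
    convention rather than undefined.
    """
    missing = net.nodes - part.nodes
    if missing:
        raise PartitionError(f"nodes missing from partition: {sorted(missing)[:5]}")
    nodes = sorted(net.graph.nodes, key=str)
    module_of = {n: part.membership[n] for n in nodes}

    ki = {n: net.graph.degree[n] for n in nodes}
    ki_s: dict = {n: {} for n in nodes}
    for a, b in net.graph.edges:
        ki_s[a][module_of[b]] = ki_s[a].get(module_of[b], 0) + 1
        ki_s[b][module_of[a]] = ki_s[b].get(module_of[a], 0) + 1
    ki_in = {n: ki_s[n].get(module_of[n], 0) for n in nodes}

    zi = {}
    for module in set(module_of.values()):
        members = [n for n in nodes if module_of[n] == module]
        within = np.array([ki_in[n] for n in members], dtype=float)
        sd = within.std()  # population sd
        mean = within.mean()
        for n in members:
            zi[n] = 0.0 if sd == 0 else (ki_in[n] - mean) / sd

    pi = {}
    for n in nodes:
        k = ki[n]
        pi[n] = 0.0 if k == 0 else 1.0 - sum(
            (count / k) ** 2 for count in ki_s[n].values()
        )

    return pd.DataFrame(
        {
            "module": [module_of[n] for n in nodes],
            "ki": [ki[n] for n in nodes],
            "ki_in": [ki_in[n] for n in nodes],
            "zi": [zi[n] for n in nodes],
            "pi": [pi[n] for n in nodes],
        },
        index=pd.Index(nodes, name="taxon_id"),
    )


def classify_roles(table: pd.DataFrame) -> pd.DataFrame:
    """Assign one role per node from its (Zi, Pi) coordinates.

    Boundaries follow the standard inequalities exactly: Zi = 2.5 counts
    as hub-side, Pi = 0.62 as connector-side, so (2.5, 0.62) is a network
    hub.
    """
    roles = []
    for zi_value, pi_value in zip(table["zi"], table["pi"]):
        hub = zi_value >= ZI_THRESHOLD
        connector = pi_value >= PI_THRESHOLD
        if hub and connector:
            roles.append(ROLE_NETWORK_HUB)
        elif hub:
            roles.append(ROLE_MODULE_HUB)
        elif connector:
            roles.append(ROLE_CONNECTOR)
        else:
            roles.append(ROLE_PERIPHERAL)
    out = table.copy()
    out["role"] = roles
    return out


def keystone_nodes(role_table: pd.DataFrame) -> set:
    """Keystones are all non-peripheral nodes."""
    return set(role_table.index[role_table["role"] != ROLE_PERIPHERAL])


def keystone_overlap(role_a: pd.DataFrame, role_b: pd.DataFrame) -> dict:
    """Keystone counts of two networks and their intersection by taxon id."""
    keys_a, keys_b = keystone_nodes(role_a), keystone_nodes(role_b)
    return dict(
        keystones_a=len(keys_a),
        keystones_b=len(keys_b),
        shared=len(keys_a & keys_b),
        shared_ids=sorted(keys_a & keys_b, key=str),
    )


def node_phylum_composition(net: CoNetwork, taxonomy: dict) -> pd.Series:
    """Percentage of networked nodes per predominant phylum (plus Others)."""
    uncovered = [n for n in net.graph.nodes if n not in taxonomy]
    if uncovered:
        warnings.warn(
            f"{len(uncovered)} networked taxa missing from taxonomy; "
            "binned as Others",
            CoverageWarning,
            stacklevel=2,
        )
    counts = {p: 0 for p in (*PREDOMINANT_PHYLA, OTHERS)}
    for node in net.graph.nodes:
        counts[phylum_of(taxonomy, node)] += 1
    total = max(net.n_nodes, 1)
    return pd.Series(
        {p: 100.0 * c / total for p, c in counts.items()}, name="percent"
    )
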