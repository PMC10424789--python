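"""Network stability: robustness to random removal and vulnerability.

Global efficiency is E = sum_{i != j} [1 / d(i, j)] / (n (n - 1)) with
d(i, j) the unweighted shortest-path length and disconnected pairs
contributing zero.  Vulnerability is the worst single-node damage,
V = max_i (E - E_i) / E, where E_i is the efficiency of the graph with
node i (and all its links) removed, normalised over its own n - 1 nodes.

Robustness simulates random species loss: remove a growing random
fraction of nodes and count the species that remain *connected* (not
removed and still holding at least one link); averaging the remaining
proportion over repetitions gives the robustness curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .containers import CoNetwork
from .errors import UndefinedVulnerabilityError

#: Removal-fraction grid step: 0.05% of nodes per step.
REMOVAL_STEP = 0.0005


def _graph_of(net) -> nx.Graph:
    return net.graph if isinstance(net, CoNetwork) else net


def global_efficiency(net) -> float:
    """Average inverse shortest-path length over ordered node pairs."""
    graph = _graph_of(net)
    n = graph.number_of_nodes()
    if n < 2:
        return 0.0
    total = 0.0
    for node in graph:
        lengths = nx.single_source_shortest_path_length(graph, node)
        total += sum(1.0 / d for target, d in lengths.items() if target != node)
    return total / (n * (n - 1))


@dataclass
class VulnerabilityResult:
    E: float                 # global efficiency of the intact network
    Ei: dict                 # node -> efficiency after removing that node
    V: float                 # max relative efficiency drop
    argmax_node: object      # node whose removal causes the drop

    def as_dict(self) -> dict:
        return dict(E=self.E, V=self.V, argmax_node=str(self.argmax_node),
                    Ei={str(k): v for k, v in self.Ei.items()})


def vulnerability(net) -> VulnerabilityResult:
    """Worst-case relative efficiency loss over single-node removals.

    Removing a peripheral node can *raise* efficiency (negative term);
    the maximum is still taken over all nodes.
    """
    graph = _graph_of(net)
    e = global_efficiency(graph)
    if e == 0:
        raise UndefinedVulnerabilityError(
            "global efficiency is zero; vulnerability undefined"
        )
    ei: dict = {}
    best_node, best_term = None, -np.inf
    for node in graph:
        reduced = graph.copy()
        reduced.remove_node(node)
        ei[node] = global_efficiency(reduced)
        term = (e - ei[node]) / e
        if term > best_term:
            best_node, best_term = node, term
    return VulnerabilityResult(E=e, Ei=ei, V=float(best_term),
                               argmax_node=best_node)


@dataclass
class RobustnessCurve:
    fractions: np.ndarray    # removal-fraction grid, step REMOVAL_STEP
    mean: np.ndarray         # mean remaining proportion per fraction
    sd: np.ndarray           # spread over repetitions
    n_repetitions: int
    seed: int


def robustness_curve(
    net, n_repetitions: int = 100, seed: int = 0
) -> RobustnessCurve:
    """Remaining proportion of connected species under random removal.

    Each repetition draws one uniformly random removal *order*; the first
    ``round(f * n)`` nodes of that order are the removed set at fraction
    ``f`` (the first k elements of a random permutation are a uniform
    k-subset, so every grid point sees a uniform random removal, and the
    curve is non-increasing within each repetition).  A node survives if
    it is not removed and keeps at least one surviving neighbour; the
    proportion is taken over the original node count.

    The per-repetition sweep is closed-form: with p_i the position of
    node i in the removal order and m_i the largest position among its
    neighbours, node i survives stage k iff min(p_i, m_i) >= k, so one
    reverse cumulative histogram yields the whole curve.
    """
    graph = _graph_of(net)
    n = graph.number_of_nodes()
    if n == 0:
        raise ValueError("robustness of an empty network is undefined")
    if n_repetitions < 1:
        raise ValueError("n_repetitions must be >= 1")
    nodes = list(graph.nodes)
    index = {node: i for i, node in enumerate(nodes)}
    neighbours = [np.array([index[v] for v in graph[u]], dtype=int)
                  for u in nodes]

    rng = np.random.default_rng(seed)
    fractions = np.round(np.arange(0, round(1 / REMOVAL_STEP) + 1)
                         * REMOVAL_STEP, 10)
    ks = np.rint(fractions * n).astype(int)
    per_rep = np.empty((n_repetitions, len(fractions)))
    for rep in range(n_repetitions):
        order = rng.permutation(n)
        position = np.empty(n, dtype=int)
        position[order] = np.arange(n)
        last_neighbour = np.array(
            [position[nbrs].max() if len(nbrs) else -1 for nbrs in neighbours]
        )
        survives_until = np.minimum(position, last_neighbour)
        # survivors(k) = #{i : survives_until_i >= k}, via a suffix count
        counts = np.bincount(survives_until + 1, minlength=n + 2)
        suffix = np.cumsum(counts[::-1])[::-1]
        alive = suffix[1:]  # alive[k] = survivors(k) for k = 0..n
        per_rep[rep] = alive[ks] / n
    return RobustnessCurve(
        fractions=fractions,
        mean=per_rep.mean(axis=0),
        sd=per_rep.std(axis=0),
        n_repetitions=n_repetitions,
        seed=seed,
    )


def robustness_scalar(curve: RobustnessCurve, at_fraction: float = 0.5) -> float:
    """Mean remaining proportion at one removal fraction (interpolated)."""
    if not 0.0 <= at_fraction <= 1.0:
        raise ValueError("at_fraction must be in [0, 1]")
    return float(np.interp(at_fraction, curve.fractions, curve.mean))
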