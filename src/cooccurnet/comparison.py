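"""Cross-network and cross-community comparison statistics.

Covers the control-vs-treatment comparisons: shared nodes and links,
edge-set dissimilarity, Bray-Curtis community distances, ANOSIM and
Mantel permutation tests, and preserved-module detection by one-sided
Fisher's exact test with Bonferroni adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .containers import AbundanceTable, CoNetwork
from .errors import (
    GroupSizeError,
    PartitionError,
    UndefinedCorrelationError,
    UndefinedDissimilarityError,
    UndefinedDistanceError,
)
from .topology import BIG_MODULE_SIZE, ModulePartition

DISSIMILARITY_VARIANTS = ("jaccard_links", "sorensen_links", "poisot_wn")


def _link_set(net: CoNetwork, signed: bool) -> set:
    if not signed:
        return net.links
    return {(frozenset((a, b)), 1 if data["r"] >= 0 else -1)
            for a, b, data in net.graph.edges(data=True)}


def shared_elements(
    net_a: CoNetwork, net_b: CoNetwork, signed: bool = False
) -> tuple[int, int]:
    """Shared node and link counts.

    Links match by unordered taxon pair; with ``signed=True`` a link only
    matches when its correlation sign agrees as well (weights are never
    compared).
    """
    shared_nodes = len(net_a.nodes & net_b.nodes)
    shared_links = len(_link_set(net_a, signed) & _link_set(net_b, signed))
    return shared_nodes, shared_links


def network_dissimilarity(
    net_a: CoNetwork,
    net_b: CoNetwork,
    variant: str = "jaccard_links",
    signed: bool = False,
) -> float:
    """Edge-set dissimilarity between two networks, in [0, 1].

    ``jaccard_links``: 1 - a / (LA + LB - a); ``sorensen_links``:
    1 - 2a / (LA + LB); ``poisot_wn``: the Whittaker-form beta over edge
    sets, (LA + LB - 2a) / (LA + LB - a) — algebraically equal to
    ``jaccard_links`` for edge-set comparison, kept as an explicit label.
    The variant is part of the reported value because published
    dissimilarities rarely state which form was used.
    """
    if variant not in DISSIMILARITY_VARIANTS:
        raise ValueError(f"unknown dissimilarity variant: {variant!r}")
    la, lb = net_a.n_links, net_b.n_links
    if la == 0 and lb == 0:
        raise UndefinedDissimilarityError("both networks are empty")
    a = len(_link_set(net_a, signed) & _link_set(net_b, signed))
    if variant == "sorensen_links":
        return 1.0 - 2.0 * a / (la + lb)
    return (la + lb - 2.0 * a) / (la + lb - a)


def bray_curtis(table: AbundanceTable, sample_subset=None) -> pd.DataFrame:
    """Pairwise Bray-Curtis distances between samples."""
    values = table.values
    if sample_subset is not None:
        values = values[list(sample_subset)]
    if values.shape[1] < 2:
        raise ValueError("need at least 2 samples for a distance matrix")
    zero = values.sum(axis=0) == 0
    if zero.any():
        raise UndefinedDistanceError(
            f"all-zero samples: {list(values.columns[zero])}"
        )
    matrix = squareform(pdist(values.to_numpy(dtype=float).T, metric="braycurtis"))
    return pd.DataFrame(matrix, index=values.columns, columns=values.columns)


def euclidean_profile_distance(profile: pd.Series) -> pd.DataFrame:
    """|x_u - x_v| distances between samples for one scalar profile row."""
    x = profile.to_numpy(dtype=float)
    matrix = np.abs(x[:, None] - x[None, :])
    return pd.DataFrame(matrix, index=profile.index, columns=profile.index)


@dataclass
class AnosimResult:
    R: float
    p: float
    n_permutations: int
    seed: int


def _as_matrix(dist) -> np.ndarray:
    matrix = dist.to_numpy(dtype=float) if isinstance(dist, pd.DataFrame) else np.asarray(dist, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(matrix, matrix.T) or not np.allclose(np.diag(matrix), 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    return matrix


def anosim_r(dist, groups) -> float:
    """The ANOSIM statistic R = (rb - rw) / (M / 2).

    Ranks all M = n(n-1)/2 pairwise distances (midpoint ties), takes the
    mean rank between groups (rb) and within groups (rw).  R is near 0
    when grouping is unrelated to distance, 1 when every between-group
    distance exceeds every within-group one.
    """
    matrix = _as_matrix(dist)
    labels = np.asarray(groups)
    iu, ju = np.triu_indices(matrix.shape[0], k=1)
    ranks = stats.rankdata(matrix[iu, ju], method="average")
    between = labels[iu] != labels[ju]
    m = ranks.size
    return float((ranks[between].mean() - ranks[~between].mean()) / (m / 2.0))


def anosim(dist, groups, n_permutations: int = 999, seed: int = 0) -> AnosimResult:
    """ANOSIM with a label-permutation p-value (add-one rule).

    ``p = (1 + #{permuted R >= observed R}) / (1 + n_permutations)``;
    the observed labelling is counted once, so p is never zero.
    """
    matrix = _as_matrix(dist)
    labels = np.asarray(groups)
    if labels.size != matrix.shape[0]:
        raise ValueError("one group label per sample required")
    unique, counts = np.unique(labels, return_counts=True)
    if unique.size < 2:
        raise GroupSizeError("ANOSIM needs at least two groups")
    if (counts < 2).any():
        small = unique[counts < 2].tolist()
        raise GroupSizeError(f"groups with fewer than two samples: {small}")
    observed = anosim_r(matrix, labels)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        permuted = rng.permutation(labels)
        if anosim_r(matrix, permuted) >= observed - 1e-12:
            hits += 1
    return AnosimResult(
        R=observed,
        p=(1 + hits) / (1 + n_permutations),
        n_permutations=n_permutations,
        seed=seed,
    )


@dataclass
class MantelResult:
    r: float
    p: float
    n_permutations: int
    seed: int
    category: str | None = None


def mantel(
    d1,
    d2,
    n_permutations: int = 999,
    seed: int = 0,
    category: str | None = None,
) -> MantelResult:
    """Mantel test: Pearson r between two distance matrices, one-sided
    permutation p (rows/columns of the second matrix permuted jointly,
    counting permuted r >= observed, add-one rule)."""
    m1, m2 = _as_matrix(d1), _as_matrix(d2)
    if m1.shape != m2.shape:
        raise ValueError("distance matrices must have the same shape")
    iu, ju = np.triu_indices(m1.shape[0], k=1)
    x, y = m1[iu, ju], m2[iu, ju]
    if x.std() == 0 or y.std() == 0:
        raise UndefinedCorrelationError("constant off-diagonal distances")
    observed = float(np.corrcoef(x, y)[0, 1])
    rng = np.random.default_rng(seed)
    n = m1.shape[0]
    hits = 0
    for _ in range(n_permutations):
        order = rng.permutation(n)
        permuted = m2[np.ix_(order, order)][iu, ju]
        if float(np.corrcoef(x, permuted)[0, 1]) >= observed - 1e-12:
            hits += 1
    return MantelResult(
        r=observed,
        p=(1 + hits) / (1 + n_permutations),
        n_permutations=n_permutations,
        seed=seed,
        category=category,
    )


def build_contingency(module_a, module_b, nodes_a, nodes_b) -> tuple[int, int, int, int]:
    """2x2 node-membership contingency over the union of two node sets.

    a = nodes in both modules; b = only in module 1; c = only in module 2;
    d = in neither, with the universe being the union of the two networks'
    node sets, so a + b + c + d = |nodes_a | nodes_b|.
    """
    module_a, module_b = set(module_a), set(module_b)
    nodes_a, nodes_b = set(nodes_a), set(nodes_b)
    if not module_a <= nodes_a:
        raise PartitionError("module 1 not contained in its network's nodes")
    if not module_b <= nodes_b:
        raise PartitionError("module 2 not contained in its network's nodes")
    universe = nodes_a | nodes_b
    a = len(module_a & module_b)
    b = len(module_a - module_b)
    c = len(module_b - module_a)
    d = len(universe) - a - b - c
    return a, b, c, d


def fisher_one_sided(a: int, b: int, c: int, d: int) -> float:
    """One-sided (over-enrichment) Fisher exact p for a 2x2 table —
    the hypergeometric upper tail P(X >= a)."""
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="greater")[1])


@dataclass
class PreservedModulePair:
    module_a: int
    module_b: int
    a: int
    b: int
    c: int
    d: int
    p: float
    p_adjusted: float
    preserved: bool


def preserved_modules(
    part_a: ModulePartition,
    part_b: ModulePartition,
    min_module_size: int = BIG_MODULE_SIZE,
    alpha: float = 0.05,
) -> list[PreservedModulePair]:
    """Detect module pairs sharing more nodes than a hypergeometric null.

    Every pair of big modules (>= ``min_module_size`` nodes in both
    partitions) is tested one-sided for node over-enrichment; p-values
    are Bonferroni-adjusted with m = the number of pairs tested for this
    network pair.  A pair is preserved when adjusted p < alpha.  Results
    are sorted by adjusted p (ties by module ids).
    """
    nodes_a, nodes_b = part_a.nodes, part_b.nodes
    big_a = part_a.big_modules(min_module_size)
    big_b = part_b.big_modules(min_module_size)
    pairs: list[PreservedModulePair] = []
    m = len(big_a) * len(big_b)
    for ma in big_a:
        members_a = part_a.members(ma)
        for mb in big_b:
            a, b, c, d = build_contingency(
                members_a, part_b.members(mb), nodes_a, nodes_b
            )
            p = fisher_one_sided(a, b, c, d)
            adjusted = min(1.0, p * m)
            pairs.append(
                PreservedModulePair(
                    module_a=ma, module_b=mb, a=a, b=b, c=c, d=d,
                    p=p, p_adjusted=adjusted, preserved=adjusted < alpha,
                )
            )
    pairs.sort(key=lambda pair: (pair.p_adjusted, pair.p,
                                 pair.module_a, pair.module_b))
    return pairs


@dataclass
class NetworkComparison:
    """One control-vs-treatment comparison record (one table row)."""

    shared_nodes: int
    shared_links: int
    dissimilarity: float
    dissimilarity_variant: str
    anosim_R: float
    anosim_p: float
    n_permutations: int
    seed: int
    preserved: list = field(default_factory=list)

    def as_dict(self) -> dict:
        out = dict(
            shared_nodes=self.shared_nodes,
            shared_links=self.shared_links,
            dissimilarity=self.dissimilarity,
            dissimilarity_variant=self.dissimilarity_variant,
            anosim_R=self.anosim_R,
            anosim_p=self.anosim_p,
            n_permutations=self.n_permutations,
            seed=self.seed,
            n_preserved_modules=sum(p.preserved for p in self.preserved),
            n_module_pairs_tested=len(self.preserved),
        )
        return out


def compare_networks(
    net_a: CoNetwork,
    net_b: CoNetwork,
    community: AbundanceTable,
    groups,
    part_a: ModulePartition | None = None,
    part_b: ModulePartition | None = None,
    variant: str = "jaccard_links",
    n_permutations: int = 999,
    seed: int = 0,
    min_module_size: int = BIG_MODULE_SIZE,
    alpha: float = 0.05,
) -> NetworkComparison:
    """Full pairwise comparison: shared elements, dissimilarity, ANOSIM
    on the combined community samples, and (if partitions are given)
    preserved modules."""
    shared_nodes, shared_links = shared_elements(net_a, net_b)
    dissimilarity = network_dissimilarity(net_a, net_b, variant)
    result = anosim(bray_curtis(community), groups, n_permutations, seed)
    preserved = (
        preserved_modules(part_a, part_b, min_module_size, alpha)
        if part_a is not None and part_b is not None
        else []
    )
    return NetworkComparison(
        shared_nodes=shared_nodes,
        shared_links=shared_links,
        dissimilarity=dissimilarity,
        dissimilarity_variant=variant,
        anosim_R=result.R,
        anosim_p=result.p,
        n_permutations=n_permutations,
        seed=seed,
        preserved=preserved,
    )
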