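"""Shared elements, dissimilarity, Bray-Curtis, ANOSIM, Mantel, Fisher."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from cooccurnet import (
    anosim,
    anosim_r,
    bray_curtis,
    build_contingency,
    fisher_one_sided,
    mantel,
    network_dissimilarity,
    preserved_modules,
    shared_elements,
)
from cooccurnet.errors import (
    GroupSizeError,
    PartitionError,
    UndefinedCorrelationError,
    UndefinedDissimilarityError,
    UndefinedDistanceError,
)
from cooccurnet.topology import ModulePartition

from conftest import make_table, network_from_edges


class TestSharedElements:
    def test_identity(self, triangle):
        assert shared_elements(triangle, triangle) == (3, 3)

    def test_disjoint(self, triangle):
        other = network_from_edges([("x", "y")])
        assert shared_elements(triangle, other) == (0, 0)

    def test_triangle_vs_path(self, triangle):
        path = network_from_edges([("a", "b"), ("b", "c")])
        assert shared_elements(triangle, path) == (3, 2)

    def test_link_identity_ignores_sign(self, triangle):
        flipped = network_from_edges([("a", "b", -0.95), ("b", "c", 0.91),
                                      ("c", "a", 0.99)])
        assert shared_elements(triangle, flipped) == (3, 3)
        # the opt-in signed mode counts the flipped edge as different
        assert shared_elements(triangle, flipped, signed=True) == (3, 2)


class TestNetworkDissimilarity:
    def test_identity_zero(self, triangle):
        for variant in ("jaccard_links", "sorensen_links", "poisot_wn"):
            assert network_dissimilarity(triangle, triangle, variant) == 0.0

    def test_edge_disjoint_one(self, triangle):
        other = network_from_edges([("x", "y"), ("y", "z")])
        for variant in ("jaccard_links", "sorensen_links", "poisot_wn"):
            assert network_dissimilarity(triangle, other, variant) == 1.0

    def test_symmetry(self, triangle):
        path = network_from_edges([("a", "b"), ("b", "c"), ("c", "d")])
        assert network_dissimilarity(triangle, path) == pytest.approx(
            network_dissimilarity(path, triangle))

    def test_both_empty_undefined(self):
        from cooccurnet import CoNetwork

        with pytest.raises(UndefinedDissimilarityError):
            network_dissimilarity(CoNetwork(), CoNetwork())

    def test_jaccard_from_published_link_counts(self):
        """1585 and 756 links sharing 71 give 1 - 71/2270 ~ 0.9687."""
        rng = np.random.default_rng(0)
        # synthetic stand-ins with exactly those link counts and overlap
        shared = [(f"s{i}", f"s{i}'") for i in range(71)]
        only_a = [(f"a{i}", f"a{i}'") for i in range(1585 - 71)]
        only_b = [(f"b{i}", f"b{i}'") for i in range(756 - 71)]
        net_a = network_from_edges(shared + only_a)
        net_b = network_from_edges(shared + only_b)
        value = network_dissimilarity(net_a, net_b, "jaccard_links")
        assert value == pytest.approx(1 - 71 / 2270, abs=1e-12)
        assert round(value, 4) == 0.9687


class TestBrayCurtis:
    def test_identity_and_range(self):
        table = make_table([[1, 1, 4], [2, 2, 0], [3, 3, 1]])
        distances = bray_curtis(table)
        assert distances.iloc[0, 1] == 0.0
        assert ((distances.to_numpy() >= 0) & (distances.to_numpy() <= 1)).all()

    def test_disjoint_taxa(self):
        table = make_table([[1, 0], [2, 0], [0, 3]])
        assert bray_curtis(table).iloc[0, 1] == pytest.approx(1.0)

    def test_hand_computed(self):
        table = make_table([[1, 3], [2, 2], [3, 1]])
        assert bray_curtis(table).iloc[0, 1] == pytest.approx(1.0 / 3.0)

    def test_zero_sample_rejected(self):
        table = make_table([[1, 0], [2, 0]])
        with pytest.raises(UndefinedDistanceError):
            bray_curtis(table)


def rank_midpoint(values):
    """Independent midpoint ranking for the ANOSIM oracle."""
    order = np.argsort(values, kind="stable")
    ranks = np.empty(len(values), dtype=float)
    i = 0
    sorted_values = np.asarray(values)[order]
    while i < len(values):
        j = i
        while j + 1 < len(values) and sorted_values[j + 1] == sorted_values[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


def anosim_r_oracle(matrix, labels):
    n = matrix.shape[0]
    pairs = list(itertools.combinations(range(n), 2))
    ranks = rank_midpoint([matrix[i, j] for i, j in pairs])
    between = np.array([labels[i] != labels[j] for i, j in pairs])
    m = len(pairs)
    return (ranks[between].mean() - ranks[~between].mean()) / (m / 2)


class TestAnosim:
    def separated(self):
        # two groups of 3; every between-distance exceeds every within
        within = 0.1
        matrix = np.full((6, 6), 0.9)
        for group in (range(3), range(3, 6)):
            for i in group:
                for j in group:
                    matrix[i, j] = 0.0 if i == j else within
        return matrix, np.array(["g1"] * 3 + ["g2"] * 3)

    def test_maximal_separation_r_one(self):
        matrix, labels = self.separated()
        assert anosim_r(matrix, labels) == pytest.approx(1.0)

    def test_tied_identical_samples_r_zero(self):
        matrix = np.zeros((6, 6))
        labels = np.array(["g1"] * 3 + ["g2"] * 3)
        assert anosim_r(matrix, labels) == pytest.approx(0.0)

    def test_null_r_near_zero(self):
        """Random labels on a structureless matrix: E[R] ~ 0 (20 seeds)."""
        rs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            raw = rng.uniform(size=(10, 10))
            matrix = (raw + raw.T) / 2
            np.fill_diagonal(matrix, 0.0)
            labels = rng.permutation(["g1"] * 5 + ["g2"] * 5)
            rs.append(anosim_r(matrix, labels))
        assert abs(np.mean(rs)) < 0.1

    def test_r_statistic_matches_independent_oracle(self):
        rng = np.random.default_rng(3)
        raw = rng.uniform(size=(8, 8))
        matrix = (raw + raw.T) / 2
        np.fill_diagonal(matrix, 0.0)
        labels = np.array(["a"] * 4 + ["b"] * 4)
        assert anosim_r(matrix, labels) == pytest.approx(
            anosim_r_oracle(matrix, labels), abs=1e-12)

    def test_r_matches_reference_implementation(self):
        """Cross-check the statistic against scikit-bio on random data."""
        skbio_distance = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(11)
        raw = rng.uniform(size=(9, 9))
        matrix = (raw + raw.T) / 2
        np.fill_diagonal(matrix, 0.0)
        labels = ["a"] * 4 + ["b"] * 5
        reference = skbio_distance.anosim(
            skbio_distance.DistanceMatrix(matrix), grouping=list(labels),
            permutations=0,
        )
        assert anosim_r(matrix, labels) == pytest.approx(
            reference["test statistic"], abs=1e-12)

    def test_permutation_p_matches_enumeration(self):
        """n = 4 (2+2): sampled permutation p agrees with exhaustive
        enumeration over all 4! relabelings within 0.01."""
        rng = np.random.default_rng(5)
        raw = rng.uniform(size=(4, 4))
        matrix = (raw + raw.T) / 2
        np.fill_diagonal(matrix, 0.0)
        labels = np.array(["a", "a", "b", "b"])
        observed = anosim_r_oracle(matrix, labels)
        hits = total = 0
        for perm in itertools.permutations(range(4)):
            total += 1
            if anosim_r_oracle(matrix, labels[list(perm)]) >= observed - 1e-12:
                hits += 1
        exact = hits / total
        result = anosim(matrix, labels, n_permutations=20_000, seed=0)
        assert result.p == pytest.approx(exact, abs=0.01)

    def test_group_of_one_rejected(self):
        matrix = np.zeros((3, 3))
        with pytest.raises(GroupSizeError):
            anosim(matrix, ["a", "a", "b"], n_permutations=9)


class TestMantel:
    def symmetric(self, seed, n=6):
        rng = np.random.default_rng(seed)
        raw = rng.uniform(size=(n, n))
        matrix = (raw + raw.T) / 2
        np.fill_diagonal(matrix, 0.0)
        return matrix

    def test_identity_r_one(self):
        matrix = self.symmetric(0)
        result = mantel(matrix, matrix, n_permutations=9, seed=0)
        assert result.r == pytest.approx(1.0)

    def test_affine_invariance(self):
        matrix = self.symmetric(1)
        scaled = 3.0 * matrix + 0.5
        np.fill_diagonal(scaled, 0.0)
        result = mantel(matrix, scaled, n_permutations=9, seed=0)
        assert result.r == pytest.approx(1.0)

    def test_r_matches_reference_implementation(self):
        skbio_distance = pytest.importorskip("skbio.stats.distance")
        d1, d2 = self.symmetric(2), self.symmetric(3)
        reference_r, _, _ = skbio_distance.mantel(
            d1, d2, method="pearson", permutations=0, alternative="greater")
        result = mantel(d1, d2, n_permutations=9, seed=0)
        assert result.r == pytest.approx(reference_r, abs=1e-12)

    def test_permutation_p_matches_enumeration(self):
        """4x4 matrices: sampled p vs all 4! joint permutations."""
        d1, d2 = self.symmetric(4, n=4), self.symmetric(5, n=4)
        iu = np.triu_indices(4, k=1)
        observed = np.corrcoef(d1[iu], d2[iu])[0, 1]
        hits = total = 0
        for perm in itertools.permutations(range(4)):
            total += 1
            permuted = d2[np.ix_(perm, perm)]
            if np.corrcoef(d1[iu], permuted[iu])[0, 1] >= observed - 1e-12:
                hits += 1
        exact = hits / total
        result = mantel(d1, d2, n_permutations=20_000, seed=1)
        assert result.p == pytest.approx(exact, abs=0.01)

    def test_constant_matrix_rejected(self):
        flat = np.zeros((4, 4))
        with pytest.raises(UndefinedCorrelationError):
            mantel(flat, self.symmetric(6, n=4), n_permutations=9)


class TestContingency:
    def test_full_overlap(self):
        universe = set("abcde")
        assert build_contingency(universe, universe, universe, universe) == \
            (5, 0, 0, 0)

    def test_disjoint_modules_disjoint_networks(self):
        nodes_a = {f"a{i}" for i in range(5)}
        nodes_b = {f"b{i}" for i in range(7)}
        cells = build_contingency({"a0", "a1"}, {"b0", "b1", "b2"},
                                  nodes_a, nodes_b)
        assert cells == (0, 2, 3, 7)

    def test_module_outside_network_rejected(self):
        with pytest.raises(PartitionError):
            build_contingency({"x"}, {"a"}, {"a", "b"}, {"a"})

    def test_cells_sum_to_union(self):
        rng = np.random.default_rng(0)
        labels = np.array([f"n{i}" for i in range(40)])
        nodes_a = set(labels[rng.random(40) < 0.7])
        nodes_b = set(labels[rng.random(40) < 0.7])
        module_a = set(rng.choice(sorted(nodes_a), 5, replace=False))
        module_b = set(rng.choice(sorted(nodes_b), 5, replace=False))
        cells = build_contingency(module_a, module_b, nodes_a, nodes_b)
        assert sum(cells) == len(nodes_a | nodes_b)


def hypergeometric_tail(a, b, c, d):
    """Independent oracle: direct summation of the upper tail
    P(X >= a) for X hypergeometric with module sizes as margins."""
    total = a + b + c + d
    size_1 = a + b
    size_2 = a + c
    denominator = math.comb(total, size_2)
    upper = min(size_1, size_2)
    return sum(
        math.comb(size_1, k) * math.comb(total - size_1, size_2 - k)
        for k in range(a, upper + 1)
    ) / denominator


class TestFisher:
    def test_published_cells_match_tail_summation(self):
        """Cells (13, 67, 23, 614): p equals the hypergeometric tail
        sum_{k=13}^{36} C(80,k) C(637,36-k) / C(717,36)."""
        expected = hypergeometric_tail(13, 67, 23, 614)
        assert fisher_one_sided(13, 67, 23, 614) == pytest.approx(
            expected, rel=1e-10)

    @pytest.mark.parametrize("seed", range(10))
    def test_random_tables_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        while True:
            cells = rng.integers(0, 50, size=4)
            if cells.sum() <= 200 and cells.sum() > 0:
                break
        a, b, c, d = (int(x) for x in cells)
        assert fisher_one_sided(a, b, c, d) == pytest.approx(
            hypergeometric_tail(a, b, c, d), abs=1e-10)


class TestPreservedModules:
    def test_identical_partitions_self_preserved(self):
        membership = {f"n{i}": (i // 10) + 1 for i in range(30)}
        part = ModulePartition(membership)
        pairs = preserved_modules(part, part, min_module_size=5, alpha=0.05)
        diagonal = [p for p in pairs if p.module_a == p.module_b]
        assert len(diagonal) == 3
        for pair in diagonal:
            assert pair.a == 10
            assert pair.preserved
        # off-diagonal pairs share nothing
        for pair in pairs:
            if pair.module_a != pair.module_b:
                assert pair.a == 0 and not pair.preserved

    def test_sorted_by_adjusted_p(self):
        membership_a = {f"n{i}": (i // 8) + 1 for i in range(32)}
        rng = np.random.default_rng(1)
        shuffled = rng.permutation([f"n{i}" for i in range(32)])
        membership_b = {node: (k // 8) + 1 for k, node in enumerate(shuffled)}
        pairs = preserved_modules(ModulePartition(membership_a),
                                  ModulePartition(membership_b))
        adjusted = [p.p_adjusted for p in pairs]
        assert adjusted == sorted(adjusted)

    def test_bonferroni_uses_pair_count(self):
        membership = {f"n{i}": (i // 10) + 1 for i in range(20)}
        part = ModulePartition(membership)
        pairs = preserved_modules(part, part)
        assert len(pairs) == 4  # 2 x 2 big-module pairs
        for pair in pairs:
            assert pair.p_adjusted == pytest.approx(min(1.0, pair.p * 4))
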