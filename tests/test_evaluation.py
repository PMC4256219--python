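import itertools

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score, mutual_info_score, rand_score

from gofunsim import (
    cluster_graph,
    compare_partitions,
    pearson,
    roc_auc,
    sample_negatives,
)
from gofunsim.evaluation import EvaluationError


class TestSampleNegatives:
    PROTEINS = ["a", "b", "c", "d"]

    def test_samples_distinct_unordered_pairs(self):
        pairs = sample_negatives(self.PROTEINS, 3, seed=1)
        assert len(pairs) == 3
        assert len({frozenset(p) for p in pairs}) == 3
        assert all(a != b for a, b in pairs)

    def test_deterministic_under_seed(self):
        assert sample_negatives(self.PROTEINS, 3, seed=5) == sample_negatives(
            self.PROTEINS, 3, seed=5
        )

    def test_forbidden_pairs_excluded(self):
        forbidden = [("a", "b"), ("c", "d")]
        for _ in range(5):
            pairs = sample_negatives(self.PROTEINS, 4, forbidden, seed=3)
            assert not ({frozenset(p) for p in pairs} & {frozenset(f) for f in forbidden})

    def test_exhausted_pool_is_an_error(self):
        all_pairs = list(itertools.combinations(self.PROTEINS, 2))
        with pytest.raises(EvaluationError):
            sample_negatives(self.PROTEINS, 1, all_pairs, seed=0)


class TestRocAuc:
    def test_perfect_separation(self):
        auc, _ = roc_auc([0.9, 0.8], [0.2, 0.1])
        assert auc == 1.0

    def test_partial_overlap(self):
        auc, _ = roc_auc([0.9, 0.4], [0.5, 0.1])
        assert auc == pytest.approx(0.75)

    def test_all_ties_give_half(self):
        auc, _ = roc_auc([0.5], [0.5])
        assert auc == pytest.approx(0.5)

    def test_nan_rejected(self):
        with pytest.raises(EvaluationError):
            roc_auc([0.5, float("nan")], [0.1])

    def test_complement_symmetry(self):
        rng = np.random.default_rng(9)
        pos = rng.random(30)
        neg = rng.random(40)
        assert roc_auc(pos, neg)[0] + roc_auc(neg, pos)[0] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_exhaustive_pair_ordering_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pos = rng.integers(0, 10, size=rng.integers(2, 15)) / 10
        neg = rng.integers(0, 10, size=rng.integers(2, 15)) / 10
        wins = sum(
            1.0 if p > n else 0.5 if p == n else 0.0
            for p in pos
            for n in neg
        )
        auc, points = roc_auc(pos, neg)
        assert auc == pytest.approx(wins / (len(pos) * len(neg)))
        assert points["tpr"].iloc[-1] == 1.0 and points["fpr"].iloc[-1] == 1.0


class TestPearson:
    def test_linear_relations(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert pearson(x, [2 * v + 1 for v in x]) == pytest.approx(1.0)
        assert pearson(x, [-v for v in x]) == pytest.approx(-1.0)

    def test_hand_value(self):
        assert pearson([1, 2, 3], [1, 3, 2]) == pytest.approx(0.5)

    def test_zero_variance_rejected(self):
        with pytest.raises(EvaluationError):
            pearson([1, 1, 1], [1, 2, 3])


class TestClusterGraph:
    @staticmethod
    def _clique_edges(nodes, weight=1.0):
        return [(a, b, weight) for a, b in itertools.combinations(nodes, 2)]

    def test_two_cliques_with_bridge(self):
        left = [f"l{i}" for i in range(4)]
        right = [f"r{i}" for i in range(4)]
        edges = (
            self._clique_edges(left)
            + self._clique_edges(right)
            + [("l0", "r0", 0.1)]
        )
        part = cluster_graph(edges, seed=0)
        assert len({part[n] for n in left}) == 1
        assert len({part[n] for n in right}) == 1
        assert part["l0"] != part["r0"]

    def test_single_edge_one_cluster(self):
        part = cluster_graph([("a", "b", 1.0)], seed=0)
        assert part["a"] == part["b"]

    def test_isolated_nodes_become_singletons(self):
        part = cluster_graph([], seed=0, nodes=["a", "b", "c"])
        assert len(set(part.values())) == 3

    def test_empty_graph_rejected(self):
        with pytest.raises(EvaluationError):
            cluster_graph([], seed=0)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(4)
        nodes = [f"n{i}" for i in range(30)]
        edges = [
            (nodes[i], nodes[j], float(rng.random()))
            for i in range(30)
            for j in range(i + 1, 30)
            if rng.random() < 0.2
        ]
        assert cluster_graph(edges, seed=11) == cluster_graph(edges, seed=11)


class TestComparePartitions:
    def test_identical_partitions(self):
        g = {"a": 1, "b": 1, "c": 2, "d": 2}
        cmp = compare_partitions(g, g)
        assert cmp.nmi == pytest.approx(1.0)
        assert cmp.rand_index == pytest.approx(1.0)

    def test_orthogonal_partitions(self):
        g = {"a": 1, "b": 1, "c": 2, "d": 2}
        c = {"a": 1, "b": 2, "c": 1, "d": 2}
        cmp = compare_partitions(g, c)
        assert cmp.mutual_information == pytest.approx(0.0, abs=1e-12)
        assert cmp.nmi == pytest.approx(0.0, abs=1e-12)
        assert cmp.rand_index == pytest.approx(2 / 6)

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(2)
        g = {f"p{i}": int(rng.integers(0, 4)) for i in range(40)}
        relabel = {0: 9, 1: 7, 2: 5, 3: 3}
        c = {p: relabel[v] for p, v in g.items()}
        cmp = compare_partitions(g, c)
        assert cmp.nmi == pytest.approx(1.0)
        assert cmp.rand_index == pytest.approx(1.0)

    def test_mismatched_universes_rejected(self):
        with pytest.raises(EvaluationError):
            compare_partitions({"a": 1}, {"b": 1})

    def test_contingency_margins_are_cluster_sizes(self):
        rng = np.random.default_rng(3)
        g = {f"p{i}": int(rng.integers(0, 3)) for i in range(30)}
        c = {f"p{i}": int(rng.integers(0, 4)) for i in range(30)}
        cmp = compare_partitions(g, c)
        assert cmp.contingency.to_numpy().sum() == 30
        assert cmp.contingency.sum(axis=1).to_dict() == cmp.sizes_truth
        assert cmp.contingency.sum(axis=0).to_dict() == cmp.sizes_clustering

    @pytest.mark.parametrize("seed", range(20))
    def test_cross_check_against_sklearn(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 50))
        g = {f"p{i}": int(rng.integers(0, 4)) for i in range(n)}
        c = {f"p{i}": int(rng.integers(0, 3)) for i in range(n)}
        keys = sorted(g)
        gv = [g[k] for k in keys]
        cv = [c[k] for k in keys]
        cmp = compare_partitions(g, c)
        assert cmp.mutual_information == pytest.approx(mutual_info_score(gv, cv))
        assert cmp.rand_index == pytest.approx(rand_score(gv, cv))

    def test_sqrt_variant(self):
        g = {"a": 1, "b": 1, "c": 2, "d": 2}
        c = {"a": 1, "b": 1, "c": 2, "d": 1}
        s = compare_partitions(g, c, variant="sum")
        q = compare_partitions(g, c, variant="sqrt")
        assert 0 < s.nmi < 1 and 0 < q.nmi < 1
        assert s.nmi != pytest.approx(q.nmi)

    def test_rand_one_iff_identical_up_to_labels(self):
        g = {"a": 0, "b": 0, "c": 1, "d": 1}
        c = {"a": 0, "b": 1, "c": 1, "d": 1}
        assert compare_partitions(g, c).rand_index < 1.0
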