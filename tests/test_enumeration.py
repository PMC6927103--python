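import networkx as nx
import numpy as np
import pytest

from vaffp.enumeration import (
    count_spanning_trees,
    enumerate_valid_trees,
    min_epsilon_search,
    rank_trees_by_weight,
)
from vaffp.graphs import build_approximate_graph, build_strict_graph
from vaffp.model import ClonalTree, ReadCountMatrix, VAFMatrix

from _oracles import (
    all_arborescences,
    min_epsilon_oracle,
    random_strict_instance,
    valid_trees_oracle,
)


def tree_keys(solutions):
    return {frozenset(t.parent.items()) for t in solutions.trees}


class TestEnumerate:
    def test_sum_condition_excludes_star(self, chain_F):
        G = build_strict_graph(chain_F)
        sols = enumerate_valid_trees(G, chain_F, 0.0)
        assert [sorted(t.edges()) for t in sols.trees] == [
            [("1", "2"), ("2", "3")]
        ]

    def test_relaxation_recovers_star(self, chain_F):
        G = build_strict_graph(chain_F)
        assert len(enumerate_valid_trees(G, chain_F, 0.2)) == 2

    def test_single_node_graph_has_one_empty_tree(self):
        F = VAFMatrix([[0.5]], mutation_ids=["1"])
        sols = enumerate_valid_trees(build_strict_graph(F), F)
        assert len(sols) == 1 and sols.trees[0].edges() == []

    @pytest.mark.parametrize("epsilon", [0.0, 0.03, 0.1])
    def test_matches_bruteforce_oracle(self, rng, epsilon):
        """Sound and complete against naive enumerate-then-filter, n <= 6."""
        for _ in range(30):
            n = int(rng.integers(2, 7))
            F, G = random_strict_instance(rng, n)
            sols = enumerate_valid_trees(G, F, epsilon)
            assert tree_keys(sols) == valid_trees_oracle(G, F, epsilon)

    def test_epsilon_monotonicity(self, rng):
        for _ in range(15):
            F, G = random_strict_instance(rng, 6)
            previous = set()
            for eps in [0.0, 0.02, 0.05, 0.2]:
                current = tree_keys(enumerate_valid_trees(G, F, eps))
                assert previous <= current
                previous = current

    def test_truncation_flag(self, chain_F):
        G = build_strict_graph(chain_F)
        sols = enumerate_valid_trees(G, chain_F, 0.2, cap=1)
        assert len(sols) == 1 and sols.truncated

    def test_deterministic_order(self, rng):
        F, G = random_strict_instance(rng, 6)
        a = enumerate_valid_trees(G, F, 0.05)
        b = enumerate_valid_trees(G, F, 0.05)
        assert [t.parent for t in a.trees] == [t.parent for t in b.trees]

    def test_every_tree_spans_and_validates(self, rng):
        from vaffp.model import check_sum_condition

        F, G = random_strict_instance(rng, 6)
        sols = enumerate_valid_trees(G, F, 0.05)
        for t in sols.trees:
            assert set(t.nodes) == set(F.mutation_ids)
            assert check_sum_condition(t, F, 0.05)[0]


class TestCount:
    def test_tournament_count(self, chain_F):
        assert count_spanning_trees(build_strict_graph(chain_F)) == 2

    def test_complete_dag_count(self):
        F = VAFMatrix([[0.5, 0.4, 0.3, 0.2]], mutation_ids=list("1234"))
        assert count_spanning_trees(build_strict_graph(F)) == 6

    def test_chain_graph_has_one(self):
        G = nx.DiGraph([("a", "b"), ("b", "c")], designated_root="a")
        assert count_spanning_trees(G) == 1

    def test_matches_exhaustive_enumeration(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 7))
            F, G = random_strict_instance(rng, n)
            if not nx.is_directed_acyclic_graph(G):
                continue
            root = G.graph["designated_root"]
            if G.in_degree(root) != 0:
                continue
            assert count_spanning_trees(G) == len(all_arborescences(G, root))

    def test_upper_bounds_valid_tree_count(self, rng):
        for _ in range(10):
            F, G = random_strict_instance(rng, 6)
            if not nx.is_directed_acyclic_graph(G):
                continue
            if G.in_degree(G.graph["designated_root"]) != 0:
                continue
            assert count_spanning_trees(G) >= len(enumerate_valid_trees(G, F, 0.0))

    def test_cycle_rejected(self):
        G = nx.DiGraph([("a", "b"), ("b", "a")], designated_root="a")
        with pytest.raises(ValueError):
            count_spanning_trees(G)

    def test_root_with_incoming_edge_rejected(self):
        G = nx.DiGraph([("a", "b"), ("b", "c"), ("a", "c")], designated_root="b")
        with pytest.raises(ValueError):
            count_spanning_trees(G)


class TestMinEpsilon:
    def test_star_overflow_is_min_epsilon(self, two_sample_F):
        G = build_strict_graph(two_sample_F)
        assert min_epsilon_search(G, two_sample_F) == pytest.approx(0.2)

    def test_zero_when_strict_solution_exists(self, chain_F):
        G = build_strict_graph(chain_F)
        assert min_epsilon_search(G, chain_F) == 0.0

    def test_matches_bruteforce_minimum(self, rng):
        for _ in range(15):
            F, G = random_strict_instance(rng, 5)
            try:
                expected = min_epsilon_oracle(G, F)
            except ValueError:
                with pytest.raises(ValueError):
                    min_epsilon_search(G, F)
                continue
            assert min_epsilon_search(G, F) == pytest.approx(expected, abs=1e-12)

    def test_no_arborescence_raises(self):
        F = VAFMatrix([[0.5, 0.4, 0.4]], mutation_ids=["1", "2", "3"])
        G = nx.DiGraph(designated_root="1")
        G.add_nodes_from(["1", "2", "3"])
        G.add_edge("1", "2")
        with pytest.raises(ValueError):
            min_epsilon_search(G, F)


class TestRanking:
    def two_node_graph(self, w12, w21):
        G = nx.DiGraph(kind="approximate", designated_root="1")
        G.add_edge("1", "2", weight=w12)
        G.add_edge("2", "1", weight=w21)
        return G

    def test_rank_one_is_max_weight(self):
        F = VAFMatrix([[0.4, 0.3]], mutation_ids=["1", "2"])
        sols = rank_trees_by_weight(self.two_node_graph(0.9, 0.1), F, k=2)
        # only the arborescence rooted at the designated root is considered
        assert sols.trees[0].edges() == [("1", "2")]
        assert sols.weights == pytest.approx([0.9])

    def test_ordering_matches_sorted_full_enumeration(self, rng):
        for _ in range(8):
            n = 6
            v = rng.integers(5, 25, (2, n))
            R = ReadCountMatrix(v, np.full((2, n), 50))
            F = R.vaf_matrix()
            G = build_approximate_graph(R)
            sols = rank_trees_by_weight(G, F, k=10**6, epsilon=0.05)
            assert sols.weights == sorted(sols.weights, reverse=True)
            assert tree_keys(sols) == valid_trees_oracle(G, F, 0.05)

    def test_strict_and_approximate_sets_agree_at_epsilon_zero(self, rng):
        """The complete weighted graph admits no extra sum-condition trees."""
        for _ in range(8):
            n = int(rng.integers(3, 7))
            v = rng.integers(0, 25, (2, n))
            R = ReadCountMatrix(v, np.full((2, n), 50))
            F = R.vaf_matrix()
            strict = enumerate_valid_trees(build_strict_graph(F), F, 0.0)
            approx = rank_trees_by_weight(build_approximate_graph(R), F, k=10**6)
            assert tree_keys(strict) == tree_keys(approx)

    def test_no_valid_tree_returns_empty(self):
        # only arborescence from the designated root overflows the sum condition
        F = VAFMatrix([[0.1, 0.3]], mutation_ids=["1", "2"])
        sols = rank_trees_by_weight(self.two_node_graph(0.5, 0.5), F, k=5)
        assert len(sols) == 0 and not sols.truncated
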