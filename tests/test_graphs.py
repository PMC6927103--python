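import numpy as np
import pytest

from vaffp.graphs import (
    beta_ancestral_probability,
    build_approximate_graph,
    build_strict_graph,
)
from vaffp.model import ReadCountMatrix, VAFMatrix, check_sum_condition
from vaffp.simulate import SimulationConfig, simulate_trial

from _oracles import mc_beta_ge


class TestStrictGraph:
    def test_total_order_gives_transitive_tournament(self, chain_F):
        G = build_strict_graph(chain_F)
        assert set(G.edges) == {("1", "2"), ("1", "3"), ("2", "3")}
        assert G.graph["designated_root"] == "1"

    def test_incomparable_columns_share_no_edge(self, two_sample_F):
        G = build_strict_graph(two_sample_F)
        assert set(G.edges) == {("1", "2"), ("1", "3")}
        assert G.graph["designated_root"] == "1"

    def test_exact_tie_keeps_both_directions(self):
        F = VAFMatrix([[0.4, 0.4]], mutation_ids=["1", "2"])
        G = build_strict_graph(F)
        assert set(G.edges) == {("1", "2"), ("2", "1")}

    def test_edges_match_bruteforce_condition(self, rng):
        F = VAFMatrix(rng.random((3, 6)) * 0.5)
        G = build_strict_graph(F)
        for j, mj in enumerate(F.mutation_ids):
            for k, mk in enumerate(F.mutation_ids):
                if j == k:
                    continue
                expected = bool(np.all(F.values[:, j] >= F.values[:, k]))
                assert G.has_edge(mj, mk) == expected

    def test_ambiguous_root_falls_back_to_max_total_frequency(self, caplog):
        F = VAFMatrix([[0.5, 0.4], [0.4, 0.5]], mutation_ids=["a", "b"])
        with caplog.at_level("WARNING"):
            G = build_strict_graph(F)
        assert G.graph["designated_root"] == "a"  # tie broken by column order
        assert "in-degree-0" in caplog.text


class TestBetaProbability:
    def test_identical_counts_give_half(self):
        p = beta_ancestral_probability([5, 9], [20, 30], [5, 9], [20, 30])
        assert p == pytest.approx(0.5, abs=1e-9)

    def test_known_closed_form(self):
        # X ~ Beta(2,1) vs Y ~ Beta(1,2): P(X >= Y) = 5/6
        p = beta_ancestral_probability([1], [1], [0], [1])
        assert p == pytest.approx(5 / 6, abs=1e-9)

    def test_weakest_sample_rules(self):
        per_sample = [
            beta_ancestral_probability([v1], [r1], [v2], [r2])
            for v1, r1, v2, r2 in [(30, 60, 10, 60), (20, 60, 18, 60)]
        ]
        combined = beta_ancestral_probability(
            [30, 20], [60, 60], [10, 18], [60, 60]
        )
        assert combined == pytest.approx(min(per_sample), abs=1e-12)

    def test_monotone_in_sample_count(self, rng):
        v1 = rng.integers(0, 30, 6)
        v2 = rng.integers(0, 30, 6)
        r = np.full(6, 40)
        probs = [
            beta_ancestral_probability(v1[: i + 1], r[: i + 1], v2[: i + 1], r[: i + 1])
            for i in range(6)
        ]
        assert all(a >= b - 1e-12 for a, b in zip(probs, probs[1:]))

    def test_matches_monte_carlo(self, rng):
        """Exact finite-sum tail probability agrees with simulation to 3 sigma."""
        for _ in range(5):
            v1, v2 = rng.integers(0, 40, 2)
            r1, r2 = rng.integers(40, 80, 2)
            exact = beta_ancestral_probability([v1], [r1], [v2], [r2])
            est, se = mc_beta_ge(v1 + 1, r1 - v1 + 1, v2 + 1, r2 - v2 + 1, rng)
            assert abs(exact - est) < 3 * se + 1e-9

    def test_rejects_bad_counts(self):
        with pytest.raises(ValueError):
            beta_ancestral_probability([5], [3], [0], [3])


class TestApproximateGraph:
    def make_counts(self, rng, n, s=1, depth=50):
        v = rng.integers(0, depth // 2, (s, n))
        return ReadCountMatrix(v, np.full((s, n), depth))

    def test_two_node_weights_sum_to_one(self, rng):
        R = self.make_counts(rng, 2)
        G = build_approximate_graph(R)
        assert len(G.edges) == 2
        w = [d["weight"] for _, _, d in G.edges(data=True)]
        assert sum(w) == pytest.approx(1.0, abs=1e-9)

    def test_single_node_has_no_edges(self):
        G = build_approximate_graph(ReadCountMatrix([[4]], [[10]]))
        assert len(G.edges) == 0

    def test_strict_edges_get_majority_weight_at_equal_depth(self, rng):
        R = self.make_counts(rng, 6)
        F = R.vaf_matrix()
        strict = build_strict_graph(F)
        approx = build_approximate_graph(R)
        for u, v in strict.edges:
            assert approx.edges[u, v]["weight"] >= 0.5 - 1e-9

    def test_contains_every_strict_arborescence_edge(self, rng):
        R = self.make_counts(rng, 5, s=2)
        strict = build_strict_graph(R.vaf_matrix())
        approx = build_approximate_graph(R)
        assert set(strict.edges) <= set(approx.edges)
        assert all(0 < d["weight"] < 1 for _, _, d in approx.edges(data=True))


class TestNoiseFreeRecovery:
    def test_true_tree_consistent_with_exact_frequencies(self, rng):
        """With F set exactly to the mutation frequencies, the underlying
        tree's edges survive in the strict graph and the sum condition holds."""
        for seed in range(10):
            gt = simulate_trial(SimulationConfig(n=8, s=3, seed=seed))
            F = VAFMatrix(
                np.tile(gt.f, (3, 1)), mutation_ids=gt.F.mutation_ids
            )
            G = build_strict_graph(F)
            assert set(gt.tree.edges()) <= set(G.edges)
            ok, overflow = check_sum_condition(gt.tree, F, 0.0)
            assert ok and overflow <= 1e-12
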