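import numpy as np
import pytest
from scipy import stats

from vaffp.enumeration import enumerate_valid_trees
from vaffp.graphs import build_strict_graph
from vaffp.model import VAFMatrix, check_sum_condition, clonal_matrix_from_tree
from vaffp.simulate import (
    SimulationConfig,
    mutation_frequencies,
    random_tree,
    sample_clone_frequencies,
    simulate_reads,
    simulate_trial,
)

from conftest import chain, star


class TestRandomTree:
    def test_single_node(self, rng):
        t = random_tree(1, rng)
        assert t.n_nodes == 1 and t.parent[t.root] is None

    def test_two_nodes_forced_edge(self, rng):
        for _ in range(10):
            assert random_tree(2, rng).edges() == [("m1", "m2")]

    def test_mean_leaf_count_matches_recursive_tree_expectation(self, rng):
        """Uniform random recursive trees average n/2 leaves."""
        n, reps = 10, 20000
        leaves = np.empty(reps)
        for i in range(reps):
            parents = rng.integers(0, np.arange(1, n))
            leaves[i] = n - len(set(parents.tolist()))
        se = leaves.std() / np.sqrt(reps)
        assert abs(leaves.mean() - n / 2) < 3 * se + 1e-12


class TestCloneFrequencies:
    def test_single_clone(self, rng):
        assert sample_clone_frequencies(1, rng).tolist() == [1.0]

    def test_simplex_symmetry(self, rng):
        u = np.array([sample_clone_frequencies(3, rng) for _ in range(20000)])
        np.testing.assert_allclose(u.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(np.abs(u.mean(axis=0) - 1 / 3) < 0.01)

    def test_two_clone_marginal_is_uniform(self, rng):
        u1 = np.array([sample_clone_frequencies(2, rng)[0] for _ in range(4000)])
        assert stats.kstest(u1, "uniform").pvalue > 1e-4


class TestMutationFrequencies:
    def test_chain(self):
        B = clonal_matrix_from_tree(chain("m1", "m2"), ["m1", "m2"])
        np.testing.assert_allclose(
            mutation_frequencies([0.4, 0.6], B), [0.5, 0.3]
        )

    def test_star(self):
        B = clonal_matrix_from_tree(star("m1", "m2", "m3"), ["m1", "m2", "m3"])
        np.testing.assert_allclose(
            mutation_frequencies([0.2, 0.5, 0.3], B), [0.5, 0.25, 0.15]
        )

    def test_root_concentrated(self, rng):
        t = random_tree(6, rng)
        B = clonal_matrix_from_tree(t, t.nodes)
        u = np.zeros(6)
        u[0] = 1.0
        f = mutation_frequencies(u, B)
        assert f[0] == 0.5 and f[1:].sum() == 0

    def test_root_frequency_always_half(self, rng):
        for _ in range(10):
            t = random_tree(7, rng)
            B = clonal_matrix_from_tree(t, t.nodes)
            u = sample_clone_frequencies(7, rng)
            f = mutation_frequencies(u, B)
            assert f[0] == pytest.approx(0.5)
            assert np.all((0 <= f) & (f <= 0.5 + 1e-12))


class TestSimulateReads:
    def test_high_coverage_concentrates(self, rng):
        _, F = simulate_reads(np.array([0.3]), 1, 1e4, 0.0, rng)
        assert abs(F.values[0, 0] - 0.3) < 0.02

    def test_overdispersion_parameters(self, rng):
        # rho=0.5, f=0.3 -> Beta(alpha=0.3, beta=0.7), mean f
        rho, f = 0.5, 0.3
        scale = (1 - rho) / rho
        assert scale * f == pytest.approx(0.3)
        assert scale * (1 - f) == pytest.approx(0.7)
        draws = rng.beta(scale * f, scale * (1 - f), 40000)
        assert abs(draws.mean() - f) < 0.01

    def test_variance_increases_with_overdispersion(self, rng):
        f = np.array([0.3])
        variances = []
        for rho in [0.0, 0.05, 0.09]:
            _, F = simulate_reads(np.tile(f, 4000), 1, 100.0, rho, rng)
            variances.append(F.values.var())
        assert variances[0] < variances[1] < variances[2]

    def test_degenerate_frequencies_stay_point_masses(self, rng):
        reads, F = simulate_reads(np.array([0.0, 0.5]), 3, 50.0, 0.3, rng)
        assert np.all(reads.variant[:, 0] == 0)
        assert 0 < F.values[:, 1].mean() < 1

    def test_zero_coverage_yields_zero_vafs(self, rng, caplog):
        with caplog.at_level("WARNING"):
            _, F = simulate_reads(np.array([0.3]), 2, 0.0, 0.0, rng)
        assert F.values.sum() == 0


class TestSimulateTrial:
    def test_deterministic_from_seed(self):
        cfg = SimulationConfig(n=6, s=3, coverage=80, rho=0.05, seed=11)
        a, b = simulate_trial(cfg), simulate_trial(cfg)
        assert a.tree == b.tree
        np.testing.assert_array_equal(a.reads.variant, b.reads.variant)
        np.testing.assert_array_equal(a.F.values, b.F.values)

    def test_shapes_and_invariants(self):
        gt = simulate_trial(SimulationConfig(n=10, s=5, coverage=60, seed=3))
        assert gt.F.values.shape == (5, 10)
        assert gt.u.sum() == pytest.approx(1.0)
        assert np.all((0 <= gt.f) & (gt.f <= 0.5 + 1e-12))
        nonzero = gt.reads.total > 0
        np.testing.assert_allclose(
            gt.F.values[nonzero],
            gt.reads.variant[nonzero] / gt.reads.total[nonzero],
        )

    def test_generator_respects_isa(self):
        """Noise-free frequencies admit the true tree as a strict solution."""
        for seed in range(8):
            gt = simulate_trial(SimulationConfig(n=7, s=2, seed=seed))
            F = VAFMatrix(np.tile(gt.f, (2, 1)), mutation_ids=gt.F.mutation_ids)
            ok, overflow = check_sum_condition(gt.tree, F, 0.0)
            assert ok and overflow <= 1e-12
            sols = enumerate_valid_trees(build_strict_graph(F), F, 0.0)
            assert any(t == gt.tree for t in sols.trees)

    def test_mean_vaf_converges_to_f_under_overdispersion(self, rng):
        f = np.array([0.25])
        _, F = simulate_reads(np.tile(f, 3000), 1, 200.0, 0.09, rng)
        assert abs(F.values.mean() - 0.25) < 0.01

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SimulationConfig(n=0)
        with pytest.raises(ValueError):
            SimulationConfig(rho=1.0)
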