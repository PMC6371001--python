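import numpy as np
import pytest
from scipy.stats import spearmanr

from deltaomics import (consensus_merge, dpi_prune, mutual_information_matrix,
                        reconstruct_subset, run_scs, spectral_subsets)
from deltaomics.scs import ENGINES, RelevanceMatrix

from conftest import planted_matrix


class TestMutualInformation:
    def test_matches_copula_closed_form(self, rng):
        X = rng.standard_normal((60, 4))
        rel = mutual_information_matrix(X)
        rho_s = spearmanr(X).statistic
        rho_g = 2 * np.sin(np.pi * rho_s / 6)
        expected = -0.5 * np.log(1 - rho_g ** 2)
        np.fill_diagonal(expected, 0.0)
        np.testing.assert_allclose(rel.values, expected, atol=1e-10)

    def test_rho_g_08_gives_half_nat(self):
        # MI = -1/2 ln(1 - 0.8^2) ~ 0.5108 nats
        assert -0.5 * np.log(1 - 0.64) == pytest.approx(0.5108, abs=5e-4)
        n = 4000
        rng = np.random.default_rng(3)
        z = rng.standard_normal(n)
        x = 0.8 * z + np.sqrt(1 - 0.64) * rng.standard_normal(n)
        rel = mutual_information_matrix(np.column_stack([z, x]))
        assert rel.values[0, 1] == pytest.approx(0.5108, abs=0.02)

    def test_symmetric_nonnegative_zero_diagonal(self, mini):
        blocks, _ = mini
        rel = mutual_information_matrix(blocks[1].values)
        np.testing.assert_array_equal(rel.values, rel.values.T)
        assert np.all(rel.values >= 0)
        assert np.all(np.diag(rel.values) == 0)
        assert rel.values.max() <= np.log(27)

    def test_gaussian_convergence_to_closed_form(self):
        rng = np.random.default_rng(9)
        n, rho = 5000, 0.6
        z = rng.standard_normal(n)
        x = rho * z + np.sqrt(1 - rho ** 2) * rng.standard_normal(n)
        rel = mutual_information_matrix(np.column_stack([z, x]))
        assert rel.values[0, 1] == pytest.approx(
            -0.5 * np.log(1 - rho ** 2), abs=0.02)

    def test_constant_column_rejected(self, rng):
        X = rng.standard_normal((30, 3))
        X[:, 2] = 1.0
        with pytest.raises(ValueError, match="constant"):
            mutual_information_matrix(X, ["a", "b", "c"])

    def test_binning_estimator_available(self, rng):
        X = rng.standard_normal((100, 3))
        rel = mutual_information_matrix(X, estimator="binning")
        assert rel.values.shape == (3, 3) and np.all(rel.values >= 0)


class TestSpectralSubsets:
    def test_two_disconnected_cliques_recovered(self):
        W = np.zeros((10, 10))
        W[:5, :5] = 0.8
        W[5:, 5:] = 0.8
        np.fill_diagonal(W, 0.0)
        rel = RelevanceMatrix(W, list(range(10)))
        subs = spectral_subsets(rel, eigvec_fraction=0.14,
                                coord_threshold=0.03)
        member_sets = {frozenset(s.members) for s in subs}
        assert member_sets == {frozenset(range(5)), frozenset(range(5, 10))}

    def test_single_eigenvector_gives_single_subset(self, rng):
        X = rng.standard_normal((50, 8))
        rel = mutual_information_matrix(X)
        subs = spectral_subsets(rel, eigvec_fraction=1e-6,
                                coord_threshold=0.0)
        assert len(subs) == 1

    def test_union_covers_all_variables(self, mini):
        blocks, _ = mini
        rel = mutual_information_matrix(blocks[3].values)
        subs = spectral_subsets(rel)
        covered = set().union(*(s.members for s in subs))
        assert covered == set(range(blocks[3].n_features))

    def test_invalid_parameters_rejected(self, rng):
        rel = mutual_information_matrix(rng.standard_normal((20, 5)))
        with pytest.raises(ValueError):
            spectral_subsets(rel, eigvec_fraction=0.0)
        with pytest.raises(ValueError):
            spectral_subsets(rel, coord_threshold=-0.1)


class TestEngines:
    @staticmethod
    def _chain_data(n=500, seed=0):
        rng = np.random.default_rng(seed)
        x1 = rng.standard_normal(n)
        x2 = 0.8 * x1 + 0.6 * rng.standard_normal(n)
        x3 = 0.8 * x2 + 0.6 * rng.standard_normal(n)
        return np.column_stack([x1, x2, x3])

    @pytest.mark.parametrize("engine", ENGINES)
    def test_gaussian_chain_skeleton(self, engine):
        X = self._chain_data()
        edges = reconstruct_subset(X, engine, alpha=0.05)
        assert edges == {frozenset((0, 1)), frozenset((1, 2))}

    @pytest.mark.parametrize("engine", ENGINES)
    def test_independent_variables_give_empty_set(self, engine):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((500, 3))
        assert reconstruct_subset(X, engine, alpha=0.01) == set()

    def test_dpi_drops_weakest_triangle_edge(self):
        W = np.array([[0.0, 0.9, 0.1],
                      [0.9, 0.0, 0.8],
                      [0.1, 0.8, 0.0]])
        A = dpi_prune(W)
        assert not A[0, 2] and A[0, 1] and A[1, 2]

    def test_subset_too_small_rejected(self, rng):
        with pytest.raises(ValueError, match=">= 3"):
            reconstruct_subset(rng.standard_normal((20, 2)), "mi_dpi")

    def test_unknown_engine_rejected(self, rng):
        with pytest.raises(ValueError, match="unknown engine"):
            reconstruct_subset(rng.standard_normal((20, 4)), "magic")


class TestConsensus:
    DATA = np.random.default_rng(2).standard_normal((30, 3))
    IDS = ["a", "b", "c"]

    def _merge(self, per_subset, quorum):
        return consensus_merge(per_subset, quorum, self.DATA, self.IDS,
                               engines=("e1", "e2", "e3"))

    def test_unanimous_edge_kept_at_any_quorum(self):
        e = frozenset(("a", "b"))
        per = {0: {"e1": {e}, "e2": {e}, "e3": {e}}}
        for q in (1, 2, 3):
            assert self._merge(per, q).edge_set() == {e}

    def test_minority_edge_dropped_at_quorum_two(self):
        e = frozenset(("a", "b"))
        per = {0: {"e1": {e}, "e2": set(), "e3": set()}}
        assert self._merge(per, 2).edge_set() == set()

    def test_max_vote_across_subsets(self):
        e = frozenset(("a", "c"))
        per = {0: {"e1": {e}},
               1: {"e1": {e}, "e2": {e}, "e3": {e}}}
        net = self._merge(per, 2)
        assert net.edges[0][2] == 3     # votes

    def test_sign_from_spearman(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(40)
        data = np.column_stack([x, -x + 0.1 * rng.standard_normal(40),
                                rng.standard_normal(40)])
        e = frozenset(("a", "b"))
        net = consensus_merge({0: {"e1": {e}, "e2": {e}}}, 2, data,
                              self.IDS, engines=("e1", "e2"))
        assert net.edges[0][3] == -1

    def test_quorum_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            self._merge({}, 4)


class TestRunScs:
    def test_planted_recovery_f1(self, mini_big):
        """Consensus reconstruction over the planted variables at n=200,
        sigma=0.3 recovers the planted dependence graph with F1 >= 0.7."""
        blocks, truth = mini_big
        X, ids, classes = planted_matrix(blocks, truth)
        net = run_scs(X, variables=ids, node_classes=classes)
        found = net.edge_set()
        tp = len(found & truth.edges)
        prec = tp / max(len(found), 1)
        rec = tp / len(truth.edges)
        f1 = 2 * prec * rec / max(prec + rec, 1e-12)
        assert f1 >= 0.7

    def test_pure_noise_density_below_twice_alpha(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((200, 30))
        net = run_scs(X, variables=[f"v{i}" for i in range(30)], alpha=0.05)
        assert net.n_edges / (30 * 29 / 2) < 0.10

    def test_quorum_monotonicity(self, mini_big):
        blocks, truth = mini_big
        X, ids, classes = planted_matrix(blocks, truth)
        e_by_q = {q: run_scs(X, variables=ids, quorum=q).edge_set()
                  for q in (1, 2, 3)}
        assert e_by_q[3] <= e_by_q[2] <= e_by_q[1]

    def test_deterministic(self, mini):
        blocks, truth = mini
        X, ids, classes = planted_matrix(blocks, truth)
        n1 = run_scs(X, variables=ids, node_classes=classes)
        n2 = run_scs(X, variables=ids, node_classes=classes)
        assert n1.edges == n2.edges

    def test_node_classes_passed_through(self, mini_big):
        blocks, truth = mini_big
        X, ids, classes = planted_matrix(blocks, truth)
        net = run_scs(X, variables=ids, node_classes=classes)
        assert all(net.nodes[v] == classes[v] for v in ids)

    def test_too_few_variables_rejected(self, rng):
        with pytest.raises(ValueError, match=">= 5"):
            run_scs(rng.standard_normal((30, 4)))
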