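import numpy as np
import pytest

from deltaomics import (CanonicalPLS, PipelineConfig, fit_pls_canonical,
                        prevalence_filter, run_all_pairs, threshold_network)
from deltaomics.blocks import DeltaBlock


def _delta(values, cls="clinical", name=None):
    values = np.asarray(values, float)
    n, p = values.shape
    return DeltaBlock(name=name or cls, block_class=cls,
                      subjects=[f"s{i}" for i in range(n)],
                      features=[f"{cls}_{j}" for j in range(p)],
                      values=values)


def _svd_leading(X, Y):
    Xc = (X - X.mean(0)) / X.std(0, ddof=1)
    Yc = (Y - Y.mean(0)) / Y.std(0, ddof=1)
    U, _s, Vt = np.linalg.svd(Xc.T @ Yc, full_matrices=False)
    return U[:, 0], Vt[0]


class TestFit:
    @pytest.mark.parametrize("seed", range(20))
    def test_component1_weights_equal_svd_of_cross_product(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((30, 8))
        Y = rng.standard_normal((30, 6))
        m = CanonicalPLS(n_components=2).fit(X, Y)
        u, v = _svd_leading(X, Y)
        sgn = np.sign(u @ m.x_weights_[:, 0])
        np.testing.assert_allclose(m.x_weights_[:, 0], sgn * u, atol=1e-8)
        np.testing.assert_allclose(m.y_weights_[:, 0], sgn * v, atol=1e-8)

    def test_weights_unit_norm_and_variates_orthogonal(self, mini):
        blocks, _ = mini
        m = fit_pls_canonical(blocks[0], blocks[3], n_components=3)
        for W in (m.x_weights_, m.y_weights_):
            np.testing.assert_allclose(np.linalg.norm(W, axis=0), 1.0,
                                       atol=1e-10)
        G = m.x_scores_.T @ m.x_scores_
        np.testing.assert_allclose(G - np.diag(np.diag(G)), 0.0, atol=1e-8)
        Gy = m.y_scores_.T @ m.y_scores_
        np.testing.assert_allclose(Gy - np.diag(np.diag(Gy)), 0.0, atol=1e-8)

    def test_single_shared_column_self_association(self, rng):
        x = rng.standard_normal((20, 1))
        m = CanonicalPLS(n_components=1).fit(x, x.copy())
        c = np.corrcoef(m.x_scores_[:, 0], x[:, 0])[0, 1]
        assert abs(abs(c) - 1) < 1e-10
        cy = np.corrcoef(m.y_scores_[:, 0], x[:, 0])[0, 1]
        assert abs(abs(cy) - 1) < 1e-10

    def test_h_too_large_rejected(self, rng):
        X = rng.standard_normal((10, 3))
        with pytest.raises(ValueError, match="n_components"):
            CanonicalPLS(n_components=4).fit(X, X.copy())

    def test_matches_sklearn_cross_decomposition(self, rng):
        """Independent cross-check against sklearn's canonical-mode PLS."""
        from sklearn.cross_decomposition import PLSCanonical
        X = rng.standard_normal((40, 7))
        Y = rng.standard_normal((40, 5))
        ours = CanonicalPLS(n_components=2).fit(X, Y)
        ref = PLSCanonical(n_components=2, scale=True, tol=1e-12,
                           max_iter=5000).fit(X, Y)
        for h in range(2):
            a, b = ours.x_weights_[:, h], ref.x_weights_[:, h]
            # sklearn stops on the squared weight change, so ~1e-6 agreement
            # is its convergence floor; this is a cross-check, not an oracle
            assert min(np.abs(a - b).max(), np.abs(a + b).max()) < 1e-4


class TestSimilarity:
    def test_p_q_one_equals_pearson(self, rng):
        x = rng.standard_normal((25, 1))
        y = 0.5 * x + rng.standard_normal((25, 1))
        m = CanonicalPLS(n_components=1).fit(x, y)
        sim = m.similarity_matrix()
        r = np.corrcoef(x.ravel(), y.ravel())[0, 1]
        assert sim[0, 0] == pytest.approx(r, abs=1e-10)

    def test_self_similarity_diagonal_is_one(self, rng):
        X = rng.standard_normal((12, 4))
        m = CanonicalPLS(n_components=4).fit(X, X.copy())
        sim = m.similarity_matrix()
        np.testing.assert_allclose(np.diag(sim), 1.0, atol=1e-8)

    @pytest.mark.parametrize("seed", range(100))
    def test_bounded_by_one_everywhere(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((15, 6))
        Y = rng.standard_normal((15, 5))
        m = CanonicalPLS(n_components=3).fit(X, Y)
        for variates in ("x", "mean"):
            assert np.all(np.abs(m.similarity_matrix(variates)) <= 1 + 1e-12)

    def test_affine_rescaling_invariance(self, rng):
        X = rng.standard_normal((20, 4))
        Y = rng.standard_normal((20, 3))
        s1 = CanonicalPLS(2).fit(X, Y).similarity_matrix()
        s2 = CanonicalPLS(2).fit(X * 7.0 + 3.0, Y * 0.2 - 1.0) \
            .similarity_matrix()
        np.testing.assert_allclose(s1, s2, atol=1e-9)

    def test_zero_variance_column_zeroed_with_warning(self, rng):
        X = rng.standard_normal((20, 3))
        X[:, 1] = 5.0
        Y = rng.standard_normal((20, 3))
        m = CanonicalPLS(1).fit(X, Y)
        with pytest.warns(UserWarning, match="zero-variance"):
            sim = m.similarity_matrix()
        assert np.all(sim[1, :] == 0)


class TestThreshold:
    def test_tau_zero_keeps_all_pairs(self):
        sim = np.array([[0.1, -0.2], [0.3, 0.0]])
        net = threshold_network(sim, 0.0, ["x0", "x1"], ["y0", "y1"])
        assert net.n_edges == 4

    def test_counting_at_tau(self):
        sim = np.array([[0.8, -0.2], [0.72, 0.9]])
        net = threshold_network(sim, 0.75, ["x0", "x1"], ["y0", "y1"])
        kept = {(u, v): c for u, v, c in net.edges}
        assert set(kept) == {("x0", "y0"), ("x1", "y1")}

    def test_boundary_tie_kept(self):
        sim = np.array([[0.75]])
        assert threshold_network(sim, 0.75, ["x"], ["y"]).n_edges == 1

    def test_sign_recorded_via_coefficient(self):
        sim = np.array([[-0.8]])
        net = threshold_network(sim, 0.7, ["x"], ["y"])
        assert net.edges[0][2] == -0.8

    def test_prevalence_filter_keeps_min_two_subjects(self):
        blk = _delta(np.array([[1.0, 1.0, 0.0],
                               [2.0, 0.0, 0.0],
                               [0.0, 0.0, 0.0]]), cls="mgs")
        kept = prevalence_filter(blk, min_subjects=2)
        assert kept.features == ["mgs_0"]


class TestRunAllPairs:
    def test_default_config_yields_seven_networks(self, mini):
        blocks, _ = mini
        nets = run_all_pairs(blocks, PipelineConfig())
        assert len(nets) == 7
        assert {n.pair for n in nets} == {
            "clinical:lifestyle", "clinical:mgs", "clinical:fecal_metab",
            "clinical:urine_metab", "clinical:serum_metab",
            "clinical:transcriptome", "serum_metab:transcriptome"}

    def test_noiseless_planted_edges_all_present(self):
        """With no noise and one planted feature per block, every planted
        feature is an exact transform of the latent factor and must pass
        the strictest threshold against the IS markers."""
        from deltaomics import MINI_DIMS, generate_study
        n_pl = {k: 1 for k in ("lifestyle", "mgs", "fecal_metab",
                               "urine_metab", "serum_metab", "transcriptome")}
        blocks, truth = generate_study(dims=MINI_DIMS, sigma=0.0,
                                       n_planted=n_pl, seed=8)
        cfg = PipelineConfig(pairs=[[a, b, 0.75] for a, b, _ in
                                    PipelineConfig().pairs])
        nets = {n.pair: n for n in run_all_pairs(blocks, cfg)}
        for blk, feats in truth.planted.items():
            if blk == "clinical":
                continue
            net = nets[f"clinical:{blk}"]
            nodes = set(net.nodes())
            assert set(feats) <= nodes

    def test_planted_signal_beats_pure_noise_edge_counts(self):
        """Networks from planted-signal data carry more edges on average
        than pure-noise data of the same shape (50 seeds, n=27)."""
        from deltaomics import MINI_DIMS, generate_study
        cfg = PipelineConfig()
        signal, noise = [], []
        for seed in range(50):
            b_sig, _ = generate_study(dims=MINI_DIMS, seed=seed, sigma=0.5)
            n_sig = sum(n.n_edges for n in run_all_pairs(b_sig, cfg))
            b_noi, _ = generate_study(
                dims=MINI_DIMS, seed=seed, sigma=0.5, effect=0.0,
                n_planted={k: 0 for k in ("lifestyle", "mgs", "fecal_metab",
                                          "urine_metab", "serum_metab",
                                          "transcriptome")})
            n_noi = sum(n.n_edges for n in run_all_pairs(b_noi, cfg))
            signal.append(n_sig)
            noise.append(n_noi)
        assert np.mean(signal) > np.mean(noise)
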