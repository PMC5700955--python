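import numpy as np
import pytest
import scipy.sparse as sp

from cytohsne import (
    JointProbabilities,
    TransitionMatrix,
    build_knn,
    exact_gradient,
    joint_probabilities,
    kl_divergence,
    transition_from_knn,
    tsne_embed,
)
from cytohsne.embedding import _init_coords


def _jp(dense):
    dense = np.asarray(dense, dtype=float)
    np.fill_diagonal(dense, 0.0)
    dense = (dense + dense.T) / 2
    dense /= dense.sum()
    return JointProbabilities(p=sp.csr_matrix(dense))


@pytest.fixture
def mixture_p():
    """Joint probabilities of a 500-point 2-component Gaussian mixture."""
    rng = np.random.default_rng(8)
    x = np.vstack([rng.normal(0, 1, (250, 6)), rng.normal(4, 1, (250, 6))])
    g = build_knn(x, k=20)
    t = transition_from_knn(g, perplexity=10.0)
    return joint_probabilities(t)


class TestJointProbabilities:
    def test_symmetric_input_proportional(self):
        probs = sp.csr_matrix(np.array([[0, 0.5, 0.5], [0.5, 0, 0.5], [0.5, 0.5, 0]]))
        p = joint_probabilities(TransitionMatrix(probs=probs, n=3))
        dense = p.p.toarray()
        np.testing.assert_allclose(dense[dense > 0], 1 / 6, atol=1e-12)

    def test_sums_to_one(self, mixture_p):
        assert mixture_p.p.sum() == pytest.approx(1.0, abs=1e-9)

    def test_four_node_asymmetric_hand_computed(self):
        t = np.array(
            [
                [0.0, 0.7, 0.3, 0.0],
                [0.2, 0.0, 0.5, 0.3],
                [0.1, 0.1, 0.0, 0.8],
                [0.0, 0.6, 0.4, 0.0],
            ]
        )
        p = joint_probabilities(TransitionMatrix(probs=sp.csr_matrix(t), n=4))
        raw = (t + t.T) / (2 * 4)
        np.fill_diagonal(raw, 0.0)
        expected = raw / raw.sum()
        np.testing.assert_allclose(p.p.toarray(), expected, atol=1e-12)


class TestExactGradient:
    def test_two_points_equal_and_opposite(self):
        p = _jp([[0, 1.0], [1.0, 0]])
        coords = np.array([[0.0, 0.0], [1.0, 0.5]])
        g = exact_gradient(p, coords)
        np.testing.assert_allclose(g[0], -g[1], atol=1e-12)

    def test_identical_coords_finite(self):
        p = _jp(np.ones((4, 4)))
        g = exact_gradient(p, np.zeros((4, 2)))
        assert np.all(np.isfinite(g))

    def test_matches_finite_differences(self):
        """Central finite differences of KL(P||Q) on a 10-point instance."""
        rng = np.random.default_rng(1)
        p = _jp(rng.random((10, 10)))
        coords = rng.normal(size=(10, 2))
        grad = exact_gradient(p, coords)
        eps = 1e-6
        for i in range(10):
            for d in range(2):
                up, dn = coords.copy(), coords.copy()
                up[i, d] += eps
                dn[i, d] -= eps
                fd = (kl_divergence(p, up) - kl_divergence(p, dn)) / (2 * eps)
                assert grad[i, d] == pytest.approx(fd, rel=1e-4, abs=1e-8)


class TestKlDivergence:
    def test_two_point_kl_is_zero(self):
        # with n = 2 the Student-t Q is (1/2, 1/2) for any separation, so
        # P = (1/2, 1/2) gives exactly KL = 0
        p = _jp([[0, 1.0], [1.0, 0]])
        assert kl_divergence(p, np.array([[0.0, 0.0], [3.0, 1.0]])) == pytest.approx(0.0, abs=1e-12)

    def test_nonnegative(self):
        rng = np.random.default_rng(2)
        p = _jp(rng.random((8, 8)))
        assert kl_divergence(p, rng.normal(size=(8, 2))) >= 0

    def test_matches_bruteforce_double_sum(self):
        rng = np.random.default_rng(3)
        p = _jp(rng.random((5, 5)))
        coords = rng.normal(size=(5, 2))
        pd = p.p.toarray()
        w = np.zeros((5, 5))
        for i in range(5):
            for j in range(5):
                if i != j:
                    w[i, j] = 1.0 / (1.0 + np.sum((coords[i] - coords[j]) ** 2) + 1e-12)
        q = w / w.sum()
        expected = sum(
            pd[i, j] * np.log(pd[i, j] / q[i, j])
            for i in range(5)
            for j in range(5)
            if pd[i, j] > 0
        )
        assert kl_divergence(p, coords) == pytest.approx(expected, rel=1e-9)


class TestBarnesHut:
    def test_gradient_matches_exact_within_five_percent(self, mixture_p):
        """BH repulsion (theta = 0.5) against the dense oracle at a random
        iterate: per-coordinate error below 5% of the gradient scale."""
        rng = np.random.default_rng(4)
        coords = rng.normal(scale=3.0, size=(mixture_p.n, 2))
        from cytohsne._barnes_hut import barnes_hut_repulsion

        exact = exact_gradient(mixture_p, coords)
        from cytohsne.embedding import _attractive

        attr = _attractive(sp.coo_matrix(mixture_p.p), coords)
        rep, z = barnes_hut_repulsion(coords, theta=0.5)
        bh = 4.0 * (attr - rep / z)
        scale = np.abs(exact).max()
        assert np.abs(bh - exact).max() <= 0.05 * scale

    def test_theta_zero_matches_dense_exactly(self):
        rng = np.random.default_rng(5)
        coords = rng.normal(size=(60, 2))
        from cytohsne._barnes_hut import barnes_hut_repulsion

        rep, z = barnes_hut_repulsion(coords, theta=0.0)
        d2 = ((coords[:, None] - coords[None, :]) ** 2).sum(-1)
        w = 1.0 / (1.0 + d2)
        np.fill_diagonal(w, 0.0)
        assert z == pytest.approx(w.sum(), rel=1e-12)
        expected = (w**2).sum(1)[:, None] * coords - (w**2) @ coords
        np.testing.assert_allclose(rep, expected, rtol=1e-9, atol=1e-12)

    def test_coincident_points_finite(self):
        from cytohsne._barnes_hut import barnes_hut_repulsion

        coords = np.zeros((10, 2))
        rep, z = barnes_hut_repulsion(coords, theta=0.5)
        assert np.all(np.isfinite(rep))
        assert z == pytest.approx(10 * 9, rel=1e-12)  # all pairs at q = 1


class TestTsneEmbed:
    def test_two_point_symmetry(self):
        p = _jp([[0, 1.0], [1.0, 0]])
        emb = tsne_embed(p, n_iter=300, theta=0.0, seed=0)
        np.testing.assert_allclose(emb.coords.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(emb.coords[0], -emb.coords[1], atol=1e-9)

    def test_kl_decreases_after_exaggeration(self, mixture_p):
        emb = tsne_embed(mixture_p, n_iter=600, theta=0.5, seed=1)
        kl_at_exaggeration_end = emb.kl_trace[250 // 50 - 1]
        assert emb.kl_trace[-1] <= kl_at_exaggeration_end

    def test_deterministic_given_seed(self, mixture_p):
        a = tsne_embed(mixture_p, n_iter=100, theta=0.5, seed=3)
        b = tsne_embed(mixture_p, n_iter=100, theta=0.5, seed=3)
        np.testing.assert_array_equal(a.coords, b.coords)

    def test_separates_disconnected_blocks(self):
        """Two similarity blocks with zero cross terms end up linearly
        separable in the embedding."""
        rng = np.random.default_rng(6)
        block = rng.random((30, 30)) + 0.1
        dense = np.zeros((60, 60))
        dense[:30, :30] = block
        dense[30:, 30:] = rng.random((30, 30)) + 0.1
        p = _jp(dense)
        emb = tsne_embed(p, n_iter=500, theta=0.0, seed=2)
        labels = np.repeat([0, 1], 30)
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        clf = LinearDiscriminantAnalysis().fit(emb.coords, labels)
        assert clf.score(emb.coords, labels) == 1.0

    def test_init_is_permutation_equivariant(self):
        ids = np.arange(50)
        perm = np.random.default_rng(7).permutation(50)
        a = _init_coords(ids, seed=9)
        b = _init_coords(ids[perm], seed=9)
        np.testing.assert_array_equal(b, a[perm])

    def test_single_node_rejected(self):
        p = JointProbabilities(p=sp.csr_matrix((1, 1)))
        with pytest.raises(ValueError):
            tsne_embed(p, n_iter=10)
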