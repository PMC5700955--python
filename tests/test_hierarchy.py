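import itertools

import numpy as np
import pytest
import scipy.sparse as sp

from cytohsne import (
    HsneParams,
    InfluenceMatrix,
    TransitionMatrix,
    build_hierarchy,
    build_next_level,
    compute_influence,
    exact_hit_distribution,
    load_hierarchy,
    recommended_levels,
    save_hierarchy,
    select_landmarks,
)
from cytohsne.synthetic import make_mixture
from cytohsne.io import arcsinh_transform

from conftest import random_row_stochastic


class TestRecommendedLevels:
    def test_minimum_of_two_levels(self):
        assert recommended_levels(150) == 2

    def test_rounds_to_nearest(self):
        assert recommended_levels(100_000) == 3  # log10(1000) = 3.0
        assert recommended_levels(31_623) == 3  # log10(316) = 2.50
        assert recommended_levels(31_622) == 2  # log10(316.2) = 2.4999...

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValueError):
            recommended_levels(100)


class TestSelectLandmarks:
    def test_deterministic_two_cycle_even_length(self):
        probs = sp.csr_matrix(np.array([[0.0, 1.0], [1.0, 0.0]]))
        t = TransitionMatrix(probs=probs, n=2)
        params = HsneParams(n_walks_selection=50, walk_length=4, beta=1.0, seed=1)
        landmarks, hits = select_landmarks(t, params)
        np.testing.assert_array_equal(hits, [50, 50])  # endpoints = start nodes
        np.testing.assert_array_equal(landmarks, [0, 1])

    def test_star_graph_hub_dominates(self):
        """Odd-length walks from every leaf end at the hub, so the hub's
        endpoint count is 20x the per-node walk budget and only the hub
        passes the threshold."""
        n_leaves = 20
        rows = [0] * n_leaves + list(range(1, n_leaves + 1))
        cols = list(range(1, n_leaves + 1)) + [0] * n_leaves
        vals = [1.0 / n_leaves] * n_leaves + [1.0] * n_leaves
        t = TransitionMatrix(probs=sp.csr_matrix((vals, (rows, cols))), n=n_leaves + 1)
        params = HsneParams(n_walks_selection=100, walk_length=5, beta=1.5, seed=2)
        landmarks, hits = select_landmarks(t, params)
        assert hits[0] == n_leaves * 100
        assert hits[1:].max() < 1.5 * 100
        np.testing.assert_array_equal(landmarks, [0])

    def test_monte_carlo_matches_matrix_power_oracle(self):
        """Endpoint frequencies correlate with the exact walk-length-step
        distribution computed by matrix powers."""
        t = random_row_stochastic(100, 6, seed=9)
        params = HsneParams(n_walks_selection=1000, walk_length=15, seed=9)
        _, hits = select_landmarks(t, params)
        exact = exact_hit_distribution(t, 15)
        freq = hits / hits.sum()
        r = np.corrcoef(freq, exact)[0, 1]
        assert r >= 0.95

    def test_every_component_gets_a_landmark(self):
        # two disconnected 2-cycles; hits are uniform so the threshold at
        # beta > 1 selects nobody and one node per component must be forced
        probs = sp.block_diag(
            [np.array([[0.0, 1.0], [1.0, 0.0]])] * 2, format="csr"
        )
        t = TransitionMatrix(probs=probs, n=4)
        params = HsneParams(n_walks_selection=50, walk_length=3, beta=1.5, seed=0)
        landmarks, _ = select_landmarks(t, params)
        assert len(set(landmarks) & {0, 1}) >= 1
        assert len(set(landmarks) & {2, 3}) >= 1

    def test_same_seed_same_landmarks(self, small_params):
        t = random_row_stochastic(80, 5, seed=4)
        a = select_landmarks(t, small_params)
        b = select_landmarks(t, small_params)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])


class TestExactHitDistribution:
    def test_symmetric_two_cycle(self):
        t = TransitionMatrix(probs=sp.csr_matrix(np.array([[0.0, 1.0], [1.0, 0.0]])), n=2)
        np.testing.assert_allclose(exact_hit_distribution(t, 7), [0.5, 0.5])

    def test_identity_chain_uniform(self):
        t = TransitionMatrix(probs=sp.identity(5, format="csr"), n=5)
        np.testing.assert_allclose(exact_hit_distribution(t, 3), np.full(5, 0.2))

    def test_matches_path_enumeration_on_chain(self):
        """Brute-force enumeration of every length-L path on a 5-node chain."""
        n, L = 5, 4
        p = np.zeros((n, n))
        for i in range(n):
            nbrs = [j for j in (i - 1, i + 1) if 0 <= j < n]
            for j in nbrs:
                p[i, j] = 1.0 / len(nbrs)
        t = TransitionMatrix(probs=sp.csr_matrix(p), n=n)
        expect = np.zeros(n)
        for path in itertools.product(range(n), repeat=L + 1):
            prob = 1.0 / n
            for a, b in zip(path, path[1:]):
                prob *= p[a, b]
            expect[path[-1]] += prob
        np.testing.assert_allclose(exact_hit_distribution(t, L), expect, atol=1e-12)


class TestComputeInfluence:
    def test_single_landmark_absorbs_everything(self, small_params):
        t = random_row_stochastic(30, 4, seed=5)
        infl = compute_influence(t, np.array([7]), small_params)
        np.testing.assert_allclose(infl.influence.toarray().ravel(), 1.0)

    def test_landmark_terminates_at_itself(self, chain3, small_params):
        infl = compute_influence(chain3, np.array([0, 2]), small_params)
        dense = infl.influence.toarray()
        assert dense[0, 0] == 1.0
        assert dense[2, 1] == 1.0

    def test_chain_midpoint_splits_evenly(self, chain3, small_params):
        """Absorbing-chain closed form: b reaches a and c with prob 1/2 each;
        Monte-Carlo estimate must land within 3 binomial sigma."""
        infl = compute_influence(chain3, np.array([0, 2]), small_params)
        n_walks = small_params.n_walks_influence
        sigma = np.sqrt(0.25 / n_walks)
        dense = infl.influence.toarray()
        assert dense[1, 0] == pytest.approx(0.5, abs=3 * sigma)
        assert dense[1, 1] == pytest.approx(0.5, abs=3 * sigma)

    def test_rows_sum_to_one(self, small_params):
        t = random_row_stochastic(60, 5, seed=6)
        landmarks, _ = select_landmarks(t, small_params)
        infl = compute_influence(t, landmarks, small_params)
        np.testing.assert_allclose(np.asarray(infl.influence.sum(axis=1)).ravel(), 1.0, atol=1e-9)


class TestBuildNextLevel:
    @pytest.fixture
    def chain_influence(self):
        infl = sp.csr_matrix(np.array([[1.0, 0.0], [0.5, 0.5], [0.0, 1.0]]))
        return InfluenceMatrix(influence=infl, landmarks=np.array([0, 2]))

    def test_hand_computed_similarity_and_weights(self, chain_influence):
        lg = build_next_level(chain_influence, np.ones(3))
        assert lg.similarities[0, 1] == pytest.approx(0.25)
        assert lg.similarities[1, 0] == pytest.approx(0.25)
        np.testing.assert_allclose(lg.weights, [1.5, 1.5])

    def test_disjoint_aoi_no_edge(self):
        infl = sp.csr_matrix(np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0]]))
        lg = build_next_level(InfluenceMatrix(influence=infl, landmarks=np.array([0, 2])), np.ones(3))
        assert lg.similarities.nnz == 0

    def test_weight_conservation(self, chain_influence):
        w = np.array([2.0, 3.0, 5.0])
        lg = build_next_level(chain_influence, w)
        assert lg.weights.sum() == pytest.approx(w.sum())

    def test_count_mode_counts_overlap_weight(self, chain_influence):
        lg = build_next_level(chain_influence, np.ones(3), overlap="count")
        # only node b lies in both AoIs, parent weight 1
        assert lg.similarities[0, 1] == pytest.approx(1.0)


@pytest.fixture(scope="module")
def blob_hierarchy():
    rng = np.random.default_rng(11)
    x = rng.normal(size=(1000, 5))
    params = HsneParams(k=15, perplexity=8.0, n_levels=2, seed=11)
    return build_hierarchy(x, params), params, x


class TestBuildHierarchy:
    def test_two_levels_conserve_weight(self, blob_hierarchy):
        h, _, _ = blob_hierarchy
        assert h.n_levels == 2
        assert h.level_graphs[0].weights.sum() == pytest.approx(1000, rel=1e-9)

    def test_same_seed_reproduces_hierarchy(self, blob_hierarchy):
        h, params, x = blob_hierarchy
        h2 = build_hierarchy(x, params)
        np.testing.assert_array_equal(
            h.level_graphs[0].landmark_parent_ids, h2.level_graphs[0].landmark_parent_ids
        )
        assert (h.level_graphs[0].similarities != h2.level_graphs[0].similarities).nnz == 0

    def test_landmarks_map_injectively(self, blob_hierarchy):
        h, _, _ = blob_hierarchy
        ids = h.level_graphs[0].landmark_parent_ids
        assert len(np.unique(ids)) == len(ids)
        assert ids.max() < 1000

    def test_persistence_round_trip(self, blob_hierarchy, tmp_path):
        h, _, _ = blob_hierarchy
        save_hierarchy(h, tmp_path / "c")
        back = load_hierarchy(tmp_path / "c")
        assert back.level_sizes == h.level_sizes
        np.testing.assert_allclose(
            back.level_graphs[0].weights, h.level_graphs[0].weights, rtol=1e-12
        )
        assert (back.data_transition.probs != h.data_transition.probs).nnz == 0
        diff = back.level_graphs[0].similarities - h.level_graphs[0].similarities
        assert abs(diff).max() < 1e-15 if diff.nnz else True

    def test_small_mixture_three_levels_invariants(self):
        data = make_mixture(n_cells=4000, n_markers=6, n_components=3, rare_fraction=0.1, seed=3)
        m = arcsinh_transform(data.matrix)
        params = HsneParams(k=20, perplexity=10.0, n_levels=3, seed=3)
        h = build_hierarchy(m, params)
        sizes = h.level_sizes
        assert sizes[0] > sizes[1] > sizes[2]  # monotone shrinkage
        for s in (1, 2):
            assert h.weights_at(s).sum() == pytest.approx(4000, rel=1e-6)
            rows = np.asarray(h.influences[s - 1].influence.sum(axis=1)).ravel()
            np.testing.assert_allclose(rows, 1.0, atol=1e-9)

    def test_collapse_raises_helpful_error(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(300, 3))
        params = HsneParams(k=10, perplexity=5.0, n_levels=6, seed=0)
        with pytest.raises(RuntimeError, match="fewer levels"):
            build_hierarchy(x, params)
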