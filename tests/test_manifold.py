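import warnings

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from sisoboost import (
    FeatureTable,
    SISOMAPParams,
    build_neighborhood_graph,
    classical_mds,
    isomap_fit,
    pairwise_dissimilarity,
    repair_connectivity,
    resolve_beta,
    shortest_paths,
    sisomap_fit,
    sisomap_transform,
)
from sisoboost.manifold import DisconnectedGraphError, GeodesicMatrix

from oracles import brute_force_shortest_paths, random_connected_graph


class TestPairwiseDissimilarity:
    def test_zero_distance_same_class(self):
        X = np.zeros((2, 3))
        D = pairwise_dissimilarity(X, np.array([1, 1]), alpha=0.5, beta=1.0)
        assert D.D[0, 1] == 0.0

    def test_zero_distance_different_class(self):
        X = np.zeros((2, 3))
        D = pairwise_dissimilarity(X, np.array([0, 1]), alpha=0.5, beta=1.0)
        assert D.D[0, 1] == pytest.approx(0.5, abs=1e-15)

    def test_unit_distance_same_class(self):
        # frozen oracle: sqrt(1 - e^{-1})
        X = np.array([[0.0], [1.0]])
        D = pairwise_dissimilarity(X, np.array([0, 0]), alpha=0.5, beta=1.0)
        assert D.D[0, 1] == pytest.approx(0.7950600976206501, abs=1e-12)

    def test_unit_distance_different_class_alpha_zero(self):
        # frozen oracle: e^{1/2}
        X = np.array([[0.0], [1.0]])
        D = pairwise_dissimilarity(X, np.array([0, 1]), alpha=0.0, beta=1.0)
        assert D.D[0, 1] == pytest.approx(1.6487212707001282, abs=1e-12)

    def test_unsupervised_mode_uses_same_class_branch(self):
        X = np.random.default_rng(0).normal(size=(6, 4))
        D_unsup = pairwise_dissimilarity(X, None, alpha=0.5, beta=2.0)
        D_same = pairwise_dissimilarity(
            X, np.zeros(6, dtype=int), alpha=0.5, beta=2.0
        )
        assert not D_unsup.supervised
        np.testing.assert_allclose(D_unsup.D, D_same.D)

    def test_matrix_invariants(self, rng):
        X = rng.normal(size=(15, 5))
        y = rng.integers(0, 2, 15)
        D = pairwise_dissimilarity(X, y, alpha=0.5, beta=resolve_beta(X)).D
        assert np.allclose(D, D.T)
        assert np.all(np.diag(D) == 0)
        assert np.all(D >= 0) and np.all(np.isfinite(D))
        same = y[:, None] == y[None, :]
        off = ~np.eye(15, dtype=bool)
        assert np.all(D[same & off] < 1.0)
        assert np.all(D[~same] >= 1.0 - 0.5)

    def test_branch_separation_on_distance_grid(self):
        # for any d >= 0: same-class < 1, different-class >= 1 - alpha;
        # with alpha <= 0 every between-class value beats every within-class one
        d = np.linspace(0, 10, 200)
        beta = 3.0
        same = np.sqrt(1 - np.exp(-d ** 2 / beta))
        for alpha in (-1.0, 0.0, 0.5, 1.0):
            diff = np.exp(d ** 2 / (2 * beta)) - alpha
            assert np.all(same < 1.0)
            assert np.all(diff >= 1.0 - alpha)
            if alpha <= 0:
                assert diff.min() > same.max()

    def test_rejects_non_finite(self):
        X = np.array([[0.0, 1.0], [np.nan, 2.0], [1.0, 1.0]])
        with pytest.raises(ValueError, match="non-finite"):
            pairwise_dissimilarity(X, None, alpha=0.5, beta=1.0)

    def test_rejects_overflow_advising_beta(self):
        X = np.array([[0.0], [2000.0]])
        with pytest.raises(ValueError, match="beta"):
            pairwise_dissimilarity(X, np.array([0, 1]), alpha=0.5, beta=1.0)


class TestResolveBeta:
    def test_two_points(self):
        assert resolve_beta(np.array([[0.0], [2.0]])) == pytest.approx(4.0)

    def test_three_collinear(self):
        X = np.array([[0.0], [1.0], [3.0]])
        assert resolve_beta(X) == pytest.approx(14 / 3)

    def test_identical_points_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            resolve_beta(np.ones((4, 3)))


class TestNeighborhoodGraph:
    def test_k_max_gives_complete_graph(self, rng):
        X = rng.normal(size=(3, 2))
        D = pairwise_dissimilarity(X, None, 0.5, 1.0)
        G = build_neighborhood_graph(D, X, k=2)
        assert G.edges == {(0, 1), (0, 2), (1, 2)}

    def test_line_k1_union_symmetrization(self, line_table):
        # point 3 (at 10) selects 2 as its nearest neighbour, so the union
        # rule keeps edge (2, 3) even though 2 does not select 3
        D = pairwise_dissimilarity(line_table.X, None, 0.5, 10.0)
        G = build_neighborhood_graph(D, line_table.X, k=1)
        assert G.edges == {(0, 1), (1, 2), (2, 3)}
        assert G.n_components == 1

    def test_tie_broken_by_smaller_index(self, line_table):
        # point 1 is equidistant from 0 and 2; the tie goes to index 0
        D = pairwise_dissimilarity(line_table.X, None, 0.5, 10.0)
        G = build_neighborhood_graph(D, line_table.X, k=1)
        assert (0, 1) in G.edges

    def test_two_clusters_k1_disconnected(self):
        X = np.array([[0.0], [1.0], [10.0], [11.0]])
        D = pairwise_dissimilarity(X, None, 0.5, 50.0)
        G = build_neighborhood_graph(D, X, k=1)
        assert G.edges == {(0, 1), (2, 3)}
        assert G.n_components == 2

    def test_epsilon_rule_bridges_clusters(self):
        X = np.array([[0.0], [1.0], [10.0], [11.0]])
        D = pairwise_dissimilarity(X, None, 0.5, 50.0)
        G = build_neighborhood_graph(D, X, k=1, epsilon=9.5)
        assert (1, 2) in G.edges  # Euclidean distance 9 < 9.5
        assert (0, 2) not in G.edges  # distance 10 >= 9.5
        assert G.n_components == 1

    def test_edge_weights_are_dissimilarities(self, line_table):
        D = pairwise_dissimilarity(line_table.X, None, 0.5, 10.0)
        G = build_neighborhood_graph(D, line_table.X, k=2)
        for i, j in G.edges:
            assert G.weights[i, j] == D.D[i, j]

    def test_k_out_of_range(self, line_table):
        D = pairwise_dissimilarity(line_table.X, None, 0.5, 10.0)
        with pytest.raises(ValueError, match="k must be"):
            build_neighborhood_graph(D, line_table.X, k=4)

    def test_no_self_loops(self, rng):
        X = rng.normal(size=(10, 3))
        D = pairwise_dissimilarity(X, None, 0.5, 1.0)
        G = build_neighborhood_graph(D, X, k=3)
        assert all(i != j for i, j in G.edges)


class TestRepairConnectivity:
    def test_idempotent_on_connected(self, rng):
        X = rng.normal(size=(8, 2))
        D = pairwise_dissimilarity(X, None, 0.5, 1.0)
        G = build_neighborhood_graph(D, X, k=7)
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            G2 = repair_connectivity(G, D)
        np.testing.assert_array_equal(G.weights, G2.weights)

    def test_repair_adds_closest_bridging_edge(self):
        X = np.array([[0.0], [1.0], [10.0], [11.0]])
        D = pairwise_dissimilarity(X, None, 0.5, 50.0)
        G = build_neighborhood_graph(D, X, k=1)
        with pytest.warns(UserWarning, match="added 1"):
            G2 = repair_connectivity(G, D)
        assert (1, 2) in G2.edges  # closest cross-component pair
        assert G2.n_components == 1

    def test_three_singletons_minimal_connection(self):
        # points at 0, 1, 3: cross distances 1, 2, 3 -> edges (0,1) and (1,2)
        X = np.array([[0.0], [1.0], [3.0]])
        from sisoboost.manifold import DissimilarityMatrix, NeighborhoodGraph

        D = DissimilarityMatrix(D=squareform(pdist(X)), supervised=False)
        W = np.full((3, 3), np.inf)
        np.fill_diagonal(W, 0.0)
        G = NeighborhoodGraph(weights=W, component_labels=np.arange(3))
        with pytest.warns(UserWarning, match="added 2"):
            G2 = repair_connectivity(G, D)
        assert G2.edges == {(0, 1), (1, 2)}  # total weight 3, the minimum

    def test_never_removes_edges_and_reduces_components(self, rng):
        for _ in range(10):
            X = rng.normal(size=(12, 2)) * 0.1
            X[6:] += 50.0  # force two clusters
            D = pairwise_dissimilarity(X, None, 0.5, resolve_beta(X))
            G = build_neighborhood_graph(D, X, k=2)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                G2 = repair_connectivity(G, D)
            assert G.edges <= G2.edges
            assert G2.n_components == 1
            assert len(G2.edges) - len(G.edges) == G.n_components - 1


class TestShortestPaths:
    def test_triangle_shortcut(self):
        from sisoboost.manifold import NeighborhoodGraph

        W = np.array([
            [0.0, 1.0, 3.0],
            [1.0, 0.0, 1.0],
            [3.0, 1.0, 0.0],
        ])
        G = NeighborhoodGraph(weights=W, component_labels=np.zeros(3, int))
        geo = shortest_paths(G)
        assert geo.D_G[0, 2] == pytest.approx(2.0)

    def test_single_edge(self):
        from sisoboost.manifold import NeighborhoodGraph

        W = np.array([[0.0, 0.7], [0.7, 0.0]])
        G = NeighborhoodGraph(weights=W, component_labels=np.zeros(2, int))
        assert shortest_paths(G).D_G[0, 1] == pytest.approx(0.7)

    def test_matches_brute_force_enumeration(self, rng):
        from sisoboost.manifold import NeighborhoodGraph

        for _ in range(20):
            n = int(rng.integers(3, 8))
            W = random_connected_graph(rng, n)
            G = NeighborhoodGraph(weights=W, component_labels=np.zeros(n, int))
            got = shortest_paths(G).D_G
            expected = brute_force_shortest_paths(W)
            np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_rejects_disconnected(self):
        from sisoboost.manifold import NeighborhoodGraph

        W = np.full((3, 3), np.inf)
        np.fill_diagonal(W, 0.0)
        W[0, 1] = W[1, 0] = 1.0
        G = NeighborhoodGraph(weights=W, component_labels=np.array([0, 0, 1]))
        with pytest.raises(DisconnectedGraphError):
            shortest_paths(G)

    def test_zero_weight_edges_survive(self):
        # duplicate points create zero-dissimilarity edges that must still
        # act as edges
        from sisoboost.manifold import NeighborhoodGraph

        W = np.array([
            [0.0, 0.0, np.inf],
            [0.0, 0.0, 2.0],
            [np.inf, 2.0, 0.0],
        ])
        G = NeighborhoodGraph(weights=W, component_labels=np.zeros(3, int))
        geo = shortest_paths(G)
        assert geo.D_G[0, 2] == pytest.approx(2.0)

    def test_triangle_inequality(self, rng):
        from sisoboost.manifold import NeighborhoodGraph

        W = random_connected_graph(rng, 7)
        G = NeighborhoodGraph(weights=W, component_labels=np.zeros(7, int))
        D_G = shortest_paths(G).D_G
        for l in range(7):
            assert np.all(D_G <= D_G[:, [l]] + D_G[[l], :] + 1e-12)


class TestClassicalMDS:
    def test_two_points(self):
        geo = GeodesicMatrix(D_G=np.array([[0.0, 2.0], [2.0, 0.0]]))
        emb = classical_mds(geo, d=1)
        assert sorted(emb.Y[:, 0]) == pytest.approx([-1.0, 1.0])

    def test_unit_square_roundtrip(self):
        pts = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        geo = GeodesicMatrix(D_G=squareform(pdist(pts)))
        emb = classical_mds(geo, d=2)
        np.testing.assert_allclose(
            squareform(pdist(emb.Y)), geo.D_G, atol=1e-10
        )

    def test_random_configuration_roundtrip(self, rng):
        for _ in range(10):
            n, d = int(rng.integers(5, 30)), int(rng.integers(1, 5))
            pts = rng.normal(size=(n, d))
            geo = GeodesicMatrix(D_G=squareform(pdist(pts)))
            emb = classical_mds(geo, d=d)
            np.testing.assert_allclose(
                squareform(pdist(emb.Y)), geo.D_G, atol=1e-8
            )

    def test_eigenvalues_descending_positive(self, rng):
        pts = rng.normal(size=(12, 4))
        emb = classical_mds(GeodesicMatrix(D_G=squareform(pdist(pts))), d=4)
        assert np.all(np.diff(emb.eigenvalues) <= 1e-9)
        assert np.all(emb.eigenvalues > 0)

    def test_sign_convention(self, rng):
        pts = rng.normal(size=(9, 3))
        emb = classical_mds(GeodesicMatrix(D_G=squareform(pdist(pts))), d=3)
        for j in range(3):
            col = emb.eigenvectors[:, j]
            assert col[np.argmax(np.abs(col))] > 0

    def test_d_too_large_rejected(self):
        geo = GeodesicMatrix(D_G=np.array([[0.0, 1.0], [1.0, 0.0]]))
        with pytest.raises(ValueError, match="d must be"):
            classical_mds(geo, d=2)

    def test_dimension_reduced_when_rank_deficient(self):
        # 3 collinear points have a rank-1 Gram matrix
        pts = np.array([[0.0], [1.0], [2.0]])
        geo = GeodesicMatrix(D_G=squareform(pdist(pts)))
        with pytest.warns(UserWarning, match="reducing embedding"):
            emb = classical_mds(geo, d=2)
        assert emb.Y.shape == (3, 1)


class TestFitPipelines:
    def test_supervision_increases_separation_ratio(self, gauss_classes):
        def ratio(M, y):
            D = squareform(pdist(M))
            same = y[:, None] == y[None, :]
            off = ~np.eye(len(y), dtype=bool)
            return D[~same].mean() / D[same & off].mean()

        params = SISOMAPParams(k=5, alpha=0.5, beta="auto", d=3)
        emb = sisomap_fit(gauss_classes, params)
        r_in = ratio(gauss_classes.X, gauss_classes.y)
        r_out = ratio(emb.Y, gauss_classes.y)
        assert r_out > r_in

    def test_uniform_labels_match_isomap_edges(self, rng):
        X = rng.normal(size=(25, 4))
        table_sup = FeatureTable(
            ids=[str(i) for i in range(25)], X=X, y=np.zeros(25, dtype=int)
        )
        table_unsup = FeatureTable(ids=[str(i) for i in range(25)], X=X)
        emb_s = sisomap_fit(table_sup, SISOMAPParams(k=4, d=2))
        emb_u = isomap_fit(table_unsup, k=4, d=2)
        assert emb_s.graph_.edges == emb_u.graph_.edges

    def test_two_points(self):
        table = FeatureTable(ids=["a", "b"], X=np.array([[0.0], [3.0]]),
                             y=np.array([0, 1]))
        emb = sisomap_fit(table, SISOMAPParams(k=1, d=1, beta=9.0))
        D12 = emb.Y[0, 0] - emb.Y[1, 0]
        expected = np.exp(9.0 / 18.0) - 0.5
        assert abs(D12) == pytest.approx(expected, rel=1e-12)
        assert sorted(emb.Y[:, 0]) == pytest.approx(
            [-expected / 2, expected / 2]
        )

    def test_isomap_affine_subspace_exact(self, rng):
        # complete graph => geodesic = Euclidean => MDS exact
        base = rng.normal(size=(15, 2))
        lift = rng.normal(size=(2, 6))
        X = base @ lift
        table = FeatureTable(ids=[str(i) for i in range(15)], X=X)
        emb = isomap_fit(table, k=14, d=2)
        np.testing.assert_allclose(
            squareform(pdist(emb.Y)), squareform(pdist(X)), atol=1e-6
        )

    def test_permutation_covariance(self, gauss_classes, rng):
        params = SISOMAPParams(k=5, d=3)
        emb = sisomap_fit(gauss_classes, params)
        perm = rng.permutation(gauss_classes.n_samples)
        permuted = FeatureTable(
            ids=[gauss_classes.ids[i] for i in perm],
            X=gauss_classes.X[perm],
            y=gauss_classes.y[perm],
        )
        emb_p = sisomap_fit(permuted, params)
        np.testing.assert_allclose(emb_p.Y, emb.Y[perm], atol=1e-8)

    def test_requires_labels(self, line_table):
        with pytest.raises(ValueError, match="labels"):
            sisomap_fit(line_table, SISOMAPParams(k=2, d=1))

    def test_deterministic(self, gauss_classes):
        params = SISOMAPParams(k=5, d=3)
        Y1 = sisomap_fit(gauss_classes, params).Y
        Y2 = sisomap_fit(gauss_classes, params).Y
        np.testing.assert_array_equal(Y1, Y2)


class TestTransform:
    def test_training_rows_self_consistent(self, gauss_classes):
        emb = sisomap_fit(gauss_classes, SISOMAPParams(k=5, d=3))
        Y_back = sisomap_transform(emb, gauss_classes.X)
        assert np.abs(Y_back - emb.Y).max() <= 1e-6

    def test_midpoint_lands_between_neighbors(self):
        # dense 1-D manifold in R^2, all same class
        t = np.linspace(0, 1, 30)
        X = np.column_stack([t, t ** 2])
        table = FeatureTable(
            ids=[str(i) for i in range(30)], X=X, y=np.zeros(30, dtype=int)
        )
        emb = sisomap_fit(table, SISOMAPParams(k=3, d=1))
        mid = (X[10] + X[11]) / 2
        y_mid = sisomap_transform(emb, mid[None, :])[0]
        d_gap = np.linalg.norm(emb.Y[10] - emb.Y[11])
        assert np.linalg.norm(y_mid - emb.Y[10]) < d_gap
        assert np.linalg.norm(y_mid - emb.Y[11]) < d_gap

    def test_empty_input(self, gauss_classes):
        emb = sisomap_fit(gauss_classes, SISOMAPParams(k=5, d=3))
        out = sisomap_transform(emb, np.empty((0, 10)))
        assert out.shape == (0, 3)

    def test_dimension_mismatch_rejected(self, gauss_classes):
        emb = sisomap_fit(gauss_classes, SISOMAPParams(k=5, d=3))
        with pytest.raises(ValueError, match="features"):
            sisomap_transform(emb, np.zeros((2, 7)))


class TestTransductive:
    def test_shapes_and_determinism(self, gauss_classes, rng):
        from sisoboost import sisomap_fit_transductive

        X_new = rng.normal(size=(5, 10))
        params = SISOMAPParams(k=5, d=3)
        Y_tr1, Y_te1 = sisomap_fit_transductive(gauss_classes, X_new, params)
        Y_tr2, Y_te2 = sisomap_fit_transductive(gauss_classes, X_new, params)
        assert Y_tr1.shape == (40, 3) and Y_te1.shape == (5, 3)
        np.testing.assert_array_equal(Y_tr1, Y_tr2)
        np.testing.assert_array_equal(Y_te1, Y_te2)


class TestFeatureTable:
    def test_rejects_nan(self):
        with pytest.raises(ValueError, match="non-finite"):
            FeatureTable(ids=["a", "b"], X=np.array([[1.0], [np.nan]]))

    def test_rejects_nonbinary_labels(self):
        with pytest.raises(ValueError, match="binary"):
            FeatureTable(ids=["a", "b"], X=np.zeros((2, 1)),
                         y=np.array([0, 2]))

    def test_rejects_length_mismatch(self):
        with pytest.raises(ValueError, match="ids"):
            FeatureTable(ids=["a"], X=np.zeros((2, 1)))


class TestParams:
    def test_alpha_bound(self):
        with pytest.raises(ValueError, match="alpha"):
            SISOMAPParams(alpha=1.5)

    def test_beta_positive(self):
        with pytest.raises(ValueError, match="beta"):
            SISOMAPParams(beta=-1.0)

    def test_auto_beta_passthrough(self):
        assert SISOMAPParams(beta="auto").beta == "auto"
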