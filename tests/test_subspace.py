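"""Unit and property tests for the feature-weighted subspace clustering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import tskfuzzy as tf
from tskfuzzy import subspace as sub
from tskfuzzy.subspace import project_rows_to_simplex

from conftest import match_clusters, random_instance


class TestInitialization:
    def test_uniform_initial_weights(self):
        rng = np.random.default_rng(0)
        data = tf.FeatureMatrix(rng.normal(size=(10, 4)))
        state = tf.initialize_state(data, tf.ClusteringConfig(n_clusters=3))
        assert np.all(state.weights == 0.25)
        assert np.all(state.regularizers == 1.0)

    def test_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(1)
        data = tf.FeatureMatrix(rng.normal(size=(20, 3)))
        cfg = tf.ClusteringConfig(n_clusters=4, seed=7)
        a = tf.initialize_state(data, cfg)
        b = tf.initialize_state(data, cfg)
        assert np.array_equal(a.centers, b.centers)
        assert np.array_equal(a.memberships, b.memberships)

    def test_centers_are_data_rows(self):
        rng = np.random.default_rng(2)
        data = tf.FeatureMatrix(rng.normal(size=(15, 3)))
        state = tf.initialize_state(data, tf.ClusteringConfig(n_clusters=5, seed=3))
        for center in state.centers:
            assert any(np.array_equal(center, row) for row in data.values)
        # distinct rows: no repeated center
        assert len({tuple(c) for c in state.centers}) == 5

    def test_single_cluster_memberships_are_one(self):
        rng = np.random.default_rng(3)
        data = tf.FeatureMatrix(rng.normal(size=(6, 2)))
        state = tf.initialize_state(data, tf.ClusteringConfig(n_clusters=1))
        assert np.allclose(state.memberships, 1.0)

    def test_too_few_samples_rejected(self):
        data = tf.FeatureMatrix(np.eye(3))
        with pytest.raises(tf.ValidationError, match="insufficient samples"):
            tf.initialize_state(data, tf.ClusteringConfig(n_clusters=5))


class TestWeightUpdate:
    def test_symmetric_dispersion_gives_uniform_weights(self):
        # data and centers symmetric under feature permutation: every feature
        # contributes the same dispersion, so the bracketed term vanishes
        data = tf.FeatureMatrix(np.array([[1.0, 1.0, 1.0], [-1.0, -1.0, -1.0]]))
        state = sub.ClusteringState(
            memberships=np.array([[0.5, 0.5]]),
            centers=np.zeros((1, 3)),
            weights=np.full((1, 3), 1 / 3),
            regularizers=np.array([1.0]),
        )
        w = tf.update_feature_weights(data, state, tf.ClusteringConfig(n_clusters=1))
        assert np.allclose(w, 1 / 3)

    @pytest.mark.parametrize("seed", [7, 11, 13])
    def test_matches_constrained_minimizer_on_the_simplex(self, seed):
        from scipy.optimize import minimize

        data, state, config = random_instance(seed)
        w_mine = tf.update_feature_weights(data, state, config)
        for c in range(config.n_clusters):
            def objective(w, c=c):
                trial = w_mine.copy()
                trial[c] = w
                probe = sub.ClusteringState(
                    state.memberships, state.centers, trial, state.regularizers
                )
                return tf.objective_value(data, probe, config)

            d = data.n_features
            res = minimize(
                objective,
                np.full(d, 1 / d),
                method="SLSQP",
                bounds=[(0.0, 1.0)] * d,
                constraints=[{"type": "eq", "fun": lambda w: w.sum() - 1.0}],
                options={"ftol": 1e-14, "maxiter": 500},
            )
            assert np.abs(w_mine[c] - res.x).max() < 1e-6

    def test_high_dispersion_feature_weighted_below_average(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(30, 3)) * np.array([0.1, 0.1, 10.0])
        data = tf.FeatureMatrix(x)
        state = sub.ClusteringState(
            memberships=np.full((1, 30), 1.0),
            centers=np.zeros((1, 3)),
            weights=np.full((1, 3), 1 / 3),
            regularizers=np.array([x.var() * 30.0]),
        )
        w = tf.update_feature_weights(data, state, tf.ClusteringConfig(n_clusters=1))
        assert w[0, 2] < 1 / 3

    def test_rows_sum_to_one(self):
        data, state, config = random_instance(21, n_clusters=3, n_features=4, n_samples=8)
        w = tf.update_feature_weights(data, state, config)
        assert np.abs(w.sum(axis=1) - 1.0).max() < 1e-10
        assert w.min() >= 0.0

    def test_degenerate_regularizer_rejected(self):
        data, state, config = random_instance(1)
        state.regularizers = np.array([0.0, 1.0])
        with pytest.raises(tf.ValidationError, match="degenerate regularizer"):
            tf.update_feature_weights(data, state, config)


class TestRegularizerUpdate:
    def test_zero_scatter_hits_floor(self):
        data = tf.FeatureMatrix(np.array([[1.0, 2.0], [1.0, 2.0]]))
        state = sub.ClusteringState(
            memberships=np.ones((1, 2)),
            centers=np.array([[1.0, 2.0]]),
            weights=np.full((1, 2), 0.5),
            regularizers=np.ones(1),
        )
        delta = tf.update_regularizers(data, state, tf.ClusteringConfig(n_clusters=1))
        assert delta[0] == pytest.approx(1e-12)

    def test_direct_formula_on_three_samples(self):
        # hand evaluation with uniform weights: delta = d * weighted scatter
        x = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 0.0]])
        data = tf.FeatureMatrix(x)
        u = np.array([[0.9, 0.5, 0.1]])
        v = np.array([[1.0, 0.5]])
        w = np.full((1, 2), 0.5)
        state = sub.ClusteringState(u, v, w, np.ones(1))
        cfg = tf.ClusteringConfig(n_clusters=1, fuzzifier=2.0)
        expected = sum(
            u[0, i] ** 2 * sum(0.5 * (x[i, j] - v[0, j]) ** 2 for j in range(2))
            for i in range(3)
        ) / sum(0.5**2 for _ in range(2))
        delta = tf.update_regularizers(data, state, cfg)
        assert delta[0] == pytest.approx(expected, rel=1e-12)

    def test_linearity_in_membership_mass(self):
        data, state, config = random_instance(9)
        base = tf.update_regularizers(data, state, config)
        boosted = sub.ClusteringState(
            state.memberships * 2 ** (1 / config.fuzzifier),
            state.centers,
            state.weights,
            state.regularizers,
        )
        doubled = tf.update_regularizers(data, boosted, config)
        assert np.allclose(doubled, 2.0 * base)


class TestMembershipUpdate:
    def test_single_cluster_gives_ones(self):
        data, state, _ = random_instance(2, n_clusters=1)
        u = tf.update_memberships(data, state, tf.ClusteringConfig(n_clusters=1))
        assert np.allclose(u, 1.0)

    def test_sample_on_center_gets_crisp_membership(self):
        data = tf.FeatureMatrix(np.array([[1.0, 2.0], [5.0, 5.0]]))
        state = sub.ClusteringState(
            memberships=np.zeros((2, 2)),
            centers=np.array([[1.0, 2.0], [0.0, 0.0]]),
            weights=np.full((2, 2), 0.5),
            regularizers=np.ones(2),
        )
        u = tf.update_memberships(data, state, tf.ClusteringConfig(n_clusters=2))
        assert u[0, 0] == 1.0 and u[1, 0] == 0.0

    def test_tied_zero_distances_split_equally(self):
        data = tf.FeatureMatrix(np.array([[0.0], [9.0]]))
        state = sub.ClusteringState(
            memberships=np.zeros((2, 2)),
            centers=np.array([[0.0], [0.0]]),
            weights=np.ones((2, 1)),
            regularizers=np.ones(2),
        )
        u = tf.update_memberships(data, state, tf.ClusteringConfig(n_clusters=2))
        assert u[0, 0] == 0.5 and u[1, 0] == 0.5

    def test_closed_form_quarter_three_quarters(self):
        # weighted squared distances 1 and 3 with m = 2 give 0.75 / 0.25
        data = tf.FeatureMatrix(np.array([[0.0], [10.0]]))
        state = sub.ClusteringState(
            memberships=np.zeros((2, 2)),
            centers=np.array([[1.0], [np.sqrt(3.0)]]),
            weights=np.ones((2, 1)),
            regularizers=np.ones(2),
        )
        u = tf.update_memberships(data, state, tf.ClusteringConfig(n_clusters=2))
        assert u[0, 0] == pytest.approx(0.75, abs=1e-12)
        assert u[1, 0] == pytest.approx(0.25, abs=1e-12)

    @pytest.mark.parametrize("seed", [4, 8])
    def test_matches_constrained_minimizer(self, seed):
        from scipy.optimize import minimize

        data, state, config = random_instance(seed)
        u_mine = tf.update_memberships(data, state, config)
        dist = sub._weighted_sq_distances(data.values, state.centers, state.weights)
        for i in range(data.n_samples):
            res = minimize(
                lambda u: np.sum(u**config.fuzzifier * dist[:, i]),
                np.full(config.n_clusters, 1 / config.n_clusters),
                method="SLSQP",
                bounds=[(0.0, 1.0)] * config.n_clusters,
                constraints=[{"type": "eq", "fun": lambda u: u.sum() - 1.0}],
                options={"ftol": 1e-16, "maxiter": 1000},
            )
            assert np.abs(u_mine[:, i] - res.x).max() < 1e-6


class TestCenterUpdate:
    def test_crisp_memberships_give_plain_means(self):
        x = np.array([[0.0, 0.0], [2.0, 2.0], [10.0, 10.0], [12.0, 14.0]])
        data = tf.FeatureMatrix(x)
        u = np.array([[1.0, 1.0, 0.0, 0.0], [0.0, 0.0, 1.0, 1.0]])
        state = sub.ClusteringState(u, np.zeros((2, 2)), np.full((2, 2), 0.5), np.ones(2))
        v = tf.update_centers(data, state, tf.ClusteringConfig(n_clusters=2))
        assert np.allclose(v[0], [1.0, 1.0])
        assert np.allclose(v[1], [11.0, 12.0])

    def test_equal_memberships_give_global_mean(self):
        data, state, config = random_instance(6, n_clusters=3, n_samples=7)
        state.memberships = np.full((3, 7), 1 / 3)
        v = tf.update_centers(data, state, config)
        assert np.allclose(v, data.values.mean(axis=0)[None, :])

    def test_matches_per_coordinate_minimizer(self):
        from scipy.optimize import minimize_scalar

        data, state, config = random_instance(17)
        v_mine = tf.update_centers(data, state, config)
        um = state.memberships**config.fuzzifier
        for c in range(config.n_clusters):
            for j in range(data.n_features):
                if state.weights[c, j] <= 0:
                    continue  # objective independent of this coordinate
                res = minimize_scalar(
                    lambda v: np.sum(um[c] * (data.values[:, j] - v) ** 2),
                    bounds=(data.values[:, j].min() - 1, data.values[:, j].max() + 1),
                    method="bounded",
                    options={"xatol": 1e-12},
                )
                assert abs(v_mine[c, j] - res.x) < 1e-6

    def test_recovers_separated_cluster_means(self):
        rng = np.random.default_rng(12)
        means = np.array([[0.0, 0.0], [8.0, 8.0]])
        x = np.vstack(
            [rng.normal(m, 0.2, size=(60, 2)) for m in means]
        )
        data = tf.FeatureMatrix(x)
        state = tf.fit_subspace_clustering(data, tf.ClusteringConfig(n_clusters=2, seed=0))
        fitted = state.centers[np.argsort(state.centers[:, 0])]
        assert np.abs(fitted - means).max() < 0.1

    def test_empty_cluster_reseeded(self):
        data = tf.FeatureMatrix(np.array([[0.0], [1.0], [10.0]]))
        state = sub.ClusteringState(
            memberships=np.array([[1.0, 1.0, 1.0], [0.0, 0.0, 0.0]]),
            centers=np.array([[0.5], [0.5]]),
            weights=np.ones((2, 1)),
            regularizers=np.ones(2),
        )
        v = tf.update_centers(data, state, tf.ClusteringConfig(n_clusters=2))
        assert v[1, 0] == 10.0  # farthest sample from its best center


class TestObjective:
    def test_hand_computed_instance(self):
        data = tf.FeatureMatrix(np.array([[0.0], [2.0]]))
        state = sub.ClusteringState(
            memberships=np.ones((1, 2)),
            centers=np.array([[1.0]]),
            weights=np.ones((1, 1)),
            regularizers=np.ones(1),
        )
        j = tf.objective_value(data, state, tf.ClusteringConfig(n_clusters=1))
        assert j == pytest.approx(3.0)

    def test_pure_penalty_when_samples_on_centers(self):
        data = tf.FeatureMatrix(np.array([[1.0, 2.0], [1.0, 2.0]]))
        state = sub.ClusteringState(
            memberships=np.ones((1, 2)),
            centers=np.array([[1.0, 2.0]]),
            weights=np.full((1, 2), 0.5),
            regularizers=np.array([1e-12]),
        )
        j = tf.objective_value(data, state, tf.ClusteringConfig(n_clusters=1))
        assert j == pytest.approx(1e-12 * 0.5)

    @pytest.mark.parametrize("seed", range(5))
    def test_non_negative(self, seed):
        data, state, config = random_instance(seed)
        assert tf.objective_value(data, state, config) >= 0.0


class TestFit:
    def test_informative_features_out_weigh_noise(self, subspace_data):
        data, truth = subspace_data
        state = tf.fit_subspace_clustering(data, tf.ClusteringConfig(n_clusters=3, seed=0))
        mapping = match_clusters(state.memberships.argmax(axis=0), truth["assignments"], 3)
        for c, t in mapping.items():
            informative = truth["informative"][t]
            assert state.weights[c][informative].min() > state.weights[c][~informative].max()

    def test_infinite_tolerance_stops_after_one_sweep(self):
        rng = np.random.default_rng(0)
        data = tf.FeatureMatrix(rng.normal(size=(20, 3)))
        cfg = tf.ClusteringConfig(n_clusters=2, tolerance=np.inf)
        state = tf.fit_subspace_clustering(data, cfg)
        assert state.n_iter == 1

    def test_bit_identical_across_runs(self):
        rng = np.random.default_rng(5)
        data = tf.FeatureMatrix(rng.normal(size=(40, 4)))
        cfg = tf.ClusteringConfig(n_clusters=3, seed=2)
        a = tf.fit_subspace_clustering(data, cfg)
        b = tf.fit_subspace_clustering(data, cfg)
        assert np.array_equal(a.memberships, b.memberships)
        assert np.array_equal(a.centers, b.centers)
        assert np.array_equal(a.weights, b.weights)
        assert a.history == b.history

    @pytest.mark.parametrize("seed", range(10))
    def test_objective_non_increasing(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 40))
        d = int(rng.integers(2, 6))
        c = int(rng.integers(2, 5))
        data = tf.FeatureMatrix(rng.normal(size=(n, d)) * rng.uniform(0.5, 3.0))
        state = tf.fit_subspace_clustering(data, tf.ClusteringConfig(n_clusters=c, seed=seed))
        assert np.all(np.diff(state.history) <= 1e-8)

    @pytest.mark.parametrize("seed", range(5))
    def test_constraints_conserved(self, seed):
        rng = np.random.default_rng(100 + seed)
        data = tf.FeatureMatrix(rng.normal(size=(25, 4)))
        state = tf.fit_subspace_clustering(data, tf.ClusteringConfig(n_clusters=3, seed=seed))
        assert np.abs(state.memberships.sum(axis=0) - 1.0).max() < 1e-10
        assert np.abs(state.weights.sum(axis=1) - 1.0).max() < 1e-10

    def test_sample_permutation_permutes_membership_columns(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=(30, 3))
        perm = rng.permutation(30)
        cfg = tf.ClusteringConfig(n_clusters=2, seed=1)
        # permutation-invariant initialization: fix centers explicitly by
        # running on both orders from the same initial centers
        a = tf.initialize_state(tf.FeatureMatrix(x), cfg)
        data_p = tf.FeatureMatrix(x[perm])
        b = sub.ClusteringState(
            memberships=np.zeros((2, 30)),
            centers=a.centers.copy(),
            weights=a.weights.copy(),
            regularizers=a.regularizers.copy(),
        )
        b.memberships = tf.update_memberships(data_p, b, cfg)
        assert np.allclose(a.memberships[:, perm], b.memberships)
        va = tf.update_centers(tf.FeatureMatrix(x), a, cfg)
        vb = tf.update_centers(data_p, b, cfg)
        assert np.allclose(va, vb)


class TestFcmEquivalence:
    def test_matches_textbook_fuzzy_c_means(self):
        """With uniform frozen weights and no penalty, the membership and
        center updates reduce to classical fuzzy c-means (the 1/d distance
        scaling cancels in the membership ratio)."""
        rng = np.random.default_rng(42)
        x = rng.normal(size=(40, 3))
        m = 2.0
        c = 3
        centers = x[:c].copy()

        # textbook FCM reference, written independently of the package path
        ref_centers = centers.copy()
        for _ in range(10):
            dist = ((x[None, :, :] - ref_centers[:, None, :]) ** 2).sum(axis=2)
            dist = np.maximum(dist, 1e-300)
            inv = dist ** (-1.0 / (m - 1.0))
            ref_u = inv / inv.sum(axis=0, keepdims=True)
            um = ref_u**m
            ref_centers = (um @ x) / um.sum(axis=1)[:, None]

        data = tf.FeatureMatrix(x)
        cfg = tf.ClusteringConfig(n_clusters=c, fuzzifier=m)
        state = sub.ClusteringState(
            memberships=np.zeros((c, 40)),
            centers=centers.copy(),
            weights=np.full((c, 3), 1 / 3),  # frozen uniform
            regularizers=np.ones(c),
        )
        for _ in range(10):
            state.memberships = tf.update_memberships(data, state, cfg)
            state.centers = tf.update_centers(data, state, cfg)

        assert np.abs(state.centers - ref_centers).max() < 1e-8
        assert np.abs(state.memberships - ref_u).max() < 1e-8


class TestSimplexProjection:
    @settings(derandomize=True, max_examples=50)
    @given(
        arrays(
            np.float64,
            (3, 5),
            elements=st.floats(-10, 10, allow_nan=False),
        )
    )
    def test_projection_lands_on_the_simplex(self, rows):
        proj = project_rows_to_simplex(rows)
        assert proj.min() >= 0.0
        assert np.abs(proj.sum(axis=1) - 1.0).max() < 1e-9

    def test_identity_on_simplex_points(self):
        rng = np.random.default_rng(0)
        rows = rng.dirichlet(np.ones(4), size=6)
        assert np.allclose(project_rows_to_simplex(rows), rows, atol=1e-12)
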