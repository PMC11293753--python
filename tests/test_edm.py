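import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.base import clone

import edmcontrol as ec
from edmcontrol.errors import InsufficientLibraryError, ParameterError
from conftest import random_library


def _library(rows, futures, times=None):
    rows = np.asarray(rows, float)
    spec = ec.EmbeddingSpec(tuple((f"c{i}", 0) for i in range(rows.shape[1])),
                            "c0", Tp=1)
    n = rows.shape[0]
    times = np.arange(n) if times is None else np.asarray(times)
    return ec.StateSpaceLibrary(rows, times.astype(np.int64),
                                np.asarray(futures, float), spec)


class TestNearestNeighbors:
    def test_matches_brute_force_sort(self, rng):
        for _ in range(30):
            lib = random_library(rng)
            y = rng.normal(size=lib.E)
            d = np.linalg.norm(lib.rows - y, axis=1)
            order = np.lexsort((lib.row_times, d))
            for k in {1, 2, lib.k_N // 2, lib.k_N} - {0}:
                nn = ec.nearest_neighbors(lib, y, k, require_future=False)
                np.testing.assert_array_equal(nn.indices, order[:k])
                assert np.all(np.diff(nn.distances) >= 0)
                assert nn.mean_distance == pytest.approx(d[order[:k]].mean())

    def test_two_point_example(self):
        lib = _library([[0, 0], [1, 1], [2, 2]], [0.0, 1.0, 2.0])
        nn = ec.nearest_neighbors(lib, [0.9, 0.9], k=2)
        assert nn.indices.tolist() == [1, 0]
        np.testing.assert_allclose(nn.distances ** 2, [0.02, 1.62])

    def test_exact_match_has_zero_distance(self):
        lib = _library([[1, 2], [3, 4]], [0.0, 1.0])
        nn = ec.nearest_neighbors(lib, [3, 4], k=1)
        assert nn.indices[0] == 1
        assert nn.distances[0] == 0.0

    def test_equidistant_ties_break_by_time(self):
        lib = _library([[1.0], [-1.0], [1.0]], [0, 0, 0], times=[5, 6, 7])
        nn = ec.nearest_neighbors(lib, [0.0], k=3)
        assert nn.indices.tolist() == [0, 1, 2]

    def test_exclusion_removes_rows_by_time(self):
        lib = _library([[0.0], [0.1], [5.0]], [0, 0, 0])
        nn = ec.nearest_neighbors(lib, [0.0], k=1, exclusion={0, 1})
        assert nn.indices.tolist() == [2]

    def test_k_beyond_available_rows_rejected(self):
        lib = _library([[0.0], [1.0]], [0, 0])
        with pytest.raises(ParameterError):
            ec.nearest_neighbors(lib, [0.0], k=3)


class TestSimplex:
    def test_equal_futures_give_that_value(self):
        lib = _library([[0.0], [1.0], [2.0], [3.0]], [7.0] * 4)
        assert ec.simplex_predict(lib, [0.5], k=3) == pytest.approx(7.0)

    def test_coincident_query_dominated_by_exact_match(self):
        lib = _library([[0.0], [1.0], [2.0]], [10.0, 0.0, 0.0])
        pred = ec.simplex_predict(lib, [0.0], k=3)
        # zero nearest distance: the exact match gets all the weight
        assert pred == pytest.approx(10.0)
        assert 0.0 <= pred <= 10.0

    def test_prediction_bounded_by_neighbor_futures(self, rng):
        for _ in range(50):
            lib = random_library(rng)
            k = min(lib.E + 1, lib.k_N)
            y = rng.normal(size=lib.E)
            nn = ec.nearest_neighbors(lib, y, k)
            futures = lib.target_futures[nn.indices]
            pred = ec.simplex_predict(lib, y, k)
            assert futures.min() - 1e-12 <= pred <= futures.max() + 1e-12

    def test_logistic_map_leave_one_out_skill(self, logistic_table):
        """Deterministic chaos is near-perfectly predictable one step
        ahead from an E=2 delay embedding."""
        spec = ec.EmbeddingSpec.univariate("x", E=2, Tp=1)
        lib = ec.embed(logistic_table, spec)
        mask = lib.has_future
        preds = np.array([
            ec.simplex_predict(lib, lib.rows[i],
                               exclusion={int(lib.row_times[i])})
            for i in np.flatnonzero(mask)
        ])
        rho = ec.pearson_skill(lib.target_futures[mask], preds)
        assert rho > 0.99

    def test_insufficient_futures_raise(self):
        lib = _library([[0.0], [1.0]], [np.nan, np.nan])
        with pytest.raises(InsufficientLibraryError):
            ec.simplex_predict(lib, [0.0], k=1)


class TestSMap:
    def test_theta_zero_recovers_exact_linear_rule(self):
        x = np.linspace(0, 1, 20)[:, None]
        lib = _library(x, 0.5 * x.ravel() + 0.1)
        sol = ec.smap_predict(lib, [0.3], theta=0.0)
        np.testing.assert_allclose(sol.coefficients, [0.1, 0.5], atol=1e-10)
        assert sol.prediction == pytest.approx(0.25)

    def test_constant_library_predicts_constant(self):
        lib = _library(np.full((8, 2), 2.0), np.full(8, 9.0))
        sol = ec.smap_predict(lib, [2.0, 2.0], theta=1.5)
        assert sol.prediction == pytest.approx(9.0)
        # all rows coincide: uniform-weight fallback
        np.testing.assert_allclose(sol.weights, 1.0)

    def test_weight_at_mean_distance_is_exp_minus_theta(self):
        # four rows all at distance 1 from the query: D = 1, w = exp(-theta)
        rows = [[1, 0], [-1, 0], [0, 1], [0, -1]]
        lib = _library(rows, [1.0, 2.0, 3.0, 4.0])
        for theta in (0.0, 0.5, 2.0):
            sol = ec.smap_predict(lib, [0.0, 0.0], theta=theta)
            np.testing.assert_allclose(sol.weights, np.exp(-theta))

    def test_theta_zero_gives_unit_weights(self, rng):
        lib = random_library(rng, n_rows=40, E=3)
        sol = ec.smap_predict(lib, rng.normal(size=3), theta=0.0)
        np.testing.assert_allclose(sol.weights, 1.0)

    def test_weights_decrease_with_distance_and_theta(self, rng):
        lib = random_library(rng, n_rows=60, E=2)
        y = rng.normal(size=2)
        d = np.linalg.norm(lib.rows - y, axis=1)
        order = np.argsort(d)
        w1 = ec.smap_predict(lib, y, theta=1.0).weights
        w3 = ec.smap_predict(lib, y, theta=3.0).weights
        assert np.all(np.diff(w1[order]) <= 0)
        assert np.all(w3 < w1)  # fixed distances, larger theta

    def test_rank_deficient_design_returns_minimum_norm(self):
        # second coordinate constant: collinear with the intercept
        rows = np.column_stack([np.linspace(0, 1, 10), np.full(10, 4.0)])
        lib = _library(rows, 2.0 * rows[:, 0] + 1.0)
        sol = ec.smap_predict(lib, [0.5, 4.0], theta=0.0)
        assert sol.prediction == pytest.approx(2.0, abs=1e-8)

    def test_large_theta_interpolates_noiseless_map(self, logistic_table):
        """On a deterministic map, increasingly local weighting drives
        in-sample prediction error toward zero."""
        spec = ec.EmbeddingSpec.univariate("x", E=2, Tp=1)
        lib = ec.embed(logistic_table, spec)
        idx = np.flatnonzero(lib.has_future)[::10]
        errors = []
        for theta in (0.0, 2.0, 5.0, 10.0):
            e = [abs(ec.smap_predict(lib, lib.rows[i], theta).prediction
                     - lib.target_futures[i]) for i in idx]
            errors.append(np.mean(e))
        assert np.all(np.diff(errors) < 0)
        assert errors[-1] < 0.05 * errors[0]


class TestPearsonSkill:
    def test_identity_and_antisymmetry(self, rng):
        x = rng.normal(size=50)
        assert ec.pearson_skill(x, x) == pytest.approx(1.0)
        assert ec.pearson_skill(x, -x) == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        # textbook covariance / sqrt(var*var) on 4 points
        obs, pred = [1, 2, 3, 4], [2, 2.5, 4, 4.5]
        assert ec.pearson_skill(obs, pred) == pytest.approx(
            4.5 / np.sqrt(5.0 * 4.25))

    def test_nan_pairs_dropped(self):
        obs = [1.0, 2.0, np.nan, 4.0, 5.0]
        pred = [1.1, 2.2, 3.0, np.nan, 5.1]
        assert ec.pearson_skill(obs, pred) == pytest.approx(
            ec.pearson_skill([1, 2, 5], [1.1, 2.2, 5.1]))

    def test_degenerate_inputs_give_nan_sentinel(self):
        assert np.isnan(ec.pearson_skill([1, 2], [1, 2]))
        assert np.isnan(ec.pearson_skill([1, 1, 1], [1, 2, 3]))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(scale=st.floats(0.01, 100), shift=st.floats(-50, 50),
           seed=st.integers(0, 1000))
    def test_invariant_under_positive_affine_maps(self, scale, shift, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=20), rng.normal(size=20)
        base = ec.pearson_skill(x, y)
        assert ec.pearson_skill(scale * x + shift, y) == pytest.approx(
            base, abs=1e-9)


class TestEstimatorAPI:
    def test_fit_predict_and_clone(self, rng):
        X = rng.normal(size=(50, 3))
        y = X @ [1.0, -2.0, 0.5] + 0.3
        for est in (ec.SMapRegressor(theta=0.0), ec.SimplexRegressor()):
            fitted = clone(est).fit(X, y)
            pred = fitted.predict(X[:5])
            assert pred.shape == (5,)
        smap = ec.SMapRegressor(theta=0.0).fit(X, y)
        np.testing.assert_allclose(smap.predict(X), y, atol=1e-8)
        assert smap.score(X, y) == pytest.approx(1.0)

    def test_exclusion_radius_blocks_self_matching(self, rng):
        X = rng.normal(size=(30, 2))
        y = rng.normal(size=30)
        times = np.arange(30)
        plain = ec.SimplexRegressor().fit(X, y, times=times)
        excl = ec.SimplexRegressor(exclusion_radius=1).fit(X, y, times=times)
        # with itself available the nearest neighbor is the query row
        assert plain.predict(X[5:6], times=[5])[0] == pytest.approx(y[5])
        assert excl.predict(X[5:6], times=[5])[0] != pytest.approx(y[5])

    def test_solve_exposes_local_jacobian(self, rng):
        X = rng.normal(size=(80, 2))
        y = 3.0 * X[:, 0] - 1.0 * X[:, 1]
        sol = ec.SMapRegressor(theta=0.0).fit(X, y).solve([0.2, 0.4])
        np.testing.assert_allclose(sol.coefficients[1:], [3.0, -1.0],
                                   atol=1e-8)
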