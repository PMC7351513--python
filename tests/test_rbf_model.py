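"""RBF network: normalization, geometry, pseudo-inverse solve, training."""

import numpy as np
import pandas as pd
import pytest
from scipy import linalg

from decostress import (
    RBFNetwork,
    compute_sigma,
    design_matrix,
    euclidean_distance_sq,
    kmeans_within_ss,
    minmax_normalize,
    rmse,
    scan_cluster_counts,
    select_cluster_count,
    solve_weights,
    train_rbf,
)


class TestMinMaxNormalize:
    def test_column_maps_to_unit_interval(self):
        g, scaler = minmax_normalize(np.array([[2.0], [4.0], [6.0]]))
        assert g.ravel().tolist() == [0.0, 0.5, 1.0]

    def test_round_trip_inversion(self):
        rng = np.random.default_rng(0)
        raw = rng.lognormal(0, 0.4, size=(20, 5))
        g, scaler = minmax_normalize(raw)
        assert np.all((g >= 0) & (g <= 1))
        assert np.allclose(scaler.inverse(g), raw, rtol=1e-12, atol=1e-12)

    def test_constant_column_is_named_in_error(self):
        frame = pd.DataFrame({"ok": [1.0, 2.0], "flat": [3.0, 3.0]})
        with pytest.raises(ValueError, match="flat"):
            minmax_normalize(frame)


class TestGeometry:
    def test_distance_of_point_to_itself_is_zero(self):
        x = np.array([0.2, 0.7, 0.1])
        assert euclidean_distance_sq(x, x) == 0.0

    def test_three_four_five_triangle(self):
        assert euclidean_distance_sq(
            np.array([0.0, 0.0]), np.array([0.3, 0.4])
        ) == pytest.approx(0.25)

    def test_distance_matches_loop_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            x, m = rng.uniform(size=(2, 6))
            oracle = sum((a - b) ** 2 for a, b in zip(x, m))
            assert euclidean_distance_sq(x, m) == pytest.approx(oracle, abs=1e-14)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            euclidean_distance_sq(np.zeros(2), np.zeros(3))

    def test_sigma_two_centroids_at_distance_two(self):
        centroids = np.array([[0.0], [2.0]])
        assert compute_sigma(centroids) == pytest.approx(2.0 / np.sqrt(4.0))

    def test_sigma_shrinks_with_sqrt_of_count_at_fixed_dmax(self):
        two = np.array([[0.0], [2.0]])
        four = np.array([[0.0], [2.0], [0.0], [2.0]])
        assert compute_sigma(four) == pytest.approx(compute_sigma(two) / np.sqrt(2))

    def test_identical_centroids_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            compute_sigma(np.ones((3, 2)))


class TestDesignMatrix:
    def test_point_at_centroid_gives_unit_entry(self):
        c = np.array([[0.5, 0.5]])
        theta = design_matrix(c, c, sigma=0.3)
        assert theta[0, 0] == pytest.approx(1.0)
        assert theta[0, -1] == 1.0

    def test_distant_point_decays_to_zero(self):
        theta = design_matrix(
            np.array([[100.0, 100.0]]), np.array([[0.0, 0.0]]), sigma=0.3
        )
        assert theta[0, 0] < 1e-300 or theta[0, 0] == 0.0

    def test_entries_match_elementwise_exponential_oracle(self):
        rng = np.random.default_rng(2)
        pts = rng.uniform(size=(7, 4))
        cents = rng.uniform(size=(3, 4))
        sigma = 0.4
        theta = design_matrix(pts, cents, sigma)
        for k in range(7):
            for j in range(3):
                e = euclidean_distance_sq(pts[k], cents[j])
                assert theta[k, j] == pytest.approx(
                    np.exp(-e / (2 * sigma**2)), abs=1e-14
                )
        assert np.all(theta[:, -1] == 1.0)
        assert np.all((theta[:, :-1] > 0) & (theta[:, :-1] <= 1))


class TestSolveWeights:
    def test_matches_normal_equation_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = int(rng.integers(7, 21))
            s = int(rng.integers(1, 6))
            pts = rng.uniform(size=(n, 3))
            cents = rng.uniform(size=(s, 3))
            theta = design_matrix(pts, cents, sigma=0.5)
            y = rng.normal(size=n)
            a, b = solve_weights(theta, y)
            oracle = linalg.solve(theta.T @ theta, theta.T @ y, assume_a="pos")
            assert np.max(np.abs(np.concatenate([a, [b]]) - oracle)) < 1e-6

    def test_square_nonsingular_design_interpolates(self):
        rng = np.random.default_rng(4)
        pts = rng.uniform(size=(4, 2))
        cents = rng.uniform(size=(3, 2))
        theta = design_matrix(pts, cents, sigma=0.6)
        y = rng.normal(size=4)
        a, b = solve_weights(theta, y)
        assert rmse(theta @ np.concatenate([a, [b]]), y) < 1e-8

    def test_zero_response_gives_zero_weights(self):
        rng = np.random.default_rng(5)
        theta = design_matrix(rng.uniform(size=(10, 2)), rng.uniform(size=(3, 2)), 0.5)
        a, b = solve_weights(theta, np.zeros(10))
        assert np.allclose(a, 0.0, atol=1e-12) and b == pytest.approx(0.0, abs=1e-12)

    def test_solution_is_a_least_squares_optimum(self):
        rng = np.random.default_rng(6)
        theta = design_matrix(rng.uniform(size=(15, 3)), rng.uniform(size=(4, 3)), 0.5)
        y = rng.normal(size=15)
        a, b = solve_weights(theta, y)
        w = np.concatenate([a, [b]])
        base = np.sum((theta @ w - y) ** 2)
        for i in range(w.size):
            for delta in (1e-3, -1e-3):
                w2 = w.copy()
                w2[i] += delta
                assert np.sum((theta @ w2 - y) ** 2) >= base - 1e-12


class TestPredictAndRmse:
    def test_point_at_single_centroid(self):
        model = RBFNetwork(
            centroids=np.array([[0.5, 0.5]]), sigma=0.3,
            weights=np.array([1.0]), bias=0.0,
        )
        assert model.predict_normalized(np.array([[0.5, 0.5]]))[0] == pytest.approx(1.0)

    def test_far_point_approaches_bias(self):
        model = RBFNetwork(
            centroids=np.array([[0.5, 0.5]]), sigma=0.3,
            weights=np.array([2.0]), bias=0.7,
        )
        assert model.predict_normalized(np.array([[50.0, 50.0]]))[0] == pytest.approx(0.7)

    def test_prediction_matches_hand_rolled_oracle(self):
        rng = np.random.default_rng(7)
        model = RBFNetwork(
            centroids=rng.uniform(size=(3, 4)), sigma=0.45,
            weights=rng.normal(size=3), bias=0.2,
        )
        pts = rng.uniform(size=(10, 4))
        preds = model.predict_normalized(pts)
        for k, x in enumerate(pts):
            psi = model.bias
            for j in range(3):
                psi += model.weights[j] * np.exp(
                    -euclidean_distance_sq(x, model.centroids[j]) / (2 * model.sigma**2)
                )
            assert preds[k] == pytest.approx(psi, abs=1e-12)

    def test_prediction_is_bounded_by_weight_mass(self):
        rng = np.random.default_rng(8)
        model = RBFNetwork(
            centroids=rng.uniform(size=(5, 3)), sigma=0.3,
            weights=rng.normal(size=5), bias=-0.4,
        )
        preds = model.predict_normalized(rng.uniform(-2, 3, size=(200, 3)))
        bound = np.sum(np.abs(model.weights)) + abs(model.bias)
        assert np.all(np.abs(preds) <= bound + 1e-12)

    @pytest.mark.parametrize(
        "pred, obs, expected",
        [([1.0, 2.0], [1.0, 2.0], 0.0), ([1.5, 2.5], [1.0, 2.0], 0.5)],
    )
    def test_rmse_trivial_cases(self, pred, obs, expected):
        assert rmse(pred, obs) == pytest.approx(expected)

    def test_rmse_matches_two_line_oracle(self):
        rng = np.random.default_rng(9)
        p, o = rng.normal(size=(2, 40))
        assert rmse(p, o) == pytest.approx(np.sqrt(np.mean((p - o) ** 2)), abs=1e-14)

    def test_rmse_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rmse([1.0], [1.0, 2.0])


class TestClusterSelection:
    def test_each_point_its_own_cluster_gives_zero(self):
        pts = np.arange(6, dtype=float).reshape(-1, 1)
        assert kmeans_within_ss(pts, j=6, seed=0) == pytest.approx(0.0, abs=1e-12)

    def test_single_cluster_equals_total_scatter(self):
        rng = np.random.default_rng(10)
        pts = rng.uniform(size=(20, 3))
        total = float(np.sum((pts - pts.mean(axis=0)) ** 2))
        assert kmeans_within_ss(pts, j=1, seed=0) == pytest.approx(total, rel=1e-9)

    def test_within_ss_non_increasing(self):
        rng = np.random.default_rng(11)
        pts = rng.uniform(size=(30, 2))
        ws = [kmeans_within_ss(pts, j, seed=0) for j in range(1, 9)]
        assert all(ws[i + 1] <= ws[i] + 1e-9 for i in range(len(ws) - 1))

    def test_cluster_count_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            kmeans_within_ss(np.zeros((5, 2)), j=6)

    def test_exact_power_law_recovers_exponent(self):
        ws = [10.0 * j ** (-1.0) for j in range(1, 9)]
        sel = select_cluster_count(ws)
        assert sel.decay_exponent == pytest.approx(1.0, abs=1e-10)

    def test_flat_decay_selects_one(self):
        sel = select_cluster_count([5.0] * 6)
        assert sel.decay_exponent == pytest.approx(0.0, abs=1e-12)
        assert sel.selected == 1

    def test_three_blobs_selected_in_most_seeded_runs(self):
        centers = np.array([[0.1, 0.1], [0.9, 0.1], [0.5, 0.9]])
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            pts = np.vstack([c + rng.normal(0, 0.02, size=(20, 2)) for c in centers])
            if scan_cluster_counts(pts, s_max=8, seed=seed).selected == 3:
                hits += 1
        assert hits >= 18

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            select_cluster_count([1.0, 0.5])


class TestTrainRbf:
    def test_fixed_seed_is_deterministic(self):
        rng = np.random.default_rng(12)
        g = rng.uniform(size=(15, 2))
        y = rng.uniform(size=15)
        r1 = train_rbf(g, y, s=3, trials=1, seed=42)
        r2 = train_rbf(g, y, s=3, trials=1, seed=42)
        assert r1.training_rmse == r2.training_rmse
        assert np.array_equal(r1.model.centroids, r2.model.centroids)

    def test_best_of_trials_is_non_increasing(self):
        rng = np.random.default_rng(13)
        g = rng.uniform(size=(20, 3))
        y = rng.uniform(size=20)
        errors = [
            train_rbf(g, y, s=3, trials=t, seed=5).training_rmse for t in (1, 10, 100)
        ]
        assert errors[0] >= errors[1] >= errors[2]

    def test_smooth_noiseless_target_is_approximated(self):
        rng = np.random.default_rng(14)
        g = rng.uniform(size=(60, 1))
        y = 0.2 + 0.6 * g.ravel()  # noiseless linear target
        result = train_rbf(g, y, s=4, trials=200, seed=3)
        assert result.training_rmse < 0.05

    def test_serialization_round_trip(self, tmp_path):
        rng = np.random.default_rng(15)
        g = rng.uniform(size=(12, 2))
        y = rng.uniform(size=12)
        model = train_rbf(g, y, s=2, trials=5, seed=1).model
        path = tmp_path / "model.json"
        model.to_json(path)
        loaded = RBFNetwork.from_json(path)
        pts = rng.uniform(size=(5, 2))
        assert np.allclose(
            loaded.predict_normalized(pts), model.predict_normalized(pts), atol=1e-12
        )

    @pytest.mark.parametrize("bad", [dict(s=0), dict(trials=0)])
    def test_invalid_arguments_rejected(self, bad):
        g = np.random.default_rng(0).uniform(size=(5, 2))
        with pytest.raises(ValueError):
            train_rbf(g, np.ones(5), **{"s": 2, "trials": 1, **bad})
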