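import numpy as np
import pytest

import kinogen as kg
from kinogen.perturb import (
    PerturbationConfig,
    add_noise,
    fit_clusters,
    perturb_cloud,
    perturb_point,
    sweep_parameters,
)
from kinogen.synthetic_data import BlobSpec, make_latent_blobs


class TestPerturbPoint:
    def test_s_zero_returns_original_encoding(self):
        x, c = np.arange(5.0), np.ones(5)
        np.testing.assert_array_equal(perturb_point(x, c, 0.0), x)

    def test_s_one_returns_centroid(self):
        x, c = np.arange(5.0), np.ones(5)
        np.testing.assert_array_equal(perturb_point(x, c, 1.0), c)

    def test_linear_interpolation_arithmetic(self):
        out = perturb_point(np.zeros(2), np.ones(2), 0.8)
        np.testing.assert_allclose(out, [0.8, 0.8])

    def test_contraction_identity_random_triples(self):
        # ||x* - c|| = (1 - s) ||x - c|| exactly, for random (x, c, s)
        rng = np.random.default_rng(123)
        for _ in range(200):
            d = rng.integers(2, 50)
            x, c = rng.standard_normal(d) * 10, rng.standard_normal(d) * 10
            s = rng.random()
            lhs = np.linalg.norm(perturb_point(x, c, s) - c)
            rhs = (1 - s) * np.linalg.norm(x - c)
            assert abs(lhs - rhs) < 1e-10

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            perturb_point(np.zeros(3), np.zeros(4), 0.5)
        with pytest.raises(ValueError):
            perturb_point(np.zeros(3), np.zeros(3), 1.2)
        with pytest.raises(ValueError):
            PerturbationConfig(s=-0.1)


class TestFitClusters:
    def test_k1_centroid_is_grand_mean(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((40, 6))
        model = fit_clusters(X, k=1, seed=0)
        np.testing.assert_allclose(model.centroids[0], X.mean(axis=0), atol=1e-10)

    def test_identical_points_zero_inertia(self):
        model = fit_clusters(np.ones((10, 4)), k=1, seed=0)
        assert model.inertia == pytest.approx(0.0, abs=1e-12)

    def test_well_separated_blobs_pure_assignment(self):
        X, labels = make_latent_blobs(BlobSpec(k=3, d=30, per_blob_n=40, separation=50, spread=1, seed=2))
        model = fit_clusters(X, k=3, seed=0)
        # purity up to label permutation
        for cl in range(3):
            true = labels[model.assignment == cl]
            assert len(np.unique(true)) == 1

    def test_each_point_assigned_to_nearest_centroid(self):
        X, _ = make_latent_blobs(BlobSpec(k=3, d=10, per_blob_n=30, separation=20, spread=1, seed=4))
        model = fit_clusters(X, k=3, seed=1)
        dists = np.linalg.norm(X[:, None, :] - model.centroids[None], axis=2)
        np.testing.assert_array_equal(model.assignment, dists.argmin(axis=1))

    def test_centroids_are_cluster_means(self):
        X, _ = make_latent_blobs(BlobSpec(k=2, d=8, per_blob_n=25, separation=30, spread=1, seed=5))
        model = fit_clusters(X, k=2, seed=0)
        for cl in range(2):
            np.testing.assert_allclose(
                model.centroids[cl], X[model.assignment == cl].mean(axis=0), atol=1e-8
            )

    def test_row_permutation_same_centroids_up_to_order(self):
        X, _ = make_latent_blobs(BlobSpec(k=3, d=12, per_blob_n=30, separation=40, spread=1, seed=6))
        perm = np.random.default_rng(0).permutation(len(X))
        a = fit_clusters(X, k=3, seed=7)
        b = fit_clusters(X[perm], k=3, seed=7)
        sort = lambda C: C[np.lexsort(C.T)]
        np.testing.assert_allclose(sort(a.centroids), sort(b.centroids), atol=1e-8)

    def test_fewer_points_than_clusters_fatal(self):
        with pytest.raises(ValueError):
            fit_clusters(np.zeros((2, 3)), k=5)


class TestAddNoise:
    def test_zero_level_is_identity(self):
        x = np.arange(6.0)
        rng = np.random.default_rng(0)
        np.testing.assert_array_equal(add_noise(x, 0.0, np.ones(6), rng), x)

    def test_noise_is_zero_mean(self):
        rng = np.random.default_rng(8)
        x = np.array([2.0, -3.0, 0.5])
        per_dim_std = np.array([1.0, 2.0, 0.5])
        samples = np.array([add_noise(x, 10.0, per_dim_std, rng) for _ in range(10_000)])
        se = (10.0 / 100) * per_dim_std / np.sqrt(10_000)
        assert np.all(np.abs(samples.mean(axis=0) - x) < 4 * se)

    def test_noise_std_matches_relative_model(self):
        rng = np.random.default_rng(9)
        x = np.zeros(4)
        per_dim_std = np.array([1.0, 2.0, 4.0, 8.0])
        level = 25.0
        samples = np.array([add_noise(x, level, per_dim_std, rng) for _ in range(10_000)])
        expected = (level / 100) * per_dim_std
        np.testing.assert_allclose(samples.std(axis=0), expected, rtol=0.05)

    def test_absolute_model_isotropic(self):
        rng = np.random.default_rng(10)
        samples = np.array(
            [add_noise(np.zeros(3), 0.5, np.ones(3), rng, model="absolute") for _ in range(5000)]
        )
        np.testing.assert_allclose(samples.std(axis=0), 0.5, rtol=0.07)

    def test_negative_std_rejected(self):
        with pytest.raises(ValueError):
            add_noise(np.zeros(2), 5.0, np.array([-1.0, 1.0]), np.random.default_rng(0))


class TestPerturbCloud:
    def test_contraction_moves_points_toward_centroids(self, surrogate, library_latent):
        cfg = PerturbationConfig(k=3, s=0.8, noise_level=0.0, seed=0)
        perturbed, model = perturb_cloud(library_latent, cfg, np.random.default_rng(0))
        for i in range(len(library_latent)):
            c = model.centroid_of(i)
            assert np.linalg.norm(perturbed[i] - c) <= np.linalg.norm(library_latent[i] - c) + 1e-12


class TestSweep:
    def test_single_configuration_single_row(self, seed_sets, surrogate):
        df = sweep_parameters(
            seed_sets, surrogate, grid=[{"k": 3, "s": 0.8, "noise_level": 5.0}], sweep_seeds=[0]
        )
        assert len(df) == 1
        assert set(df.columns) >= {"k", "s", "noise_level", "valid_yield", "unique_novel"}
        assert 0.0 <= df.valid_yield.iloc[0] <= 1.0

    def test_empty_grid_rejected(self, seed_sets, surrogate):
        with pytest.raises(ValueError):
            sweep_parameters(seed_sets, surrogate, grid=[])

    def test_reproducible_per_seed(self, seed_sets, surrogate):
        grid = [{"k": 3, "s": 0.8, "noise_level": 5.0}]
        a = sweep_parameters(seed_sets, surrogate, grid, sweep_seeds=[3])
        b = sweep_parameters(seed_sets, surrogate, grid, sweep_seeds=[3])
        assert a.equals(b)

    def test_yield_orderings_match_optimal_configuration(self, seed_sets, surrogate):
        """Median valid-molecule yield at the optimal (k=3, s=0.8, noise=5)
        is at least that at low scaling (s=0.2) and at high noise (30)."""
        grid = [
            {"k": 3, "s": 0.8, "noise_level": 5.0},
            {"k": 3, "s": 0.2, "noise_level": 5.0},
            {"k": 3, "s": 0.8, "noise_level": 30.0},
        ]
        df = sweep_parameters(seed_sets, surrogate, grid, sweep_seeds=range(20))
        med = df.groupby(["s", "noise_level"]).valid_yield.median()
        assert med[(0.8, 5.0)] >= med[(0.2, 5.0)]
        assert med[(0.8, 5.0)] >= med[(0.8, 30.0)]
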