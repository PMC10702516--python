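"""The synthetic-city generator: geometry, fields, imagery, SAR process."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist

from greensar.greenspace import compute_gvi, compute_ndvi, extract_ndvi_at_points
from greensar.diagnostics import morans_i
from greensar.synthetic_city import (SyntheticCityConfig, generate_city,
                                     generate_covariates, generate_greenspace_field,
                                     generate_points, render_band_rasters,
                                     render_segmented_images, simulate_pollution,
                                     smooth_field)
from greensar.weights import build_kernel_weights


class TestGeneratePoints:
    def test_count_and_spacing_bound(self):
        cfg = SyntheticCityConfig(n_points=4, extent=(200.0, 200.0), seed=1)
        pts = generate_points(cfg)
        assert pts.n == 4
        assert pdist(pts.coords).min() >= cfg.spacing / 2

    def test_deterministic_given_seed(self):
        cfg = SyntheticCityConfig(n_points=50, extent=(600.0, 600.0), seed=9)
        a, b = generate_points(cfg), generate_points(cfg)
        np.testing.assert_array_equal(a.coords, b.coords)

    def test_nearest_neighbor_distance_realistic(self):
        # brute-force pairwise distances; median NN spacing near the 50 m target
        cfg = SyntheticCityConfig(n_points=400, extent=(1500.0, 1500.0), seed=2)
        pts = generate_points(cfg)
        from scipy.spatial.distance import squareform

        D = squareform(pdist(pts.coords))
        np.fill_diagonal(D, np.inf)
        nn = D.min(axis=1)
        assert nn.min() >= 25.0
        assert 25.0 <= np.median(nn) <= 100.0

    def test_extent_too_small_raises(self):
        with pytest.raises(ValueError, match="cannot place"):
            generate_points(SyntheticCityConfig(n_points=100, extent=(200.0, 200.0)))


class TestGreenspaceField:
    def test_zero_sd_gives_constant_field(self, points200):
        cfg = SyntheticCityConfig(gvi_sd=0.0, gvi_mean=14.0)
        gvi, _ = generate_greenspace_field(points200, cfg)
        np.testing.assert_allclose(gvi, 14.0)

    def test_mean_within_clt_bound(self):
        cfg = SyntheticCityConfig(n_points=900, extent=(2000.0, 2000.0),
                                  gvi_mean=14.0, gvi_sd=10.0, seed=4)
        pts = generate_points(cfg)
        gvi, ndvi = generate_greenspace_field(pts, cfg)
        # spatial correlation inflates the CLT bound; 3 sigma at n=900 plus slack
        assert abs(gvi.mean() - 14.0) < 3 * (10.0 / 30.0) * 3
        assert np.all((gvi >= 0) & (gvi <= 100))
        assert np.all((ndvi >= -1) & (ndvi <= 1))

    def test_spatial_correlation_decays_with_distance(self, points200):
        # empirical variogram oracle: short-range pairs correlate, long-range don't
        cfg = SyntheticCityConfig(field_range=300.0, seed=6)
        gvi, _ = generate_greenspace_field(points200, cfg)
        z = (gvi - gvi.mean()) / gvi.std()
        D = np.linalg.norm(points200.coords[:, None] - points200.coords[None], axis=-1)
        iu = np.triu_indices_from(D, k=1)
        prod = np.outer(z, z)[iu]
        d = D[iu]
        near = prod[d < cfg.field_range / 4].mean()
        far = prod[d > 4 * cfg.field_range].mean()
        assert near > far

    def test_gvi_ndvi_positively_correlated(self, points200):
        cfg = SyntheticCityConfig(seed=7)
        gvi, ndvi = generate_greenspace_field(points200, cfg)
        assert np.corrcoef(gvi, ndvi)[0, 1] > 0.3

    def test_nonpositive_range_raises(self, points200, rng):
        with pytest.raises(ValueError, match="field_range"):
            smooth_field(points200, 0.0, rng)


class TestSegmentedImages:
    def test_extremes(self):
        assert all(m.sum() == 0 for m in render_segmented_images(0.0))
        assert all((m == 1).all() for m in render_segmented_images(100.0))

    def test_round_trip_within_pixel_quantum(self):
        rng = np.random.default_rng(0)
        shape = (40, 40)
        quantum = 100.0 / (6 * shape[0] * shape[1])
        for g in rng.uniform(0, 100, size=1000):
            masks = render_segmented_images(g, image_shape=shape, seed=1)
            assert abs(compute_gvi(masks) - g) <= quantum / 2 + 1e-12

    def test_reference_value_round_trip(self):
        masks = render_segmented_images(14.15, image_shape=(100, 100), seed=2)
        assert abs(compute_gvi(masks) - 14.15) <= 100.0 / 60000

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError, match=r"\[0, 100\]"):
            render_segmented_images(101.0)


class TestBandRasters:
    def test_zero_ndvi_gives_equal_bands(self, points200):
        raster = render_band_rasters(points200, np.zeros(points200.n))
        r, c = raster.transform.rowcol(points200.x, points200.y)
        np.testing.assert_allclose(raster.nir[r, c], 0.5)
        np.testing.assert_allclose(raster.red[r, c], 0.5)

    def test_algebraic_identity(self, points200):
        v = np.full(points200.n, 0.39)
        raster = render_band_rasters(points200, v)
        ndvi = compute_ndvi(raster)
        got = extract_ndvi_at_points(ndvi, raster.transform, points200)
        np.testing.assert_allclose(got, 0.39, atol=1e-15)

    def test_full_round_trip(self, points200, rng):
        v = rng.uniform(-0.5, 0.9, points200.n)
        raster = render_band_rasters(points200, v)
        got = extract_ndvi_at_points(compute_ndvi(raster), raster.transform, points200)
        assert np.max(np.abs(got - v)) < 1e-12

    def test_extreme_values_clipped_with_warning(self, points200):
        v = np.zeros(points200.n)
        v[0] = 1.0
        with pytest.warns(UserWarning, match="clipped"):
            raster = render_band_rasters(points200, v)
        got = extract_ndvi_at_points(compute_ndvi(raster), raster.transform, points200)
        assert abs(got[0] - (1 - 1e-6)) < 1e-9


class TestSimulatePollution:
    def test_reduces_to_xbeta_without_spatial_terms(self, weights200, rng):
        X = np.column_stack([np.ones(200), rng.standard_normal((200, 2))])
        beta = np.array([1.0, 2.0, -1.0])
        y = simulate_pollution(weights200, X, beta, rho=0.0, sigma_eps=0.0)
        np.testing.assert_allclose(y, X @ beta, atol=1e-10)

    def test_sparse_solve_residual(self, weights200, rng):
        import scipy.sparse as sp

        X = np.column_stack([np.ones(200), rng.standard_normal((200, 2))])
        beta = np.array([1.0, 0.5, -0.5])
        rho, seed = 0.7, 3
        y = simulate_pollution(weights200, X, beta, rho=rho, sigma_eps=1.0, seed=seed)
        eps = np.random.default_rng(seed).standard_normal(200) * 1.0
        lhs = (sp.identity(200) - rho * weights200.W) @ y
        assert np.max(np.abs(lhs - (X @ beta + eps))) < 1e-8

    def test_positive_autocorrelation_under_spatial_feedback(self):
        hits = 0
        for s in range(10):
            cfg = SyntheticCityConfig(n_points=300, extent=(1300.0, 1300.0), seed=s)
            pts = generate_points(cfg)
            swm = build_kernel_weights(pts, k=10)
            rng = np.random.default_rng(s)
            X = np.column_stack([np.ones(300), rng.standard_normal(300)])
            y = simulate_pollution(swm, X, [0.0, 1.0], rho=0.7, sigma_eps=1.0, seed=s)
            hits += morans_i(y, swm, n_perm=99, seed=s).p_perm < 0.05
        assert hits >= 9

    def test_contract_errors(self, weights200, points200):
        X = np.column_stack([np.ones(200), np.arange(200.0)])
        with pytest.raises(ValueError, match="stationary"):
            simulate_pollution(weights200, X, [0, 1], rho=1.0, sigma_eps=1.0)
        raw = build_kernel_weights(points200, k=10, standardize=False)
        with pytest.raises(ValueError, match="row-standardized"):
            simulate_pollution(raw, X, [0, 1], rho=0.5, sigma_eps=1.0)
        with pytest.raises(ValueError, match="intercept"):
            simulate_pollution(weights200, X[:, 1:], [1.0], rho=0.5, sigma_eps=1.0)


class TestCovariates:
    def test_strictly_positive_defaults(self, points200):
        cov = generate_covariates(points200, seed=1)
        assert (cov.to_numpy() > 0).all()

    def test_zero_variance_gives_constants(self, points200):
        cov = generate_covariates(points200, seed=1, variances=(0, 0, 0, 0))
        assert (cov.nunique() == 1).all()

    def test_spatial_smoothness(self, points200):
        cov = generate_covariates(points200, seed=8, field_range=300.0)
        z = cov["temperature"].to_numpy()
        z = (z - z.mean()) / z.std()
        D = np.linalg.norm(points200.coords[:, None] - points200.coords[None], axis=-1)
        iu = np.triu_indices_from(D, k=1)
        prod, d = np.outer(z, z)[iu], D[iu]
        assert prod[d < 75].mean() > prod[d > 1200].mean()


class TestGenerateCity:
    def test_bundle_is_bit_reproducible(self):
        cfg = SyntheticCityConfig(n_points=100, extent=(600.0, 600.0), seed=21)
        a, b = generate_city(cfg), generate_city(cfg)
        np.testing.assert_array_equal(a.pollutants.to_numpy(), b.pollutants.to_numpy())
        np.testing.assert_array_equal(a.gvi, b.gvi)

    def test_pollutants_positive_and_complete(self, city400):
        assert (city400.pollutants.to_numpy() > 0).all()
        assert list(city400.pollutants.columns) == ["pm25", "no2", "no", "co", "co2"]

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError, match="rho_true"):
            SyntheticCityConfig(rho_true=1.0)
        with pytest.raises(ValueError, match="sigma_eps"):
            SyntheticCityConfig(sigma_eps=-1.0)
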