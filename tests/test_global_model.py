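"""Tests for the global background-model pipeline stages."""

import math

import numpy as np
import pytest

from icebg.geometry import DetectorGeometry, PolarGrid, pixel_overlap_fractions, radius_map
from icebg.global_model import (
    GlobalBackgroundModel,
    ImageStack,
    PolarImage,
    accumulate_mean,
    build_global_model,
    fill_missing_diffusion,
    inverse_polar_transform,
    median_filter_columns,
    polar_transform,
)


class TestAccumulateMean:
    def test_constant_stack_gives_zero_variance(self):
        img = np.arange(64, dtype=float).reshape(8, 8) + 1
        stack = ImageStack(np.repeat(img[None], 20, axis=0))
        stats, usable = accumulate_mean(stack)
        np.testing.assert_allclose(stats.mean, img)
        np.testing.assert_allclose(stats.variance, 0.0)
        assert usable.all()
        assert (stats.n_contrib == 20).all()

    def test_sparsely_contributing_pixel_is_excluded(self):
        images = np.ones((50, 4, 4))
        masks = np.ones((50, 4, 4), dtype=bool)
        masks[5:, 1, 2] = False  # only 5 of 50 images contribute at (1, 2)
        _, usable = accumulate_mean(ImageStack(images, masks), min_images=10)
        assert not usable[1, 2]
        assert usable.sum() == 15

    def test_short_stack_reduces_required_minimum(self):
        images = np.ones((6, 3, 3))
        masks = np.ones((6, 3, 3), dtype=bool)
        masks[0, 0, 0] = False  # 5 contributions: below the reduced minimum of 5
        _, usable = accumulate_mean(ImageStack(images, masks), min_images=10)
        assert usable[1, 1]  # 6 > 5
        assert not usable[0, 0]  # 5 is not > 5

    def test_all_masked_pixel_has_no_contributions(self):
        images = np.ones((12, 3, 3))
        masks = np.ones((12, 3, 3), dtype=bool)
        masks[:, 2, 2] = False
        stats, usable = accumulate_mean(ImageStack(images, masks))
        assert stats.n_contrib[2, 2] == 0
        assert not usable[2, 2]
        assert np.isnan(stats.mean[2, 2])

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError):
            ImageStack(np.empty((0, 4, 4)))

    def test_poisson_dispersion_centres_on_one(self):
        rng = np.random.default_rng(11)
        images = rng.poisson(10.0, size=(200, 24, 24))
        stats, _ = accumulate_mean(ImageStack(images))
        assert np.median(stats.dispersion) == pytest.approx(1.0, abs=0.05)


class TestPolarTransform:
    def test_all_masked_gives_invalid_empty(self, geom64, overlap64):
        image = np.full(geom64.shape, 7.0)
        p = polar_transform(image, np.zeros(geom64.shape, bool), overlap64)
        assert not p.valid.any()
        assert p.total() == 0.0

    def test_uniform_field_preserved(self, geom64, overlap64):
        p = polar_transform(np.full(geom64.shape, 3.25), None, overlap64)
        np.testing.assert_allclose(p.ratio[p.valid], 3.25, rtol=1e-6)

    def test_count_conservation_random_masked_images(self, geom64, overlap64):
        rng = np.random.default_rng(2)
        for _ in range(5):
            image = rng.poisson(25.0, size=geom64.shape).astype(float)
            mask = rng.random(geom64.shape) > 0.3
            p = polar_transform(image, mask, overlap64)
            expected = image[mask & overlap64.on_grid].sum()
            assert p.total() == pytest.approx(expected, rel=1e-9)

    def test_shape_mismatch_rejected(self, overlap64):
        with pytest.raises(ValueError):
            polar_transform(np.zeros((8, 8)), None, overlap64)


def _manual_polar(n_res=6, n_az=24, fill=10.0):
    grid = PolarGrid(
        res_edges=np.arange(n_res + 1, dtype=float),
        az_edges=np.linspace(-math.pi, math.pi, n_az + 1),
    )
    values = np.full(grid.shape, fill)
    weight = np.ones(grid.shape)
    valid = np.ones(grid.shape, bool)
    return PolarImage(values=values, weight=weight, valid=valid, grid=grid)


class TestMedianFilter:
    def test_constant_column_unchanged(self):
        p = _manual_polar()
        out = median_filter_columns(p, window=10)
        np.testing.assert_allclose(out.values, p.values)

    def test_single_spike_removed(self):
        p = _manual_polar(fill=10.0)
        p.values[3, 7] = 1000.0
        out = median_filter_columns(p, window=10)
        assert out.values[3, 7] == pytest.approx(10.0)

    def test_window_larger_than_valid_count_leaves_column_unchanged(self):
        p = _manual_polar(n_az=8)
        p.values[2] = np.arange(8.0)
        out = median_filter_columns(p, window=10)
        np.testing.assert_allclose(out.values[2], p.values[2])

    def test_matches_brute_force_circular_median_oracle(self):
        rng = np.random.default_rng(3)
        p = _manual_polar(n_res=5, n_az=40)
        p.values[:] = rng.poisson(20.0, size=p.values.shape).astype(float)
        p.valid[:] = rng.random(p.values.shape) > 0.25
        window = 6
        out = median_filter_columns(p, window=window)
        ratio = p.values / p.weight
        for i in range(p.grid.n_res):
            cols = np.nonzero(p.valid[i])[0]
            if cols.size <= window:
                continue
            for pos, c in enumerate(cols):
                # gather the window//2 nearest valid neighbours on each side
                neigh = [
                    ratio[i, cols[(pos + off) % cols.size]]
                    for off in range(-(window // 2), window - window // 2 + 1)
                ]
                assert out.values[i, c] == pytest.approx(np.median(neigh))

    def test_invalid_cells_left_invalid_and_untouched(self):
        p = _manual_polar()
        p.valid[2, 5] = False
        p.values[2, 5] = -99.0  # sentinel
        out = median_filter_columns(p, window=4)
        assert not out.valid[2, 5]
        assert out.values[2, 5] == -99.0


class TestDiffusionFill:
    def test_single_missing_cell_takes_neighbour_value(self):
        p = _manual_polar(fill=5.0)
        p.valid[3, 10] = False
        out = fill_missing_diffusion(p)
        assert out.valid.all()
        assert out.ratio[3, 10] == pytest.approx(5.0, abs=1e-9)

    def test_missing_band_fills_linearly(self):
        # 1-D Laplace between Dirichlet values is a straight line; make the
        # field azimuth-independent so the problem is effectively 1-D in radius
        p = _manual_polar(n_res=12, n_az=16)
        p.values[:4] = 2.0
        p.values[8:] = 10.0
        p.valid[4:8] = False
        out = fill_missing_diffusion(p, method="jacobi", tol=1e-9)
        expected = 2.0 + (10.0 - 2.0) * np.arange(1, 5) / 5.0
        np.testing.assert_allclose(out.ratio[4:8, 0], expected, atol=1e-5)

    def test_maximum_principle_and_method_agreement(self):
        rng = np.random.default_rng(4)
        p = _manual_polar(n_res=10, n_az=30)
        p.values[:] = rng.uniform(5.0, 50.0, size=p.values.shape)
        p.valid[:] = rng.random(p.values.shape) > 0.4
        lo, hi = p.values[p.valid].min(), p.values[p.valid].max()
        direct = fill_missing_diffusion(p, method="direct")
        jacobi = fill_missing_diffusion(p, method="jacobi", tol=1e-10, max_iter=50000)
        for out in (direct, jacobi):
            assert out.valid.all()
            assert out.ratio.min() >= lo - 1e-6
            assert out.ratio.max() <= hi + 1e-6
        np.testing.assert_allclose(direct.ratio, jacobi.ratio, atol=1e-5)

    def test_valid_cells_are_dirichlet_data(self):
        rng = np.random.default_rng(5)
        p = _manual_polar()
        p.values[:] = rng.uniform(1, 9, p.values.shape)
        p.valid[1, 3] = False
        out = fill_missing_diffusion(p)
        np.testing.assert_array_equal(out.values[p.valid], p.values[p.valid])

    def test_no_valid_cells_is_an_error(self):
        p = _manual_polar()
        p.valid[:] = False
        with pytest.raises(ValueError):
            fill_missing_diffusion(p)

    def test_non_convergence_warns_and_flags(self):
        p = _manual_polar(n_res=20, n_az=30)
        p.values[:1] = 0.0
        p.values[19:] = 100.0
        p.valid[1:19] = False
        with pytest.warns(RuntimeWarning):
            out = fill_missing_diffusion(p, method="jacobi", tol=1e-12, max_iter=3)
        assert out.meta["fill_converged"] is False


class TestInversePolarTransform:
    def test_round_trip_of_constant_is_identity(self, geom64, overlap64):
        image = np.full(geom64.shape, 6.5)
        p = polar_transform(image, None, overlap64)
        filled = fill_missing_diffusion(p)
        model = inverse_polar_transform(filled, overlap64)
        on = overlap64.on_grid
        np.testing.assert_allclose(model.b[on], 6.5, rtol=1e-6)
        assert model.off_grid[~on].all()
        assert np.all(model.b[~on] == 0.0)

    def test_round_trip_conserves_total_counts(self, geom64, overlap64):
        # with every covered cell kept (threshold 0) the round trip is an
        # exact redistribution identity: sum(b) = sum(ratio * weight) = sum(image)
        rng = np.random.default_rng(6)
        image = rng.poisson(40.0, size=geom64.shape).astype(float)
        p = polar_transform(image, None, overlap64, weight_threshold=0.0)
        model = inverse_polar_transform(p, overlap64)
        on = overlap64.on_grid
        assert model.b[on].sum() == pytest.approx(image[on].sum(), rel=1e-9)

    def test_requires_fully_valid_input(self, geom64, overlap64):
        p = polar_transform(np.ones(geom64.shape), None, overlap64)
        with pytest.raises(ValueError):
            inverse_polar_transform(p, overlap64)

    def test_sharp_ring_survives_round_trip(self, diffuse_small):
        """Ring peak position is preserved (±1 px) through the regridding."""
        cfg, data = diffuse_small
        geom = cfg.geometry
        truth = data.truth.mean_map
        ov = pixel_overlap_fractions(geom)
        p = polar_transform(truth, None, ov)
        filled = fill_missing_diffusion(p)
        model = inverse_polar_transform(filled, ov)
        r = radius_map(geom)
        r_bins = np.arange(10, int(r.max()) - 8)
        def radial_profile(img):
            idx = np.clip(np.digitize(r.ravel(), r_bins) - 1, 0, len(r_bins) - 2)
            prof = np.bincount(idx, weights=img.ravel(), minlength=len(r_bins) - 1)
            n = np.bincount(idx, minlength=len(r_bins) - 1)
            return prof / np.maximum(n, 1)
        true_prof = radial_profile(truth)
        model_prof = radial_profile(model.b)
        assert abs(int(np.argmax(true_prof)) - int(np.argmax(model_prof))) <= 1


class TestBuildGlobalModel:
    def test_flat_poisson_stack_recovers_constant(self, geom64):
        rng = np.random.default_rng(8)
        lam, n_images = 20.0, 50
        stack = ImageStack(rng.poisson(lam, size=(n_images, *geom64.shape)))
        est = GlobalBackgroundModel(geometry=geom64).fit(stack)
        on = ~est.model_.off_grid
        rms = np.sqrt(np.mean((est.background_[on] - lam) ** 2))
        assert rms < 3.0 * math.sqrt(lam) / math.sqrt(n_images)

    def test_ring_peaks_at_simulated_d_spacings(self, diffuse_small):
        cfg, data = diffuse_small
        est = GlobalBackgroundModel(geometry=cfg.geometry).fit(data.stack)
        r = radius_map(cfg.geometry)
        ring_r = cfg.geometry.radius_at_resolution(cfg.rings[0].d)
        on_ring = np.abs(r - ring_r) < 1.5
        off_ring = (np.abs(r - ring_r) > 6) & (np.abs(r - ring_r) < 12)
        assert est.background_[on_ring].mean() > 1.5 * est.background_[off_ring].mean()

    def test_image_order_is_irrelevant(self, geom64):
        rng = np.random.default_rng(9)
        images = rng.poisson(15.0, size=(12, *geom64.shape))
        ov = pixel_overlap_fractions(geom64)
        m1 = build_global_model(ImageStack(images), geom64, overlap=ov)
        m2 = build_global_model(ImageStack(images[::-1].copy()), geom64, overlap=ov)
        np.testing.assert_array_equal(m1.b, m2.b)

    def test_noiseless_radial_background_recovered_within_5_percent(self):
        geom = DetectorGeometry(96, 96, 0.2, 25.0, (48.0, 48.0), 1.0)
        u = radius_map(geom) / geom.max_corner_radius()
        lam = 30.0 - 10.0 * u + 5.0 * u**2
        stack = ImageStack(np.repeat(lam[None], 12, axis=0))
        est = GlobalBackgroundModel(geometry=geom).fit(stack)
        on = ~est.model_.off_grid
        rel = np.abs(est.background_ - lam) / lam
        assert rel[on].max() < 0.05

    def test_conservation_recorded_through_pipeline(self, geom64):
        rng = np.random.default_rng(10)
        stack = ImageStack(rng.poisson(30.0, size=(15, *geom64.shape)))
        est = GlobalBackgroundModel(geometry=geom64).fit(stack)
        cons = est.conservation_
        assert cons["polar_total"] == pytest.approx(cons["input_total"], rel=1e-9)
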