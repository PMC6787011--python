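"""Raster engine: aggregation, resampling, slope, distance, presence, PCA, I/O."""

import numpy as np
import pytest

from scalesdm.raster import (
    PredictorStack,
    Raster,
    aggregate,
    bilinear_resample,
    distance_raster,
    pca_reduce,
    rasterize_presence,
    read_ascii_grid,
    slope_from_dem,
    write_ascii_grid,
)


def _raster(values, cell=30.0, nodata=None):
    values = np.asarray(values, float)
    return Raster(values, x0=0.0, y0=values.shape[0] * cell, cell=cell, nodata=nodata)


class TestAggregate:
    def test_blockwise_mean_matches_hand_computation(self):
        r = _raster(np.arange(1, 17).reshape(4, 4))
        out = aggregate(r, 2, "mean")
        assert out.cell == 60.0
        np.testing.assert_allclose(out.values, [[3.5, 5.5], [11.5, 13.5]])

    def test_factor_one_is_identity(self):
        r = _raster(np.random.default_rng(0).random((5, 7)))
        out = aggregate(r, 1)
        np.testing.assert_array_equal(out.values, r.values)

    def test_grain_ladder_from_successive_doubling(self):
        r = _raster(np.zeros((128, 128)), cell=30.0)
        cells = []
        for _ in range(6):
            r = aggregate(r, 2)
            cells.append(r.cell)
        assert cells == [60, 120, 240, 480, 960, 1920]

    def test_median_variant_and_nodata_blocks(self):
        vals = np.array([[1.0, 2.0, -9, -9], [3.0, 100.0, -9, -9]])
        r = _raster(vals, nodata=-9)
        out = aggregate(r, 2, "median")
        assert out.values[0, 0] == 2.5  # median of 1,2,3,100
        assert out.values[0, 1] == -9  # all-nodata block stays nodata

    def test_mixed_nodata_block_uses_valid_cells_only(self):
        vals = np.array([[2.0, -9], [4.0, 6.0]])
        out = aggregate(_raster(vals, nodata=-9), 2, "mean")
        assert out.values[0, 0] == 4.0

    def test_partial_trailing_blocks_dropped(self):
        r = _raster(np.arange(25.0).reshape(5, 5))
        out = aggregate(r, 2)
        assert out.shape == (2, 2)

    def test_global_mean_preserved_on_full_blocks(self):
        rng = np.random.default_rng(1)
        r = _raster(rng.random((8, 12)))
        out = aggregate(r, 4)
        assert out.values.mean() == pytest.approx(r.values.mean(), abs=1e-12)

    def test_aggregation_composes_for_mean(self):
        rng = np.random.default_rng(2)
        r = _raster(rng.random((8, 8)))
        twice = aggregate(aggregate(r, 2), 2)
        once = aggregate(r, 4)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-12)
        assert twice.cell == once.cell

    def test_invalid_factor_or_size_raises(self):
        r = _raster(np.ones((3, 3)))
        with pytest.raises(ValueError):
            aggregate(r, 0)
        with pytest.raises(ValueError):
            aggregate(r, 4)


class TestBilinearResample:
    def test_constant_raster_stays_constant(self):
        r = _raster(np.full((6, 6), 3.25), cell=250.0)
        out = bilinear_resample(r, 90.0)
        np.testing.assert_allclose(out.values, 3.25)

    def test_exact_on_affine_surfaces(self):
        cell = 100.0
        nr, nc = 10, 12
        a, b, c = 0.3, -0.2, 5.0
        xs = (np.arange(nc) + 0.5) * cell
        ys = nr * cell - (np.arange(nr) + 0.5) * cell
        X, Y = np.meshgrid(xs, ys)
        r = Raster(a * X + b * Y + c, x0=0, y0=nr * cell, cell=cell)
        out = bilinear_resample(r, 40.0)
        Xo, Yo = out.cell_centers()
        interior = (
            (Xo > xs[0]) & (Xo < xs[-1]) & (Yo < ys[0]) & (Yo > ys[-1])
        )
        np.testing.assert_allclose(
            out.values[interior], (a * Xo + b * Yo + c)[interior], atol=1e-9
        )

    def test_250m_to_240m_preserves_footprint(self):
        r = _raster(np.random.default_rng(3).random((10, 10)), cell=250.0)
        out = bilinear_resample(r, 240.0)
        assert out.cell == 240.0
        xmin, ymin, xmax, ymax = out.bounds
        rxmin, rymin, rxmax, rymax = r.bounds
        assert abs(xmax - rxmax) < 250.0 and abs(ymin - rymin) < 250.0

    def test_all_nodata_raises(self):
        r = _raster(np.full((4, 4), -9.0), nodata=-9)
        with pytest.raises(ValueError):
            bilinear_resample(r, 15.0)


class TestSlope:
    def test_flat_dem_gives_zero(self):
        out = slope_from_dem(_raster(np.full((5, 5), 1000.0)))
        np.testing.assert_allclose(out.values, 0.0)

    def test_unit_gradient_plane_is_45_degrees(self):
        cell = 30.0
        vals = np.tile(np.arange(6) * cell, (6, 1))  # dz/dx = 1
        out = slope_from_dem(_raster(vals, cell=cell))
        np.testing.assert_allclose(out.values[1:-1, 1:-1], 45.0, atol=1e-9)

    def test_matches_horn_stencil_on_random_patch(self):
        rng = np.random.default_rng(7)
        cell = 30.0
        z = rng.random((3, 3)) * 100
        out = slope_from_dem(_raster(z, cell=cell))
        a, b, c, d, _, f, g, h, i = z.ravel()
        dzdx = ((c + 2 * f + i) - (a + 2 * d + g)) / (8 * cell)
        dzdy = ((g + 2 * h + i) - (a + 2 * b + c)) / (8 * cell)
        expected = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
        assert out.values[1, 1] == pytest.approx(expected, abs=1e-12)

    def test_too_small_dem_raises(self):
        with pytest.raises(ValueError):
            slope_from_dem(_raster(np.ones((2, 5))))


def _brute_force_distance(px, py, features):
    """Independent point-to-segment oracle."""
    best = np.inf
    for feat in features:
        arr = np.atleast_2d(np.asarray(feat, float))
        for v in arr:
            best = min(best, np.hypot(px - v[0], py - v[1]))
        for s, e in zip(arr[:-1], arr[1:]):
            d = e - s
            t = np.clip(np.dot([px - s[0], py - s[1]], d) / (d @ d), 0, 1)
            proj = s + t * d
            best = min(best, np.hypot(px - proj[0], py - proj[1]))
    return best


class TestDistance:
    def test_center_on_feature_is_zero(self):
        grid = _raster(np.zeros((3, 3)), cell=30.0)
        out = distance_raster([(45.0, 45.0)], grid)  # center of middle cell
        assert out.values[1, 1] == 0.0

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        grid = _raster(np.zeros((8, 8)), cell=30.0)
        features = [rng.random((4, 2)) * 240, rng.random(2) * 240]
        out = distance_raster(features, grid)
        X, Y = grid.cell_centers()
        for i in range(8):
            for j in range(8):
                assert out.values[i, j] == pytest.approx(
                    _brute_force_distance(X[i, j], Y[i, j], features), abs=1e-9
                )

    def test_monotone_along_ray_from_point(self):
        grid = _raster(np.zeros((1, 20)), cell=30.0)
        out = distance_raster([(15.0, 15.0)], grid)
        assert np.all(np.diff(out.values[0]) >= 0)

    def test_empty_feature_set_raises(self):
        with pytest.raises(ValueError):
            distance_raster([], _raster(np.zeros((2, 2))))


class TestRasterizePresence:
    def test_two_points_in_one_cell(self):
        grid = _raster(np.zeros((4, 4)), cell=30.0)
        pg = rasterize_presence([(10.0, 10.0), (20.0, 10.0)], grid)
        assert pg.n_cells == 1 and pg.n_points == 2
        assert pg.counts.values.max() == 2

    def test_straddling_points_merge_after_aggregation(self):
        # 40 m apart across a 30 m cell edge: 2 cells at 30 m, 1 at 60 m
        grid30 = _raster(np.zeros((4, 4)), cell=30.0)
        pts = [(10.0, 45.0), (50.0, 45.0)]
        pg30 = rasterize_presence(pts, grid30)
        assert pg30.n_cells == 2
        grid60 = aggregate(grid30, 2)
        pg60 = rasterize_presence(pts, grid60)
        assert pg60.n_cells == 1

    def test_prevalence_is_cells_over_valid_total(self):
        grid = _raster(np.zeros((10, 10)), cell=30.0)
        pts = [(15.0, 15.0), (75.0, 75.0), (135.0, 135.0)]
        pg = rasterize_presence(pts, grid)
        assert pg.prevalence == pytest.approx(0.03)

    def test_outside_points_dropped_and_empty_ok(self):
        grid = _raster(np.zeros((3, 3)), cell=30.0)
        pg = rasterize_presence([(-5.0, 10.0), (10.0, 10.0)], grid)
        assert pg.n_points == 1
        empty = rasterize_presence([], grid)
        assert empty.n_cells == 0 and empty.prevalence == 0.0

    def test_cells_monotone_under_coarsening(self):
        rng = np.random.default_rng(5)
        grid = _raster(np.zeros((64, 64)), cell=30.0)
        pts = rng.random((200, 2)) * 64 * 30
        prev, g = None, grid
        for _ in range(5):
            n = rasterize_presence(pts, g).n_cells
            if prev is not None:
                assert n <= prev
            prev = n
            g = aggregate(g, 2)


class TestPCA:
    def _stack(self, bands, cell=30.0):
        layers = {
            f"b{i}": _raster(b, cell=cell) for i, b in enumerate(bands)
        }
        return PredictorStack(name="pheno", layers=layers, grain=cell)

    def test_two_latent_fields_need_few_components(self):
        rng = np.random.default_rng(13)
        l1, l2 = rng.random((30, 30)), rng.random((30, 30))
        bands = [
            l1 * w + l2 * (1 - w) + 0.001 * rng.random((30, 30))
            for w in np.linspace(0, 1, 11)
        ]
        out = pca_reduce(self._stack(bands), 0.99)
        assert len(out.layers) <= 3

    def test_identical_bands_give_single_component(self):
        b = np.random.default_rng(17).random((10, 10))
        out = pca_reduce(self._stack([b, b.copy()]), 0.99)
        assert len(out.layers) == 1

    def test_eleven_weak_bands_hit_component_cap(self):
        rng = np.random.default_rng(19)
        bands = [rng.random((40, 40)) for _ in range(11)]
        out = pca_reduce(self._stack(bands), 0.99, max_components=5)
        assert len(out.layers) == 5

    def test_components_orthogonal(self):
        rng = np.random.default_rng(23)
        l1, l2, l3 = (rng.random((25, 25)) for _ in range(3))
        bands = [
            a * l1 + b * l2 + c * l3 + 0.05 * rng.random((25, 25))
            for a, b, c in rng.random((8, 3))
        ]
        out = pca_reduce(self._stack(bands), 1.0, max_components=8)
        X, _ = out.table()
        X = X - X.mean(axis=0)
        cov = X.T @ X / (len(X) - 1)
        off = cov - np.diag(np.diag(cov))
        assert np.abs(off).max() < 1e-8

    def test_constant_band_dropped_all_constant_raises(self):
        rng = np.random.default_rng(29)
        varying = rng.random((6, 6))
        out = pca_reduce(self._stack([varying, varying * 2, np.ones((6, 6))]), 0.99)
        assert len(out.layers) >= 1
        with pytest.raises(ValueError):
            pca_reduce(self._stack([np.ones((6, 6)), np.zeros((6, 6))]), 0.99)


class TestAsciiGridIO:
    def test_roundtrip_preserves_grid(self, tmp_path):
        rng = np.random.default_rng(31)
        r = Raster(rng.random((7, 5)), x0=1200.0, y0=9000.0, cell=60.0, nodata=-9999.0)
        vals = r.values.copy()
        vals[2, 3] = -9999.0
        r = r.with_values(vals)
        path = tmp_path / "grid.asc"
        write_ascii_grid(r, path)
        back = read_ascii_grid(path)
        np.testing.assert_array_equal(back.values, r.values)
        assert (back.x0, back.y0, back.cell, back.nodata) == (1200.0, 9000.0, 60.0, -9999.0)

    def test_header_is_bit_exact(self, tmp_path):
        r = Raster(np.zeros((2, 3)), x0=0.0, y0=60.0, cell=30.0, nodata=-9999.0)
        path = tmp_path / "g.asc"
        write_ascii_grid(r, path)
        head = path.read_text().splitlines()[:6]
        assert head == [
            "ncols 3", "nrows 2", "xllcorner 0", "yllcorner 0",
            "cellsize 30", "NODATA_value -9999",
        ]


class TestCoordinateConvention:
    def test_point_to_cell_half_open(self):
        r = _raster(np.zeros((4, 4)), cell=30.0)
        row, col = r.index_of(30.0, 120.0)  # on edges: belongs to cell (0, 1)
        assert (row, col) == (0, 1)
        row, col = r.index_of(29.999, 119.999)
        assert (row, col) == (0, 0)

    def test_crop_alignment(self):
        r = _raster(np.arange(64.0).reshape(8, 8), cell=30.0)
        sub = r.crop((60.0, 60.0, 180.0, 180.0))
        assert sub.x0 == 60.0 and sub.cell == 30.0
        assert sub.shape == (4, 4)
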