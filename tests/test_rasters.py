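"""Gridding operations against independent brute-force oracles."""

import numpy as np
import pytest
import shapely
from shapely.geometry import LineString, Point

from middensdm.cloud import (GROUND, UNCLASSIFIED, VEGETATION, PointCloud,
                             merge_vegetation)
from middensdm.features import FeatureSet
from middensdm.grids import GridAlignmentError, GridSpec, RasterGrid
from middensdm.rasters import (build_dem, canopy_density, canopy_height,
                               euclidean_distance, idw_fill,
                               rasterize_features, slope_aspect,
                               stack_predictors)


def _cloud(xyzk):
    arr = np.asarray(xyzk, dtype=float)
    return PointCloud(arr[:, 0], arr[:, 1], arr[:, 2],
                      arr[:, 3].astype(np.int8))


class TestMergeVegetation:
    def test_relabels_unclassified_only(self):
        cloud = _cloud([(0, 1, 5, GROUND)] * 3 + [(1, 1, 9, VEGETATION)] * 2
                       + [(2, 1, 7, UNCLASSIFIED)] * 5)
        merged = merge_vegetation(cloud)
        assert merged.class_counts() == {"ground": 3, "vegetation": 7,
                                         "unclassified": 0}
        assert len(merged) == len(cloud)

    def test_all_ground_unchanged_and_idempotent(self):
        cloud = _cloud([(0, 1, 5, GROUND), (1, 2, 6, GROUND)])
        once = merge_vegetation(cloud)
        twice = merge_vegetation(once)
        np.testing.assert_array_equal(once.klass, cloud.klass)
        np.testing.assert_array_equal(twice.klass, once.klass)


class TestBuildDem:
    def test_cell_mean(self, tiny_spec):
        cloud = _cloud([(1.0, 29.0, 149.0, GROUND), (2.0, 28.5, 151.0, GROUND)])
        dem = build_dem(cloud, tiny_spec)
        assert dem.values[0, 0] == 150.0

    def test_flat_terrain_exact(self, tiny_spec):
        rng = np.random.default_rng(0)
        n = 500
        cloud = PointCloud(rng.uniform(0, 30, n), rng.uniform(0, 30, n),
                           np.full(n, 160.0), np.zeros(n, dtype=np.int8))
        dem = build_dem(cloud, tiny_spec)
        np.testing.assert_allclose(dem.values, 160.0)

    def test_gap_fill_within_donor_range(self, tiny_spec):
        # ground returns only in two corners with distinct elevations
        cloud = _cloud([(1.0, 29.0, 150.0, GROUND), (28.0, 1.0, 170.0, GROUND)])
        dem = build_dem(cloud, tiny_spec)
        assert dem.n_nodata == 0
        assert np.all(dem.values >= 150.0) and np.all(dem.values <= 170.0)

    def test_no_ground_returns_errors(self, tiny_spec):
        cloud = _cloud([(1.0, 1.0, 150.0, VEGETATION)])
        with pytest.raises(ValueError, match="ground"):
            build_dem(cloud, tiny_spec)

    def test_unmerged_cloud_rejected(self, tiny_spec):
        cloud = _cloud([(1.0, 1.0, 150.0, UNCLASSIFIED)])
        with pytest.raises(ValueError, match="merge"):
            build_dem(cloud, tiny_spec)


class TestCanopyDensity:
    def test_simple_ratio(self, tiny_spec):
        rows = [(1.0, 29.0, 150.0, GROUND)] * 4 + [(1.5, 28.0, 155.0, VEGETATION)] * 6
        dens = canopy_density(_cloud(rows), tiny_spec)
        assert dens.values[0, 0] == 0.6

    def test_all_ground_cell_is_zero(self, tiny_spec):
        dens = canopy_density(_cloud([(4.0, 29.0, 150.0, GROUND)]), tiny_spec)
        assert dens.values[0, 1] == 0.0

    def test_matches_bruteforce_counting(self):
        """Per-cell counting oracle on a random 10^4-return cloud."""
        spec = GridSpec(0.0, 30.0, 3.0, 10, 10)
        rng = np.random.default_rng(5)
        n = 10_000
        cloud = PointCloud(rng.uniform(0, 30, n), rng.uniform(0, 30, n),
                           rng.uniform(150, 170, n),
                           rng.choice([GROUND, VEGETATION], n).astype(np.int8))
        dens = canopy_density(cloud, spec)
        expected = np.zeros((10, 10))
        for r in range(10):
            for c in range(10):
                x0, x1 = c * 3.0, (c + 1) * 3.0
                y1, y0 = 30.0 - r * 3.0, 30.0 - (r + 1) * 3.0
                sel = ((cloud.x >= x0) & (cloud.x < x1)
                       & (cloud.y > y0) & (cloud.y <= y1))
                total = sel.sum()
                veg = (sel & (cloud.klass == VEGETATION)).sum()
                expected[r, c] = veg / total
        np.testing.assert_allclose(dens.values, expected)

    def test_in_unit_interval_after_gapfill(self, small_stack):
        vals = small_stack["canopy_density"].values
        assert np.nanmin(vals) >= 0.0 and np.nanmax(vals) <= 1.0


class TestCanopyHeight:
    def test_max_minus_ground(self, tiny_spec):
        cloud = _cloud([(1.0, 29.0, 150.0, GROUND),
                        (1.2, 28.6, 152.0, VEGETATION),
                        (1.4, 28.2, 158.0, VEGETATION)])
        dem = build_dem(cloud, tiny_spec)
        chm = canopy_height(cloud, dem)
        assert chm.values[0, 0] == 8.0

    def test_no_vegetation_gives_zero(self, tiny_spec):
        cloud = _cloud([(1.0, 29.0, 150.0, GROUND)])
        chm = canopy_height(cloud, build_dem(cloud, tiny_spec))
        assert np.all(chm.values == 0.0)

    def test_never_negative_on_synthetic_cloud(self, small_stack):
        assert np.all(small_stack["canopy_height"].values >= 0.0)

    def test_misaligned_dem_rejected(self, tiny_spec):
        cloud = _cloud([(1.0, 29.0, 150.0, GROUND)])
        other = GridSpec(0.0, 30.0, 5.0, 6, 6)
        dem = RasterGrid(other, np.zeros((6, 6)), name="elevation")
        with pytest.raises(GridAlignmentError):
            canopy_height(cloud, dem, tiny_spec)


class TestSlopeAspect:
    def test_constant_dem_flat(self, tiny_spec):
        dem = RasterGrid(tiny_spec, np.full((10, 10), 160.0), name="elevation")
        slope, aspect = slope_aspect(dem)
        assert np.all(slope.values == 0.0)
        assert np.all(aspect.values == -1.0)

    def test_plane_rising_east(self, tiny_spec):
        """dz/dx = 1 plane: slope 45 deg, steepest descent due west (270)."""
        xm, _ = tiny_spec.center_mesh()
        dem = RasterGrid(tiny_spec, xm.copy(), name="elevation")
        slope, aspect = slope_aspect(dem)
        interior = (slice(1, -1), slice(1, -1))
        np.testing.assert_allclose(slope.values[interior], 45.0, atol=1e-9)
        np.testing.assert_allclose(aspect.values[interior], 270.0, atol=1e-9)

    def test_plane_rising_north(self, tiny_spec):
        """dz/dy = 1 (north positive): descent due south (180)."""
        _, ym = tiny_spec.center_mesh()
        dem = RasterGrid(tiny_spec, ym.copy(), name="elevation")
        slope, aspect = slope_aspect(dem)
        interior = (slice(1, -1), slice(1, -1))
        np.testing.assert_allclose(slope.values[interior], 45.0, atol=1e-9)
        np.testing.assert_allclose(aspect.values[interior], 180.0, atol=1e-9)

    @pytest.mark.parametrize("gx,gy", [(0.5, 0.0), (0.2, -0.7), (-1.0, 1.0)])
    def test_plane_slope_matches_analytic_gradient(self, tiny_spec, gx, gy):
        xm, ym = tiny_spec.center_mesh()
        dem = RasterGrid(tiny_spec, gx * xm + gy * ym, name="elevation")
        slope, _ = slope_aspect(dem)
        expected = np.degrees(np.arctan(np.hypot(gx, gy)))
        interior = (slice(1, -1), slice(1, -1))
        np.testing.assert_allclose(slope.values[interior], expected, atol=1e-9)

    def test_too_small_dem_rejected(self):
        spec = GridSpec(0.0, 6.0, 3.0, 2, 2)
        dem = RasterGrid(spec, np.zeros((2, 2)), name="elevation")
        with pytest.raises(ValueError):
            slope_aspect(dem)


class TestEuclideanDistance:
    def _features(self, geom):
        return FeatureSet({"lake": [geom]})

    def test_source_cell_is_zero(self, tiny_spec):
        fs = self._features(Point(1.5, 28.5).buffer(0.5))
        dist = euclidean_distance(fs, "lake", tiny_spec)
        assert dist.values[0, 0] == 0.0

    def test_four_cells_due_east(self, tiny_spec):
        fs = self._features(shapely.box(0.1, 27.1, 2.9, 29.9))  # cell (0,0) only
        dist = euclidean_distance(fs, "lake", tiny_spec)
        assert dist.values[0, 4] == pytest.approx(12.0)

    def test_empty_class_error_names_it(self, tiny_spec):
        fs = FeatureSet({"lake": []})
        with pytest.raises(ValueError, match="lake"):
            euclidean_distance(fs, "lake", tiny_spec)

    def test_matches_bruteforce_min_distance(self):
        """O(cells^2) oracle on random 30 x 30 grids."""
        for seed in (0, 1, 2):
            spec = GridSpec(0.0, 90.0, 3.0, 30, 30)
            rng = np.random.default_rng(seed)
            pts = [Point(rng.uniform(0, 90), rng.uniform(0, 90)).buffer(2.0)
                   for _ in range(3)]
            line = LineString(rng.uniform(0, 90, size=(3, 2)))
            fs = FeatureSet({"trails": [line] + pts})
            dist = euclidean_distance(fs, "trails", spec)
            mask = rasterize_features([line] + pts, spec)
            xm, ym = spec.center_mesh()
            src = np.column_stack([xm[mask], ym[mask]])
            expected = np.empty(xm.size)
            flatx, flaty = xm.ravel(), ym.ravel()
            for i in range(xm.size):
                expected[i] = np.min(np.hypot(src[:, 0] - flatx[i],
                                              src[:, 1] - flaty[i]))
            np.testing.assert_allclose(dist.values.ravel(), expected,
                                       atol=1e-9)

    def test_lipschitz_across_neighbors(self, small_stack):
        """|d(a)-d(b)| <= sqrt(2) * cell for 8-neighbors."""
        d = small_stack["dist_trails"].values
        cs = small_stack.spec.cell_size
        bound = np.sqrt(2) * cs + 1e-9
        for dr, dc in ((0, 1), (1, 0), (1, 1), (1, -1)):
            a = d[max(dr, 0):d.shape[0] + min(dr, 0),
                  max(dc, 0):d.shape[1] + min(dc, 0)]
            b = d[max(-dr, 0):d.shape[0] + min(-dr, 0),
                  max(-dc, 0):d.shape[1] + min(-dc, 0)]
            assert np.max(np.abs(a - b)) <= bound


class TestStack:
    def test_two_aligned_rasters(self, tiny_spec):
        a = RasterGrid(tiny_spec, np.zeros((10, 10)), name="a")
        b = RasterGrid(tiny_spec, np.ones((10, 10)), name="b")
        stack = stack_predictors(a, b)
        assert len(stack) == 2 and stack.names == ["a", "b"]

    def test_differing_cell_size_rejected(self, tiny_spec):
        other = GridSpec(0.0, 30.0, 5.0, 10, 10)
        a = RasterGrid(tiny_spec, np.zeros((10, 10)), name="a")
        b = RasterGrid(other, np.zeros((10, 10)), name="b")
        with pytest.raises(GridAlignmentError, match="a.*b|b.*a"):
            stack_predictors(a, b)

    def test_roundtrip_preserves_order_and_names(self, tiny_spec, tmp_path):
        from middensdm.io import read_stack, write_stack

        rng = np.random.default_rng(2)
        rasters = [RasterGrid(tiny_spec, rng.normal(size=(10, 10)), name=n)
                   for n in ("zeta", "alpha", "mid")]
        stack = stack_predictors(*rasters)
        manifest = write_stack(stack, str(tmp_path))
        back = read_stack(manifest)
        assert back.names == ["zeta", "alpha", "mid"]
        for n in back.names:
            np.testing.assert_array_equal(back[n].values, stack[n].values)


def test_idw_fill_errors_when_everything_missing(tiny_spec):
    raster = RasterGrid(tiny_spec, np.full((10, 10), np.nan), name="x")
    with pytest.raises(ValueError):
        idw_fill(raster)
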