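"""Synthetic landscape generator: determinism, ranges, response model."""

import dataclasses

import numpy as np
import pytest

from middensdm.cloud import GROUND, VEGETATION
from middensdm.rasters import stack_predictors
from middensdm.synthetic import (LandscapeConfig, PiecewiseResponse,
                                 ResponseTruth, calibrate_intercept,
                                 default_response_truth, generate_canopy,
                                 generate_features, generate_point_cloud,
                                 generate_terrain, simulate_middens,
                                 study_area_polygon, thin_middens)
from middensdm.synthetic import ConfigurationError


class TestTerrain:
    def test_degenerate_range_gives_constant_raster(self, small_config):
        cfg = dataclasses.replace(small_config, elevation_range=(150.0, 150.0))
        elev = generate_terrain(cfg)
        assert np.all(elev.values == 150.0)

    def test_default_range_clamped(self):
        elev = generate_terrain(LandscapeConfig(seed=1))
        assert elev.values.min() >= 145.0 and elev.values.max() <= 190.0

    def test_seed_determinism_and_sensitivity(self, small_config):
        a = generate_terrain(small_config)
        b = generate_terrain(small_config)
        c = generate_terrain(dataclasses.replace(small_config, seed=8))
        np.testing.assert_array_equal(a.values, b.values)
        assert np.any(a.values != c.values)

    def test_nonpositive_cell_size_rejected(self):
        with pytest.raises(ConfigurationError):
            LandscapeConfig(cell_size=0.0)


class TestCanopy:
    def test_zero_max_height_forces_zero_raster(self, small_config):
        cfg = dataclasses.replace(small_config, max_canopy_height=0.0)
        h, _ = generate_canopy(cfg, generate_terrain(cfg))
        assert np.all(h.values == 0.0)

    def test_meadow_patch_is_bare(self, small_landscape):
        cfg = small_landscape["config"]
        spec = small_landscape["spec"]
        cx, cy = 0.78 * spec.extent_x, 0.80 * spec.extent_y
        xm, ym = spec.center_mesh()
        meadow = (xm - cx) ** 2 + (ym - cy) ** 2 <= cfg.meadow_radius ** 2
        assert np.all(small_landscape["height"].values[meadow] == 0.0)
        assert np.all(small_landscape["density"].values[meadow] == 0.0)

    def test_height_density_positively_correlated(self, small_landscape):
        r = np.corrcoef(small_landscape["height"].values.ravel(),
                        small_landscape["density"].values.ravel())[0, 1]
        assert r > 0

    def test_ranges(self, small_landscape):
        cfg = small_landscape["config"]
        h, d = small_landscape["height"], small_landscape["density"]
        assert h.values.min() >= 0 and h.values.max() <= cfg.max_canopy_height
        assert d.values.min() >= 0 and d.values.max() <= 1


class TestFeatures:
    def test_all_five_classes_non_empty(self, small_landscape):
        fs = small_landscape["features"]
        for name in ("lake", "trails", "dogtrail", "highway", "buildings"):
            assert len(fs[name]) > 0

    def test_empty_building_list_respected(self, small_config):
        cfg = dataclasses.replace(small_config, building_rects=[])
        fs = generate_features(cfg)
        assert fs["buildings"] == []
        assert len(fs["lake"]) == 1

    def test_geometries_valid_and_inside_extent(self, small_landscape):
        fs = small_landscape["features"]
        assert all(g.is_valid for geoms in fs.classes.values() for g in geoms)
        assert fs.all_within(small_landscape["spec"].bounds)


class TestPointCloud:
    def test_zero_density_gives_ground_only(self, small_config):
        elev = generate_terrain(small_config)
        h, d = generate_canopy(small_config, elev)
        zero = d.with_values(np.zeros_like(d.values))
        cloud = generate_point_cloud(small_config, elev, h, zero)
        assert np.all(cloud.klass == GROUND)

    def test_vegetation_rate_matches_configuration(self, small_landscape):
        """Per-cell vegetated-return counts match the Poisson rate within
        3 standard errors over the full (10^4-cell) landscape."""
        cfg = small_landscape["config"]
        spec = small_landscape["spec"]
        cloud = small_landscape["cloud"]
        veg = cloud.select(cloud.klass != GROUND)
        row, col = spec.index_of(veg.x, veg.y)
        counts = np.bincount(row * spec.n_cols + col,
                             minlength=spec.n_rows * spec.n_cols)
        h = small_landscape["height"].values.ravel()
        lam = np.where(h > 0,
                       cfg.veg_returns_per_cell
                       * small_landscape["density"].values.ravel(), 0.0)
        assert lam.size >= 1000
        diff = counts.sum() - lam.sum()
        se = np.sqrt(lam.sum())  # Poisson total
        assert abs(diff) <= 3 * se

    def test_z_bounded_below_by_local_elevation(self, small_landscape):
        spec = small_landscape["spec"]
        cloud = small_landscape["cloud"]
        row, col = spec.index_of(cloud.x, cloud.y)
        local = small_landscape["elevation"].values[row, col]
        noise_bound = 6 * small_landscape["config"].vertical_noise
        assert np.all(cloud.z >= local - noise_bound)

    def test_unclassified_fraction_nonzero(self, small_landscape):
        counts = small_landscape["cloud"].class_counts()
        assert counts["unclassified"] > 0
        assert counts["vegetation"] > 0


class TestSimulateMiddens:
    @pytest.fixture(scope="class")
    def truth_stack(self, small_landscape):
        return stack_predictors(small_landscape["height"],
                                small_landscape["density"])

    def test_large_negative_intercept_gives_zero_presences(self, truth_stack):
        truth = ResponseTruth(-50.0, {})
        pts, rec = simulate_middens(truth_stack, truth, seed=1)
        assert len(pts) == 0 and rec.realized_count == 0

    def test_null_model_prevalence_near_half(self, truth_stack):
        truth = ResponseTruth(0.0, {})
        pts, _ = simulate_middens(truth_stack, truth, seed=1)
        n_cells = truth_stack.spec.n_rows * truth_stack.spec.n_cols
        se = np.sqrt(0.25 * n_cells)
        assert abs(len(pts) - 0.5 * n_cells) <= 3 * se

    def test_height_response_shifts_presences_upward(self, truth_stack,
                                                     small_landscape):
        truth = ResponseTruth(0.0, {
            "canopy_height": PiecewiseResponse([4.0, 9.0, 14.0],
                                               [-1.4, 0.0, 1.4])})
        pts, _ = simulate_middens(truth_stack, truth, seed=2)
        spec = truth_stack.spec
        row, col = spec.index_of(pts[:, 0], pts[:, 1])
        h = small_landscape["height"].values
        present = np.zeros(h.shape, dtype=bool)
        present[row, col] = True
        assert h[present].mean() > h[~present].mean()

    def test_missing_layer_error_names_it(self, truth_stack):
        truth = ResponseTruth(0.0, {
            "dist_lake": PiecewiseResponse([0.0, 1.0], [0.0, 0.0])})
        with pytest.raises(ValueError, match="dist_lake"):
            simulate_middens(truth_stack, truth, seed=1)

    def test_prevalence_monotone_in_intercept(self, truth_stack):
        counts = [len(simulate_middens(truth_stack, ResponseTruth(b0, {}),
                                       seed=3)[0])
                  for b0 in (-4.0, -2.0, 0.0)]
        assert counts[0] <= counts[1] <= counts[2]

    def test_calibrated_intercept_hits_target(self, truth_stack,
                                              small_landscape):
        truth = default_response_truth()
        area = small_landscape["area"]
        b0 = calibrate_intercept(
            stack_predictors(small_landscape["height"],
                             small_landscape["density"]),
            ResponseTruth(0.0, {
                "canopy_height": truth.responses["canopy_height"],
                "canopy_density": truth.responses["canopy_density"]}),
            60.0, area)
        t2 = ResponseTruth(b0, {
            "canopy_height": truth.responses["canopy_height"],
            "canopy_density": truth.responses["canopy_density"]})
        realized = [len(simulate_middens(truth_stack, t2, seed=s, area_polygon=area)[0])
                    for s in range(5)]
        assert abs(np.mean(realized) - 60.0) <= 3 * np.sqrt(60.0)

    def test_determinism(self, truth_stack):
        truth = ResponseTruth(-2.0, {})
        a, _ = simulate_middens(truth_stack, truth, seed=5)
        b, _ = simulate_middens(truth_stack, truth, seed=5)
        np.testing.assert_array_equal(a, b)


class TestThinMiddens:
    def test_close_pair_merges(self):
        out = thin_middens(np.array([[0.0, 0.0], [5.0, 0.0]]), radius=10)
        assert len(out) == 1

    def test_distant_pair_kept(self):
        out = thin_middens(np.array([[0.0, 0.0], [15.0, 0.0]]), radius=10)
        assert len(out) == 2

    def test_every_dropped_point_near_a_kept_one(self):
        rng = np.random.default_rng(11)
        pts = rng.uniform(0, 120, size=(200, 2))
        kept = thin_middens(pts, radius=10)
        kept_set = {tuple(p) for p in kept}
        dropped = np.array([p for p in pts if tuple(p) not in kept_set])
        assert len(kept) + len(dropped) == 200
        for p in dropped:
            d = np.hypot(kept[:, 0] - p[0], kept[:, 1] - p[1])
            assert d.min() < 10.0

    def test_deterministic_order_independent_of_input_order(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(0, 50, size=(60, 2))
        a = thin_middens(pts, radius=8)
        b = thin_middens(pts[::-1], radius=8)
        assert {tuple(p) for p in a} == {tuple(p) for p in b}


class TestResponseTruth:
    def test_breakpoints_inside_generated_ranges(self, small_landscape):
        truth = default_response_truth()
        h = small_landscape["height"].values
        truth.check_breakpoints({
            "canopy_height": (float(h.min()), float(h.max())),
            "dist_trails": (0.0, 400.0),
            "canopy_density": (0.0, 1.0),
            "dist_lake": (0.0, 600.0),
        })
        with pytest.raises(ValueError, match="canopy_height"):
            truth.check_breakpoints({
                "canopy_height": (0.0, 8.0),
                "dist_trails": (0.0, 400.0),
                "canopy_density": (0.0, 1.0),
                "dist_lake": (0.0, 600.0),
            })

    def test_responses_finite_everywhere(self):
        truth = default_response_truth()
        probe = np.array([-1e9, -1.0, 0.0, 9.0, 1e9])
        for resp in truth.responses.values():
            assert np.all(np.isfinite(resp(probe)))

    def test_roundtrip_through_dict(self):
        truth = default_response_truth(-2.5)
        back = ResponseTruth.from_dict(truth.to_dict())
        assert back.intercept == truth.intercept
        for name, resp in truth.responses.items():
            assert back.responses[name].xs == resp.xs
            assert back.responses[name].ys == resp.ys


def test_study_area_polygon_has_requested_area(small_config):
    area = study_area_polygon(small_config)
    assert area.area / 1e4 == pytest.approx(small_config.study_area_ha,
                                            rel=1e-6)


def test_oversized_study_area_rejected():
    with pytest.raises(ConfigurationError):
        study_area_polygon(LandscapeConfig(extent_x=100.0, extent_y=100.0,
                                           study_area_ha=45.5))
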