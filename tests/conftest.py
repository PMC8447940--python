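import numpy as np
import pandas as pd
import pytest

from middensdm.cloud import merge_vegetation
from middensdm.features import FEATURE_CLASSES
from middensdm.grids import GridSpec
from middensdm.rasters import (build_dem, canopy_density, canopy_height,
                               euclidean_distance, slope_aspect,
                               stack_predictors)
from middensdm.synthetic import (LandscapeConfig, generate_canopy,
                                 generate_features, generate_point_cloud,
                                 generate_terrain, study_area_polygon)


@pytest.fixture(scope="session")
def small_config() -> LandscapeConfig:
    """A 300 x 300 m landscape (100 x 100 cells): cheap but non-trivial."""
    return LandscapeConfig(extent_x=300.0, extent_y=300.0, seed=7,
                           study_area_ha=5.0)


@pytest.fixture(scope="session")
def small_landscape(small_config):
    """Rasters, features, cloud and study polygon for the small landscape."""
    elevation = generate_terrain(small_config)
    height, density = generate_canopy(small_config, elevation)
    features = generate_features(small_config)
    cloud = generate_point_cloud(small_config, elevation, height, density)
    area = study_area_polygon(small_config)
    return {
        "config": small_config,
        "elevation": elevation,
        "height": height,
        "density": density,
        "features": features,
        "cloud": cloud,
        "area": area,
        "spec": small_config.grid(),
    }


@pytest.fixture(scope="session")
def small_stack(small_landscape):
    """The full 10-layer derived predictor stack on the small landscape."""
    spec = small_landscape["spec"]
    cloud = merge_vegetation(small_landscape["cloud"])
    dem = build_dem(cloud, spec)
    dens = canopy_density(cloud, spec)
    chm = canopy_height(cloud, dem)
    slope, aspect = slope_aspect(dem)
    dist = {n: euclidean_distance(small_landscape["features"], n, spec)
            for n in FEATURE_CLASSES}
    return stack_predictors(chm, dens, slope, aspect, dem, dist["lake"],
                            dist["trails"], dist["dogtrail"],
                            dist["highway"], dist["buildings"])


@pytest.fixture
def tiny_spec() -> GridSpec:
    """10 x 10 cells of 3 m with origin at (0, 30)."""
    return GridSpec(origin_x=0.0, origin_y=30.0, cell_size=3.0,
                    n_rows=10, n_cols=10)


@pytest.fixture(scope="session")
def toy_classification_table():
    """200-row nonlinear binary problem for boosting tests."""
    rng = np.random.default_rng(42)
    X = rng.normal(size=(200, 5))
    eta = 1.5 * X[:, 0] + np.sin(2.0 * X[:, 1]) - 0.8 * (X[:, 2] > 0.5)
    y = (eta + rng.normal(scale=0.7, size=200) > 0).astype(int)
    tab = pd.DataFrame(X, columns=[f"f{i}" for i in range(5)])
    tab["label"] = y
    tab["weight"] = 1.0
    return tab
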