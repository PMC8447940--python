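"""Synthetic study landscape with a known midden-response model.

Emulates the kind of site the pipeline targets: a ~45.5 ha patch of boreal
forest inside an ~880 x 850 m bounding box, elevation 145-190 m, canopy up
to ~25 m, a LIDAR cloud at ~0.82 m (2.7 ft) point spacing, five vector
feature classes (lake in the north, highway along the west edge, trail
network, dog trail, buildings near the east edge), and midden presences
drawn cell-wise from a logistic response model whose piecewise-linear
component responses are stored as ground truth, so parameter recovery can
be checked downstream.

Everything is deterministic per (config, seed): the same seed yields
bit-identical terrain, cloud, features and presences.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import shapely
from scipy import ndimage
from shapely.geometry import LineString, Point, Polygon

from .features import FEATURE_CLASSES, FeatureSet
from .grids import GridSpec, RasterGrid
from .rasters import PredictorStack

__all__ = [
    "LandscapeConfig",
    "PiecewiseResponse",
    "ResponseTruth",
    "default_response_truth",
    "study_area_polygon",
    "generate_terrain",
    "generate_canopy",
    "generate_features",
    "generate_point_cloud",
    "simulate_middens",
    "calibrate_intercept",
    "thin_middens",
]


class ConfigurationError(ValueError):
    pass


@dataclass
class LandscapeConfig:
    """Parameters of the synthetic study area.

    Defaults reproduce the reference site's descriptive statistics: an
    880 x 850 m bounding box (gridded at 3 m, truncated to whole cells),
    elevation 145-190 m, canopy heights up to 25 m, LIDAR point spacing
    0.82 m (2.7 ft) and a 45.5 ha study-area polygon.
    """

    extent_x: float = 880.0
    extent_y: float = 850.0
    cell_size: float = 3.0
    elevation_range: tuple[float, float] = (145.0, 190.0)
    max_canopy_height: float = 25.0
    lidar_point_spacing: float = 0.82
    seed: int = 0
    study_area_ha: float = 45.5
    terrain_bandwidth: float = 60.0   # Gaussian smoothing bandwidth, m
    canopy_bandwidth: float = 25.0
    vertical_noise: float = 0.04      # ground-return z noise sd, m
    veg_returns_per_cell: float = 8.0  # expected vegetation returns at density 1
    unclassified_fraction: float = 0.3
    meadow_center: tuple[float, float] | None = None  # defaults to the NE
    meadow_radius: float = 70.0
    lake_center: tuple[float, float] | None = None
    lake_radius: float | None = None  # default: 90 m, shrunk to fit small extents
    highway_offset: float = 6.0
    trail_vertices: list[list[tuple[float, float]]] | None = None
    building_rects: list[tuple[float, float, float, float]] | None = None

    def __post_init__(self) -> None:
        for name in ("extent_x", "extent_y", "cell_size", "lidar_point_spacing",
                     "max_canopy_height", "study_area_ha", "meadow_radius",
                     "lake_radius"):
            val = getattr(self, name)
            if val is None:
                continue
            if name == "max_canopy_height":
                if val < 0:
                    raise ConfigurationError(f"{name} must be >= 0, got {val}")
            elif val <= 0:
                raise ConfigurationError(f"{name} must be > 0, got {val}")
        lo, hi = self.elevation_range
        if hi < lo:
            raise ConfigurationError("elevation_range must be (low, high)")

    def grid(self) -> GridSpec:
        """Grid spec covering the extent with whole cells (floor-truncated)."""
        n_cols = int(np.floor(self.extent_x / self.cell_size + 1e-9))
        n_rows = int(np.floor(self.extent_y / self.cell_size + 1e-9))
        if n_cols < 1 or n_rows < 1:
            raise ConfigurationError("extent smaller than one cell")
        return GridSpec(origin_x=0.0, origin_y=n_rows * self.cell_size,
                        cell_size=self.cell_size, n_rows=n_rows, n_cols=n_cols)


# ---------------------------------------------------------------------------
# response truth


@dataclass
class PiecewiseResponse:
    """Piecewise-linear response on the log-odds scale.

    Evaluated by linear interpolation between (xs, ys) knots, held constant
    beyond the outermost knots, so the response is finite everywhere.
    """

    xs: list[float]
    ys: list[float]

    def __post_init__(self) -> None:
        if len(self.xs) != len(self.ys) or len(self.xs) < 2:
            raise ValueError("response needs >= 2 (x, y) knots of equal length")
        if not np.all(np.diff(self.xs) > 0):
            raise ValueError("response knots must have strictly increasing x")

    def __call__(self, v: np.ndarray) -> np.ndarray:
        return np.interp(np.asarray(v, dtype=float), self.xs, self.ys)

    def zero_crossings(self) -> list[float]:
        xs, ys = np.asarray(self.xs), np.asarray(self.ys)
        out = []
        for i in range(len(xs) - 1):
            y0, y1 = ys[i], ys[i + 1]
            if y0 == 0:
                out.append(float(xs[i]))
            elif y0 * y1 < 0:
                out.append(float(xs[i] - y0 * (xs[i + 1] - xs[i]) / (y1 - y0)))
        if ys[-1] == 0:
            out.append(float(xs[-1]))
        return out


@dataclass
class ResponseTruth:
    """The generative presence model: logit p = intercept + sum responses."""

    intercept: float
    responses: dict[str, PiecewiseResponse] = field(default_factory=dict)
    realized_count: int | None = None

    def linear_predictor(self, layers: dict[str, np.ndarray]) -> np.ndarray:
        missing = [n for n in self.responses if n not in layers]
        if missing:
            raise ValueError(f"predictor stack is missing layer '{missing[0]}'")
        eta = np.full_like(next(iter(layers.values()), np.zeros(1)),
                           self.intercept, dtype=float)
        for name, resp in self.responses.items():
            eta = eta + resp(layers[name])
        return eta

    def check_breakpoints(self, ranges: dict[str, tuple[float, float]]) -> None:
        """Every knot must lie inside its predictor's generated range."""
        for name, resp in self.responses.items():
            lo, hi = ranges[name]
            for x in resp.xs:
                if not (lo <= x <= hi) and not np.isinf(x):
                    raise ValueError(
                        f"response knot {x} for '{name}' outside generated "
                        f"range [{lo:.3g}, {hi:.3g}]"
                    )

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "responses": {n: {"xs": r.xs, "ys": r.ys}
                          for n, r in self.responses.items()},
            "realized_count": self.realized_count,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ResponseTruth":
        return cls(
            intercept=d["intercept"],
            responses={n: PiecewiseResponse(r["xs"], r["ys"])
                       for n, r in d["responses"].items()},
            realized_count=d.get("realized_count"),
        )


def default_response_truth(intercept: float = -3.0) -> ResponseTruth:
    """The standard generative model: threshold-shaped responses to canopy
    height (sign change at 9 m), trail distance (negative under 10 m,
    positive to ~30 m, a dip at 30-50 m), canopy density (sign change at
    0.45) and lake distance (positive under 250 m)."""
    return ResponseTruth(
        intercept=intercept,
        responses={
            "canopy_height": PiecewiseResponse([4.0, 9.0, 14.0], [-1.4, 0.0, 1.4]),
            "dist_trails": PiecewiseResponse(
                [0.0, 10.0, 20.0, 30.0, 40.0, 50.0],
                [-1.2, 0.0, 0.8, 0.2, -0.3, 0.0]),
            "canopy_density": PiecewiseResponse(
                [0.25, 0.45, 0.65], [-0.9, 0.0, 0.9]),
            "dist_lake": PiecewiseResponse(
                [150.0, 250.0, 350.0], [0.8, 0.0, -0.8]),
        },
    )


# ---------------------------------------------------------------------------
# terrain / canopy / features / cloud


def _smooth_field(rng: np.random.Generator, spec: GridSpec,
                  bandwidth: float) -> np.ndarray:
    """Spatially autocorrelated field: Gaussian-smoothed white noise."""
    noise = rng.standard_normal((spec.n_rows, spec.n_cols))
    sigma = max(bandwidth / spec.cell_size, 1e-9)
    return ndimage.gaussian_filter(noise, sigma=sigma, mode="reflect")


def _rescale(field_: np.ndarray, lo: float, hi: float) -> np.ndarray:
    fmin, fmax = field_.min(), field_.max()
    if hi == lo or fmax == fmin:
        return np.full_like(field_, lo)
    return lo + (hi - lo) * (field_ - fmin) / (fmax - fmin)


def _rng(config: LandscapeConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


def generate_terrain(config: LandscapeConfig) -> RasterGrid:
    """Smooth elevation raster spanning exactly ``elevation_range``."""
    spec = config.grid()
    lo, hi = config.elevation_range
    values = _rescale(_smooth_field(_rng(config, 1), spec,
                                    config.terrain_bandwidth), lo, hi)
    return RasterGrid(spec, values, name="elevation", units="m")


def generate_canopy(config: LandscapeConfig,
                    elevation: RasterGrid) -> tuple[RasterGrid, RasterGrid]:
    """Canopy height (m) and canopy density (fraction), positively
    correlated by construction, with an open-meadow patch zeroed in both."""
    spec = elevation.spec
    rng = _rng(config, 2)
    base = _rescale(_smooth_field(rng, spec, config.canopy_bandwidth), 0.0, 1.0)
    extra = _rescale(_smooth_field(rng, spec, config.canopy_bandwidth), 0.0, 1.0)
    height = base * config.max_canopy_height
    density = np.clip(0.7 * base + 0.3 * extra, 0.0, 1.0)
    cx, cy = config.meadow_center or (0.78 * spec.extent_x, 0.80 * spec.extent_y)
    xm, ym = spec.center_mesh()
    meadow = (xm - cx) ** 2 + (ym - cy) ** 2 <= config.meadow_radius ** 2
    height[meadow] = 0.0
    density[meadow] = 0.0
    return (
        RasterGrid(spec, height, name="canopy_height", units="m"),
        RasterGrid(spec, density, name="canopy_density", units="fraction"),
    )


def generate_features(config: LandscapeConfig) -> FeatureSet:
    """The five vector feature classes, all inside the grid extent."""
    spec = config.grid()
    ex, ey = spec.extent_x, spec.extent_y
    radius = config.lake_radius
    if radius is None:
        radius = min(90.0, 0.15 * min(ex, ey))
    lake_center = config.lake_center or (0.45 * ex, min(0.90 * ey,
                                                        ey - radius - 2.0))
    lake = Point(*lake_center).buffer(radius, quad_segs=16)
    highway = LineString([(config.highway_offset, 0.0),
                          (config.highway_offset, ey)])
    trail_paths = config.trail_vertices or [
        [(0.1 * ex, 0.05 * ey), (0.35 * ex, 0.35 * ey), (0.3 * ex, 0.7 * ey),
         (0.55 * ex, 0.95 * ey)],
        [(0.05 * ex, 0.5 * ey), (0.45 * ex, 0.45 * ey), (0.8 * ex, 0.55 * ey),
         (0.95 * ex, 0.4 * ey)],
        [(0.35 * ex, 0.35 * ey), (0.6 * ex, 0.2 * ey), (0.9 * ex, 0.1 * ey)],
    ]
    trails = [LineString(p) for p in trail_paths]
    dogtrail = LineString([(0.15 * ex, 0.15 * ey), (0.5 * ex, 0.1 * ey),
                           (0.85 * ex, 0.25 * ey)])
    rects = config.building_rects
    if rects is None:
        w, h = 0.04 * ex, 0.03 * ey
        rects = [(0.90 * ex, 0.60 * ey, w, h),
                 (0.90 * ex, 0.45 * ey, w, h),
                 (0.88 * ex, 0.30 * ey, w, h)]
    buildings = [shapely.box(x, y, x + w, y + h) for x, y, w, h in rects]
    fs = FeatureSet({
        "lake": [lake],
        "trails": trails,
        "dogtrail": [dogtrail],
        "highway": [highway],
        "buildings": buildings,
    })
    if not fs.all_within(spec.bounds):
        raise ConfigurationError("a generated feature falls outside the extent")
    return fs


def study_area_polygon(config: LandscapeConfig, n_vertices: int = 64) -> Polygon:
    """Irregular study-area polygon of ``study_area_ha`` hectares centered
    in the bounding box (an ellipse-approximating polygon, scaled exactly)."""
    spec = config.grid()
    target = config.study_area_ha * 1e4
    if target > spec.extent_x * spec.extent_y:
        raise ConfigurationError("study_area_ha larger than the bounding box")
    ratio = spec.extent_x / spec.extent_y
    # n-gon inscribed in an ellipse with semi-axes (a, b): area = n/2 a b sin(2pi/n)
    ab = target / (n_vertices / 2 * np.sin(2 * np.pi / n_vertices))
    b = float(np.sqrt(ab / ratio))
    a = float(ab / b)
    if a > spec.extent_x / 2 or b > spec.extent_y / 2:
        raise ConfigurationError("study area polygon does not fit the extent")
    t = np.linspace(0.0, 2 * np.pi, n_vertices, endpoint=False)
    cx, cy = spec.extent_x / 2, spec.extent_y / 2
    return Polygon(np.column_stack([cx + a * np.cos(t), cy + b * np.sin(t)]))


def generate_point_cloud(config: LandscapeConfig, elevation: RasterGrid,
                         height: RasterGrid, density: RasterGrid):
    """Classified LIDAR returns over the whole grid.

    Ground returns sit on a jittered grid at ``lidar_point_spacing`` with
    z = local elevation + Gaussian noise. Vegetation returns are drawn per
    cell with expected count ``veg_returns_per_cell * density``, z uniform
    in (elevation, elevation + canopy height]; a configurable fraction is
    labeled unclassified, as provider data typically is.
    """
    from .cloud import GROUND, UNCLASSIFIED, VEGETATION, PointCloud

    spec = elevation.spec
    elevation.assert_aligned(height)
    elevation.assert_aligned(density)
    if config.lidar_point_spacing <= 0:
        raise ConfigurationError("lidar_point_spacing must be > 0")
    rng = _rng(config, 3)
    s = config.lidar_point_spacing
    gx = np.arange(s / 2, spec.extent_x, s)
    gy = np.arange(s / 2, spec.extent_y, s)
    gxm, gym = np.meshgrid(gx, gy)
    n_ground = gxm.size
    jitter = rng.uniform(-s / 2, s / 2, size=(2, n_ground))
    x_g = np.clip(gxm.ravel() + jitter[0], 0.0, spec.extent_x - 1e-9)
    y_g = np.clip(gym.ravel() + jitter[1], 1e-9, spec.extent_y)
    row, col = spec.index_of(x_g, y_g)
    z_g = elevation.values[row, col] + rng.normal(0.0, config.vertical_noise,
                                                  n_ground)

    lam = config.veg_returns_per_cell * np.clip(density.values, 0.0, 1.0)
    lam = np.where(height.values > 0, lam, 0.0)
    counts = rng.poisson(lam)
    total_veg = int(counts.sum())
    rr, cc = np.nonzero(counts)
    reps = counts[rr, cc]
    cell_r = np.repeat(rr, reps)
    cell_c = np.repeat(cc, reps)
    cs = spec.cell_size
    x_v = spec.origin_x + (cell_c + rng.uniform(0, 1, total_veg)) * cs
    y_v = spec.origin_y - (cell_r + rng.uniform(0, 1, total_veg)) * cs
    u = rng.uniform(0, 1, total_veg)  # (0,1], scaled to the canopy column
    z_v = elevation.values[cell_r, cell_c] + (1.0 - u) * height.values[cell_r, cell_c]
    klass_v = np.where(rng.uniform(size=total_veg) < config.unclassified_fraction,
                       UNCLASSIFIED, VEGETATION)

    return PointCloud(
        np.concatenate([x_g, x_v]),
        np.concatenate([y_g, y_v]),
        np.concatenate([z_g, z_v]),
        np.concatenate([np.full(n_ground, GROUND, dtype=np.int8),
                        klass_v.astype(np.int8)]),
    )


def calibrate_intercept(stack: PredictorStack, truth: ResponseTruth,
                        target_expected: float,
                        area_polygon: Polygon | None = None) -> float:
    """Intercept such that the expected presence count over the (clipped)
    cells equals ``target_expected``; solved by bisection."""
    layers, _ = _stack_cells(stack, area_polygon)
    eta0 = ResponseTruth(0.0, truth.responses).linear_predictor(layers)

    def expected(b0: float) -> float:
        return float(np.sum(1.0 / (1.0 + np.exp(-(eta0 + b0)))))

    lo, hi = -30.0, 10.0
    if not (expected(lo) <= target_expected <= expected(hi)):
        raise ValueError("target expected count unreachable by intercept alone")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if expected(mid) < target_expected:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _stack_cells(stack: PredictorStack, area_polygon: Polygon | None):
    """Per-cell layer values (flattened), restricted to polygon cells."""
    spec = stack.spec
    if area_polygon is None:
        keep = np.ones(spec.n_rows * spec.n_cols, dtype=bool)
    else:
        xm, ym = spec.center_mesh()
        keep = shapely.contains_xy(area_polygon, xm.ravel(), ym.ravel())
    layers = {name: r.values.ravel()[keep] for name, r in stack.layers.items()}
    return layers, keep


def simulate_middens(stack: PredictorStack, truth: ResponseTruth, seed: int,
                     area_polygon: Polygon | None = None):
    """Inhomogeneous cell-wise Bernoulli presence draw.

    Each cell succeeds with probability ``logistic(intercept + sum of
    responses)``; successes yield a presence point at the cell center.
    Returns ``(points, truth_record)`` where points is an (n, 2) array of
    (x, y) and the truth record carries the realized count.
    """
    layers, keep = _stack_cells(stack, area_polygon)
    eta = truth.linear_predictor(layers)
    p = 1.0 / (1.0 + np.exp(-eta))
    rng = np.random.default_rng(np.random.SeedSequence([seed, 4]))
    hit = rng.uniform(size=p.shape) < p
    xm, ym = stack.spec.center_mesh()
    xs = xm.ravel()[keep][hit]
    ys = ym.ravel()[keep][hit]
    record = ResponseTruth(truth.intercept, truth.responses,
                           realized_count=int(hit.sum()))
    return np.column_stack([xs, ys]), record


def thin_middens(points: np.ndarray, radius: float = 10.0) -> np.ndarray:
    """Greedy merge of nearby middens into one diffuse midden.

    Points are visited in deterministic (y descending, x ascending) order;
    a point closer than ``radius`` to an already-kept point is dropped.
    Chains can leave kept points closer than ``radius`` to each other, but
    every dropped point is within ``radius`` of some kept point.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(pts) == 0:
        return pts
    order = np.lexsort((pts[:, 0], -pts[:, 1]))
    kept: list[int] = []
    r2 = radius * radius
    for i in order:
        if all((pts[i, 0] - pts[j, 0]) ** 2 + (pts[i, 1] - pts[j, 1]) ** 2 >= r2
               for j in kept):
            kept.append(i)
    kept_sorted = np.sort(np.asarray(kept))
    return pts[kept_sorted]
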