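"""Predictor rasters from a classified point cloud and vector features.

Turns LIDAR returns into the terrain and canopy layers (DEM, slope, aspect,
canopy height, canopy density) and vector feature classes into proximity
(Euclidean distance) layers, all on one aligned square-cell grid — by
default the 3 x 3 m resolution the rest of the pipeline assumes.

Gridding rules
--------------
* A return belongs to exactly one cell (half-open membership; see
  :mod:`middensdm.grids`). Returns outside the grid extent are ignored.
* DEM: mean z of ground returns per cell; empty cells are no-data and then
  filled by inverse-distance weighting from the nearest filled cells.
* Canopy density: vegetation returns / all returns per cell, in [0, 1].
* Canopy height: max z of vegetation returns minus the cell's DEM value,
  floored at 0; cells without vegetation returns are 0 (open ground).
* Distance layers: the geometry is rasterized (every cell whose area
  intersects it is a source cell); each cell then gets the Euclidean
  distance from its center to the nearest source-cell center.
"""

from __future__ import annotations

import numpy as np
import shapely
from scipy import ndimage
from scipy.spatial import cKDTree

from .cloud import GROUND, UNCLASSIFIED, VEGETATION, PointCloud
from .features import FeatureSet
from .grids import GridAlignmentError, GridSpec, RasterGrid

__all__ = [
    "build_dem",
    "canopy_density",
    "canopy_height",
    "slope_aspect",
    "rasterize_features",
    "euclidean_distance",
    "PredictorStack",
    "stack_predictors",
    "LAYER_NAMES",
    "idw_fill",
]

#: Canonical predictor layer names, in stack order.
LAYER_NAMES = (
    "canopy_height",
    "canopy_density",
    "slope",
    "aspect",
    "elevation",
    "dist_lake",
    "dist_trails",
    "dist_dogtrail",
    "dist_highway",
    "dist_buildings",
)

FLAT_ASPECT = -1.0


def _flat_cell_index(cloud: PointCloud, spec: GridSpec) -> tuple[np.ndarray, np.ndarray]:
    """Flat cell index for every in-extent return, plus the keep mask."""
    col = np.floor((cloud.x - spec.origin_x) / spec.cell_size).astype(np.int64)
    row = np.floor((spec.origin_y - cloud.y) / spec.cell_size).astype(np.int64)
    ok = (row >= 0) & (row < spec.n_rows) & (col >= 0) & (col < spec.n_cols)
    return row[ok] * spec.n_cols + col[ok], ok


def idw_fill(raster: RasterGrid, k: int = 8, power: float = 2.0) -> RasterGrid:
    """Fill no-data cells by inverse-distance weighting from the ``k``
    nearest filled cells (by center distance). Filled values stay within
    the [min, max] of their donors (convex combination)."""
    values = raster.values.copy()
    missing = np.isnan(values)
    if not missing.any():
        return raster.with_values(values)
    if missing.all():
        raise ValueError(f"raster '{raster.name}' has no data to fill from")
    xm, ym = raster.spec.center_mesh()
    src = np.column_stack([xm[~missing], ym[~missing]])
    dst = np.column_stack([xm[missing], ym[missing]])
    tree = cKDTree(src)
    kk = min(k, src.shape[0])
    dist, idx = tree.query(dst, k=kk)
    dist = np.atleast_2d(dist.reshape(dst.shape[0], kk))
    idx = np.atleast_2d(idx.reshape(dst.shape[0], kk))
    w = 1.0 / np.maximum(dist, 1e-12) ** power
    donor = values[~missing][idx]
    values[missing] = np.sum(w * donor, axis=1) / np.sum(w, axis=1)
    return raster.with_values(values)


def build_dem(cloud: PointCloud, spec: GridSpec, *, fill_k: int = 8) -> RasterGrid:
    """Digital elevation model: per-cell mean z of ground returns, gap-filled."""
    if np.any(cloud.klass == UNCLASSIFIED):
        raise ValueError("cloud has unclassified returns; run merge_vegetation first")
    ground = cloud.select(cloud.klass == GROUND)
    if len(ground) == 0:
        raise ValueError("no ground returns: cannot build a DEM")
    flat, ok = _flat_cell_index(ground, spec)
    n_cells = spec.n_rows * spec.n_cols
    sums = np.bincount(flat, weights=ground.z[ok], minlength=n_cells)
    counts = np.bincount(flat, minlength=n_cells)
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    dem = RasterGrid(spec, mean.reshape(spec.n_rows, spec.n_cols),
                     name="elevation", units="m")
    return idw_fill(dem, k=fill_k)


def canopy_density(cloud: PointCloud, spec: GridSpec, *, fill_k: int = 8) -> RasterGrid:
    """Fraction of returns per cell that are vegetation, in [0, 1]."""
    if np.any(cloud.klass == UNCLASSIFIED):
        raise ValueError("cloud has unclassified returns; run merge_vegetation first")
    flat, ok = _flat_cell_index(cloud, spec)
    n_cells = spec.n_rows * spec.n_cols
    total = np.bincount(flat, minlength=n_cells)
    veg = np.bincount(flat[cloud.klass[ok] == VEGETATION], minlength=n_cells)
    with np.errstate(invalid="ignore"):
        frac = np.where(total > 0, veg / np.maximum(total, 1), np.nan)
    dens = RasterGrid(spec, frac.reshape(spec.n_rows, spec.n_cols),
                      name="canopy_density", units="fraction")
    return idw_fill(dens, k=fill_k)


def canopy_height(cloud: PointCloud, dem: RasterGrid,
                  spec: GridSpec | None = None) -> RasterGrid:
    """Per-cell height of the highest vegetation return above the DEM."""
    if np.any(cloud.klass == UNCLASSIFIED):
        raise ValueError("cloud has unclassified returns; run merge_vegetation first")
    spec = spec or dem.spec
    dem.assert_aligned(spec, context="canopy_height")
    veg = cloud.select(cloud.klass == VEGETATION)
    n_cells = spec.n_rows * spec.n_cols
    zmax = np.full(n_cells, -np.inf)
    if len(veg):
        flat, ok = _flat_cell_index(veg, spec)
        np.maximum.at(zmax, flat, veg.z[ok])
    height = zmax.reshape(spec.n_rows, spec.n_cols) - dem.values
    height = np.where(np.isfinite(height), np.maximum(height, 0.0), 0.0)
    return RasterGrid(spec, height, name="canopy_height", units="m")


def slope_aspect(dem: RasterGrid) -> tuple[RasterGrid, RasterGrid]:
    """Slope and aspect from a DEM by Horn's 3x3 finite differences.

    Slope is in degrees. Aspect is the compass direction of steepest
    *descent*, degrees clockwise from north in [0, 360); flat cells
    (slope exactly 0) carry the sentinel -1. Edge cells use
    replicated-border padding.
    """
    if dem.spec.n_rows < 3 or dem.spec.n_cols < 3:
        raise ValueError("slope/aspect needs a DEM of at least 3 x 3 cells")
    if np.isnan(dem.values).any():
        raise ValueError("DEM contains no-data; gap-fill before slope/aspect")
    z = np.pad(dem.values, 1, mode="edge")
    cs = dem.spec.cell_size
    # Horn weights: corners 1, edge-neighbors 2. Rows run north -> south.
    nw, n_, ne = z[:-2, :-2], z[:-2, 1:-1], z[:-2, 2:]
    w_, e_ = z[1:-1, :-2], z[1:-1, 2:]
    sw, s_, se = z[2:, :-2], z[2:, 1:-1], z[2:, 2:]
    gx = ((ne + 2 * e_ + se) - (nw + 2 * w_ + sw)) / (8 * cs)  # dz/dx, east+
    gy = ((nw + 2 * n_ + ne) - (sw + 2 * s_ + se)) / (8 * cs)  # dz/dy, north+
    slope = np.degrees(np.arctan(np.hypot(gx, gy)))
    # descent vector is -(gx, gy); azimuth measured clockwise from north
    aspect = np.degrees(np.arctan2(-gx, -gy)) % 360.0
    aspect = np.where(slope == 0.0, FLAT_ASPECT, aspect)
    return (
        RasterGrid(dem.spec, slope, name="slope", units="degrees"),
        RasterGrid(dem.spec, aspect, name="aspect", units="degrees"),
    )


def rasterize_features(geoms, spec: GridSpec) -> np.ndarray:
    """Boolean source mask: True where a cell's square intersects a geometry."""
    mask = np.zeros((spec.n_rows, spec.n_cols), dtype=bool)
    cs = spec.cell_size
    for geom in geoms:
        gx0, gy0, gx1, gy1 = geom.bounds
        c0 = max(int(np.floor((gx0 - spec.origin_x) / cs)), 0)
        c1 = min(int(np.floor((gx1 - spec.origin_x) / cs)), spec.n_cols - 1)
        r0 = max(int(np.floor((spec.origin_y - gy1) / cs)), 0)
        r1 = min(int(np.floor((spec.origin_y - gy0) / cs)), spec.n_rows - 1)
        if c1 < c0 or r1 < r0:
            continue
        rr, cc = np.meshgrid(np.arange(r0, r1 + 1), np.arange(c0, c1 + 1),
                             indexing="ij")
        x0 = spec.origin_x + cc.ravel() * cs
        y1 = spec.origin_y - rr.ravel() * cs
        boxes = shapely.box(x0, y1 - cs, x0 + cs, y1)
        hit = shapely.intersects(boxes, geom)
        mask[rr.ravel()[hit], cc.ravel()[hit]] = True
    return mask


def euclidean_distance(features: FeatureSet, class_name: str,
                       spec: GridSpec) -> RasterGrid:
    """Proximity layer: distance from each cell center to the nearest
    source-cell center of the rasterized feature class (source cells = 0)."""
    geoms = features.non_empty(class_name)
    mask = rasterize_features(geoms, spec)
    if not mask.any():
        raise ValueError(
            f"feature class '{class_name}' does not intersect the grid"
        )
    # exact Euclidean distance transform on cell centers
    dist = ndimage.distance_transform_edt(~mask, sampling=spec.cell_size)
    return RasterGrid(spec, dist, name=f"dist_{class_name}", units="m")


class PredictorStack:
    """Ordered, named set of aligned predictor rasters."""

    def __init__(self, rasters: list[RasterGrid]):
        if not rasters:
            raise ValueError("stack needs at least one raster")
        first = rasters[0]
        for other in rasters[1:]:
            first.assert_aligned(other, context="stack_predictors")
        names = [r.name for r in rasters]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate layer names in stack: {names}")
        self.layers: dict[str, RasterGrid] = {r.name: r for r in rasters}
        self.spec: GridSpec = first.spec

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    def __len__(self) -> int:
        return len(self.layers)

    def __getitem__(self, name: str) -> RasterGrid:
        if name not in self.layers:
            raise KeyError(f"stack has no layer '{name}'; have {self.names}")
        return self.layers[name]

    def require(self, names) -> None:
        for name in names:
            if name not in self.layers:
                raise ValueError(f"predictor stack is missing layer '{name}'")

    def as_array(self) -> np.ndarray:
        """(n_layers, n_rows, n_cols) array in stack order."""
        return np.stack([r.values for r in self.layers.values()])

    def extract(self, x, y) -> dict[str, np.ndarray]:
        """Containing-cell values for every layer at the given points."""
        row, col = self.spec.index_of(x, y)
        out = {}
        for name, r in self.layers.items():
            vals = r.values[row, col]
            if np.isnan(vals).any():
                raise ValueError(
                    f"no-data encountered in layer '{name}'; gap-fill the stack"
                )
            out[name] = vals
        return out


def stack_predictors(*rasters: RasterGrid) -> PredictorStack:
    """Validate alignment and assemble the ordered predictor stack."""
    return PredictorStack(list(rasters))
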