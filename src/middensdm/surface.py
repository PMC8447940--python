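"""RIO surface prediction and occupancy classification.

A regular point lattice inside the study-area polygon is scored with the
boosted model, interpolated to a complete raster by inverse-distance
weighting, and thresholded so the occupied class retains a target fraction
(default 95%) of the observed presences.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import shapely
from scipy.spatial import cKDTree
from shapely.geometry.base import BaseGeometry

from .boost import BoostedModel
from .grids import GridSpec, RasterGrid
from .rasters import PredictorStack
from .sampling import extract_values

__all__ = [
    "make_lattice",
    "score_lattice",
    "idw_interpolate",
    "occupancy_threshold",
    "classify_occupancy",
    "OccupancyMap",
]


def make_lattice(area_polygon: BaseGeometry, spacing: float,
                 spec: GridSpec) -> pd.DataFrame:
    """Axis-aligned regular point lattice clipped to the polygon.

    Points sit on the predictor cell centers (stride ``spacing /
    cell_size`` cells), so at the default spacing (= cell size) every
    in-polygon cell center becomes a lattice point.
    """
    if spacing <= 0:
        raise ValueError("lattice spacing must be > 0")
    if spacing < spec.cell_size:
        warnings.warn("lattice spacing finer than the predictor cell size",
                      stacklevel=2)
    stride = max(1, int(round(spacing / spec.cell_size)))
    xs, ys = spec.cell_centers()
    xm, ym = np.meshgrid(xs[::stride], ys[::stride])
    x, y = xm.ravel(), ym.ravel()
    inside = shapely.contains_xy(area_polygon, x, y)
    if not inside.any():
        raise ValueError("lattice has no points inside the area polygon")
    out = pd.DataFrame({"x": x[inside], "y": y[inside]})
    out.insert(0, "id", np.arange(len(out)))
    return out


def score_lattice(model: BoostedModel, lattice: pd.DataFrame,
                  stack: PredictorStack) -> pd.DataFrame:
    """Attach the model's RIO to every lattice point.

    Output columns follow the PROB_0/PROB_1 convention of scored lattice
    exports: PROB_1 is the RIO, PROB_0 its complement.
    """
    table = extract_values(lattice, stack)
    rio = model.predict(table)
    out = lattice.copy().reset_index(drop=True)
    out["PROB_1"] = rio
    out["PROB_0"] = 1.0 - rio
    return out[["id", "x", "y", "PROB_0", "PROB_1"]]


def idw_interpolate(scored: pd.DataFrame, spec: GridSpec, power: float = 2.0,
                    k: int = 12, value_col: str = "PROB_1",
                    area_polygon: BaseGeometry | None = None) -> RasterGrid:
    """Inverse-distance-weighted RIO surface on the full grid.

    Each cell takes the IDW mean of its ``k`` nearest scored points with
    weights ``d**-power``; a cell whose center coincides with a point
    (d < 1e-9) takes that point's value exactly. Values are convex
    combinations, so the surface never leaves [min, max] of the points.
    """
    if k < 1:
        raise ValueError("idw needs k >= 1 neighbors")
    if len(scored) < 1:
        raise ValueError("idw needs at least one scored point")
    pts = scored[["x", "y"]].to_numpy(dtype=float)
    vals = scored[value_col].to_numpy(dtype=float)
    xm, ym = spec.center_mesh()
    targets = np.column_stack([xm.ravel(), ym.ravel()])
    tree = cKDTree(pts)
    kk = min(k, len(pts))
    dist, idx = tree.query(targets, k=kk)
    dist = dist.reshape(len(targets), kk)
    idx = idx.reshape(len(targets), kk)
    exact = dist[:, 0] < 1e-9
    with np.errstate(divide="ignore"):
        w = 1.0 / np.maximum(dist, 1e-12) ** power
    est = np.sum(w * vals[idx], axis=1) / np.sum(w, axis=1)
    est[exact] = vals[idx[exact, 0]]
    values = est.reshape(spec.n_rows, spec.n_cols)
    if area_polygon is not None:
        inside = shapely.contains_xy(area_polygon, xm.ravel(), ym.ravel())
        values = np.where(inside.reshape(values.shape), values, np.nan)
    return RasterGrid(spec, values, name="rio", units="index")


def occupancy_threshold(rio_at_presences, coverage: float = 0.95) -> float:
    """RIO cutoff retaining at least ``coverage`` of the presence values.

    The nearest-rank lower quantile: t is the k-th smallest presence RIO
    with ``k = ceil((1 - coverage) * N)``, so the fraction of presences
    with RIO >= t lies in [coverage, coverage + 1/N] (ties can only push
    it higher).
    """
    vals = np.sort(np.asarray(rio_at_presences, dtype=float))
    n = vals.size
    if n < 20:
        raise ValueError(f"need >= 20 presence values for a stable "
                         f"threshold, got {n}")
    if not 0 < coverage < 1:
        raise ValueError("coverage must be in (0, 1)")
    # epsilon guards the ceil against float error in (1 - coverage) * n
    k = int(np.ceil((1.0 - coverage) * n - 1e-9))
    k = max(k, 1)
    return float(vals[k - 1])


class OccupancyMap:
    """Binary occupancy raster with its threshold and area bookkeeping."""

    def __init__(self, raster: RasterGrid, t_occupied: float,
                 coverage: float = 0.95):
        self.raster = raster
        self.t_occupied = t_occupied
        self.coverage = coverage

    @property
    def occupied_cells(self) -> int:
        return int(np.nansum(self.raster.values))

    @property
    def area_ha(self) -> float:
        return self.occupied_cells * self.raster.spec.cell_size ** 2 / 1e4

    def presences_in_occupied(self, presences: np.ndarray) -> int:
        pts = np.asarray(presences, dtype=float).reshape(-1, 2)
        row, col = self.raster.spec.index_of(pts[:, 0], pts[:, 1])
        vals = self.raster.values[row, col]
        return int(np.nansum(vals == 1.0))


def classify_occupancy(surface: RasterGrid, t_occupied: float,
                       coverage: float = 0.95) -> OccupancyMap:
    """Binary occupancy: a cell is occupied iff RIO >= t (closed bound)."""
    if not 0 < t_occupied < 1:
        raise ValueError(f"t_occupied must be in (0, 1), got {t_occupied}")
    vals = surface.values
    binary = np.where(np.isnan(vals), np.nan, (vals >= t_occupied).astype(float))
    raster = RasterGrid(surface.spec, binary, name="occupancy", units="binary")
    return OccupancyMap(raster, t_occupied, coverage)
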