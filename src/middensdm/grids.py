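"""Planar, north-up raster grids.

Conventions pinned once for the whole package:

* row 0 is the northernmost row;
* ``(origin_x, origin_y)`` is the *outer* (north-west) corner of cell (0, 0);
* cell (r, c) has its center at
  ``(origin_x + (c + 0.5) * cell_size, origin_y - (r + 0.5) * cell_size)``;
* cell membership is half-open: a point on a shared edge belongs to the
  cell to its east/south, so every point indexes exactly one cell;
* no-data is ``NaN`` in memory and a sentinel value on disk.

Coordinates are planar meters with a carried-through CRS tag; the package
never reprojects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["GridSpec", "RasterGrid", "GridAlignmentError"]

DEFAULT_CRS = "LOCAL_METERS"


class GridAlignmentError(ValueError):
    """Two rasters do not share origin, cell size and dimensions."""


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a raster: origin (NW outer corner), cell size, shape."""

    origin_x: float
    origin_y: float
    cell_size: float
    n_rows: int
    n_cols: int
    crs: str = DEFAULT_CRS

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError(f"cell_size must be > 0, got {self.cell_size}")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")

    # -- geometry ---------------------------------------------------------

    @property
    def extent_x(self) -> float:
        return self.n_cols * self.cell_size

    @property
    def extent_y(self) -> float:
        return self.n_rows * self.cell_size

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(min_x, min_y, max_x, max_y) of the gridded area."""
        return (
            self.origin_x,
            self.origin_y - self.extent_y,
            self.origin_x + self.extent_x,
            self.origin_y,
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Center coordinates as (xs[n_cols], ys[n_rows])."""
        xs = self.origin_x + (np.arange(self.n_cols) + 0.5) * self.cell_size
        ys = self.origin_y - (np.arange(self.n_rows) + 0.5) * self.cell_size
        return xs, ys

    def center_mesh(self) -> tuple[np.ndarray, np.ndarray]:
        """Full (n_rows, n_cols) meshes of center x and y."""
        xs, ys = self.cell_centers()
        return np.meshgrid(xs, ys)

    def index_of(self, x, y, *, clip: bool = False):
        """Map point coordinates to (row, col) under the half-open rule.

        Raises ``ValueError`` listing offending points when any point falls
        outside the grid (unless ``clip``).
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.origin_x) / self.cell_size).astype(np.int64)
        row = np.floor((self.origin_y - y) / self.cell_size).astype(np.int64)
        if clip:
            return row.clip(0, self.n_rows - 1), col.clip(0, self.n_cols - 1)
        bad = (row < 0) | (row >= self.n_rows) | (col < 0) | (col >= self.n_cols)
        if np.any(bad):
            idx = np.flatnonzero(np.atleast_1d(bad))[:10]
            pts = ", ".join(
                f"({np.atleast_1d(x)[i]:.2f}, {np.atleast_1d(y)[i]:.2f})" for i in idx
            )
            raise ValueError(
                f"{int(np.sum(bad))} point(s) outside grid extent, e.g. {pts}"
            )
        return row, col

    def aligned_with(self, other: "GridSpec") -> bool:
        return (
            np.isclose(self.origin_x, other.origin_x)
            and np.isclose(self.origin_y, other.origin_y)
            and np.isclose(self.cell_size, other.cell_size)
            and self.n_rows == other.n_rows
            and self.n_cols == other.n_cols
        )


@dataclass
class RasterGrid:
    """One named raster variable on a :class:`GridSpec`.

    ``values`` is an (n_rows, n_cols) float array; NaN marks no-data.
    """

    spec: GridSpec
    values: np.ndarray
    name: str = "value"
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (self.spec.n_rows, self.spec.n_cols):
            raise ValueError(
                f"values shape {self.values.shape} does not match grid "
                f"({self.spec.n_rows}, {self.spec.n_cols})"
            )

    def copy(self, *, name: str | None = None, units: str | None = None) -> "RasterGrid":
        return RasterGrid(
            self.spec,
            self.values.copy(),
            name if name is not None else self.name,
            units if units is not None else self.units,
        )

    def with_values(self, values: np.ndarray, *, name: str | None = None,
                    units: str | None = None) -> "RasterGrid":
        return RasterGrid(
            self.spec,
            values,
            name if name is not None else self.name,
            units if units is not None else self.units,
        )

    def sample(self, x, y) -> np.ndarray:
        """Nearest-cell (containing-cell) lookup; errors outside the extent."""
        row, col = self.spec.index_of(x, y)
        return self.values[row, col]

    def assert_aligned(self, other: "RasterGrid | GridSpec", *, context: str = "") -> None:
        other_spec = other.spec if isinstance(other, RasterGrid) else other
        if not self.spec.aligned_with(other_spec):
            other_name = other.name if isinstance(other, RasterGrid) else "grid spec"
            raise GridAlignmentError(
                f"rasters '{self.name}' and '{other_name}' are misaligned"
                + (f" ({context})" if context else "")
                + f": {self.spec} vs {other_spec}"
            )

    @property
    def n_nodata(self) -> int:
        return int(np.isnan(self.values).sum())
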