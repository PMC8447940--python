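"""Abundance estimation and independent validation.

Midden counts convert to squirrel numbers through the midden-territory
assumption: every territory holds one primary midden and possibly up to
``max_secondary`` secondary middens, so the population lies between
``n_middens / (1 + max_secondary)`` (floored) and ``n_middens``. All
arithmetic is exact before the final half-up rounding used for reporting;
the raw values are always retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .grids import RasterGrid

__all__ = ["AbundanceEstimate", "abundance_summary", "ValidationReport",
           "validate_points", "round_half_up"]


def round_half_up(value: float, ndigits: int) -> float:
    """Decimal round-half-up (0.5 always rounds away from zero)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class AbundanceEstimate:
    """Densities, territory size and population bounds from a midden count."""

    n_middens: int
    area_ha: float
    max_secondary: int
    density_per_ha: float        # raw, middens / ha
    territory_ha: float          # raw, ha / midden
    pop_low: int
    pop_high: int
    density_range_per_ha: tuple[float, float]  # raw squirrels / ha

    @property
    def density_per_km2(self) -> float:
        return 100.0 * self.density_per_ha

    def rounded(self, density_dp: int = 2) -> dict:
        """Reporting view at printed precision (half-up)."""
        lo, hi = self.density_range_per_ha
        return {
            "n_middens": self.n_middens,
            "area_ha": self.area_ha,
            "density_per_ha": round_half_up(self.density_per_ha, density_dp),
            "density_per_km2": round_half_up(self.density_per_km2, 0),
            "territory_ha": round_half_up(self.territory_ha, 2),
            "pop_low": self.pop_low,
            "pop_high": self.pop_high,
            "density_low_per_ha": round_half_up(lo, 2),
            "density_high_per_ha": round_half_up(hi, 2),
        }


def abundance_summary(n_middens: int, area_ha: float,
                      max_secondary: int = 3) -> AbundanceEstimate:
    """Abundance estimate from a midden count over an area.

    ``density = n / area``; mean territory ``area / n``; population between
    ``floor(n / (1 + max_secondary))`` (every squirrel holds the maximum
    number of secondary middens) and ``n`` (one midden per squirrel).
    """
    if n_middens < 1:
        raise ValueError("need at least one midden")
    if area_ha <= 0:
        raise ValueError("area must be positive")
    if max_secondary < 0:
        raise ValueError("max_secondary must be >= 0")
    pop_high = n_middens
    pop_low = n_middens // (1 + max_secondary)
    return AbundanceEstimate(
        n_middens=n_middens,
        area_ha=area_ha,
        max_secondary=max_secondary,
        density_per_ha=n_middens / area_ha,
        territory_ha=area_ha / n_middens,
        pop_low=pop_low,
        pop_high=pop_high,
        density_range_per_ha=(pop_low / area_ha, pop_high / area_ha),
    )


@dataclass
class ValidationReport:
    """RIO statistics of an independent presence set vs the scored lattice."""

    n_points: int
    mean: float
    min: float
    max: float
    q1: float
    q3: float
    grid_mean: float
    frac_above_grid_mean: float

    def to_dict(self) -> dict:
        return {
            "n_points": self.n_points,
            "mean": self.mean,
            "min": self.min,
            "max": self.max,
            "q1": self.q1,
            "q3": self.q3,
            "grid_mean": self.grid_mean,
            "frac_above_grid_mean": self.frac_above_grid_mean,
        }


def validate_points(surface: RasterGrid, points: np.ndarray,
                    lattice_scores: np.ndarray) -> ValidationReport:
    """Score an independent point set against the RIO surface.

    Extracts the RIO at each point (containing cell) and summarizes it
    (min, Q1, mean, Q3, max; quartiles by linear interpolation between
    order statistics). ``frac_above_grid_mean`` is the fraction of point
    RIOs strictly greater than the mean of all scored-lattice values — the
    better-than-random check.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(pts) == 0:
        raise ValueError("validation point set is empty")
    rio = surface.sample(pts[:, 0], pts[:, 1])
    if np.isnan(rio).any():
        raise ValueError("validation point falls on a no-data cell")
    grid_mean = float(np.mean(np.asarray(lattice_scores, dtype=float)))
    return ValidationReport(
        n_points=len(pts),
        mean=float(np.mean(rio)),
        min=float(np.min(rio)),
        max=float(np.max(rio)),
        q1=float(np.quantile(rio, 0.25)),  # linear (type-7) interpolation
        q3=float(np.quantile(rio, 0.75)),
        grid_mean=grid_mean,
        frac_above_grid_mean=float(np.mean(rio > grid_mean)),
    )
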