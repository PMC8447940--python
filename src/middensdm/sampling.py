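"""Training "data cube": presences, pseudo-absences, extraction, weights.

The sample table is a pandas DataFrame with columns
``id, x, y, label, weight`` plus one column per predictor layer. Labels
are 1 (midden presence) and 0 (pseudo-absence); after balancing, the
summed weight of each class is equal, which is how the imbalanced
presence/background design (e.g. ~198 presences against 600 random
background points) is handed to the classifier.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import shapely
from shapely.geometry.base import BaseGeometry

from .rasters import PredictorStack

__all__ = [
    "random_absences",
    "extract_values",
    "balance_weights",
    "build_sample_table",
    "sampling_density_per_ha",
    "META_COLUMNS",
]

META_COLUMNS = ("id", "x", "y", "label", "weight")


def random_absences(area_polygon: BaseGeometry, n: int, seed: int,
                    *, presences: np.ndarray | None = None,
                    min_dist: float = 0.0) -> np.ndarray:
    """``n`` pseudo-absence points uniform over the polygon.

    Rejection sampling from the bounding box, deterministic per seed.
    ``min_dist`` optionally excludes candidates within that distance of a
    presence point (off by default: random background points stand in for
    absences as-is).
    """
    if n < 1:
        raise ValueError("need n >= 1 absence points")
    if area_polygon.is_empty or area_polygon.area <= 0:
        raise ValueError("degenerate area polygon")
    minx, miny, maxx, maxy = area_polygon.bounds
    rng = np.random.default_rng(seed)
    out = np.empty((0, 2))
    guard = 0
    while len(out) < n:
        m = max(2 * (n - len(out)), 64)
        cand = np.column_stack([rng.uniform(minx, maxx, m),
                                rng.uniform(miny, maxy, m)])
        ok = shapely.contains_xy(area_polygon, cand[:, 0], cand[:, 1])
        cand = cand[ok]
        if min_dist > 0 and presences is not None and len(presences):
            d2 = ((cand[:, None, :] - presences[None, :, :]) ** 2).sum(axis=2)
            cand = cand[d2.min(axis=1) >= min_dist ** 2]
        out = np.vstack([out, cand])
        guard += 1
        if guard > 10000:
            raise RuntimeError("rejection sampling failed to fill the polygon")
    return out[:n]


def extract_values(points: pd.DataFrame, stack: PredictorStack) -> pd.DataFrame:
    """Attach containing-cell predictor values to every point.

    Pure function of (points, stack); nearest-cell lookup with the
    half-open edge rule, erroring on points outside the extent or on
    no-data cells.
    """
    table = points.copy().reset_index(drop=True)
    values = stack.extract(table["x"].to_numpy(), table["y"].to_numpy())
    for name in stack.names:
        table[name] = values[name]
    return table


def balance_weights(table: pd.DataFrame) -> pd.DataFrame:
    """Class-balancing weights: absence weight 1, presence weight
    n_absence / n_presence, so both classes carry equal total weight."""
    labels = table["label"].to_numpy()
    n1 = int(np.sum(labels == 1))
    n0 = int(np.sum(labels == 0))
    if n1 == 0 or n0 == 0:
        raise ValueError(f"both classes required: {n1} presences, {n0} absences")
    out = table.copy()
    out["weight"] = np.where(labels == 1, n0 / n1, 1.0)
    return out


def build_sample_table(presences: np.ndarray, absences: np.ndarray,
                       stack: PredictorStack) -> pd.DataFrame:
    """Assemble, extract and balance the full data cube."""
    pres = pd.DataFrame({"x": presences[:, 0], "y": presences[:, 1], "label": 1})
    absn = pd.DataFrame({"x": absences[:, 0], "y": absences[:, 1], "label": 0})
    table = pd.concat([pres, absn], ignore_index=True)
    table.insert(0, "id", np.arange(len(table)))
    table = extract_values(table, stack)
    table = balance_weights(table)
    ordered = [c for c in META_COLUMNS if c in table.columns]
    ordered += [c for c in table.columns if c not in ordered]
    return table[ordered]


def sampling_density_per_ha(n_points: int, area_m2: float) -> float:
    """Background sampling density in points per hectare."""
    if area_m2 <= 0:
        raise ValueError("area must be positive")
    return n_points / (area_m2 / 1e4)
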