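"""Classified LIDAR point clouds.

A cloud is a flat table of returns (x, y, z, class) with the closed class
set {ground, vegetation, unclassified}. Providers often leave a sizeable
share of vegetated returns unclassified; :func:`merge_vegetation` folds
them into the vegetation class before any gridding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PointCloud", "CLASSES", "GROUND", "VEGETATION", "UNCLASSIFIED",
           "merge_vegetation"]

GROUND = 0
VEGETATION = 1
UNCLASSIFIED = 2

CLASSES = {"ground": GROUND, "vegetation": VEGETATION, "unclassified": UNCLASSIFIED}
CLASS_NAMES = {v: k for k, v in CLASSES.items()}


@dataclass
class PointCloud:
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    klass: np.ndarray  # integer codes from CLASSES

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.float64)
        self.z = np.asarray(self.z, dtype=np.float64)
        self.klass = np.asarray(self.klass, dtype=np.int8)
        n = self.x.shape[0]
        if not (self.y.shape[0] == self.z.shape[0] == self.klass.shape[0] == n):
            raise ValueError("x, y, z, class arrays must have equal length")
        for arr, label in ((self.x, "x"), (self.y, "y"), (self.z, "z")):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite {label} coordinate in point cloud")
        if n and not np.isin(self.klass, list(CLASSES.values())).all():
            raise ValueError("point class outside {ground, vegetation, unclassified}")

    def __len__(self) -> int:
        return int(self.x.shape[0])

    def select(self, mask: np.ndarray) -> "PointCloud":
        return PointCloud(self.x[mask], self.y[mask], self.z[mask], self.klass[mask])

    def class_counts(self) -> dict[str, int]:
        return {name: int(np.sum(self.klass == code)) for name, code in CLASSES.items()}


def merge_vegetation(cloud: PointCloud) -> PointCloud:
    """Relabel every unclassified return as vegetation.

    Ground returns are untouched and the return count is preserved; the
    operation is idempotent. This mirrors the standard treatment of
    provider-classified clouds where the unclassified and vegetation
    classes together represent all vegetation.
    """
    klass = cloud.klass.copy()
    klass[klass == UNCLASSIFIED] = VEGETATION
    return PointCloud(cloud.x.copy(), cloud.y.copy(), cloud.z.copy(), klass)
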