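"""Named vector feature classes (lake, trails, dog trail, highway, buildings).

Geometries are shapely objects in planar meter coordinates. The five class
names are fixed because each one becomes a proximity (Euclidean distance)
predictor with a fixed layer name downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import shapely
from shapely.geometry.base import BaseGeometry

__all__ = ["FeatureSet", "FEATURE_CLASSES"]

FEATURE_CLASSES = ("lake", "trails", "dogtrail", "highway", "buildings")


@dataclass
class FeatureSet:
    """Mapping of feature-class name -> list of shapely geometries."""

    classes: dict[str, list[BaseGeometry]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in FEATURE_CLASSES:
            self.classes.setdefault(name, [])
        for name, geoms in self.classes.items():
            for g in geoms:
                if not g.is_valid:
                    raise ValueError(f"invalid geometry in feature class '{name}'")

    def __getitem__(self, name: str) -> list[BaseGeometry]:
        return self.classes[name]

    def non_empty(self, name: str) -> list[BaseGeometry]:
        geoms = self.classes.get(name, [])
        if not geoms:
            raise ValueError(f"feature class '{name}' is empty")
        return geoms

    def all_within(self, bounds: tuple[float, float, float, float]) -> bool:
        box = shapely.box(*bounds)
        return all(
            box.covers(g) for geoms in self.classes.values() for g in geoms
        )
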