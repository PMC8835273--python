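"""Spatial indicators of a study unit, computed from measured primitives.

The field survey delivers scalar measurements per unit (perimeters, areas,
panorama extents, vegetation counts); photo segmentation and CAD work happen
upstream.  These operations turn the primitives into the unitless indicator
set: space enclosure, tree cover, the two 125-degree-panorama proportions
(visual obstacles, green view index) and Shannon-Wiener vegetation
diversity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "UnitGeometry",
    "VegetationCensus",
    "space_enclosure",
    "tree_cover",
    "panorama_fraction",
    "shannon_diversity",
]


@dataclass(frozen=True)
class UnitGeometry:
    """Measured geometric primitives of one study unit.

    ``enclosed_perimeter_m`` is the boundary length backed by qualifying
    vegetation or bottom elements; ``tree_projection_m2`` the summed
    vertical tree-crown projection.
    """

    perimeter_m: float
    enclosed_perimeter_m: float
    site_area_m2: float
    tree_projection_m2: float
    visible_extent: float = 0.0
    total_view_extent: float = 0.0
    green_extent: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.enclosed_perimeter_m <= self.perimeter_m:
            raise ValueError("enclosed perimeter must lie in [0, perimeter]")
        if not 0 <= self.tree_projection_m2 <= self.site_area_m2:
            raise ValueError("tree projection must lie in [0, site area]")
        for part in (self.visible_extent, self.green_extent):
            if part < 0 or (self.total_view_extent and part > self.total_view_extent):
                raise ValueError("panorama part extents must lie in [0, total]")


@dataclass(frozen=True)
class VegetationCensus:
    """Vegetation species counts in one unit."""

    species_counts: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        if not self.species_counts:
            raise ValueError("census needs at least one species")
        if any(n < 1 for _, n in self.species_counts):
            raise ValueError("species counts must be >= 1")

    @property
    def total(self) -> int:
        return sum(n for _, n in self.species_counts)


def space_enclosure(geom: UnitGeometry) -> float:
    """Enclosed-perimeter ratio L1/L in [0, 1]."""
    if geom.perimeter_m <= 0:
        raise ValueError("unit perimeter must be positive")
    return geom.enclosed_perimeter_m / geom.perimeter_m


def tree_cover(geom: UnitGeometry) -> float:
    """Tree-crown projection ratio S1/S in [0, 1]."""
    if geom.site_area_m2 <= 0:
        raise ValueError("unit site area must be positive")
    return geom.tree_projection_m2 / geom.site_area_m2


def panorama_fraction(part_extent: float, total_extent: float) -> float:
    """Percent of the 125-degree panorama covered by ``part_extent``.

    Serves both the visible-space proportion (visual obstacles) and the
    greenery proportion (green view index).
    """
    if total_extent <= 0:
        raise ValueError("total panorama extent must be positive")
    if part_extent < 0 or part_extent > total_extent:
        raise ValueError("part extent must lie in [0, total]")
    return 100.0 * part_extent / total_extent


def shannon_diversity(census: VegetationCensus) -> float:
    """Shannon-Wiener index H = -sum_i p_i ln p_i over species proportions.

    Natural-log units (nats): 0 for a single species, at most ln(k) for k
    species.
    """
    counts = np.array([n for _, n in census.species_counts], dtype=float)
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())
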