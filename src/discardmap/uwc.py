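"""Unwanted-catch hotspot layers and the Persistence Index (PI).

A multi-year series of per-cell density surfaces (e.g. juvenile density
from trawl surveys) is reduced to yearly hotspot masks by a quantile rule:
a cell is a hotspot in a year iff its density strictly exceeds the q-th
quantile of that year's positive-density cells (default q = 0.9).  The
Persistence Index of a cell is the fraction of years in which it was a
hotspot; PI = 0 means a hotspot was never observed there, PI = 1 that the
cell was a hotspot every year.

The quantile rule is a pluggable stand-in for survey-specific hotspot
delineations (e.g. thresholds on kriged density); externally supplied UWC
polygon layers with a precomputed PI can be rasterized onto the grid
instead (majority-area overlap).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union

from .grid import StudyGrid

logger = logging.getLogger(__name__)

#: Default hotspot quantile over positive-density cells.
DEFAULT_HOTSPOT_QUANTILE = 0.9


@dataclass
class DensitySurface:
    """Per-cell density of one species in one year (units arbitrary, >= 0)."""

    species: str
    year: int
    values: dict[int, float] = field(default_factory=dict)

    def __post_init__(self):
        bad = {
            c: v for c, v in self.values.items() if not np.isfinite(v) or v < 0
        }
        if bad:
            raise ValueError(f"negative/non-finite densities: {bad}")


@dataclass
class HotspotLayer:
    species: str
    year: int
    flags: dict[int, bool] = field(default_factory=dict)


@dataclass
class PersistenceLayer:
    """PI per cell: fraction of years flagged as hotspot, on {0, 1/n, ..., 1}."""

    species: str
    years: list[int]
    pi: dict[int, float] = field(default_factory=dict)


def classify_hotspots(
    surface: DensitySurface, q: float = DEFAULT_HOTSPOT_QUANTILE
) -> HotspotLayer:
    """Flag cells whose density strictly exceeds the q-quantile of positive cells.

    A constant positive surface has no cell above its own quantile, and an
    all-zero surface has no positive cells: both yield all-false flags.
    """
    if not 0.0 < q < 1.0:
        raise ValueError(f"quantile must be in (0, 1), got {q}")
    if not surface.values:
        raise ValueError("empty density surface")
    vals = np.array(list(surface.values.values()), dtype=float)
    positive = vals[vals > 0]
    if positive.size == 0:
        flags = {c: False for c in surface.values}
    else:
        thr = float(np.quantile(positive, q))
        flags = {c: v > thr for c, v in surface.values.items()}
    return HotspotLayer(surface.species, surface.year, flags)


def compute_persistence_index(layers: list[HotspotLayer]) -> PersistenceLayer:
    """PI per cell = (# years flagged) / (# years); order of years is immaterial."""
    if not layers:
        raise ValueError("need at least one yearly hotspot layer")
    species = {l.species for l in layers}
    if len(species) > 1:
        raise ValueError(f"mixed species: {sorted(species)}")
    years = [l.year for l in layers]
    if len(set(years)) != len(years):
        raise ValueError(f"duplicate years: {sorted(years)}")
    n = len(layers)
    cells = set()
    for l in layers:
        cells.update(l.flags)
    pi = {
        c: sum(1 for l in layers if l.flags.get(c, False)) / n for c in sorted(cells)
    }
    return PersistenceLayer(species.pop(), sorted(years), pi)


def polygonize_persistence(
    layer: PersistenceLayer,
    grid: StudyGrid,
    min_pi: float,
    connectivity: int = 4,
) -> list[dict]:
    """Dissolve contiguous same-PI cells with PI >= min_pi into polygons.

    Returns features ``{"species", "pi", "n_cells", "geometry"}``, ordered
    by PI then smallest cell id.  Contiguity follows the package-wide
    adjacency convention (4-connectivity by default).
    """
    from .overlap import connected_components  # shared adjacency convention

    if not 0.0 < min_pi <= 1.0:
        raise ValueError(f"min_pi must be in (0, 1], got {min_pi}")
    features = []
    by_value: dict[float, set[int]] = {}
    for cid, v in layer.pi.items():
        if v >= min_pi and 0 <= cid < len(grid):
            by_value.setdefault(round(v, 12), set()).add(cid)
    for value in sorted(by_value):
        for comp in connected_components(by_value[value], grid, connectivity):
            geom: BaseGeometry = unary_union(
                [grid.cells.iloc[c].geometry for c in sorted(comp)]
            )
            features.append(
                {
                    "species": layer.species,
                    "pi": value,
                    "n_cells": len(comp),
                    "geometry": geom,
                }
            )
    return features


def rasterize_uwc_polygons(
    features: list[dict], grid: StudyGrid, species: str
) -> PersistenceLayer:
    """Rasterize external UWC polygons (attributes species, pi) onto the grid.

    Each cell takes the PI of the feature covering the largest share of its
    area (majority-area overlap); uncovered cells get PI 0.  Years are
    unknown for external layers and reported as an empty list.
    """
    pi: dict[int, float] = {}
    mine = [f for f in features if f.get("species") == species]
    for row in grid.cells.itertuples():
        best_area, best_pi = 0.0, 0.0
        for f in mine:
            a = row.geometry.intersection(f["geometry"]).area
            if a > best_area:
                best_area, best_pi = a, float(f["pi"])
        pi[row.cell_id] = best_pi
    return PersistenceLayer(species, [], pi)
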