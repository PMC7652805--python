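"""Threshold overlap analysis: effort range × PI range, contiguous unions.

The overlap analysis is the crisp counterpart of the fuzzy overlay: the
user picks one effort metric with a closed threshold range and one species'
PI layer with a closed range; cells passing both filters are selected,
grouped into maximal contiguous components (edge-sharing adjacency by
default), summarized in a statistics table, and exportable as polygon
features.  Cells with no recorded effort count as effort 0, so a range
starting at 0 includes them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union

from .grid import StudyGrid, TimeFrame
from .effort import METRICS, EffortLayer
from .uwc import PersistenceLayer

logger = logging.getLogger(__name__)

DEFAULT_CONNECTIVITY = 4


@dataclass(frozen=True)
class OverlapQuery:
    """Closed threshold ranges on one effort metric and one species' PI."""

    metric: str
    effort_range: tuple[float, float]
    species: str
    uwc_range: tuple[float, float]
    frame: TimeFrame

    def __post_init__(self):
        if self.metric not in METRICS:
            raise ValueError(f"unknown metric {self.metric!r}; one of {METRICS}")
        for name, (lo, hi) in (
            ("effort_range", self.effort_range),
            ("uwc_range", self.uwc_range),
        ):
            if lo > hi:
                raise ValueError(f"{name}: lo {lo} > hi {hi}")


@dataclass
class OverlapResult:
    query: OverlapQuery
    selected_cells: set[int]
    components: list[set[int]]
    geometry: list[BaseGeometry]  # one dissolved polygon per component
    stats: dict


def select_cells(
    effort: EffortLayer,
    pi: PersistenceLayer,
    query: OverlapQuery,
    grid: StudyGrid,
) -> set[int]:
    """Grid cells with effort and PI both inside their closed ranges."""
    if effort.metric != query.metric:
        raise ValueError(
            f"effort layer metric {effort.metric!r} != query metric {query.metric!r}"
        )
    if effort.frame != query.frame:
        raise ValueError(f"effort frame {effort.frame} != query frame {query.frame}")
    if pi.species != query.species:
        raise ValueError(
            f"PI layer species {pi.species!r} != query species {query.species!r}"
        )
    elo, ehi = query.effort_range
    ulo, uhi = query.uwc_range
    out = set()
    for cid in grid.cell_ids:
        cid = int(cid)
        e = effort.get(cid)
        u = pi.pi.get(cid, 0.0)
        if elo <= e <= ehi and ulo <= u <= uhi:
            out.add(cid)
    return out


def connected_components(
    cells: set[int], grid: StudyGrid, connectivity: int = DEFAULT_CONNECTIVITY
) -> list[set[int]]:
    """Maximal contiguous groups of the given cells, ordered by smallest id.

    Adjacency is 4-connectivity (shared edge) by default; 8 adds corners.
    """
    unknown = {c for c in cells if c < 0 or c >= len(grid)}
    if unknown:
        raise ValueError(f"cells not in grid: {sorted(unknown)}")
    remaining = set(cells)
    components: list[set[int]] = []
    while remaining:
        seed = min(remaining)
        comp = {seed}
        queue = [seed]
        remaining.discard(seed)
        while queue:
            cur = queue.pop()
            for nb in grid.neighbors(cur, connectivity):
                if nb in remaining:
                    remaining.discard(nb)
                    comp.add(nb)
                    queue.append(nb)
        components.append(comp)
    return sorted(components, key=min)


def overlap_stats(
    selected: set[int],
    components: list[set[int]],
    effort: EffortLayer,
    pi: PersistenceLayer,
    grid: StudyGrid,
) -> dict:
    """Summary statistics of a selection.

    Keys: n_cells, n_components, total_area_km2, effort_min/mean/max,
    pi_min/mean/max, effort_share_pct (share of the frame's total effort
    inside the selection).  Means over an empty selection are None.
    """
    areas = grid.cells["area_km2"]
    stats: dict = {
        "n_cells": len(selected),
        "n_components": len(components),
        "total_area_km2": float(areas.iloc[sorted(selected)].sum()) if selected else 0.0,
    }
    total_effort = effort.total()
    if selected:
        evals = np.array([effort.get(c) for c in sorted(selected)])
        uvals = np.array([pi.pi.get(c, 0.0) for c in sorted(selected)])
        stats.update(
            effort_min=float(evals.min()),
            effort_mean=float(evals.mean()),
            effort_max=float(evals.max()),
            pi_min=float(uvals.min()),
            pi_mean=float(uvals.mean()),
            pi_max=float(uvals.max()),
            effort_share_pct=(
                100.0 * float(evals.sum()) / total_effort if total_effort > 0 else 0.0
            ),
        )
    else:
        stats.update(
            effort_min=0.0, effort_mean=None, effort_max=0.0,
            pi_min=0.0, pi_mean=None, pi_max=0.0,
            effort_share_pct=0.0,
        )
    return stats


def overlap_analysis(
    effort: EffortLayer,
    pi: PersistenceLayer,
    query: OverlapQuery,
    grid: StudyGrid,
    connectivity: int = DEFAULT_CONNECTIVITY,
) -> OverlapResult:
    """Run the full threshold overlap analysis for one query."""
    selected = select_cells(effort, pi, query, grid)
    components = connected_components(selected, grid, connectivity)
    geometry = [
        unary_union([grid.cells.iloc[c].geometry for c in sorted(comp)])
        for comp in components
    ]
    stats = overlap_stats(selected, components, effort, pi, grid)
    logger.info(
        "overlap %s %s: %d cells in %d components",
        query.metric, query.frame, stats["n_cells"], stats["n_components"],
    )
    return OverlapResult(query, selected, components, geometry, stats)


def export_selection(result: OverlapResult, path, grid: StudyGrid) -> None:
    """Write the component polygons as a GeoJSON FeatureCollection.

    One feature per contiguous component, with attributes component_id,
    n_cells and area_km2.  An empty result writes a valid empty layer.
    """
    from .io import write_feature_collection

    areas = grid.cells["area_km2"]
    features = [
        {
            "component_id": k,
            "n_cells": len(comp),
            "area_km2": float(areas.iloc[sorted(comp)].sum()),
            "geometry": geom,
        }
        for k, (comp, geom) in enumerate(zip(result.components, result.geometry))
    ]
    write_feature_collection(features, path)
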