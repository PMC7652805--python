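"""Spatial reference frame: c-squares codes and the study grid.

The c-squares scheme (Rees 2003) names every cell of a hierarchical global
lat/lon grid with a short string: a global-quadrant digit, a 10-degree
lat/lon digit pair, then colon-separated refinement cycles.  Each cycle
either divides the current square in four (a single intermediate-quadrant
digit, halving the resolution) or in a hundred (intermediate-quadrant digit
plus a lat and a lon digit, dividing the resolution by ten).  The supported
resolution ladder is therefore 10, 5, 1, 0.5, 0.1, 0.05, 0.01, 0.005,
0.001 degrees.

Cells are half-open ``[lo, hi)`` in both axes, so every point belongs to
exactly one cell; ``lat = 90`` and ``lon = 180`` clamp into the last cell,
and points on the equator / prime meridian fall in the non-negative
quadrant.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import box as shapely_box
from shapely.geometry.base import BaseGeometry
from shapely.validation import explain_validity

logger = logging.getLogger(__name__)

#: Authalic (equal-area) Earth radius, km.
EARTH_RADIUS_KM = 6371.0088

#: Supported c-squares cell sizes, decimal degrees.
RESOLUTIONS = (10.0, 5.0, 1.0, 0.5, 0.1, 0.05, 0.01, 0.005, 0.001)

# Everything positional is done on a milli-degree integer lattice so that
# half-open cell membership does not depend on binary rounding of values
# like 0.05 or 0.15.
_SCALE = 1000


class CSquareError(ValueError):
    """Invalid c-square code or unsupported coordinates/resolution."""


def _resolution_scaled(resolution: float) -> int:
    """Resolution in milli-degrees, validated against the ladder."""
    for r in RESOLUTIONS:
        if math.isclose(resolution, r, rel_tol=1e-9):
            return round(r * _SCALE)
    raise CSquareError(
        f"unsupported resolution {resolution!r}; supported: {RESOLUTIONS}"
    )


def _axis_index(value_deg: float, res_s: int, limit_deg: int) -> int:
    """Half-open lattice index floor(value/res), clamped at the upper edge.

    Values are snapped to 1e-9 degrees first so that decimal inputs that
    are not binary-exact (0.15, 41.77, ...) land on the intended lattice
    line rather than an ulp below it.
    """
    scaled = round(value_deg * _SCALE, 6)
    idx = math.floor(scaled / res_s)
    n = (limit_deg * _SCALE) // res_s
    return min(max(idx, -n), n - 1)


def _indices(lat: float, lon: float, res_s: int) -> tuple[int, int]:
    return _axis_index(lat, res_s, 90), _axis_index(lon, res_s, 180)


def _code_from_indices(ilat: int, ilon: int, res_s: int) -> str:
    """Build the c-square string for the cell at the given lattice indices."""
    m = (10 * _SCALE) // res_s  # cells per 10-degree square
    north, east = ilat >= 0, ilon >= 0
    quadrant = {(True, True): 1, (False, True): 3,
                (False, False): 5, (True, False): 7}[(north, east)]
    alat = ilat if north else -ilat - 1
    alon = ilon if east else -ilon - 1
    parts = [f"{quadrant}{alat // m}{alon // m:02d}"]
    rlat, rlon = alat % m, alon % m
    size = m
    while size > 1:
        half = size // 2
        iq = 1 + (2 if rlat >= half else 0) + (1 if rlon >= half else 0)
        if size == 2:  # final halving cycle (5, 0.5, 0.005 degrees)
            parts.append(f":{iq}")
            size = 1
        else:
            sub = size // 10
            dlat, dlon = rlat // sub, rlon // sub
            parts.append(f":{iq}{dlat}{dlon}")
            rlat -= dlat * sub
            rlon -= dlon * sub
            size = sub
    return "".join(parts)


def encode_csquare(lat: float, lon: float, resolution: float) -> str:
    """C-square code of the grid cell containing (lat, lon).

    Cells are half-open to the north/east; lat 90 / lon 180 clamp into the
    last row/column.

    >>> encode_csquare(0.5, 0.5, 10)
    '1000'
    >>> encode_csquare(-42.88, 147.33, 0.5)
    '3414:227:3'
    """
    if not (math.isfinite(lat) and -90.0 <= lat <= 90.0):
        raise CSquareError(f"latitude {lat!r} outside [-90, 90]")
    if not (math.isfinite(lon) and -180.0 <= lon <= 180.0):
        raise CSquareError(f"longitude {lon!r} outside [-180, 180]")
    res_s = _resolution_scaled(resolution)
    ilat, ilon = _indices(lat, lon, res_s)
    return _code_from_indices(ilat, ilon, res_s)


_CODE_RE = re.compile(r"([1357])(\d)(\d{2})((?::\d{1,3})*)")


def decode_csquare(code: str) -> tuple[float, float, float, float]:
    """Bounding box (lat_min, lat_max, lon_min, lon_max) of a c-square.

    >>> decode_csquare("1000")
    (0.0, 10.0, 0.0, 10.0)
    """
    if not isinstance(code, str):
        raise CSquareError(f"c-square code must be a string, got {type(code)}")
    m = _CODE_RE.fullmatch(code)
    if m is None:
        raise CSquareError(f"malformed c-square code {code!r}")
    quadrant = int(m.group(1))
    tens_lat, tens_lon = int(m.group(2)), int(m.group(3))
    if tens_lat > 8:
        raise CSquareError(f"latitude tens digit out of range in {code!r}")
    if tens_lon > 17:
        raise CSquareError(f"longitude tens digit out of range in {code!r}")
    cycles = [p for p in m.group(4).split(":") if p]
    n_full = sum(1 for p in cycles if len(p) == 3)
    n_half = sum(1 for p in cycles if len(p) == 1)
    if n_half > 1 or (n_half == 1 and len(cycles[-1]) != 1):
        raise CSquareError(f"misplaced quadrant-only cycle in {code!r}")
    if any(len(p) == 2 for p in cycles):
        raise CSquareError(f"two-digit cycle in {code!r}")
    res_s, rem = divmod(10 * _SCALE, 10 ** n_full * (2 if n_half else 1))
    if rem or res_s < 1:
        raise CSquareError(f"code {code!r} is finer than the supported ladder")

    m_cells = (10 * _SCALE) // res_s
    rlat = rlon = 0
    size = m_cells
    for part in cycles:
        iq = int(part[0])
        if not 1 <= iq <= 4:
            raise CSquareError(f"intermediate quadrant digit {iq} in {code!r}")
        if len(part) == 1:
            rlat += (size // 2) * (iq in (3, 4))
            rlon += (size // 2) * (iq in (2, 4))
            size = 1
        else:
            dlat, dlon = int(part[1]), int(part[2])
            if iq != 1 + 2 * (dlat >= 5) + (dlon >= 5):
                raise CSquareError(
                    f"quadrant digit inconsistent with lat/lon digits in {code!r}"
                )
            sub = size // 10
            rlat += dlat * sub
            rlon += dlon * sub
            size = sub
    alat_s = (tens_lat * m_cells + rlat) * res_s
    alon_s = (tens_lon * m_cells + rlon) * res_s
    if alat_s + res_s > 90 * _SCALE or alon_s + res_s > 180 * _SCALE:
        raise CSquareError(f"code {code!r} lies outside the globe")

    south, west = quadrant in (3, 5), quadrant in (5, 7)
    lat_lo, lat_hi = (-(alat_s + res_s), -alat_s) if south else (alat_s, alat_s + res_s)
    lon_lo, lon_hi = (-(alon_s + res_s), -alon_s) if west else (alon_s, alon_s + res_s)
    return (lat_lo / _SCALE, lat_hi / _SCALE, lon_lo / _SCALE, lon_hi / _SCALE)


def csquare_resolution(code: str) -> float:
    """Cell size in degrees implied by a code's structure."""
    lat_min, lat_max, _, _ = decode_csquare(code)
    return round(lat_max - lat_min, 6)


def cell_area_km2(lat_min: float, lat_max: float, lon_min: float, lon_max: float) -> float:
    """Area of a lat/lon rectangle on the authalic sphere, km^2.

    A = R^2 * (lon2 - lon1) * (sin lat2 - sin lat1), longitudes in radians.
    """
    dlon = math.radians(lon_max - lon_min)
    return (
        EARTH_RADIUS_KM ** 2
        * dlon
        * (math.sin(math.radians(lat_max)) - math.sin(math.radians(lat_min)))
    )


@dataclass(frozen=True)
class TimeFrame:
    """A quarterly or yearly aggregation window."""

    kind: str  # "quarter" | "year"
    year: int
    quarter: int | None = None

    def __post_init__(self):
        if self.kind not in ("quarter", "year"):
            raise ValueError(f"kind must be 'quarter' or 'year', got {self.kind!r}")
        if self.kind == "quarter":
            if self.quarter not in (1, 2, 3, 4):
                raise ValueError(f"quarter must be 1..4, got {self.quarter!r}")
        elif self.quarter is not None:
            raise ValueError("yearly frame must not carry a quarter")

    def __str__(self):
        return f"{self.year}" if self.kind == "year" else f"{self.year}Q{self.quarter}"


@dataclass
class StudyGrid:
    """Regular c-squares-aligned grid clipped to a study boundary.

    ``cells`` is a DataFrame with one row per cell: ``cell_id`` (stable
    0-based, ordered south-to-north then west-to-east), ``csquare``,
    ``ilat``/``ilon`` lattice indices, the bounding box, ``area_km2`` and a
    shapely ``geometry``.
    """

    boundary: BaseGeometry
    resolution: float
    cells: pd.DataFrame
    _by_index: dict[tuple[int, int], int] = field(repr=False, default_factory=dict)

    def __post_init__(self):
        if not self._by_index:
            self._by_index = {
                (r.ilat, r.ilon): r.cell_id for r in self.cells.itertuples()
            }

    def __len__(self):
        return len(self.cells)

    @property
    def cell_ids(self) -> np.ndarray:
        return self.cells["cell_id"].to_numpy()

    def cell(self, cell_id: int) -> pd.Series:
        return self.cells.iloc[cell_id]

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(lat, lon) arrays of cell centers, indexed by cell_id."""
        c = self.cells
        return (
            ((c["lat_min"] + c["lat_max"]) / 2).to_numpy(),
            ((c["lon_min"] + c["lon_max"]) / 2).to_numpy(),
        )

    def neighbors(self, cell_id: int, connectivity: int = 4) -> list[int]:
        """Adjacent cell ids under 4- (edge) or 8- (edge+corner) connectivity."""
        if connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        row = self.cells.iloc[cell_id]
        offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
        if connectivity == 8:
            offsets += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
        out = []
        for di, dj in offsets:
            hit = self._by_index.get((row.ilat + di, row.ilon + dj))
            if hit is not None:
                out.append(hit)
        return out


def build_grid(boundary: BaseGeometry, resolution: float = 0.05) -> StudyGrid:
    """Tile the boundary with c-squares-aligned cells of the given size.

    A lattice cell is kept iff its intersection with the boundary has
    positive area (cells merely touching the boundary's edge are excluded).
    """
    res_s = _resolution_scaled(resolution)
    if boundary is None or boundary.is_empty:
        raise ValueError("boundary polygon is empty")
    if boundary.geom_type not in ("Polygon", "MultiPolygon"):
        raise ValueError(f"boundary must be (Multi)Polygon, got {boundary.geom_type}")
    if not boundary.is_valid:
        raise ValueError(f"invalid boundary polygon: {explain_validity(boundary)}")

    res = res_s / _SCALE
    minx, miny, maxx, maxy = boundary.bounds
    i0 = math.floor(round(miny * _SCALE, 6) / res_s)
    i1 = math.floor(round(maxy * _SCALE, 6) / res_s)
    j0 = math.floor(round(minx * _SCALE, 6) / res_s)
    j1 = math.floor(round(maxx * _SCALE, 6) / res_s)

    rows = []
    for ilat in range(i0, i1 + 1):
        # integer milli-degree edges, so lattice lines hit decimal boundary
        # coordinates exactly instead of an ulp away
        lat_lo, lat_hi = (ilat * res_s) / _SCALE, ((ilat + 1) * res_s) / _SCALE
        for ilon in range(j0, j1 + 1):
            lon_lo, lon_hi = (ilon * res_s) / _SCALE, ((ilon + 1) * res_s) / _SCALE
            geom = shapely_box(lon_lo, lat_lo, lon_hi, lat_hi)
            inter = geom.intersection(boundary)
            if inter.is_empty or inter.area <= 1e-9 * geom.area:
                continue
            rows.append(
                dict(
                    ilat=ilat,
                    ilon=ilon,
                    csquare=_code_from_indices(ilat, ilon, res_s),
                    lat_min=lat_lo,
                    lat_max=lat_hi,
                    lon_min=lon_lo,
                    lon_max=lon_hi,
                    area_km2=cell_area_km2(lat_lo, lat_hi, lon_lo, lon_hi),
                    geometry=geom,
                )
            )
    if not rows:
        raise ValueError("boundary does not overlap any grid cell")
    cells = pd.DataFrame(rows).sort_values(["ilat", "ilon"], kind="mergesort")
    cells.insert(0, "cell_id", np.arange(len(cells)))
    cells = cells.reset_index(drop=True)
    logger.info("built grid: %d cells at %g deg", len(cells), res)
    return StudyGrid(boundary=boundary, resolution=res, cells=cells)


OUTSIDE = "outside"


def assign_points_to_cells(
    lats: np.ndarray, lons: np.ndarray, grid: StudyGrid
) -> np.ndarray:
    """Map points to grid cell_ids; points in no grid cell get ``-1``.

    Returns an int array (``-1`` encodes "outside"); use :data:`OUTSIDE`
    for a human-readable label.
    """
    res_s = round(grid.resolution * _SCALE)
    lats = np.asarray(lats, dtype=float)
    lons = np.asarray(lons, dtype=float)
    ilat = np.floor(np.round(lats * _SCALE, 6) / res_s).astype(int)
    ilon = np.floor(np.round(lons * _SCALE, 6) / res_s).astype(int)
    nlat, nlon = (90 * _SCALE) // res_s, (180 * _SCALE) // res_s
    ilat = np.clip(ilat, -nlat, nlat - 1)
    ilon = np.clip(ilon, -nlon, nlon - 1)
    out = np.full(len(lats), -1, dtype=int)
    for k in range(len(lats)):
        out[k] = grid._by_index.get((ilat[k], ilon[k]), -1)
    return out
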