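"""Gridded fishing-effort metrics from vessel tracks.

Four metrics, each per grid cell per quarter (aggregable to years):

* **fishing hours** — number of fishing-classified track points times the
  ping interval (default 10 min);
* **fishing days** — per vessel, one day for each UTC date with at least
  one fishing point; gridded by splitting each vessel-day across cells in
  proportion to that day's fishing-point counts;
* **nominal effort** — fishing days times engine power (kW·days), gridded
  like fishing days;
* **swept area** — for towed gears only: gear horizontal opening
  ``OFS = a·LOA + b`` (meters) times haul length, apportioned to cells by
  segment–cell intersection and reported in km².

Fishing activity is classified with a simple speed filter (a stand-in for
metier-aware track classifiers); the window is configurable and defaults
to 2–4.5 kn, typical of bottom otter trawling.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import LineString, box as shapely_box

from .grid import EARTH_RADIUS_KM, StudyGrid, TimeFrame, assign_points_to_cells

logger = logging.getLogger(__name__)

#: Default speed window (knots) classifying a ping as fishing, for trawlers.
DEFAULT_SPEED_WINDOW = (2.0, 4.5)

#: Default ping interval, minutes.
DEFAULT_INTERVAL_MIN = 10.0

#: Consecutive fishing pings further apart than this break the haul.
DEFAULT_MAX_GAP_MIN = 30.0

METRICS = ("fishing_hours", "fishing_days", "nominal_effort", "swept_area")
UNITS = {
    "fishing_hours": "hours",
    "fishing_days": "days",
    "nominal_effort": "kW·days",
    "swept_area": "km²",
}

TRACK_COLUMNS = ["vessel_id", "timestamp", "lat", "lon", "speed_kn"]


@dataclass
class GearModel:
    """Linear gear-width model: horizontal opening = a·LOA + b (meters)."""

    gear: str
    a: float
    b: float
    towed: bool

    def opening_m(self, loa_m: float) -> float:
        if not self.towed:
            raise ValueError(f"gear {self.gear} is not towed; no swept area")
        return self.a * loa_m + self.b


@dataclass
class EffortLayer:
    """One effort metric on the grid for one time frame.

    ``values`` maps cell_id -> non-negative value; absent cells are 0.
    """

    metric: str
    frame: TimeFrame
    values: dict[int, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.metric not in METRICS:
            raise ValueError(f"unknown metric {self.metric!r}; one of {METRICS}")
        bad = {c: v for c, v in self.values.items() if v < 0 or not math.isfinite(v)}
        if bad:
            raise ValueError(f"negative/non-finite effort values: {bad}")

    @property
    def units(self) -> str:
        return UNITS[self.metric]

    def get(self, cell_id: int) -> float:
        return self.values.get(cell_id, 0.0)

    def total(self) -> float:
        return float(sum(self.values.values()))


def clean_tracks(tracks: pd.DataFrame) -> pd.DataFrame:
    """Sort per vessel by timestamp and drop exact duplicate pings."""
    t = tracks.copy()
    t["timestamp"] = pd.to_datetime(t["timestamp"], utc=True)
    t = t.drop_duplicates(subset=["vessel_id", "timestamp"])
    return t.sort_values(["vessel_id", "timestamp"], kind="mergesort").reset_index(
        drop=True
    )


def classify_fishing_points(
    tracks: pd.DataFrame, speed_window: tuple[float, float] = DEFAULT_SPEED_WINDOW
) -> pd.DataFrame:
    """Flag pings as fishing iff lo <= speed_kn <= hi (inclusive).

    Pings with missing speed are dropped with a logged warning.
    """
    lo, hi = speed_window
    if not lo < hi:
        raise ValueError(f"speed window must satisfy lo < hi, got {speed_window}")
    t = tracks.copy()
    missing = t["speed_kn"].isna()
    if missing.any():
        logger.warning("dropping %d track points with missing speed", int(missing.sum()))
        t = t[~missing].copy()
    t["is_fishing"] = (t["speed_kn"] >= lo) & (t["speed_kn"] <= hi)
    return t


def assign_tracks_to_grid(tracks: pd.DataFrame, grid: StudyGrid) -> pd.DataFrame:
    """Attach cell_id (−1 = outside the grid) to every track point."""
    t = tracks.copy()
    t["cell_id"] = assign_points_to_cells(
        t["lat"].to_numpy(), t["lon"].to_numpy(), grid
    )
    n_out = int((t["cell_id"] < 0).sum())
    if n_out:
        logger.info("%d of %d track points fall outside the grid", n_out, len(t))
    return t


def _with_frames(t: pd.DataFrame) -> pd.DataFrame:
    ts = pd.to_datetime(t["timestamp"], utc=True)
    t = t.copy()
    t["year"] = ts.dt.year
    t["quarter"] = ts.dt.quarter
    t["date"] = ts.dt.date
    return t


def compute_fishing_hours(
    points: pd.DataFrame,
    grid: StudyGrid,
    interval_min: float = DEFAULT_INTERVAL_MIN,
) -> dict[TimeFrame, EffortLayer]:
    """Fishing hours per cell per quarter: point count × interval / 60."""
    t = _with_frames(points)
    t = t[t["is_fishing"] & (t["cell_id"] >= 0)]
    layers: dict[TimeFrame, EffortLayer] = {}
    for (year, quarter), g in t.groupby(["year", "quarter"]):
        frame = TimeFrame("quarter", int(year), int(quarter))
        counts = g.groupby("cell_id").size()
        layers[frame] = EffortLayer(
            "fishing_hours",
            frame,
            {int(c): float(n) * interval_min / 60.0 for c, n in counts.items()},
        )
    return layers


def _day_cell_shares(points: pd.DataFrame) -> pd.DataFrame:
    """Per (vessel, date): share of that day's in-grid fishing points per cell.

    Shares over cells sum to 1 for every vessel-day that has at least one
    in-grid fishing point; days fished entirely outside the grid still count
    as fishing days but have no cells to receive them.
    """
    f = points[points["is_fishing"] & (points["cell_id"] >= 0)]
    counts = (
        f.groupby(["vessel_id", "date", "year", "quarter", "cell_id"])
        .size()
        .rename("n")
        .reset_index()
    )
    counts["share"] = counts["n"] / counts.groupby(["vessel_id", "date"])[
        "n"
    ].transform("sum")
    return counts


def compute_fishing_days(
    points: pd.DataFrame, grid: StudyGrid
) -> tuple[dict[TimeFrame, EffortLayer], pd.DataFrame]:
    """Gridded fishing days per quarter plus the per-vessel FD table.

    A vessel accrues one fishing day for each UTC date with >= 1 fishing
    point; the day is attributed to cells proportionally to the vessel's
    fishing-point counts on that date.  The FD table has columns
    vessel_id, year, quarter, fishing_days.
    """
    t = _with_frames(points)
    fishing = t[t["is_fishing"]]
    fd = (
        fishing.groupby(["vessel_id", "year", "quarter"])["date"]
        .nunique()
        .rename("fishing_days")
        .reset_index()
    )
    shares = _day_cell_shares(t)
    layers: dict[TimeFrame, EffortLayer] = {}
    for (year, quarter), g in shares.groupby(["year", "quarter"]):
        frame = TimeFrame("quarter", int(year), int(quarter))
        vals = g.groupby("cell_id")["share"].sum()
        layers[frame] = EffortLayer(
            "fishing_days", frame, {int(c): float(v) for c, v in vals.items()}
        )
    return layers, fd


def compute_nominal_effort(
    points: pd.DataFrame, register: pd.DataFrame, grid: StudyGrid
) -> tuple[dict[TimeFrame, EffortLayer], dict]:
    """Nominal effort (kW·days) per cell per quarter.

    Each vessel-day contributes its engine power, split across cells like
    fishing days.  Vessels absent from the register are skipped with a
    warning; their ids are returned in the QC summary.
    """
    t = _with_frames(points)
    power = register.set_index("vessel_id")["power_kw"]
    shares = _day_cell_shares(t)
    known = shares["vessel_id"].isin(power.index)
    skipped = sorted(shares.loc[~known, "vessel_id"].unique().tolist())
    if skipped:
        logger.warning("vessels missing from register skipped: %s", skipped)
    shares = shares[known].copy()
    shares["kw_days"] = shares["share"] * shares["vessel_id"].map(power).astype(float)
    layers: dict[TimeFrame, EffortLayer] = {}
    for (year, quarter), g in shares.groupby(["year", "quarter"]):
        frame = TimeFrame("quarter", int(year), int(quarter))
        vals = g.groupby("cell_id")["kw_days"].sum()
        layers[frame] = EffortLayer(
            "nominal_effort", frame, {int(c): float(v) for c, v in vals.items()}
        )
    return layers, {"vessels_skipped": skipped}


def haversine_m(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance on the authalic sphere, meters."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dp, dl = p2 - p1, math.radians(lon2 - lon1)
    a = math.sin(dp / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dl / 2) ** 2
    return 2 * EARTH_RADIUS_KM * 1000.0 * math.asin(min(1.0, math.sqrt(a)))


def _segment_cell_fractions(
    lat1: float, lon1: float, lat2: float, lon2: float, grid: StudyGrid
) -> list[tuple[int, float]]:
    """Fraction of a track segment's length inside each grid cell.

    Fractions are measured along the segment in lon/lat space (they are
    ratios, so the spherical correction cancels for these short,
    near-straight segments).  A zero-length segment maps to its cell.
    """
    seg = LineString([(lon1, lat1), (lon2, lat2)])
    if seg.length == 0.0:
        cid = assign_points_to_cells(np.array([lat1]), np.array([lon1]), grid)[0]
        return [(int(cid), 1.0)] if cid >= 0 else []
    res = grid.resolution
    i0 = math.floor(min(lat1, lat2) / res) - 1
    i1 = math.floor(max(lat1, lat2) / res) + 1
    j0 = math.floor(min(lon1, lon2) / res) - 1
    j1 = math.floor(max(lon1, lon2) / res) + 1
    out = []
    for ilat in range(i0, i1 + 1):
        for ilon in range(j0, j1 + 1):
            cid = grid._by_index.get((ilat, ilon))
            if cid is None:
                continue
            cell = shapely_box(ilon * res, ilat * res, (ilon + 1) * res, (ilat + 1) * res)
            inter = seg.intersection(cell)
            if not inter.is_empty and inter.length > 0:
                out.append((cid, inter.length / seg.length))
    return out


def compute_swept_area(
    points: pd.DataFrame,
    register: pd.DataFrame,
    gear_models: dict[str, GearModel],
    grid: StudyGrid,
    max_gap_min: float = DEFAULT_MAX_GAP_MIN,
) -> tuple[dict[TimeFrame, EffortLayer], dict]:
    """Swept area (km²) per cell per quarter, towed gears only.

    Per vessel: OFS = a·LOA + b from its gear model; hauls are maximal runs
    of consecutive fishing pings with no intervening non-fishing ping and
    gaps <= ``max_gap_min``; each haul segment's great-circle length is
    apportioned to cells by intersection and multiplied by OFS.
    Non-towed gears (e.g. purse seine) produce no swept area; towed vessels
    with no gear model are skipped with a warning.
    """
    t = _with_frames(points).sort_values(["vessel_id", "timestamp"], kind="mergesort")
    reg = register.set_index("vessel_id")
    acc: dict[TimeFrame, dict[int, float]] = {}
    skipped: list[str] = []
    for vessel_id, track in t.groupby("vessel_id"):
        if vessel_id not in reg.index:
            skipped.append(str(vessel_id))
            continue
        gear = str(reg.loc[vessel_id, "gear"])
        model = gear_models.get(gear)
        if model is None or not model.towed:
            if model is None:
                skipped.append(str(vessel_id))
                logger.warning("vessel %s: no gear model for %s", vessel_id, gear)
            continue  # purse seines etc. contribute no swept area
        ofs_m = model.opening_m(float(reg.loc[vessel_id, "loa_m"]))
        ts = pd.to_datetime(track["timestamp"], utc=True)
        lat = track["lat"].to_numpy()
        lon = track["lon"].to_numpy()
        fishing = track["is_fishing"].to_numpy()
        for k in range(len(track) - 1):
            if not (fishing[k] and fishing[k + 1]):
                continue  # a non-fishing ping between fishing pings breaks the haul
            gap_min = (ts.iloc[k + 1] - ts.iloc[k]).total_seconds() / 60.0
            if gap_min > max_gap_min:
                continue
            length_m = haversine_m(lat[k], lon[k], lat[k + 1], lon[k + 1])
            if length_m == 0.0:
                continue
            frame = TimeFrame(
                "quarter", int(track["year"].iloc[k]), int(track["quarter"].iloc[k])
            )
            cell_vals = acc.setdefault(frame, {})
            for cid, frac in _segment_cell_fractions(
                lat[k], lon[k], lat[k + 1], lon[k + 1], grid
            ):
                swa_km2 = ofs_m * (length_m * frac) / 1e6
                cell_vals[cid] = cell_vals.get(cid, 0.0) + swa_km2
    layers = {
        frame: EffortLayer("swept_area", frame, vals) for frame, vals in acc.items()
    }
    return layers, {"vessels_skipped": sorted(set(skipped))}


def aggregate_effort(quarterly: list[EffortLayer]) -> EffortLayer:
    """Sum up to four quarterly layers of one metric/year into a yearly layer."""
    if not quarterly:
        raise ValueError("no quarterly layers to aggregate")
    metrics = {l.metric for l in quarterly}
    years = {l.frame.year for l in quarterly}
    if len(metrics) > 1:
        raise ValueError(f"mixed metrics: {sorted(metrics)}")
    if len(years) > 1:
        raise ValueError(f"mixed years: {sorted(years)}")
    quarters = [l.frame.quarter for l in quarterly]
    if any(l.frame.kind != "quarter" for l in quarterly):
        raise ValueError("aggregate_effort expects quarterly layers")
    if len(set(quarters)) != len(quarters):
        raise ValueError(f"duplicate quarters: {quarters}")
    out: dict[int, float] = {}
    for layer in quarterly:
        for cid, v in layer.values.items():
            out[cid] = out.get(cid, 0.0) + v
    return EffortLayer(metrics.pop(), TimeFrame("year", years.pop()), out)


def aggregate_all_years(
    layers: dict[TimeFrame, EffortLayer]
) -> dict[TimeFrame, EffortLayer]:
    """Yearly aggregation of a quarterly layer set, keyed by yearly frames."""
    by_year: dict[int, list[EffortLayer]] = {}
    for frame, layer in layers.items():
        by_year.setdefault(frame.year, []).append(layer)
    return {
        TimeFrame("year", y): aggregate_effort(ls) for y, ls in sorted(by_year.items())
    }
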