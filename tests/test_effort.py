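import math

import numpy as np
import pandas as pd
import pytest

from discardmap import (
    EffortLayer,
    GearModel,
    TimeFrame,
    aggregate_effort,
    assign_tracks_to_grid,
    classify_fishing_points,
    clean_tracks,
    compute_fishing_days,
    compute_fishing_hours,
    compute_nominal_effort,
    compute_swept_area,
    haversine_m,
)
from .conftest import make_track

OTB = {"OTB": GearModel("OTB", a=2.0, b=10.0, towed=True),
       "PS": GearModel("PS", a=float("nan"), b=float("nan"), towed=False)}


def _prep(track, grid, window=(2.0, 4.5)):
    t = clean_tracks(track)
    t = classify_fishing_points(t, window)
    return assign_tracks_to_grid(t, grid)


def register(rows):
    return pd.DataFrame(
        rows, columns=["vessel_id", "loa_m", "power_kw", "gear", "gear_secondary"]
    )


# ------------------------------------------------------------ classification

def test_speed_filter_window_semantics():
    t = make_track([(0.1, 0.1, 1.0), (0.1, 0.1, 3.0), (0.1, 0.1, 9.0)])
    out = classify_fishing_points(t, (2.0, 4.5))
    assert out["is_fishing"].tolist() == [False, True, False]


def test_speed_filter_empty_and_full_window():
    empty = make_track([])
    assert len(classify_fishing_points(empty.reindex(columns=empty.columns.tolist() or
                ["vessel_id", "timestamp", "lat", "lon", "speed_kn"]), (2, 4))) == 0
    t = make_track([(0.1, 0.1, s) for s in (0.0, 5.0, 20.0)])
    assert classify_fishing_points(t, (0.0, math.inf))["is_fishing"].all()


def test_speed_filter_drops_missing_speed(caplog):
    t = make_track([(0.1, 0.1, 3.0), (0.1, 0.1, np.nan)])
    with caplog.at_level("WARNING"):
        out = classify_fishing_points(t, (2.0, 4.5))
    assert len(out) == 1 and "missing speed" in caplog.text


def test_speed_filter_rejects_bad_window():
    with pytest.raises(ValueError):
        classify_fishing_points(make_track([]), (4.5, 2.0))


# ------------------------------------------------------------ fishing hours

def test_fishing_hours_thirty_points_is_five_hours(unit_grid):
    t = _prep(make_track([(0.1, 0.1, 3.0)] * 30), unit_grid)
    layers = compute_fishing_hours(t, unit_grid)
    (frame,) = layers
    assert frame == TimeFrame("quarter", 2014, 1)
    assert layers[frame].total() == pytest.approx(5.0)


def test_fishing_hours_split_between_cells(unit_grid):
    pts = [(0.1, 0.1, 3.0)] * 12 + [(0.7, 0.7, 3.0)] * 18
    t = _prep(make_track(pts), unit_grid)
    (layer,) = compute_fishing_hours(t, unit_grid).values()
    vals = sorted(layer.values.values())
    assert vals == [pytest.approx(2.0), pytest.approx(3.0)]


def test_fishing_hours_no_fishing_points(unit_grid):
    t = _prep(make_track([(0.1, 0.1, 9.0)] * 5), unit_grid)
    assert compute_fishing_hours(t, unit_grid) == {}


def test_fishing_hours_conservation(tiny_case, unit_grid):
    from discardmap import build_grid

    grid = build_grid(tiny_case["boundary"], 0.05)
    t = _prep(tiny_case["tracks"], grid)
    n = int((t["is_fishing"] & (t["cell_id"] >= 0)).sum())
    layers = compute_fishing_hours(t, grid)
    total = sum(l.total() for l in layers.values())
    assert total == pytest.approx(n * 10 / 60)


# -------------------------------------------------------------- fishing days

def test_fishing_days_one_per_date(unit_grid):
    pts = []
    for day in ("01", "02", "03"):
        pts.append(make_track([(0.1, 0.1, 3.0)] * 4, t0=f"2014-03-{day}T06:00:00Z"))
    t = _prep(pd.concat(pts, ignore_index=True), unit_grid)
    layers, fd = compute_fishing_days(t, unit_grid)
    (layer,) = layers.values()
    assert layer.total() == pytest.approx(3.0)
    assert fd["fishing_days"].tolist() == [3]


def test_fishing_days_many_points_single_date(unit_grid):
    t = _prep(make_track([(0.1, 0.1, 3.0)] * 100, step_min=1), unit_grid)
    layers, fd = compute_fishing_days(t, unit_grid)
    assert fd["fishing_days"].tolist() == [1]
    (layer,) = layers.values()
    assert layer.total() == pytest.approx(1.0)


def test_fishing_days_proportional_split(unit_grid):
    pts = [(0.1, 0.1, 3.0)] * 3 + [(0.7, 0.7, 3.0)] * 1
    t = _prep(make_track(pts), unit_grid)
    (layer,) = compute_fishing_days(t, unit_grid)[0].values()
    assert sorted(layer.values.values()) == [pytest.approx(0.25), pytest.approx(0.75)]


def test_fishing_days_bounded_by_calendar(tiny_case):
    from discardmap import build_grid

    grid = build_grid(tiny_case["boundary"], 0.05)
    t = _prep(tiny_case["tracks"], grid)
    _, fd = compute_fishing_days(t, grid)
    assert (fd["fishing_days"] <= 92).all()


# ----------------------------------------------------------- nominal effort

def test_nominal_effort_fd_times_power(unit_grid):
    pts = []
    for day in ("01", "02", "03"):
        pts.append(make_track([(0.1, 0.1, 3.0)] * 2, t0=f"2014-03-{day}T06:00:00Z"))
    t = _prep(pd.concat(pts, ignore_index=True), unit_grid)
    reg = register([("V1", 20.0, 200.0, "OTB", "")])
    layers, qc = compute_nominal_effort(t, reg, unit_grid)
    (layer,) = layers.values()
    assert layer.total() == pytest.approx(600.0)
    assert qc["vessels_skipped"] == []


def test_nominal_effort_two_vessels_additive(unit_grid):
    a = make_track([(0.1, 0.1, 3.0)] * 2, vessel="A", t0="2014-03-01T06:00:00Z")
    a2 = make_track([(0.1, 0.1, 3.0)] * 2, vessel="A", t0="2014-03-02T06:00:00Z")
    b = make_track([(0.1, 0.1, 3.0)] * 2, vessel="B", t0="2014-03-01T06:00:00Z")
    t = _prep(pd.concat([a, a2, b], ignore_index=True), unit_grid)
    reg = register([("A", 15.0, 100.0, "OTB", ""), ("B", 25.0, 400.0, "OTB", "")])
    (layer,) = compute_nominal_effort(t, reg, unit_grid)[0].values()
    assert layer.total() == pytest.approx(2 * 100 + 1 * 400)


def test_nominal_effort_missing_vessel_skipped(unit_grid, caplog):
    t = _prep(make_track([(0.1, 0.1, 3.0)] * 2), unit_grid)
    with caplog.at_level("WARNING"):
        layers, qc = compute_nominal_effort(
            t, register([("OTHER", 20.0, 200.0, "OTB", "")]), unit_grid
        )
    assert qc["vessels_skipped"] == ["V1"] and layers == {}


# --------------------------------------------------------------- swept area

def test_haversine_equator_hundredth_degree():
    assert haversine_m(0, 0, 0, 0.01) == pytest.approx(1111.9493, abs=0.01)


def test_swept_area_direct_product(unit_grid):
    # two fishing pings 0.01 deg apart on the equator, LOA 20 -> OFS 50 m
    t = _prep(make_track([(0.005, 0.1, 3.0), (0.005, 0.11, 3.0)]), unit_grid)
    reg = register([("V1", 20.0, 200.0, "OTB", "")])
    (layer,) = compute_swept_area(t, reg, OTB, unit_grid)[0].values()
    tl = haversine_m(0.005, 0.1, 0.005, 0.11)
    assert layer.total() == pytest.approx(50.0 * tl / 1e6, rel=1e-6)


def test_swept_area_purse_seine_excluded(unit_grid):
    t = _prep(make_track([(0.005, 0.1, 3.0), (0.005, 0.11, 3.0)]), unit_grid)
    reg = register([("V1", 20.0, 200.0, "PS", "")])
    layers, qc = compute_swept_area(t, reg, OTB, unit_grid)
    assert layers == {} and qc["vessels_skipped"] == []


def test_swept_area_unknown_gear_skipped_with_warning(unit_grid, caplog):
    t = _prep(make_track([(0.005, 0.1, 3.0), (0.005, 0.11, 3.0)]), unit_grid)
    reg = register([("V1", 20.0, 200.0, "DRB", "")])
    with caplog.at_level("WARNING"):
        layers, qc = compute_swept_area(t, reg, OTB, unit_grid)
    assert layers == {} and qc["vessels_skipped"] == ["V1"]


def test_swept_area_gap_and_nonfishing_break_haul(unit_grid):
    # second pair separated by 60 min: the haul is broken there
    t1 = make_track([(0.005, 0.1, 3.0), (0.005, 0.11, 3.0)])
    t2 = make_track([(0.005, 0.3, 3.0), (0.005, 0.31, 3.0)], t0="2014-03-01T10:00:00Z")
    t = _prep(pd.concat([t1, t2], ignore_index=True), unit_grid)
    reg = register([("V1", 20.0, 200.0, "OTB", "")])
    (layer,) = compute_swept_area(t, reg, OTB, unit_grid)[0].values()
    # 3 consecutive-pair candidates; the 20->10:00 gap pair is excluded
    tl = haversine_m(0, 0.1, 0, 0.11)
    assert layer.total() == pytest.approx(2 * 50.0 * tl / 1e6, rel=1e-4)


def test_swept_area_apportioned_across_cell_edge(unit_grid):
    # segment crossing lon=0.5 symmetric: half the area in each cell
    t = _prep(make_track([(0.25, 0.49, 3.0), (0.25, 0.51, 3.0)]), unit_grid)
    reg = register([("V1", 20.0, 200.0, "OTB", "")])
    (layer,) = compute_swept_area(t, reg, OTB, unit_grid)[0].values()
    v = list(layer.values.values())
    assert len(v) == 2 and v[0] == pytest.approx(v[1], rel=1e-9)


def test_swept_area_scales_linearly_in_loa(unit_grid):
    pts = [(0.005 + 0.001 * k, 0.1 + 0.01 * k, 3.0) for k in range(6)]
    t = _prep(make_track(pts), unit_grid)
    out = {}
    for loa in (20.0, 28.0):
        reg = register([("V1", loa, 200.0, "OTB", "")])
        (layer,) = compute_swept_area(t, reg, OTB, unit_grid)[0].values()
        out[loa] = layer
    ratio = (2.0 * 28.0 + 10.0) / (2.0 * 20.0 + 10.0)
    for cid, v in out[20.0].values.items():
        assert out[28.0].values[cid] == pytest.approx(v * ratio, rel=1e-12)


def test_widening_speed_window_monotone_per_cell(tiny_case):
    """More inclusive classification never lowers hours/SWA in any cell."""
    from discardmap import build_grid

    grid = build_grid(tiny_case["boundary"], 0.05)
    reg = tiny_case["fleet"]
    gears = OTB
    narrow = _prep(tiny_case["tracks"], grid, (2.5, 4.0))
    wide = _prep(tiny_case["tracks"], grid, (2.0, 4.5))
    for fn in (
        lambda t: compute_fishing_hours(t, grid),
        lambda t: compute_swept_area(t, reg, gears, grid)[0],
    ):
        ln, lw = fn(narrow), fn(wide)
        for frame, layer in ln.items():
            for cid, v in layer.values.items():
                assert lw[frame].get(cid) >= v - 1e-12
    _, fd_n = compute_fishing_days(narrow, grid)
    _, fd_w = compute_fishing_days(wide, grid)
    merged = fd_n.merge(fd_w, on=["vessel_id", "year", "quarter"], how="left")
    assert (merged["fishing_days_y"] >= merged["fishing_days_x"]).all()


# -------------------------------------------------------------- aggregation

def test_aggregate_quarters_to_year():
    frames = [TimeFrame("quarter", 2014, q) for q in (1, 2, 3, 4)]
    layers = [
        EffortLayer("fishing_hours", f, {0: v})
        for f, v in zip(frames, (1.0, 2.0, 0.0, 1.5))
    ]
    y = aggregate_effort(layers)
    assert y.frame == TimeFrame("year", 2014)
    assert y.values[0] == pytest.approx(4.5)


def test_aggregate_missing_quarter_is_zero():
    layers = [
        EffortLayer("fishing_hours", TimeFrame("quarter", 2014, q), {0: 1.0})
        for q in (1, 3)
    ]
    assert aggregate_effort(layers).values[0] == pytest.approx(2.0)


def test_aggregate_conserves_cell_totals(tiny_case):
    from discardmap import aggregate_all_years, build_grid

    grid = build_grid(tiny_case["boundary"], 0.05)
    t = _prep(tiny_case["tracks"], grid)
    quarterly = compute_fishing_hours(t, grid)
    yearly = aggregate_all_years(quarterly)
    assert sum(l.total() for l in yearly.values()) == pytest.approx(
        sum(l.total() for l in quarterly.values())
    )


@pytest.mark.parametrize(
    "layers",
    [
        [EffortLayer("fishing_hours", TimeFrame("quarter", 2014, 1), {}),
         EffortLayer("fishing_days", TimeFrame("quarter", 2014, 2), {})],
        [EffortLayer("fishing_hours", TimeFrame("quarter", 2014, 1), {}),
         EffortLayer("fishing_hours", TimeFrame("quarter", 2015, 2), {})],
        [EffortLayer("fishing_hours", TimeFrame("quarter", 2014, 1), {}),
         EffortLayer("fishing_hours", TimeFrame("quarter", 2014, 1), {})],
    ],
)
def test_aggregate_rejects_mixed_or_duplicate(layers):
    with pytest.raises(ValueError):
        aggregate_effort(layers)


def test_effort_layer_rejects_negative():
    with pytest.raises(ValueError):
        EffortLayer("fishing_hours", TimeFrame("year", 2014), {0: -1.0})
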