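import numpy as np
import pandas as pd
import pytest
from hypothesis import settings
from shapely.geometry import box

from discardmap import SynthConfig, build_grid

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def unit_grid():
    """1°x1° box at 0.5°: exactly 4 cells."""
    return build_grid(box(0, 0, 1, 1), 0.5)


@pytest.fixture(scope="session")
def toy_grid():
    """5x5 cells of 0.1° starting at the origin."""
    return build_grid(box(0, 0, 0.5, 0.5), 0.1)


@pytest.fixture(scope="session")
def grid20():
    """20x20 cells of 0.1°, used for mask-based component tests."""
    return build_grid(box(0, 0, 2, 2), 0.1)


@pytest.fixture(scope="session")
def tiny_config():
    """Small synthetic world: quick to generate, all defaults otherwise."""
    return SynthConfig(seed=7, n_vessels=2, years=(2012, 2013), days_at_sea_per_year=6)


@pytest.fixture(scope="session")
def tiny_case(tiny_config):
    from discardmap import generate_case_study

    boundary, fleet, tracks, surfaces, gears = generate_case_study(tiny_config)
    return dict(
        config=tiny_config, boundary=boundary, fleet=fleet, tracks=tracks,
        surfaces=surfaces, gears=gears,
    )


def make_track(points, vessel="V1", t0="2014-03-01T00:00:00Z", step_min=10):
    """Track DataFrame from (lat, lon, speed) tuples at a regular interval."""
    t = pd.Timestamp(t0)
    rows = [
        {
            "vessel_id": vessel,
            "timestamp": t + pd.Timedelta(minutes=step_min * k),
            "lat": lat,
            "lon": lon,
            "speed_kn": sp,
        }
        for k, (lat, lon, sp) in enumerate(points)
    ]
    return pd.DataFrame(rows)


def mask_to_cells(mask: np.ndarray, grid) -> set[int]:
    """Cells of a 20x20 grid selected by a boolean (row=lat, col=lon) mask."""
    sel = set()
    lut = {(r.ilat, r.ilon): r.cell_id for r in grid.cells.itertuples()}
    for i in range(mask.shape[0]):
        for j in range(mask.shape[1]):
            if mask[i, j]:
                sel.add(lut[(i, j)])
    return sel
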