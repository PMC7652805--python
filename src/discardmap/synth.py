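"""Synthetic fictional case study: fleet, tracks, density surfaces.

Generates a small, fully reproducible trawl-fishery world in a lon/lat box
(defaults mimic open water near an isolated Pacific atoll): a fleet of
12–30 m otter trawlers (plus optional purse seiners), daily trips with
steaming legs and a correlated-random-walk fishing bout concentrated on
known effort patches, and multi-year species density surfaces built from
stationary Gaussian hotspot patches plus truncated noise.  Because patch
centers are known, the whole pipeline (effort → PI → fuzzy overlay →
overlap) can be validated against ground truth without any external data.

All randomness flows from ``SynthConfig.seed``; identical configs produce
byte-identical CSV outputs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from shapely.geometry import box as shapely_box

from .grid import StudyGrid
from .effort import GearModel
from .uwc import DensitySurface

logger = logging.getLogger(__name__)

KN_TO_DEG_PER_MIN = 1.0 / 60.0 / 60.0  # 1 kn = 1 nm/h = (1/60) deg lat / 60 min


@dataclass(frozen=True)
class Patch:
    """A Gaussian patch: center (lon, lat), s.d. in degrees, weight/peak."""

    lon: float
    lat: float
    sd: float
    weight: float

    def __post_init__(self):
        if self.sd <= 0:
            raise ValueError("patch sd must be > 0")
        if self.weight < 0:
            raise ValueError("patch weight must be >= 0")


@dataclass(frozen=True)
class SynthConfig:
    """Stated world of the fictional case study.

    Defaults: a 1°×1° box near 6°N 198°E-ish (reprojected to −162°E),
    2012–2016, 10-min pings, six trawlers fishing 40 days a year on two
    effort patches, two species with hotspot patches (one coincident with
    an effort patch), trawl speeds 3±0.4 kn and steaming 9±1 kn.
    """

    seed: int = 0
    n_vessels: int = 6
    n_purse_seiners: int = 0
    years: tuple[int, ...] = (2012, 2013, 2014, 2015, 2016)
    ping_interval_min: float = 10.0
    days_at_sea_per_year: int = 40
    fishing_pings_per_day: int = 36  # a 6-hour trawling bout
    boundary_box: tuple[float, float, float, float] = (-162.6, 5.4, -161.6, 6.4)
    # (lon_min, lat_min, lon_max, lat_max)
    effort_patches: tuple[Patch, ...] = (
        Patch(-162.35, 5.70, 0.05, 0.7),
        Patch(-161.85, 6.10, 0.05, 0.3),
    )
    species_patches: dict = field(
        default_factory=lambda: {
            "MUT": (Patch(-162.35, 5.70, 0.06, 10.0),),   # coincident with effort
            "HKE": (Patch(-161.95, 5.85, 0.07, 8.0),),
        }
    )
    noise_sd: float = 0.5
    noise_mode: str = "truncnorm"  # or "lognormal"
    fishing_speed: tuple[float, float] = (3.0, 0.4)  # mean, sd (kn)
    steaming_speed: tuple[float, float] = (9.0, 1.0)
    loa_range: tuple[float, float] = (12.0, 30.0)

    def __post_init__(self):
        if self.n_vessels < 1:
            raise ValueError("need at least one vessel")
        if self.noise_mode not in ("truncnorm", "lognormal"):
            raise ValueError(f"unknown noise mode {self.noise_mode!r}")
        if not self.effort_patches:
            raise ValueError("need at least one effort patch")

    def with_seed(self, seed: int) -> "SynthConfig":
        return replace(self, seed=seed)


DEFAULT_GEAR_MODELS = {
    # Generic linear gear-width parameters for a demersal otter trawl:
    # wing-tip opening ≈ 2·LOA + 10 m for 12–30 m coastal trawlers.
    "OTB": GearModel("OTB", a=2.0, b=10.0, towed=True),
    "PS": GearModel("PS", a=float("nan"), b=float("nan"), towed=False),
}


def generate_boundary(config: SynthConfig):
    lon0, lat0, lon1, lat1 = config.boundary_box
    return shapely_box(lon0, lat0, lon1, lat1)


def generate_fleet(config: SynthConfig) -> pd.DataFrame:
    """Fleet register: LOA ~ U(loa_range), power ≈ 20·LOA + noise (kW)."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n = config.n_vessels
    loa = rng.uniform(*config.loa_range, size=n)
    power = np.maximum(50.0, 20.0 * loa + rng.normal(0.0, 30.0, size=n))
    gear = ["OTB"] * n
    for k in range(min(config.n_purse_seiners, n)):
        gear[n - 1 - k] = "PS"
    return pd.DataFrame(
        {
            "vessel_id": [f"FV{k:03d}" for k in range(n)],
            "loa_m": np.round(loa, 2),
            "power_kw": np.round(power, 1),
            "gear": gear,
            "gear_secondary": [""] * n,
        }
    )


def _sample_patch(rng: np.random.Generator, patches: tuple[Patch, ...]) -> Patch:
    w = np.array([p.weight for p in patches], dtype=float)
    if w.sum() <= 0:
        w = np.ones_like(w)
    return patches[rng.choice(len(patches), p=w / w.sum())]


def _clip_to_box(lon, lat, box):
    lon0, lat0, lon1, lat1 = box
    eps = 1e-6
    return min(max(lon, lon0 + eps), lon1 - eps), min(max(lat, lat0 + eps), lat1 - eps)


def generate_tracks(config: SynthConfig, fleet: pd.DataFrame) -> pd.DataFrame:
    """Daily trips: steam out, correlated-random-walk fishing bout, steam home.

    Pings are emitted at the configured interval with speeds drawn from the
    steaming model on transit legs and the fishing model during the bout,
    so the default 2–4.5 kn speed filter recovers the bout.  The walk is
    mean-reverting toward the day's patch center, keeping fishing points
    within a few patch s.d.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    lon0, lat0, lon1, lat1 = config.boundary_box
    port = (lon0 + 0.02, lat0 + 0.02)
    dt = config.ping_interval_min
    f_mu, f_sd = config.fishing_speed
    s_mu, s_sd = config.steaming_speed
    rows = []
    for vessel in fleet.itertuples():
        for year in config.years:
            day_pool = pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D")
            n_days = min(config.days_at_sea_per_year, len(day_pool))
            days = sorted(rng.choice(len(day_pool), size=n_days, replace=False))
            for d in days:
                day = day_pool[d]
                patch = _sample_patch(rng, config.effort_patches)
                t = day + pd.Timedelta(hours=5)  # depart 05:00 UTC
                lon, lat = port
                coslat = math.cos(math.radians(lat))

                def ping(speed):
                    rows.append(
                        (vessel.vessel_id, t.isoformat(), round(lat, 6),
                         round(lon, 6), round(max(0.1, speed), 2))
                    )

                # steam toward the patch
                while math.hypot((patch.lon - lon) * coslat, patch.lat - lat) > 0.03:
                    sp = rng.normal(s_mu, s_sd)
                    step = sp * dt * KN_TO_DEG_PER_MIN
                    ang = math.atan2(patch.lat - lat, (patch.lon - lon) * coslat)
                    lat += step * math.sin(ang)
                    lon += step * math.cos(ang) / coslat
                    lon, lat = _clip_to_box(lon, lat, config.boundary_box)
                    ping(sp)
                    t += pd.Timedelta(minutes=dt)
                # fishing bout: mean-reverting correlated random walk
                heading = rng.uniform(0, 2 * math.pi)
                for _ in range(config.fishing_pings_per_day):
                    sp = rng.normal(f_mu, f_sd)
                    step = sp * dt * KN_TO_DEG_PER_MIN
                    heading += rng.normal(0.0, 0.5)
                    # pull back toward the patch center, stronger when far
                    dx = (patch.lon - lon) * coslat
                    dy = patch.lat - lat
                    dist = math.hypot(dx, dy)
                    pull = min(1.0, dist / (2.0 * patch.sd))
                    ang = math.atan2(dy, dx)
                    move = (1 - pull) * np.array(
                        [math.cos(heading), math.sin(heading)]
                    ) + pull * np.array([math.cos(ang), math.sin(ang)])
                    norm = math.hypot(*move) or 1.0
                    lon += step * move[0] / norm / coslat
                    lat += step * move[1] / norm
                    lon, lat = _clip_to_box(lon, lat, config.boundary_box)
                    ping(sp)
                    t += pd.Timedelta(minutes=dt)
                # steam home
                while math.hypot((port[0] - lon) * coslat, port[1] - lat) > 0.03:
                    sp = rng.normal(s_mu, s_sd)
                    step = sp * dt * KN_TO_DEG_PER_MIN
                    ang = math.atan2(port[1] - lat, (port[0] - lon) * coslat)
                    lat += step * math.sin(ang)
                    lon += step * math.cos(ang) / coslat
                    lon, lat = _clip_to_box(lon, lat, config.boundary_box)
                    ping(sp)
                    t += pd.Timedelta(minutes=dt)
    tracks = pd.DataFrame(
        rows, columns=["vessel_id", "timestamp", "lat", "lon", "speed_kn"]
    )
    logger.info("generated %d track points for %d vessels", len(tracks), len(fleet))
    return tracks


def generate_density_surfaces(
    config: SynthConfig, grid: StudyGrid
) -> list[DensitySurface]:
    """Per species-year surfaces: sum of Gaussian patches + truncated noise.

    Patch centers are stationary across years, so patch-core cells are
    hotspots every year and earn PI ≈ 1 under the quantile rule.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    lat_c, lon_c = grid.cell_centers()
    out = []
    for species in sorted(config.species_patches):
        patches = config.species_patches[species]
        base = np.zeros(len(grid))
        for p in patches:
            d2 = (lon_c - p.lon) ** 2 + (lat_c - p.lat) ** 2
            base += p.weight * np.exp(-d2 / (2 * p.sd**2))
        for year in config.years:
            if config.noise_sd == 0:
                noisy = base.copy()
            elif config.noise_mode == "truncnorm":
                noisy = np.maximum(
                    0.0, base + rng.normal(0.0, config.noise_sd, size=len(base))
                )
            else:  # lognormal multiplicative noise
                noisy = base * rng.lognormal(0.0, config.noise_sd, size=len(base))
            out.append(
                DensitySurface(
                    species,
                    int(year),
                    {int(c): float(v) for c, v in zip(grid.cell_ids, noisy)},
                )
            )
    return out


def gear_models_table(models: dict[str, GearModel] = None) -> pd.DataFrame:
    models = models or DEFAULT_GEAR_MODELS
    return pd.DataFrame(
        [
            {"gear": m.gear, "a": m.a, "b": m.b, "towed": m.towed}
            for m in models.values()
        ]
    )


def generate_case_study(config: SynthConfig, outdir=None):
    """Generate the full fictional case study; optionally write it to disk.

    Returns (boundary, fleet, tracks, surfaces, gear_models).  With
    ``outdir`` set, writes boundary.geojson, fleet.csv, tracks.csv,
    density.csv and gear_models.csv — exactly the formats the pipeline
    reads.
    """
    from . import io as dio
    from .grid import build_grid

    boundary = generate_boundary(config)
    fleet = generate_fleet(config)
    tracks = generate_tracks(config, fleet)
    grid = build_grid(boundary, resolution=0.05)
    surfaces = generate_density_surfaces(config, grid)
    gears = gear_models_table()
    if outdir is not None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        dio.write_boundary_geojson(boundary, outdir / "boundary.geojson")
        fleet.to_csv(outdir / "fleet.csv", index=False)
        tracks.to_csv(outdir / "tracks.csv", index=False)
        dio.write_density_csv(surfaces, outdir / "density.csv")
        gears.to_csv(outdir / "gear_models.csv", index=False)
    return boundary, fleet, tracks, surfaces, gears
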