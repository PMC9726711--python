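"""Synthetic study inputs: plume fields, cohorts, and damaged records.

The real inputs of a dose-reconstruction study — an ATDM concentration
database and behavioural questionnaires — are not publicly available, so
this module generates stand-ins with the statistical structure the
pipeline assumes:

* :func:`generate_plume` — multi-episode Gaussian-puff releases advected
  by a constant per-episode wind, with puff variance growing linearly in
  travel time and ¹³¹I radioactive decay, sampled onto the regular grid.
  This is deliberately *not* an atmospheric-transport model; it is cheap,
  analytic and linear in the source strength, which is what the lookup
  and dose code need to be exercised against.

* :func:`generate_cohort` — municipality-based questionnaires: each person
  stays home until a sampled evacuation hour (evacuees only), travels in a
  straight line to the destination, and stays there; indoor/outdoor flags
  are sampled per stay segment.

* :func:`generate_incomplete_records` — removes late coverage from a
  chosen fraction of records so the Table-1-style exclusion bookkeeping
  (received / excluded / analysed) has something to do.

Everything is deterministic for a fixed seed; equal seeds give
byte-identical questionnaire files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from datetime import timedelta

import numpy as np
import yaml

from .plume import ConcentrationField, FORMS, GridSpec
from .tapwater import LAMBDA_I131_PER_HOUR
from .trajectory import ExposureWindow, MicroEnv, PersonRecord, Waypoint, position_at

__all__ = [
    "ReleaseEpisode",
    "Municipality",
    "TapZone",
    "ScenarioConfig",
    "default_scenario",
    "generate_plume",
    "generate_cohort",
    "generate_incomplete_records",
]

KM_PER_DEG_LAT = 110.57
KM_PER_DEG_LON_EQ = 111.32


@dataclass(frozen=True)
class ReleaseEpisode:
    """One release episode: hourly puffs advected by a constant wind."""

    start_hour: int  # 1-based exposure-window hour of the first puff
    duration_h: int
    source_strength: float  # nominal Bq·m⁻³·km² emitted per puff (all forms)
    wind_u_kmh: float  # eastward
    wind_v_kmh: float  # northward
    sigma0_km: float = 1.0
    growth_km2_per_h: float = 4.0  # linear growth of puff variance
    form_fractions: tuple = (1 / 3, 1 / 3, 1 / 3)  # particulate/elemental/methyl

    def __post_init__(self) -> None:
        if self.duration_h < 1:
            raise ValueError("duration_h must be >= 1")
        if self.source_strength < 0:
            raise ValueError("source_strength must be >= 0")
        if abs(sum(self.form_fractions) - 1.0) > 1e-9 or min(self.form_fractions) < 0:
            raise ValueError("form_fractions must be a non-negative triple summing to 1")


@dataclass(frozen=True)
class Municipality:
    name: str
    lat: float
    lon: float
    n_people: int
    evac_fraction: float
    evac_mean_hour: float  # hours after window start
    evac_sd_hour: float
    dest_lat: float
    dest_lon: float
    home_jitter_km: float = 2.0
    outdoor_prob: float = 0.15

    def __post_init__(self) -> None:
        if not 0 <= self.evac_fraction <= 1:
            raise ValueError("evac_fraction must lie in [0, 1]")
        if self.n_people < 0:
            raise ValueError("n_people must be >= 0")


@dataclass(frozen=True)
class TapZone:
    zone_id: str
    lat: float
    lon: float
    turnover_per_h: float = 0.01
    transfer_coefficient: float = 5.0e-4  # driver (Bq/m³ air) -> Bq/m³ water per hour
    is_well: bool = False

    def __post_init__(self) -> None:
        if self.turnover_per_h < 0 or self.transfer_coefficient < 0:
            raise ValueError("rates must be >= 0")


@dataclass
class ScenarioConfig:
    """Everything needed to synthesise one study scenario."""

    grid: GridSpec
    source_lat: float
    source_lon: float
    episodes: list
    municipalities: list
    zones: list
    window: ExposureWindow = dc_field(default_factory=ExposureWindow)
    age_choices: tuple = tuple(range(20))
    travel_speed_kmh: float = 30.0
    dropout_fraction: float = 0.0
    radioactive_decay: bool = True
    puff_max_age_h: int = 96
    seed: int = 0

    # -- YAML round trip ---------------------------------------------------
    def to_yaml(self, path) -> None:
        doc = {
            "grid": {
                "origin_lat": self.grid.origin_lat,
                "origin_lon": self.grid.origin_lon,
                "cell_size_lat": self.grid.cell_size_lat,
                "cell_size_lon": self.grid.cell_size_lon,
                "n_rows": self.grid.n_rows,
                "n_cols": self.grid.n_cols,
            },
            "source": {"lat": self.source_lat, "lon": self.source_lon},
            "episodes": [
                {
                    "start_hour": e.start_hour,
                    "duration_h": e.duration_h,
                    "source_strength": e.source_strength,
                    "wind_u_kmh": e.wind_u_kmh,
                    "wind_v_kmh": e.wind_v_kmh,
                    "sigma0_km": e.sigma0_km,
                    "growth_km2_per_h": e.growth_km2_per_h,
                    "form_fractions": list(e.form_fractions),
                }
                for e in self.episodes
            ],
            "municipalities": [
                {
                    "name": m.name,
                    "lat": m.lat,
                    "lon": m.lon,
                    "n_people": m.n_people,
                    "evac_fraction": m.evac_fraction,
                    "evac_mean_hour": m.evac_mean_hour,
                    "evac_sd_hour": m.evac_sd_hour,
                    "dest_lat": m.dest_lat,
                    "dest_lon": m.dest_lon,
                    "home_jitter_km": m.home_jitter_km,
                    "outdoor_prob": m.outdoor_prob,
                }
                for m in self.municipalities
            ],
            "zones": [
                {
                    "zone_id": z.zone_id,
                    "lat": z.lat,
                    "lon": z.lon,
                    "turnover_per_h": z.turnover_per_h,
                    "transfer_coefficient": z.transfer_coefficient,
                    "is_well": z.is_well,
                }
                for z in self.zones
            ],
            "age_choices": list(self.age_choices),
            "travel_speed_kmh": self.travel_speed_kmh,
            "dropout_fraction": self.dropout_fraction,
            "radioactive_decay": self.radioactive_decay,
            "puff_max_age_h": self.puff_max_age_h,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(
            grid=GridSpec(**doc["grid"]),
            source_lat=doc["source"]["lat"],
            source_lon=doc["source"]["lon"],
            episodes=[
                ReleaseEpisode(
                    start_hour=e["start_hour"],
                    duration_h=e["duration_h"],
                    source_strength=e["source_strength"],
                    wind_u_kmh=e["wind_u_kmh"],
                    wind_v_kmh=e["wind_v_kmh"],
                    sigma0_km=e.get("sigma0_km", 1.0),
                    growth_km2_per_h=e.get("growth_km2_per_h", 4.0),
                    form_fractions=tuple(e.get("form_fractions", (1 / 3, 1 / 3, 1 / 3))),
                )
                for e in doc["episodes"]
            ],
            municipalities=[Municipality(**m) for m in doc["municipalities"]],
            zones=[TapZone(**z) for z in doc["zones"]],
            age_choices=tuple(doc.get("age_choices", tuple(range(20)))),
            travel_speed_kmh=doc.get("travel_speed_kmh", 30.0),
            dropout_fraction=doc.get("dropout_fraction", 0.0),
            radioactive_decay=doc.get("radioactive_decay", True),
            puff_max_age_h=doc.get("puff_max_age_h", 96),
            seed=doc.get("seed", 0),
        )


def default_scenario(n_per_municipality: int = 200, seed: int = 0) -> ScenarioConfig:
    """A two-episode March-2011-like scenario on a 100×100 ~1 km grid.

    Episode 1 (afternoon of day 1) blows north over the on-axis coastal
    town; episode 2 (day 4) blows north-west over the inland town.  The
    off-axis town south of the source sits under neither plume, and
    evacuees head to the clean south-west corner of the domain.
    """
    grid = GridSpec(37.0, 140.5, 0.009, 0.0113, 100, 100)
    episodes = [
        ReleaseEpisode(7, 6, 5.0e5, wind_u_kmh=0.0, wind_v_kmh=15.0),
        ReleaseEpisode(76, 8, 8.0e5, wind_u_kmh=-10.0, wind_v_kmh=8.0),
    ]
    dest = (37.08, 140.62)
    municipalities = [
        Municipality("on_axis_town", 37.65, 141.02, n_per_municipality, 0.9, 30.0, 12.0, *dest),
        Municipality("inland_town", 37.62, 140.78, n_per_municipality, 0.2, 90.0, 24.0, *dest),
        Municipality("off_axis_town", 37.12, 141.02, n_per_municipality, 0.05, 60.0, 24.0, *dest),
    ]
    zones = [
        TapZone("z_on_axis", 37.65, 141.02),
        TapZone("z_inland", 37.62, 140.78),
        TapZone("z_off_axis", 37.12, 141.02),
        TapZone("z_dest_well", dest[0], dest[1], is_well=True),
    ]
    return ScenarioConfig(
        grid=grid,
        source_lat=37.42,
        source_lon=141.03,
        episodes=episodes,
        municipalities=municipalities,
        zones=zones,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# plume


def _km_coords(grid: GridSpec) -> tuple[np.ndarray, np.ndarray, float]:
    """Cell-centre coordinates in km relative to the grid origin."""
    clat, clon = grid.cell_centers()
    coslat = math.cos(math.radians(grid.origin_lat + grid.n_rows * grid.cell_size_lat / 2))
    y = (clat - grid.origin_lat) * KM_PER_DEG_LAT
    x = (clon - grid.origin_lon) * KM_PER_DEG_LON_EQ * coslat
    return y, x, coslat


def generate_plume(config: ScenarioConfig) -> ConcentrationField:
    """Superpose Gaussian puffs onto the grid, hour by hour.

    Each episode releases one puff per hour at the source; a puff of age t
    sits at ``source + wind·t`` with variance ``σ₀² + growth·t`` and
    contributes ``m·exp(−d²/2σ²)/(2πσ²)`` (2-D Gaussian, mass-conserving
    before decay), decayed radioactively when enabled.
    """
    if not config.episodes:
        raise ValueError("scenario needs at least one release episode")
    grid = config.grid
    y, x, coslat = _km_coords(grid)
    src_y = (config.source_lat - grid.origin_lat) * KM_PER_DEG_LAT
    src_x = (config.source_lon - grid.origin_lon) * KM_PER_DEG_LON_EQ * coslat
    Y = y[:, None]  # (rows, 1)
    X = x[None, :]  # (1, cols)
    n_hours = config.window.n_hours
    vals = np.zeros((n_hours, grid.n_rows, grid.n_cols, len(FORMS)))
    for ep in config.episodes:
        if ep.source_strength == 0.0:
            continue
        masses = np.array(ep.form_fractions) * ep.source_strength
        for release in range(ep.start_hour, ep.start_hour + ep.duration_h):
            last = min(n_hours, release + config.puff_max_age_h - 1)
            for hour in range(release, last + 1):
                age = hour - release
                cy = src_y + ep.wind_v_kmh * age
                cx = src_x + ep.wind_u_kmh * age
                sigma2 = ep.sigma0_km**2 + ep.growth_km2_per_h * age
                d2 = (Y - cy) ** 2 + (X - cx) ** 2
                shape = np.exp(-d2 / (2.0 * sigma2)) / (2.0 * math.pi * sigma2)
                if config.radioactive_decay:
                    shape = shape * math.exp(-LAMBDA_I131_PER_HOUR * age)
                vals[hour - 1] += shape[:, :, None] * masses[None, None, :]
    return ConcentrationField(grid, vals, config.window)


# ---------------------------------------------------------------------------
# cohort


def _stay_env(rng: np.random.Generator, outdoor_prob: float) -> MicroEnv:
    return MicroEnv.OUTDOOR if rng.uniform() < outdoor_prob else MicroEnv.INDOOR


def generate_cohort(config: ScenarioConfig, seed: int | None = None) -> list[PersonRecord]:
    """Sample questionnaire records for every municipality.

    Non-evacuees hold their (jittered) home position for the whole window;
    evacuees leave home at a normally distributed hour, travel to the
    destination in a straight line at ``travel_speed_kmh``, and stay.
    Ages are drawn uniformly from ``config.age_choices``.
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    window = config.window
    coslat = math.cos(math.radians(config.grid.origin_lat))
    records: list[PersonRecord] = []
    for muni in config.municipalities:
        jit_lat = muni.home_jitter_km / KM_PER_DEG_LAT
        jit_lon = muni.home_jitter_km / (KM_PER_DEG_LON_EQ * coslat)
        for i in range(muni.n_people):
            pid = f"{muni.name}-{i:05d}"
            age = int(rng.choice(config.age_choices))
            home = (
                muni.lat + rng.normal(0.0, jit_lat),
                muni.lon + rng.normal(0.0, jit_lon),
            )
            env_home = _stay_env(rng, muni.outdoor_prob)
            evacuates = rng.uniform() < muni.evac_fraction
            if not evacuates:
                wps = [
                    Waypoint(window.start, *home, env_home),
                    Waypoint(window.end, *home, env_home),
                ]
            else:
                evac_h = float(np.clip(rng.normal(muni.evac_mean_hour, muni.evac_sd_hour), 2.0, 260.0))
                dest = (
                    muni.dest_lat + rng.normal(0.0, jit_lat),
                    muni.dest_lon + rng.normal(0.0, jit_lon),
                )
                dist_km = math.hypot(
                    (dest[0] - home[0]) * KM_PER_DEG_LAT,
                    (dest[1] - home[1]) * KM_PER_DEG_LON_EQ * coslat,
                )
                travel_h = max(dist_km / config.travel_speed_kmh, 0.5)
                t_leave = window.start + timedelta(hours=evac_h)
                t_arrive = t_leave + timedelta(hours=travel_h)
                env_dest = _stay_env(rng, muni.outdoor_prob)
                wps = [
                    Waypoint(window.start, *home, env_home),
                    Waypoint(t_leave, *home, env_home),
                    Waypoint(t_arrive, *dest, env_dest),
                    Waypoint(window.end, *dest, env_dest),
                ]
            records.append(PersonRecord(pid, age, wps, municipality=muni.name))
    return records


def generate_incomplete_records(
    records: list[PersonRecord], dropout_fraction: float, seed: int = 0
) -> list[PersonRecord]:
    """Damage a ``round(dropout_fraction · n)``-sized random subset of
    records by truncating their coverage before the end of the window, so
    they fail the completeness check with reason ``incomplete_window``."""
    if not 0 <= dropout_fraction <= 1:
        raise ValueError("dropout_fraction must lie in [0, 1]")
    n = len(records)
    k = round(dropout_fraction * n)
    rng = np.random.default_rng(seed)
    damaged = set(rng.choice(n, size=k, replace=False).tolist()) if k else set()
    out: list[PersonRecord] = []
    for idx, rec in enumerate(records):
        if idx not in damaged:
            out.append(rec)
            continue
        window_start = rec.waypoints[0].timestamp
        cutoff = window_start + timedelta(hours=float(rng.uniform(48.0, 250.0)))
        kept = [w for w in rec.waypoints if w.timestamp < cutoff]
        if not kept:
            kept = [rec.waypoints[0]]
        lat, lon = position_at(rec.waypoints, cutoff)
        kept.append(Waypoint(cutoff, lat, lon, kept[-1].micro_environment))
        out.append(PersonRecord(rec.person_id, rec.age_years, kept, rec.municipality))
    return out
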