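"""Tap-water ¹³¹I series (one-compartment model) and ingestion TED.

Tap-water concentration in a supply zone is modelled with a first-order
mass balance: deposition-driven input minus first-order removal,

    dC/dt = input_rate · driver(t) − k · C,

stepped hour by hour with exact exponential decay between inputs.  The
removal rate ``k`` is at least the ¹³¹I radioactive decay constant
(half-life 8.02 days) plus the zone's water-turnover rate.  Measured
concentrations, where available, override the modelled series for the
hours they cover.

The ingestion TED follows

    TED_ingest = Σ_i  pTWI/24 · C_i,tap · e_ingest · FC  (· tap_fraction)

with pTWI the age-specific median potentially-ingested tap-water volume
(m³/day) and C_i,tap the concentration of the zone the person is in at
hour *i*.  Well water is assumed free of contamination, so hours spent in
a well-water zone contribute nothing; where a municipality partly relies
on wells, ``tap_fraction`` (e.g. 0.7) scales the total.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .inhalation import ExposureParameters
from .trajectory import ExposureWindow, HourlyTrack

__all__ = [
    "LAMBDA_I131_PER_HOUR",
    "I131_HALF_LIFE_DAYS",
    "CompartmentParams",
    "TapWaterSeries",
    "ZoneMap",
    "tapwater_series",
    "ingestion_ted",
]

I131_HALF_LIFE_DAYS = 8.02
#: Radioactive decay constant of ¹³¹I, per hour.
LAMBDA_I131_PER_HOUR = math.log(2.0) / (I131_HALF_LIFE_DAYS * 24.0)


@dataclass(frozen=True)
class CompartmentParams:
    """One-compartment parameters for a supply zone.

    ``input_rate`` converts the driver series (deposition or air
    concentration) into Bq/m³ added to the water body per hour;
    ``removal_rate`` is the total first-order loss (radioactive decay plus
    water turnover), per hour.
    """

    input_rate: float
    removal_rate: float = LAMBDA_I131_PER_HOUR

    def __post_init__(self) -> None:
        if self.input_rate < 0:
            raise ValueError("input_rate must be >= 0")
        if self.removal_rate < LAMBDA_I131_PER_HOUR * (1 - 1e-12):
            raise ValueError("removal_rate cannot be below the 131I decay constant")


@dataclass
class TapWaterSeries:
    """Hourly ¹³¹I concentration (Bq/m³) in one supply zone's tap water."""

    zone_id: str
    values: np.ndarray
    source: str = "modelled"  # modelled | measured | mixed

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be one-dimensional")
        if np.any(self.values < 0):
            raise ValueError("tap-water concentrations must be non-negative")

    def __len__(self) -> int:
        return len(self.values)

    def override_with_measured(self, hour_indices, measured_values) -> "TapWaterSeries":
        """Replace the modelled values at the given 1-based hours with
        measurements; untouched hours keep the model."""
        vals = self.values.copy()
        idx = np.asarray(hour_indices, dtype=int) - 1
        vals[idx] = np.asarray(measured_values, dtype=float)
        return TapWaterSeries(self.zone_id, vals, source="mixed")


def tapwater_series(
    driver: np.ndarray,
    params: CompartmentParams,
    zone_id: str = "",
    c0: float = 0.0,
    dt_hours: float = 1.0,
) -> TapWaterSeries:
    """Run the one-compartment recurrence over an hourly driver series.

    ``C(i) = C(i−1)·exp(−k·Δt) + input_rate·driver(i)`` — the pulse input
    of hour *i* is added after the stock has decayed exactly through Δt.
    """
    driver = np.asarray(driver, dtype=float)
    if np.any(driver < 0):
        raise ValueError("driver must be non-negative")
    decay = math.exp(-params.removal_rate * dt_hours)
    out = np.empty_like(driver)
    c = c0
    for i, d in enumerate(driver):
        c = c * decay + params.input_rate * d
        out[i] = c
    return TapWaterSeries(zone_id, out)


@dataclass
class ZoneMap:
    """Assign positions to tap-water supply zones by nearest zone centroid.

    ``zones`` is a DataFrame with columns ``zone_id``, ``lat``, ``lon`` and
    boolean ``is_well``; persons located in an ``is_well`` zone drink
    uncontaminated well water.
    """

    zones: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"zone_id", "lat", "lon", "is_well"}
        if not required.issubset(self.zones.columns):
            raise ValueError(f"zone table needs columns {sorted(required)}")
        self.zones = self.zones.reset_index(drop=True)

    def assign(self, lat, lon) -> np.ndarray:
        """Zone id of the nearest centroid for each position (degree metric)."""
        lat = np.atleast_1d(np.asarray(lat, dtype=float))
        lon = np.atleast_1d(np.asarray(lon, dtype=float))
        zlat = self.zones["lat"].to_numpy()
        zlon = self.zones["lon"].to_numpy()
        d2 = (lat[:, None] - zlat[None, :]) ** 2 + (lon[:, None] - zlon[None, :]) ** 2
        return self.zones["zone_id"].to_numpy()[np.argmin(d2, axis=1)]

    def is_well(self, zone_id: str) -> bool:
        row = self.zones[self.zones["zone_id"] == zone_id]
        if row.empty:
            raise KeyError(f"unknown zone {zone_id!r}")
        return bool(row["is_well"].iloc[0])

    def to_csv(self, path) -> None:
        self.zones.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ZoneMap":
        df = pd.read_csv(path, dtype={"zone_id": str})
        df["is_well"] = df["is_well"].astype(bool)
        return cls(df)


def ingestion_ted(
    track: HourlyTrack,
    zone_map: ZoneMap,
    series_by_zone: dict,
    params: ExposureParameters,
    window: ExposureWindow | None = None,
) -> tuple[np.ndarray, float]:
    """Per-hour ingestion dose (mSv) along a track and its total.

    Each hour contributes ``pTWI/24 · C_tap(zone(i), i) · e_ingest · FC``;
    the zone is the person's position that hour (they drink the water of
    wherever they are).  Hours in well-water zones contribute zero.  The
    summed dose is scaled by ``params.tap_fraction``.
    """
    window = window or track.window
    zone_ids = zone_map.assign(track.latitudes, track.longitudes)
    c_tap = np.zeros(window.n_hours)
    for zone in pd.unique(zone_ids):
        mask = zone_ids == zone
        if zone_map.is_well(zone):
            continue
        if zone not in series_by_zone:
            raise KeyError(f"no tap-water series for zone {zone!r}")
        series = series_by_zone[zone]
        if len(series) != window.n_hours:
            raise ValueError(f"tap-water series for zone {zone!r} has wrong length")
        c_tap[mask] = series.values[mask]
    per_hour = (
        (params.ptwi_m3_per_day / 24.0) * c_tap * params.e_ingest * params.fc * params.tap_fraction
    )
    return per_hour, float(per_hour.sum())
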