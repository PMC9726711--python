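"""Whereabouts questionnaires: waypoints, validation, and hourly resampling.

A person's questionnaire record is an ordered sequence of timestamped
waypoints (latitude/longitude in decimal degrees, WGS84) with a
micro-environment flag (indoor / outdoor / vehicle / unknown).  Dose
computation requires a position for every one of the 330 exposure hours
between 06:00 JST on 12 March 2011 and 24:00 JST on 25 March 2011, so
records are resampled to an hourly track: between consecutive waypoints the
person is assumed to move in a straight line at constant speed ("as the
crow flies"), and hours before the first or after the last waypoint hold
that endpoint's position.

Records that do not explicitly cover the whole exposure window are excluded
from analysis rather than silently extrapolated; :func:`validate_track`
implements that completeness rule and returns a machine-readable verdict.

All timestamps are naive datetimes interpreted as JST; no time-zone
arithmetic is exposed.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MicroEnv",
    "Waypoint",
    "ExposureWindow",
    "HourlyTrack",
    "PersonRecord",
    "TrackVerdict",
    "resample_waypoints",
    "validate_track",
    "position_at",
    "read_waypoint_csv",
    "write_waypoint_csv",
    "write_track_csv",
    "read_track_csv",
]

#: Japan bounding box used to sanity-check coordinates.
LAT_RANGE = (20.0, 50.0)
LON_RANGE = (120.0, 150.0)


class MicroEnv(str, enum.Enum):
    """Micro-environment of an hour or a waypoint."""

    INDOOR = "indoor"
    OUTDOOR = "outdoor"
    VEHICLE = "vehicle"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class Waypoint:
    """A single timestamped whereabouts statement.

    ``latitude``/``longitude`` may be ``None`` (or NaN) to encode a stated
    *unknown whereabouts* interval; such records fail validation.
    """

    timestamp: datetime
    latitude: float | None
    longitude: float | None
    micro_environment: MicroEnv = MicroEnv.UNKNOWN

    def __post_init__(self) -> None:
        lat, lon = self.latitude, self.longitude
        if lat is not None and isinstance(lat, float) and math.isnan(lat):
            object.__setattr__(self, "latitude", None)
            lat = None
        if lon is not None and isinstance(lon, float) and math.isnan(lon):
            object.__setattr__(self, "longitude", None)
            lon = None
        if (lat is None) != (lon is None):
            raise ValueError("latitude and longitude must both be set or both missing")
        if lat is not None:
            if not (LAT_RANGE[0] <= lat <= LAT_RANGE[1]):
                raise ValueError(f"latitude {lat} outside Japan bounding box {LAT_RANGE}")
            if not (LON_RANGE[0] <= lon <= LON_RANGE[1]):
                raise ValueError(f"longitude {lon} outside Japan bounding box {LON_RANGE}")

    @property
    def has_position(self) -> bool:
        return self.latitude is not None


@dataclass(frozen=True)
class ExposureWindow:
    """The fixed 330-hour exposure window of the March 2011 plume period.

    Runs from 06:00 JST on 12 March 2011 to 24:00 JST on 25 March 2011
    (midnight ending 25 March); hour index ``i`` is 1-based and hour ``i``
    spans ``[start + (i-1) h, start + i h)``.
    """

    start: datetime = datetime(2011, 3, 12, 6, 0)
    n_hours: int = 330

    def __post_init__(self) -> None:
        if self.n_hours < 1:
            raise ValueError("n_hours must be >= 1")

    @property
    def end(self) -> datetime:
        return self.start + timedelta(hours=self.n_hours)

    def hour_start(self, i: int) -> datetime:
        self._check_index(i)
        return self.start + timedelta(hours=i - 1)

    def hour_mid(self, i: int) -> datetime:
        self._check_index(i)
        return self.start + timedelta(hours=i - 1, minutes=30)

    def _check_index(self, i: int) -> None:
        if not 1 <= i <= self.n_hours:
            raise IndexError(f"hour index {i} outside 1..{self.n_hours}")

    def times(self, hour_position: str = "mid") -> list[datetime]:
        """Representative timestamps of all hours (``mid`` = hh:30)."""
        if hour_position == "mid":
            return [self.hour_mid(i) for i in range(1, self.n_hours + 1)]
        if hour_position == "start":
            return [self.hour_start(i) for i in range(1, self.n_hours + 1)]
        raise ValueError("hour_position must be 'mid' or 'start'")

    def hour_index_of(self, t: datetime) -> int:
        """1-based hour containing ``t``; raises if outside the window."""
        delta = (t - self.start).total_seconds()
        if not 0 <= delta < self.n_hours * 3600:
            raise IndexError(f"{t} outside exposure window")
        return int(delta // 3600) + 1


@dataclass
class HourlyTrack:
    """A person's position and micro-environment for every exposure hour."""

    person_id: str
    age_years: int
    latitudes: np.ndarray
    longitudes: np.ndarray
    micro_env: list[MicroEnv]
    window: ExposureWindow = field(default_factory=ExposureWindow)

    def __post_init__(self) -> None:
        self.latitudes = np.asarray(self.latitudes, dtype=float)
        self.longitudes = np.asarray(self.longitudes, dtype=float)
        n = self.window.n_hours
        if not (len(self.latitudes) == len(self.longitudes) == len(self.micro_env) == n):
            raise ValueError(f"track of person {self.person_id!r} must have exactly {n} entries")
        if self.age_years < 0:
            raise ValueError("age_years must be >= 0")
        if (
            self.latitudes.min() < LAT_RANGE[0]
            or self.latitudes.max() > LAT_RANGE[1]
            or self.longitudes.min() < LON_RANGE[0]
            or self.longitudes.max() > LON_RANGE[1]
        ):
            raise ValueError(f"track of person {self.person_id!r} leaves the Japan bounding box")

    def __len__(self) -> int:
        return self.window.n_hours

    def to_frame(self, hour_position: str = "mid") -> pd.DataFrame:
        times = self.window.times(hour_position)
        return pd.DataFrame(
            {
                "hour_index": np.arange(1, self.window.n_hours + 1),
                "iso_timestamp": [t.isoformat() for t in times],
                "lat": self.latitudes,
                "lon": self.longitudes,
                "micro_env": [e.value for e in self.micro_env],
            }
        )

    def to_waypoints(self, hour_position: str = "mid") -> list[Waypoint]:
        """Re-express the track as one waypoint per hour (round-trips
        exactly through :func:`resample_waypoints`)."""
        times = self.window.times(hour_position)
        return [
            Waypoint(t, float(la), float(lo), env)
            for t, la, lo, env in zip(times, self.latitudes, self.longitudes, self.micro_env)
        ]


@dataclass
class PersonRecord:
    """One questionnaire: a person's ordered waypoint statements."""

    person_id: str
    age_years: int
    waypoints: list[Waypoint]
    municipality: str | None = None

    def sorted_ok(self) -> bool:
        ts = [w.timestamp for w in self.waypoints]
        return all(a < b for a, b in zip(ts, ts[1:]))


@dataclass(frozen=True)
class TrackVerdict:
    """Outcome of the completeness check on a questionnaire record."""

    accepted: bool
    reason: str | None = None  # incomplete_window | unknown_whereabouts | ...
    detail: str = ""


def validate_track(
    waypoints: Sequence[Waypoint], window: ExposureWindow | None = None
) -> TrackVerdict:
    """Decide whether a waypoint record completely covers the exposure window.

    A record is excluded when any part of the window is not covered by
    explicit whereabouts information: the record is empty, its timestamps
    are unordered, any waypoint states *unknown whereabouts* (missing
    coordinates), or — for records with two or more waypoints — the span
    of timestamps does not contain the whole window.  A single-waypoint
    record is read as a stated stay covering the entire window.

    Never raises on record content.
    """
    window = window or ExposureWindow()
    wps = list(waypoints)
    if not wps:
        return TrackVerdict(False, "no_waypoints")
    ts = [w.timestamp for w in wps]
    if any(a >= b for a, b in zip(ts, ts[1:])):
        return TrackVerdict(False, "unordered_timestamps")
    if any(not w.has_position for w in wps):
        return TrackVerdict(False, "unknown_whereabouts", "record contains an unknown-whereabouts interval")
    if len(wps) == 1:
        return TrackVerdict(True)
    if ts[0] > window.start or ts[-1] < window.end:
        return TrackVerdict(
            False,
            "incomplete_window",
            f"coverage {ts[0].isoformat()}..{ts[-1].isoformat()} does not span "
            f"{window.start.isoformat()}..{window.end.isoformat()}",
        )
    return TrackVerdict(True)


def position_at(waypoints: Sequence[Waypoint], t: datetime) -> tuple[float, float]:
    """Straight-line constant-speed position at time ``t``.

    Linear interpolation in degrees between the bracketing waypoints;
    clamped to the first/last waypoint outside the record's span.
    """
    wps = list(waypoints)
    if not wps:
        raise ValueError("empty waypoint list")
    ts = np.array([w.timestamp.timestamp() for w in wps])
    lat = np.array([w.latitude for w in wps], dtype=float)
    lon = np.array([w.longitude for w in wps], dtype=float)
    x = t.timestamp()
    return float(np.interp(x, ts, lat)), float(np.interp(x, ts, lon))


def _segment_env(
    wps: Sequence[Waypoint], j: int, moving: bool, default_env: MicroEnv
) -> MicroEnv:
    # travel segments are vehicle hours; stays inherit the statement that
    # opened the stay, with unknown defaulting (conservatively) to indoor
    if moving:
        return MicroEnv.VEHICLE
    env = wps[j].micro_environment
    return default_env if env is MicroEnv.UNKNOWN else env


def resample_waypoints(
    waypoints: Sequence[Waypoint],
    window: ExposureWindow | None = None,
    *,
    person_id: str = "",
    age_years: int = 0,
    hour_position: str = "mid",
    default_env: MicroEnv = MicroEnv.INDOOR,
) -> HourlyTrack:
    """Resample a waypoint record to one position per exposure hour.

    Each hour is represented by a single timestamp (its midpoint hh:30 by
    default, ``hour_position='start'`` for the hour boundary).  Positions
    are linear interpolations in latitude/longitude degrees, proportional
    to elapsed time, between the waypoints bracketing that timestamp;
    hours before the first (after the last) waypoint hold that endpoint's
    position.  The hour's micro-environment is ``vehicle`` if the
    bracketing segment involves movement, otherwise the environment stated
    at the start of the stay (``unknown`` resolves to ``default_env``).
    A timestamp coinciding exactly with a waypoint takes that waypoint's
    stated environment.

    Raises ``ValueError`` on an empty record, unordered timestamps, or an
    unknown-whereabouts waypoint (use :func:`validate_track` to screen).
    """
    window = window or ExposureWindow()
    wps = list(waypoints)
    if not wps:
        raise ValueError(f"person {person_id!r}: empty waypoint list")
    ts = [w.timestamp for w in wps]
    if any(a >= b for a, b in zip(ts, ts[1:])):
        raise ValueError(f"person {person_id!r}: waypoint timestamps not strictly increasing")
    if any(not w.has_position for w in wps):
        raise ValueError(f"person {person_id!r}: waypoint without coordinates (unknown whereabouts)")

    times = window.times(hour_position)
    tsec = np.array([t.timestamp() for t in ts])
    lat = np.array([w.latitude for w in wps], dtype=float)
    lon = np.array([w.longitude for w in wps], dtype=float)
    xsec = np.array([t.timestamp() for t in times])

    lats = np.interp(xsec, tsec, lat)
    lons = np.interp(xsec, tsec, lon)

    # segment index for each hour: j such that ts[j] <= t < ts[j+1]
    seg = np.clip(np.searchsorted(tsec, xsec, side="right") - 1, 0, len(wps) - 1)
    exact = np.isclose(xsec[:, None], tsec[None, :], rtol=0.0, atol=0.5).any(axis=1)
    envs: list[MicroEnv] = []
    for i, t in enumerate(times):
        j = int(seg[i])
        if exact[i] or xsec[i] <= tsec[0] or xsec[i] >= tsec[-1]:
            k = int(np.argmin(np.abs(tsec - xsec[i]))) if exact[i] else (0 if xsec[i] <= tsec[0] else len(wps) - 1)
            env = wps[k].micro_environment
            envs.append(default_env if env is MicroEnv.UNKNOWN else env)
            continue
        moving = (lat[j] != lat[j + 1]) or (lon[j] != lon[j + 1])
        envs.append(_segment_env(wps, j, moving, default_env))

    return HourlyTrack(person_id, age_years, lats, lons, envs, window)


# ---------------------------------------------------------------------------
# delimited-text I/O

_WAYPOINT_COLS = ["person_id", "age", "iso_timestamp", "lat", "lon", "micro_env"]


def write_waypoint_csv(records: Iterable[PersonRecord], path) -> None:
    """One row per waypoint: person_id, age, iso_timestamp, lat, lon, micro_env
    (plus municipality when any record carries one)."""
    rows = []
    for rec in records:
        for w in rec.waypoints:
            rows.append(
                {
                    "person_id": rec.person_id,
                    "age": rec.age_years,
                    "iso_timestamp": w.timestamp.isoformat(),
                    "lat": "" if w.latitude is None else repr(w.latitude),
                    "lon": "" if w.longitude is None else repr(w.longitude),
                    "micro_env": w.micro_environment.value,
                    "municipality": rec.municipality or "",
                }
            )
    df = pd.DataFrame(rows)
    if df.empty:
        df = pd.DataFrame(columns=_WAYPOINT_COLS + ["municipality"])
    if (df.get("municipality", pd.Series(dtype=str)) == "").all():
        df = df.drop(columns=["municipality"], errors="ignore")
    df.to_csv(path, index=False)


def read_waypoint_csv(path) -> list[PersonRecord]:
    df = pd.read_csv(path, dtype={"person_id": str}, keep_default_na=True)
    records: list[PersonRecord] = []
    for pid, grp in df.groupby("person_id", sort=False):
        wps = []
        for _, row in grp.iterrows():
            lat = row["lat"] if pd.notna(row["lat"]) else None
            lon = row["lon"] if pd.notna(row["lon"]) else None
            wps.append(
                Waypoint(
                    datetime.fromisoformat(row["iso_timestamp"]),
                    None if lat is None else float(lat),
                    None if lon is None else float(lon),
                    MicroEnv(row["micro_env"]),
                )
            )
        municipality = None
        if "municipality" in grp.columns:
            val = grp["municipality"].iloc[0]
            municipality = str(val) if pd.notna(val) and str(val) else None
        records.append(PersonRecord(str(pid), int(grp["age"].iloc[0]), wps, municipality))
    return records


def write_track_csv(track: HourlyTrack, path, hour_position: str = "mid") -> None:
    track.to_frame(hour_position).to_csv(path, index=False)


def read_track_csv(path, person_id: str = "", age_years: int = 0) -> HourlyTrack:
    df = pd.read_csv(path)
    return HourlyTrack(
        person_id,
        age_years,
        df["lat"].to_numpy(),
        df["lon"].to_numpy(),
        [MicroEnv(v) for v in df["micro_env"]],
    )
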