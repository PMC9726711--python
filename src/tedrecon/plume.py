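"""Gridded spatiotemporal ¹³¹I concentration fields and track lookup.

The atmospheric-dispersion database is represented as hourly ground-level
(1 m) air concentrations of the three chemical forms of ¹³¹I — particulate,
elemental vapour and methyl iodide — on a regular latitude/longitude grid
whose cell size approximates 1 km.  Dose computation only ever *queries*
this field along a person's hourly track; no transport modelling happens
here.

Storage is hour-major (time, row, col, form) so one person's 330 lookups
stream through time contiguously.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
import xarray as xr

from .trajectory import ExposureWindow, HourlyTrack

__all__ = [
    "FORMS",
    "GridSpec",
    "ConcentrationField",
    "HourlyExposureSeries",
    "lookup_concentration",
    "regrid",
]

log = logging.getLogger(__name__)

#: The three chemical forms, in storage order.
FORMS = ("particulate", "elemental", "methyl")


@dataclass(frozen=True)
class GridSpec:
    """Regular lat/lon grid; ``origin`` is the lower-left (south-west) cell edge.

    Cells are half-open ``[edge, next_edge)`` in both axes; a position on
    the extreme upper edge belongs to the last cell, so the closed domain
    is covered without double counting.
    """

    origin_lat: float
    origin_lon: float
    cell_size_lat: float
    cell_size_lon: float
    n_rows: int
    n_cols: int

    def __post_init__(self) -> None:
        if self.cell_size_lat <= 0 or self.cell_size_lon <= 0:
            raise ValueError("cell size must be positive")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one cell")

    @property
    def max_lat(self) -> float:
        return self.origin_lat + self.n_rows * self.cell_size_lat

    @property
    def max_lon(self) -> float:
        return self.origin_lon + self.n_cols * self.cell_size_lon

    def contains(self, lat, lon) -> np.ndarray:
        lat = np.asarray(lat, dtype=float)
        lon = np.asarray(lon, dtype=float)
        return (
            (lat >= self.origin_lat)
            & (lat <= self.max_lat)
            & (lon >= self.origin_lon)
            & (lon <= self.max_lon)
        )

    def cell_of(self, lat, lon) -> tuple[np.ndarray, np.ndarray]:
        """Row/col of the cell containing each position (upper edges clamp
        into the last cell).  Positions outside the domain get index -1."""
        lat = np.asarray(lat, dtype=float)
        lon = np.asarray(lon, dtype=float)
        inside = self.contains(lat, lon)
        row = np.floor((lat - self.origin_lat) / self.cell_size_lat).astype(int)
        col = np.floor((lon - self.origin_lon) / self.cell_size_lon).astype(int)
        row = np.clip(row, 0, self.n_rows - 1)
        col = np.clip(col, 0, self.n_cols - 1)
        row = np.where(inside, row, -1)
        col = np.where(inside, col, -1)
        return row, col

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        lat = self.origin_lat + (np.arange(self.n_rows) + 0.5) * self.cell_size_lat
        lon = self.origin_lon + (np.arange(self.n_cols) + 0.5) * self.cell_size_lon
        return lat, lon


@dataclass
class ConcentrationField:
    """Hourly Bq/m³ of the three ¹³¹I forms on a regular grid.

    ``values`` has shape ``(window.n_hours, n_rows, n_cols, 3)`` with the
    last axis ordered as :data:`FORMS`; all values are non-negative.
    """

    grid: GridSpec
    values: np.ndarray
    window: ExposureWindow = dc_field(default_factory=ExposureWindow)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = (self.window.n_hours, self.grid.n_rows, self.grid.n_cols, len(FORMS))
        if self.values.shape != expected:
            raise ValueError(f"values shape {self.values.shape} != {expected}")
        if np.any(self.values < 0):
            raise ValueError("concentrations must be non-negative")

    # -- xarray / NetCDF ---------------------------------------------------
    def to_xarray(self) -> xr.Dataset:
        lat, lon = self.grid.cell_centers()
        ds = xr.Dataset(
            {"concentration": (("time", "row", "col", "form"), self.values)},
            coords={
                "time": np.arange(1, self.window.n_hours + 1),
                "row": np.arange(self.grid.n_rows),
                "col": np.arange(self.grid.n_cols),
                "form": list(FORMS),
                "lat": ("row", lat),
                "lon": ("col", lon),
            },
            attrs={
                "origin_lat": self.grid.origin_lat,
                "origin_lon": self.grid.origin_lon,
                "cell_size_lat": self.grid.cell_size_lat,
                "cell_size_lon": self.grid.cell_size_lon,
                "window_start": self.window.start.isoformat(),
                "units": "Bq m-3",
            },
        )
        return ds

    @classmethod
    def from_xarray(cls, ds: xr.Dataset) -> "ConcentrationField":
        from datetime import datetime

        vals = ds["concentration"].transpose("time", "row", "col", "form").values
        grid = GridSpec(
            float(ds.attrs["origin_lat"]),
            float(ds.attrs["origin_lon"]),
            float(ds.attrs["cell_size_lat"]),
            float(ds.attrs["cell_size_lon"]),
            vals.shape[1],
            vals.shape[2],
        )
        window = ExposureWindow(datetime.fromisoformat(str(ds.attrs["window_start"])), vals.shape[0])
        return cls(grid, vals, window)

    def to_netcdf(self, path) -> None:
        self.to_xarray().to_netcdf(path, engine="scipy")

    @classmethod
    def from_netcdf(cls, path) -> "ConcentrationField":
        with xr.open_dataset(path, engine="scipy") as ds:
            return cls.from_xarray(ds.load())

    # -- long-form delimited text -----------------------------------------
    def to_long_frame(self, drop_zeros: bool = True) -> pd.DataFrame:
        h, r, c, f = np.nonzero(self.values) if drop_zeros else np.unravel_index(
            np.arange(self.values.size), self.values.shape
        )
        return pd.DataFrame(
            {
                "hour": h + 1,
                "row": r,
                "col": c,
                "form": np.array(FORMS)[f],
                "value": self.values[h, r, c, f],
            }
        )

    def to_long_csv(self, path, drop_zeros: bool = True) -> None:
        df = self.to_long_frame(drop_zeros)
        with open(path, "w") as fh:
            fh.write(
                f"# origin_lat={self.grid.origin_lat} origin_lon={self.grid.origin_lon} "
                f"cell_size_lat={self.grid.cell_size_lat} cell_size_lon={self.grid.cell_size_lon} "
                f"n_rows={self.grid.n_rows} n_cols={self.grid.n_cols} "
                f"window_start={self.window.start.isoformat()} n_hours={self.window.n_hours}\n"
            )
            df.to_csv(fh, index=False)

    @classmethod
    def from_long_csv(cls, path) -> "ConcentrationField":
        from datetime import datetime

        with open(path) as fh:
            header = fh.readline().lstrip("# ").strip()
            meta = dict(kv.split("=") for kv in header.split())
            df = pd.read_csv(fh)
        grid = GridSpec(
            float(meta["origin_lat"]),
            float(meta["origin_lon"]),
            float(meta["cell_size_lat"]),
            float(meta["cell_size_lon"]),
            int(meta["n_rows"]),
            int(meta["n_cols"]),
        )
        window = ExposureWindow(datetime.fromisoformat(meta["window_start"]), int(meta["n_hours"]))
        vals = np.zeros((window.n_hours, grid.n_rows, grid.n_cols, len(FORMS)))
        fidx = pd.Categorical(df["form"], categories=list(FORMS)).codes
        vals[df["hour"] - 1, df["row"], df["col"], fidx] = df["value"]
        return cls(grid, vals, window)


@dataclass
class HourlyExposureSeries:
    """Per-hour (particulate, elemental, methyl) Bq/m³ along one track."""

    person_id: str
    values: np.ndarray  # (n_hours, 3)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(FORMS):
            raise ValueError("values must have shape (n_hours, 3)")
        if np.any(self.values < 0):
            raise ValueError("concentrations must be non-negative")

    def __len__(self) -> int:
        return self.values.shape[0]


def lookup_concentration(
    track: HourlyTrack, field: ConcentrationField, outside: str = "error"
) -> HourlyExposureSeries:
    """Concentration triple of the grid cell containing the track position,
    hour by hour.

    ``outside`` controls positions outside the field's spatial extent:
    ``"error"`` (default) raises, ``"zero"`` assigns zero concentration and
    logs a warning (the person left the modelled domain).
    """
    if track.window.n_hours != field.window.n_hours:
        raise ValueError("track and field windows differ")
    row, col = field.grid.cell_of(track.latitudes, track.longitudes)
    out = row < 0
    if out.any():
        if outside == "error":
            hours = np.nonzero(out)[0][:3] + 1
            raise ValueError(
                f"person {track.person_id!r} outside the concentration grid "
                f"at hour(s) {hours.tolist()}{'...' if out.sum() > 3 else ''}"
            )
        if outside != "zero":
            raise ValueError("outside must be 'error' or 'zero'")
        log.warning(
            "person %s outside the concentration grid for %d hours; using zero",
            track.person_id,
            int(out.sum()),
        )
    hour = np.arange(field.window.n_hours)
    vals = np.zeros((field.window.n_hours, len(FORMS)))
    inside = ~out
    vals[inside] = field.values[hour[inside], row[inside], col[inside], :]
    return HourlyExposureSeries(track.person_id, vals)


def regrid(field: ConcentrationField, factor: int) -> ConcentrationField:
    """Block-average the field onto a grid ``factor`` times coarser.

    Partial blocks at the domain boundary average only the cells that
    exist (no zero padding), so boundary values are not diluted.  With
    dimensions divisible by ``factor`` the spatial mean of every hour/form
    slice is preserved exactly up to floating error.
    """
    if int(factor) != factor or factor < 1:
        raise ValueError("factor must be a positive integer")
    factor = int(factor)
    if factor == 1:
        return ConcentrationField(field.grid, field.values.copy(), field.window)
    g = field.grid
    nr = -(-g.n_rows // factor)
    nc = -(-g.n_cols // factor)
    sums = np.zeros((field.window.n_hours, nr, nc, len(FORMS)))
    counts = np.zeros((nr, nc))
    for r in range(g.n_rows):
        for c in range(g.n_cols):
            sums[:, r // factor, c // factor, :] += field.values[:, r, c, :]
            counts[r // factor, c // factor] += 1
    vals = sums / counts[None, :, :, None]
    grid = GridSpec(
        g.origin_lat,
        g.origin_lon,
        g.cell_size_lat * factor,
        g.cell_size_lon * factor,
        nr,
        nc,
    )
    return ConcentrationField(grid, vals, field.window)
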