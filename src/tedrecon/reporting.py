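"""Cohort summaries and the end-to-end pipeline.

Per-person doses are aggregated into the study's summary layout — mean,
median and the 5th/25th/75th/95th percentiles of the combined TED per
(municipality, age group) — and :func:`run_pipeline` wires the whole chain
together on a synthetic scenario: generate (or load) questionnaires and
the plume field, apply the completeness filter with received/excluded/
analysed bookkeeping, resample tracks, look up concentrations, compute
inhalation and ingestion TEDs, and summarise.

Percentiles use linear interpolation between order statistics (numpy's
default, the common "type 7" rule); small-group tail percentiles are
sensitive to this convention, so it is fixed here rather than left to the
caller.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .inhalation import (
    CoefficientTable,
    DoseResult,
    apply_short_lived_correction,
    band_age,
    inhalation_ted,
    per_day_breakdown,
)
from .plume import ConcentrationField, lookup_concentration
from .synthetic import ScenarioConfig, generate_cohort, generate_incomplete_records, generate_plume
from .tapwater import (
    LAMBDA_I131_PER_HOUR,
    CompartmentParams,
    ZoneMap,
    ingestion_ted,
    tapwater_series,
)
from .trajectory import PersonRecord, resample_waypoints, validate_track

__all__ = ["SummaryTable", "PipelineResult", "summarize_doses", "run_pipeline", "doses_to_frame"]

log = logging.getLogger(__name__)

_STATS = ("n", "mean", "median", "p5", "p25", "p75", "p95")


@dataclass
class SummaryTable:
    """Summary statistics of combined TED per (municipality, age group)."""

    table: pd.DataFrame  # indexed by group keys; columns _STATS

    def to_csv(self, path) -> None:
        self.table.to_csv(path)


def doses_to_frame(results: list[DoseResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "person_id": [r.person_id for r in results],
            "municipality": [r.municipality for r in results],
            "age_years": [r.age_years for r in results],
            "age_group": [band_age(r.age_years) for r in results],
            "ted_inhal": [r.ted_inhal for r in results],
            "ted_ingest": [r.ted_ingest for r in results],
            "ted_total": [r.ted_total for r in results],
        }
    )


def summarize_doses(
    results, grouping: tuple = ("municipality", "age_group"), value: str = "ted_total"
) -> SummaryTable:
    """Mean/median/5th/25th/75th/95th percentiles of ``value`` per group.

    ``results`` is a list of :class:`DoseResult` or an equivalent
    DataFrame.  Raises on empty input; empty groups simply do not appear.
    """
    df = results if isinstance(results, pd.DataFrame) else doses_to_frame(results)
    if df.empty:
        raise ValueError("no dose results to summarise")

    def _stats(s: pd.Series) -> pd.Series:
        x = s.to_numpy()
        return pd.Series(
            {
                "n": len(x),
                "mean": x.mean(),
                "median": np.quantile(x, 0.5),
                "p5": np.quantile(x, 0.05),
                "p25": np.quantile(x, 0.25),
                "p75": np.quantile(x, 0.75),
                "p95": np.quantile(x, 0.95),
            }
        )

    table = df.groupby(list(grouping))[value].apply(_stats).unstack()
    table["n"] = table["n"].astype(int)
    return SummaryTable(table[list(_STATS)])


@dataclass
class PipelineResult:
    """Everything :func:`run_pipeline` produces."""

    summary: SummaryTable
    doses: pd.DataFrame  # one row per analysed person
    bookkeeping: pd.DataFrame  # received / excluded / analysed per municipality
    field: ConcentrationField
    excluded: pd.DataFrame  # person_id, municipality, reason


def _tapwater_for_zones(config: ScenarioConfig, field: ConcentrationField) -> dict:
    """Drive each zone's one-compartment model with the plume concentration
    (all forms summed) at the zone centroid."""
    series = {}
    for zone in config.zones:
        if zone.is_well:
            continue
        row, col = field.grid.cell_of(zone.lat, zone.lon)
        r, c = int(row), int(col)
        if r < 0:
            raise ValueError(f"zone {zone.zone_id!r} centroid outside the grid")
        driver = field.values[:, r, c, :].sum(axis=1)
        # removal = radioactive decay + water turnover
        params = CompartmentParams(
            zone.transfer_coefficient, LAMBDA_I131_PER_HOUR + zone.turnover_per_h
        )
        series[zone.zone_id] = tapwater_series(driver, params, zone_id=zone.zone_id)
    return series


def run_pipeline(
    config: ScenarioConfig,
    seed: int | None = None,
    coefficients: CoefficientTable | None = None,
    df_mode: str = "global",
    records: list[PersonRecord] | None = None,
    field: ConcentrationField | None = None,
) -> PipelineResult:
    """Run the whole chain on a scenario; pure function of (config, seed).

    Stage logs record the received/excluded/analysed counts per
    municipality.  ``records``/``field`` may be supplied to reuse
    pre-generated inputs (e.g. read from disk); otherwise they are
    synthesised from the scenario.
    """
    seed = config.seed if seed is None else seed
    coefficients = coefficients or CoefficientTable.default()
    window = config.window

    if field is None:
        field = generate_plume(config)
    if records is None:
        records = generate_cohort(config, seed=seed)
        if config.dropout_fraction:
            records = generate_incomplete_records(records, config.dropout_fraction, seed=seed + 1)

    zone_map = ZoneMap(
        pd.DataFrame(
            {
                "zone_id": [z.zone_id for z in config.zones],
                "lat": [z.lat for z in config.zones],
                "lon": [z.lon for z in config.zones],
                "is_well": [z.is_well for z in config.zones],
            }
        )
    )
    tap_series = _tapwater_for_zones(config, field)

    results: list[DoseResult] = []
    excluded_rows = []
    received: dict[str, int] = {}
    excluded_n: dict[str, int] = {}
    for rec in records:
        muni = rec.municipality or "unknown"
        received[muni] = received.get(muni, 0) + 1
        verdict = validate_track(rec.waypoints, window)
        if not verdict.accepted:
            excluded_n[muni] = excluded_n.get(muni, 0) + 1
            excluded_rows.append(
                {"person_id": rec.person_id, "municipality": muni, "reason": verdict.reason}
            )
            continue
        try:
            track = resample_waypoints(
                rec.waypoints, window, person_id=rec.person_id, age_years=rec.age_years
            )
            series = lookup_concentration(track, field, outside="zero")
            params = coefficients.params_for_age(rec.age_years)
            per_hour, _ = inhalation_ted(series, params, track.micro_env, df_mode, window)
            corrected, ted_inhal = apply_short_lived_correction(
                per_hour, coefficients.sf_for_age(rec.age_years), window
            )
            _, ted_ingest = ingestion_ted(track, zone_map, tap_series, params, window)
        except Exception as exc:  # pragma: no cover - defensive context wrapper
            raise RuntimeError(f"pipeline failed for person {rec.person_id!r}: {exc}") from exc
        results.append(
            DoseResult(
                rec.person_id,
                rec.age_years,
                ted_inhal,
                ted_ingest,
                per_day=per_day_breakdown(corrected, window),
                municipality=muni,
            )
        )

    bookkeeping = pd.DataFrame(
        {
            "municipality": sorted(received),
            "received": [received[m] for m in sorted(received)],
            "excluded": [excluded_n.get(m, 0) for m in sorted(received)],
        }
    )
    bookkeeping["analysed"] = bookkeeping["received"] - bookkeeping["excluded"]
    for _, row in bookkeeping.iterrows():
        log.info(
            "municipality %s: received %d, excluded %d, analysed %d",
            row["municipality"],
            row["received"],
            row["excluded"],
            row["analysed"],
        )

    doses = doses_to_frame(results)
    summary = summarize_doses(doses)
    excluded_df = pd.DataFrame(excluded_rows, columns=["person_id", "municipality", "reason"])
    return PipelineResult(summary, doses, bookkeeping, field, excluded_df)
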