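# Methods

This note records the modelling choices behind `tedrecon`, the defaults they
produce, and what the synthetic test bed does and does not establish.

## Exposure window and trajectories

All doses accumulate over a fixed 330-hour window, 06:00 JST 12 March 2011 to
24:00 JST 25 March 2011 ("midnight ending 25 March" — the only reading
consistent with a 330-hour sum starting at 06:00). Hour *i* (1-based) spans
`[start+(i−1)h, start+i·h)`.

Questionnaire waypoints are interpolated linearly in latitude/longitude
degrees, proportional to elapsed time — straight-line, constant-speed travel.
At the sub-100-km distances involved, the difference from great-circle or
road-network routing is far below the ~1 km grid resolution. Each hour is
represented by a single timestamp at its midpoint (hh:30), which is unbiased
for constant-speed motion; `hour_position="start"` is available for
sensitivity checks. Hours whose bracketing segment involves movement are
flagged `vehicle`; stay hours inherit the environment stated at the start of
the stay, with `unknown` defaulting to `indoor` (conservative, since indoor
hours receive the sheltering factor).

A record is *analysed* only if its waypoints explicitly cover the whole
window: multi-waypoint records must start at/before 06:00 12 March and end
at/after 24:00 25 March, any stated unknown-whereabouts interval (waypoint
without coordinates) excludes the record, and a single-waypoint record is
read as a stated stay covering the window. Validation returns a verdict with
a machine-readable reason (`incomplete_window`, `unknown_whereabouts`, …) and
never raises on content; resampling, by contrast, raises hard errors naming
the person.

## Concentration field and lookup

The field stores hourly Bq/m³ of the three ¹³¹I chemical forms at 1 m height
on a regular lat/lon grid, hour-major so a person's 330 lookups stream
contiguously. Cells are half-open `[edge, next edge)` with the extreme upper
edge assigned to the last cell — deterministic, no double counting. Lookup is
nearest-cell (the containing cell), matching the database-lookup character of
the original workflow; no bilinear interpolation. Positions outside the
domain either raise (default) or contribute zero with a logged warning.
Block-average regridding supports grid-resolution sensitivity studies;
partial blocks at the boundary average only existing cells to avoid
artificial dilution.

On-disk formats: NetCDF3 via xarray's scipy engine (self-describing, grid
origin and cell size as attributes) and a long-form delimited text format
(`hour,row,col,form,value` with a metadata header line).

## Dose formulas

Inhalation: `Σ V/24 · (Σ_forms C·e) · FC · DF` per hour, summed over the
window. `df_mode="global"` applies `DF_shelter` to every hour, exactly as the
formula is written and as the default; `df_mode="per_hour"` uses the
questionnaire flags (outdoor hours DF = 1, indoor and vehicle hours
sheltered — vehicles with internal air circulation filter fine particulates
comparably to buildings). Ages are banded half-open onto the reporting grid
(1, 5, 10, 15, 20): [0,3)→1, [3,8)→5, [8,13)→10, [13,18)→15, [18,∞)→20.

The SF correction multiplies the ¹³¹I-only dose accrued inside calendar
windows (12–13 March ×1.59, 15–16 March ×1.08 for 1-year-olds) to account for
co-inhaled ¹³²I/¹³²Te/¹³³I. SF values for other ages are not published;
the shipped table reuses the age-1 values for all ages with a logged
warning — users with vetted age-specific values supply their own table. SF is
applied to the inhalation component only; the ingestion pathway's nuclide
mix is not corrected.

Ingestion: `Σ pTWI/24 · C_tap · e_ingest · FC`, scaled by `tap_fraction`.
Zone assignment is by hourly position (a person drinks the water of wherever
they are that hour). Drinking intermittency is not modelled — `pTWI/24`
spreads intake uniformly, exactly as the formula does. Well-water zones
contribute zero.

## Coefficient table

`data/coefficients.yaml` ships representative age-dependent values in the
style of ICRP 71 (inhalation) / ICRP 67 (ingestion): ventilation volumes
5.16–22.2 m³/day, thyroid TED conversion factors decreasing roughly tenfold
from infants to adults, `e_ingest(1 y) = 3.75×10⁻³ mSv/Bq`, and pTWI medians
from ~0.86 L/day (age 1, the median of the gamma intake distribution) to
1.5 L/day. The table is data, not code: any study should substitute its own
vetted coefficients via `CoefficientTable.from_yaml`. The uncertainty
results are fold *ratios* and do not depend on these values.

## Tap-water compartment model

The published workflow states only that tap-water concentrations come from a
one-compartment model; the functional form and parameters are not printed.
We implement the standard first-order balance with exact exponential stepping,
`C(i) = C(i−1)·e^(−kΔt) + input_rate·driver(i)`, with both rates explicit
configuration (`k` ≥ λ(¹³¹I) = ln2/8.02 d enforced). Reproducing a specific
study's tap-water series therefore requires that study's parameter values and
driver definition; the synthetic scenario drives each zone with the plume
concentration at the zone centroid times a transfer coefficient.

## Uncertainty propagation

Both dose formulas are products, so parameter uncertainty is a multiplicative
fold factor R of the central point estimate, independent of dose magnitude.

Central denominators (the published workflow does not define them): FC₀ =
18.6/30, DF₀ = the triangular mode 0.5, pTWI₀ = the gamma median (pTWI is
defined as a median volume), ATDM multiplier 1 (the geometric mean). A
`ptwi_central="mean"` flag exists for sensitivity.

FC samples are drawn from the normal truncated at zero (negative uptake is
unphysical); the truncated probability is ~10⁻³ at mean/SD ≈ 3.1 and the
effect on the quantiles is negligible.

Latin-Hypercube sampling places exactly one draw per equal-probability
stratum per marginal, with independent stratum permutations across
variables; per-variable substreams derive deterministically from one master
seed. Degenerate marginals (GSD 1, SD 0, zero-width triangular) are point
masses, so single-parameter intervals and the (1, 1) limit are exact.

The two-dimensional ingestion Monte Carlo draws 1000 outer pTWI values
(variability) and, per outer draw, 5000 inner LHS values of (L, FC)
(uncertainty). How such a nested simulation collapses to one printed interval
is a genuine design choice; we report as the headline the *median across the
outer loop of the per-outer uncertainty intervals* — the uncertainty band at
the typical individual — because it preserves the variability/uncertainty
separation the 2-D design exists for, and we additionally return the pooled
outer×inner interval and the full per-outer table. At the default PDFs the
headline is ≈ (0.093, 8.9)-fold and the pooled interval ≈ (0.074, 10.2)-fold;
the published interval for this pathway corresponds to the former. DF is
excluded from the ingestion ratio: sheltering does not affect drinking water.

## Synthetic scenario

The generator emulates the study conditions the pipeline was built for:
multi-episode plumes on a 100×100 grid of ~1 km cells, municipality cohorts
with configured evacuation fractions and timings, and tap-water drivers
coupled to the plume. Releases are Gaussian puffs (one per hour per episode)
advected by a constant per-episode wind, with puff variance growing linearly
in travel time and ¹³¹I decay applied — analytic, mass-conserving and linear
in source strength. It is deliberately *not* an atmospheric-transport model:
no terrain, no wet/dry deposition physics, no meteorological variability, and
no attempt to reproduce the actual March 2011 plume geometry. Source-strength
units are nominal, chosen so downwind cells see 10³–10⁵ Bq/m³ and cohort mean
TEDs land in the few-mSv range typical of the study area. The chemical-form
partition of the source is a config triple (default equal thirds).
Indoor/outdoor flags are sampled per stay segment (waypoint granularity),
not per hour; hourly flags derive from resampling.

Consequently, passing the end-to-end tests shows the pipeline's bookkeeping,
determinism and dose gradients are correct *given* a concentration field and
questionnaires — it says nothing about the fidelity of any real dispersion
database or survey data.

## Problem sizes and numerics

The test suite runs the full published Monte-Carlo sizes (500 000 LHS;
1000×5000 2-D MC) because they complete in seconds; the end-to-end scenario
uses 3 000 persons on the 100×100 grid, a scale chosen to exercise every code
path in well under a minute. Floating-point equivalence between vectorised
implementations and naive per-hour oracles is asserted at 12 significant
digits; Monte-Carlo assertions use analytic standard errors of sample
quantiles (√(p(1−p)/n)/f(q)), which are conservative for LHS. Percentile
summaries use linear interpolation between order statistics (numpy default,
"type 7") — fixed because small-group tail percentiles are
convention-sensitive.

## Known limitations

- External (cloudshine/groundshine) and food-chain ingestion doses are out of
  scope, as in the workflow this package reimplements.
- Thyroid-blocking prophylaxis and internal dosimetry beyond fixed conversion
  factors are not modelled.
- SF uncertainty and tap-water compartment-parameter uncertainty are not part
  of the uncertainty model.
- The straight-line travel assumption and nearest-cell lookup are shared with
  the original workflow; both are sources of individual-level error that the
  lognormal ATDM term is meant to absorb, not resolve.
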