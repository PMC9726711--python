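# tedrecon

Reconstruction of **thyroid equivalent doses (TEDs)** to individuals from the
radioiodine released in a nuclear accident, by combining each person's hourly
whereabouts with a gridded atmospheric-dispersion concentration field. The
package implements the questionnaire-based dose-reconstruction workflow used
to estimate children's thyroid doses after the March 2011 Fukushima Daiichi
accident, exercised end-to-end on synthetic plume fields and synthetic
questionnaires, and is aimed at radiation epidemiologists and dosimetrists who
want a reusable, testable version of that pipeline.

## The model

**Whereabouts → hourly track.** A questionnaire record is a sequence of
timestamped waypoints (lat/lon, indoor/outdoor/vehicle). Each record is
resampled to the fixed 330-hour exposure window (06:00 JST 12 March –
24:00 JST 25 March 2011), assuming straight-line, constant-speed movement
between waypoints. Records that do not cover the whole window are excluded,
with received/excluded/analysed bookkeeping.

**Inhalation.** With hourly ground-level concentrations `C_i` (Bq/m³) of the
three ¹³¹I chemical forms (particulate, elemental vapour, methyl iodide)
looked up along the track,

```
TED_inhal = Σ_{i=1..330}  V/24 · (C_i,p·e_p + C_i,el·e_el + C_i,met·e_met) · FC · DF_shelter
```

where `V` is the age-specific daily ventilation volume (m³/day), `e_*` are
age-dependent TED conversion factors (mSv/Bq), `FC = 18.6/30` corrects the
ICRP dose coefficient for the lower Japanese thyroid iodine uptake, and
`DF_shelter` (central value 0.5) accounts for sheltering. The ¹³¹I-only TED
accrued on 12–13 and 15–16 March is multiplied by short-lived-nuclide factors
`SF` (1.59 and 1.08 for 1-year-olds) to fold in ¹³²I, ¹³²Te and ¹³³I.

**Ingestion.** Tap-water concentrations per supply zone follow a
one-compartment model `dC/dt = input − k·C` (k ≥ the ¹³¹I decay constant,
half-life 8.02 d), and

```
TED_ingest = Σ_{i=1..330}  pTWI/24 · C_i,tap · e_ingest · FC
```

with `pTWI` the age-specific median daily tap-water intake. Well water is
assumed uncontaminated; a `tap_fraction` (e.g. 0.7) scales the dose where
wells dominate.

**Uncertainty.** Parameter uncertainty propagates as a *fold factor* R of the
central estimate: for inhalation `R = L·(FC/0.62)·(DF/0.5)` with
L ~ lognormal(GM 1, GSD 3) (dispersion-model error), FC ~ N(18.6, 6.0)/30,
DF ~ Triangular(0.1, 0.5, 0.95), sampled with 500 000 Latin-Hypercube draws;
for ingestion a two-dimensional Monte Carlo (1000 outer draws of
pTWI ~ Gamma(θ = 186.15, k = 4.94009) for inter-individual variability ×
5000 inner draws of (L, FC) for uncertainty) keeps variability and
uncertainty separate.

## Worked example

```python
import dataclasses
from tedrecon import default_scenario, run_pipeline, UncertaintyModel, inhalation_fold_ui

cfg = dataclasses.replace(default_scenario(n_per_municipality=200, seed=1),
                          dropout_fraction=0.01)
result = run_pipeline(cfg, seed=1)
print(result.bookkeeping.to_string(index=False))
print(result.summary.table.loc[(slice(None), 1), :].round(2).to_string())

fi = inhalation_fold_ui(UncertaintyModel(seed=1), n=500_000)
print(f"inhalation 95% UI: {fi.lower_fold:.3f}- to {fi.upper_fold:.2f}-fold")
```

prints

```
 municipality  received  excluded  analysed
  inland_town       200         1       199
off_axis_town       200         2       198
 on_axis_town       200         3       197

                          n  mean  median    p5   p25   p75    p95
municipality  age_group
inland_town   1          24  4.88    4.26  0.87  2.18  6.16  12.04
off_axis_town 1          26  0.00    0.00  0.00  0.00  0.00   0.00
on_axis_town  1          25  3.82    2.81  0.56  0.96  6.57   8.38

inhalation 95% UI: 0.079- to 9.65-fold
```

The scenario synthesises two release episodes on a 100×100 ~1 km grid: the
first plume blows north over `on_axis_town`, the second north-west over
`inland_town`, while `off_axis_town` sits south of both tracks. The summary
rows are combined inhalation + ingestion TEDs (mSv) for the 1-year age group:
downwind towns accumulate several mSv on average while the off-axis town gets
essentially nothing, and a ~1% batch of deliberately incomplete questionnaires
is excluded by the completeness filter (`analysed = received − excluded`).
The fold interval says the 95% uncertainty band on any individual inhalation
dose spans roughly 0.08× to 9.7× its central estimate, dominated by the
dispersion-model lognormal.

The same stages are scriptable from a shell: `tedrecon synth`, `lookup`,
`uq`, `summarize` and `run` (see `tedrecon --help`).

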