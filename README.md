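# nutricohort

Simulation and analysis toolkit for **digital nutrition cohorts**: studies in
which participants track food intake, continuous glucose, sleep, physical
activity, and gut microbiota remotely, with no site visits. Such cohorts
raise two recurring methodological questions — *do participants stay?* (
retention/adherence) and *can the self-logged data be trusted?* (data
quality). `nutricohort` packages the standard battery of answers as tested,
reusable code, together with a synthetic multimodal cohort generator so the
whole pipeline runs without any participant data.

It is aimed at biostatisticians and epidemiologists designing or analyzing
remote nutrition studies.

## What it computes

**Glycemic analytics** (`nutricohort.cgm`) on 15-minute CGM traces:

- time in range: fractions of readings below / in / above the consensus
  target band [3.9, 10] mmol/L;
- MAGE, the mean amplitude of glycemic excursions — the mean of
  |peak − nadir| over turning-point excursions exceeding one standard
  deviation of the trace;
- the **peak–meal matching experiment**: every CGM peak (a local maximum
  above the participant's 90th glucose percentile) is checked for a logged
  dish of ≥ 50 kcal in the 90 minutes before it, and in the same window
  translated two hours earlier (control). Per-participant matched
  proportions are compared with a one-sided Wilcoxon rank-sum test — the
  key check that food logs and sensor data agree;
- pooled weekday vs weekend diurnal glucose curves and their
  cross-correlation lag.

**Dietary intake** (`nutricohort.food`): participant-day aggregation,
removal of days below 1000 kcal, and inverse-frequency weighted individual
means — each day weighted by 1 / (count of the participant's days in the
same weekday × meteorological-season cell), algebraically the mean of cell
means, so that rare day types are not swamped. Plus mealtime histograms,
the weekend mealtime-shift statistic, and survey-style stratified
summaries (energy, meat, dairy, water, > 5 daily fruit & veg portions).

**Sleep and activity** (`nutricohort.sleep_activity`): 4–12 h duration
filter, circular-mean bed/wake clock times, weekday/weekend paired
contrasts, WHO 75 min/week activity classification.

**Cohort accounting** (`nutricohort.cohort_stats`): demographic recoding
(income/age/education/smoking/health/BMI at WHO cutoffs), completion-rate
tables per cohort and stratum, per-modality adherence day counts, exit
reason breakdowns.

**Microbiota comparison** (`nutricohort.microbiota`): 5000-read depth
filter, genus-level aggregation of lineage-annotated abundance tables,
relative abundances, Bray–Curtis dissimilarity d(x,y) = Σ|xᵢ−yᵢ| / Σ(xᵢ+yᵢ),
and classical PCoA (eigendecomposition of the double-centered −½D²).

**Synthetic cohort generator** (`nutricohort.synthetic`): glucose =
baseline + circadian sinusoid + gamma-pulse excursions per logged meal +
AR(1) noise, censored by an 8-hour sensor memory under renewal scanning;
meals/snacks with planted weekend shifts; nightly sleep with a planted
weekend wake shift; a four-phase enrollment funnel with per-phase dropout;
Dirichlet-multinomial microbiota with a between-group offset. Every
planted parameter lands in a truth record for recovery scoring.

## Worked example

```python
import nutricohort as nc
from nutricohort import cgm, food

cfg = nc.SimulationConfig(n_participants=50, seed=3, cohort_fraction_c=0.0)
ds  = nc.generate_cohort(cfg)

traces = cgm.traces_from_frame(ds.glucose)
exp = cgm.peak_match_experiment(traces, ds.dishes)
print(exp["median_experimental"], exp["median_control"], exp["p_value"])
# 0.9333333333333333 0.0898989898989899 1.5394006088765416e-15

shift, p = food.mealtime_shift_test(ds.dishes)
print(round(shift, 1), p)   # 33.5 1.2777256923979943e-05
```

93% of detected glucose peaks are preceded (within 90 min) by a logged
dish of ≥ 50 kcal, against 9% for the control window two hours earlier —
the planted meal→glucose mechanism is clearly visible, p ≪ 0.001. Weekend
dishes are logged on average 33.5 minutes later than weekday dishes,
recovering the planted 30-minute weekend shift within sampling noise.

The same pipeline runs from the shell:

```sh
nutricohort simulate --out data/ --seed 3
nutricohort report --data-dir data/ --out data/report.json --plots
nutricohort analyze cgm --glucose data/glucose.csv --dishes data/dishes.csv --out cgm.json
```

## Layout

- `src/nutricohort/` — library modules (`synthetic`, `cgm`, `food`,
  `sleep_activity`, `cohort_stats`, `microbiota`, `report`, `cli`)
- `tests/` — pytest suite, including brute-force oracles for MAGE,
  inverse-frequency weighting, Bray–Curtis, and completion rates
- `docs/methods.md` — model and design notes
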