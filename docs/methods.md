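# Methods notes

## Scope and philosophy

`nutricohort` implements the analysis battery of a remote ("digital")
nutrition cohort — glycemic summaries, the peak–meal matching experiment,
weighted dietary intake, weekday/weekend behavioral contrasts, enrollment
and adherence accounting, and genus-level microbiota comparison — plus a
synthetic data generator that emulates the statistical structure those
analyses assume. Because real participant-level data of this kind is not
publicly deposited, the generator is first-class, tested code: it is the
substrate on which every cohort-level property of the pipeline is
demonstrated and scored against planted ground truth.

## The synthetic cohort model

### Glucose

A participant's interstitial glucose on the 15-minute grid is

    G(t) = b + A·sin(2π(t − φ)/24 h) + Σ_meals a_m · κ(t − t_m) + ε(t)

with baseline `b` = 5.0 mmol/L, circadian amplitude `A` = 0.3 mmol/L
(acrophase 16:00), per-meal amplitude `a_m` = 0.25 mmol/L per 100 kcal,
and AR(1) noise `ε` with lag-1 coefficient 0.6 and marginal SD 0.25
mmol/L (the autocorrelation gives a realistic density of spurious local
maxima; white noise would make peak detection unrealistically easy).
Values are clipped below at 2.5 mmol/L.

The excursion kernel κ is a gamma-shaped pulse with shape 5, rescaled so
its mode sits at the peak delay (45 min default) with unit height, and
truncated at the excursion duration (150 min), where it has decayed to
≈ 1% of its peak. The kernel is phenomenological: any smooth nonnegative
unimodal pulse would serve; gamma is conventional and closed-form. No
insulin dynamics, glycemic-index effects, or menstrual-cycle modulation
are modeled — passing tests say the *pipeline* recovers planted structure,
not that the generator is physiological.

### Sensor-memory censoring

The sensor retains 8 hours of readings; a reading survives only if a scan
occurs within 8 h after it. Scans form a renewal process with exponential
gaps (mean 4 h default) from wear start to wear end. With a 4-hour mean
the expected retained fraction is E[min(g, 8)]/E[g] = 1 − e⁻² ≈ 86.5%
(edge effects at the wear end pull it slightly lower); real cohorts that
prompt participants to scan see far less loss.

### Meals, sleep, funnel

Three main meals per day (clock-time means 08:00 / 12:30 / 19:00, SD
30 min) plus Poisson(1)/day snacks uniform over 09:00–23:00. On Saturdays
and Sundays *all* intake-time means — snacks included — shift later by
`weekend_meal_shift` (30 min default), so the shift is identifiable from
the all-dish mealtime statistic. Dish energies are lognormal (log-mean
6.2, log-SD 0.35 for meals; 4.9/0.5 for snacks), truncated to [10, 3000]
kcal, which implies roughly 1,700 kcal of logged intake per day — at the
low end of plausible adult intake, consistent with the under-reporting
typical of food diaries. Food-group masses per dish are independent gamma
draws with means chosen to give survey-plausible daily totals.

Sleep: bed 23:40, wake 07:30, Gaussian jitter SD 30 min, weekend wake
shifted +30 min, 20% of nights missing at random. The enrollment funnel
walks enrolled → preparatory → tracking → completed with per-phase exit
probabilities (0.15, 0.12, 0.08 default, ≈ 69% completion); exit reasons
are drawn as time 27% / interest 20% / none 14% / other 39%. Participants
exiting during tracking receive a truncated window (uniform over
1..days−1). Missingness and dropout are independent across participants;
no adherence-fatigue trend is modeled.

### Microbiota

60 taxa with six-rank lineages mapping onto 25 genera (8% of taxa lack a
genus, exercising the unclassified-pooling path). A shared lognormal base
composition is tilted per group by ±offset/2 in log space (offset 0.8
default; 0 makes groups identical; an infinite offset assigns disjoint
round-robin supports). Samples are Dirichlet(concentration 50 × group
mean) compositions with multinomial counts at lognormal depths around
20,000 reads.

What the generator does **not** emulate: real compositional correlation
structure, sequencing platform effects (16S vs shotgun), geographic
clustering, true dietary–glycemic–microbiota couplings. Passing tests
demonstrate pipeline correctness and parameter recovery, not biological
fidelity.

## Analysis conventions and numerical choices

- **TIR**: in-range is the closed interval [3.9, 10]; readings exactly at
  a cutoff are in-range ("below"/"above" read strictly). Components sum
  to 100 exactly by construction.
- **MAGE**: Service-style. Turning points are found on a centered 3-point
  moving average (endpoints passed through; equal-value runs compressed
  to their midpoint, sign changes of successive differences are turning
  points); amplitudes are taken between *raw* readings at turning-point
  indices; an excursion qualifies if its amplitude exceeds one sample SD
  (ddof = 1) of the raw trace; ascending and descending excursions are
  both averaged. Published MAGE tools differ in smoothing and SD
  convention, so absolute values are comparable only within a convention;
  the implementation is pinned to an exhaustive brute-force oracle.
- **Peak detection**: a local maximum must be ≥ both neighbors and > at
  least one; plateaus collapse to their midpoint; readings with a > 30-min
  gap to either neighbor are ineligible (they sit at sensor-gap edges);
  the threshold is the participant's empirical 90th percentile, strict.
- **Matching windows** are half-open: experimental (t−90 min, t],
  control (t−210 min, t−120 min] — the control is the experimental window
  translated two hours earlier, and the defaults never overlap. A dish at
  the peak instant counts; a dish exactly at the lower edge does not.
- The cohort test is the *independent* two-sample rank-sum form even
  though proportions are paired per participant, matching the test named
  in the field's reports; a paired signed-rank alternative sits behind
  `paired=True`. When every proportion ties, p is reported as 0.5 (no
  separation).
- **Diurnal lag**: circular cross-correlation over 15-min bins within
  ±120 min, after mean-centering and circular linear interpolation of
  residual missing bins; curves with > 25% missing bins are rejected.
  Positive lag = weekend later.
- **Mealtime statistics** use a 04:00 day boundary (a Saturday 01:00
  dinner belongs to Friday evening) and plain minute means — justified
  because the boundary removes wrap-around; daily *energy totals* use
  plain calendar dates, mirroring the distinct uses of the two
  aggregations. Sleep clock times, which do wrap, use circular means;
  for spreads under ~6 h these agree with unwrapped naive means.
- **Inverse-frequency weighting** is per participant over
  weekday × season cells of kept (≥ 1000 kcal) days: w_d = 1/n_cell(d),
  equivalently the unweighted mean of cell means. Stratum summaries
  average participant means unweighted within strata. The fruit & veg
  portion is 120 g (Swiss five-a-day convention), configurable.
- **Sleep**: nights keyed by wake date; weekend = Saturday/Sunday wake.
  Durations outside [4 h, 12 h] are excluded (boundaries kept).
- **Microbiota**: depth filter strict below 5000 reads; genus aggregation
  pools missing genera per family as `unclassified_<family>` to conserve
  totals (aggregation and renormalization commute). Bray–Curtis is
  computed on the shared taxon union with absent = 0. PCoA reports
  negative eigenvalues untouched by default (Lingoes correction behind a
  flag); variance proportions are over the positive eigenvalue mass;
  coordinates are unique up to sign/rotation within eigenvalue ties.
  Cross-study merging outer-joins genera on relative abundances (counts
  converted with a warning) since depths across platforms are
  incomparable.
- **Recoding** brackets are lower-bound inclusive exactly as printed
  (income 6000 → "6000-8999"; age 35 → "35-49"; BMI 25.0 → Overweight);
  occasional smokers are current smokers; missing income/education become
  an explicit "missing" level with a warning (no imputation — multiple
  imputation is out of scope).
- The adherence target is ≥ (tracking_days − 1) food days above 1000 kcal
  (13 of 14 for the 14-day arm, 27 of 28 for the 28-day arm).
  Questionnaire-day counts are not implemented: no questionnaire stream
  exists in the data contracts.

## Determinism and problem sizes

All randomness flows from integer seed sequences; a fixed seed reproduces
a byte-identical dataset. Default test and acceptance problem sizes —
cohorts of 30–120 participants, 100 random traces for oracle ties, 1000
random participants for the weighting oracle, 50 random tables for
Bray–Curtis, a 2000-participant ledger for the completion closed form —
were chosen so the full suite runs in well under a minute while leaving
the statistical assertions comfortable margins.

## Known limitations

- The generator's defaults are design choices, not estimates fitted to
  any cohort; cohort-level magnitudes (e.g. MAGE means, energy intake)
  are therefore in realistic ranges but not calibrated to any study.
- The peak–meal experiment inherits the generator's idealization that
  *every* excursion is meal-driven; real matched proportions are lower.
- `weekday_weekend_lag` resolves lags only to the 15-min bin width.
- PCoA stores a dense distance matrix; fine for thousands of samples,
  not for hundreds of thousands.
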