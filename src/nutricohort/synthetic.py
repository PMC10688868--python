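"""Synthetic multimodal cohort generator.

Emulates the data streams of a two-arm digital nutrition cohort so the
whole analysis pipeline is testable without any download: interstitial
glucose every 15 minutes driven by logged meals, dish logs with energy and
food-group masses, nightly sleep records, activity records, an enrollment
funnel with phase-specific dropout, a demographics table, and a
compositional genus-level microbiota count table with a configurable
between-group offset.

The generative model for glucose is deliberately phenomenological:

    G(t) = baseline + A sin(2pi (t - phase)/24h)
           + sum_meals gain * kcal/100 * pulse(t - t_meal) + AR(1) noise

where ``pulse`` is a gamma-shaped kernel with mode ``excursion_peak_delay``
minutes and support ``excursion_duration`` minutes.  Sensor-memory
censoring then deletes every reading not followed by a scan within
``sensor_memory`` hours, scans arriving as a renewal process with
exponential gaps.

Every planted parameter (weekend meal/wake shifts, peak delay, dropout
probabilities, per-day energy totals) is recorded in the ``truth`` block of
the returned dataset so downstream estimators can be scored against it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .errors import ConfigurationError

__all__ = [
    "AbundanceTable",
    "CohortDataset",
    "generate_cohort",
    "generate_meal_schedule",
    "generate_glucose_trace",
    "apply_sensor_censoring",
    "generate_sleep_records",
    "generate_activity_records",
    "generate_enrollment_ledger",
    "generate_demographics",
    "generate_abundance_table",
    "write_dataset",
]

GLUCOSE_COLUMNS = ["participant_id", "timestamp", "glucose_mmol_l"]
DISH_COLUMNS = [
    "participant_id", "timestamp", "kcal",
    "meat_g", "dairy_g", "water_ml", "fruitveg_g", "method",
]
SLEEP_COLUMNS = ["participant_id", "bedtime", "waketime", "source"]
ACTIVITY_COLUMNS = [
    "participant_id", "start", "end", "kind", "source", "calories", "intensity",
]
LEDGER_COLUMNS = ["participant_id", "cohort", "phase", "exit_reason"]

PHASES = ["enrolled", "preparatory", "tracking", "completed"]
EXIT_REASONS = ["time", "interest", "none", "other"]
EXIT_REASON_PROBS = [0.27, 0.20, 0.14, 0.39]

_KERNEL_SHAPE = 5.0  # gamma shape of the excursion pulse; mode = peak delay

# mean grams per main meal; snacks are scaled down
_GROUP_MEANS = {"meat_g": 27.0, "dairy_g": 36.0, "water_ml": 280.0, "fruitveg_g": 85.0}


@dataclass
class AbundanceTable:
    """Samples x taxa abundance matrix with lineage strings and group labels.

    ``counts`` rows are samples; ``lineages`` maps each taxon column to a
    semicolon-delimited lineage (kingdom;phylum;class;order;family;genus).
    """

    counts: pd.DataFrame
    lineages: pd.Series
    groups: pd.Series
    is_relative: bool = False

    def __post_init__(self):
        if (self.counts.values < 0).any():
            raise ConfigurationError("abundance counts must be nonnegative")


@dataclass
class CohortDataset:
    participants: pd.DataFrame
    ledger: pd.DataFrame
    glucose: pd.DataFrame
    dishes: pd.DataFrame
    sleep: pd.DataFrame
    activity: pd.DataFrame
    abundances: AbundanceTable | None
    truth: dict = field(default_factory=dict)


def _rng(config: SimulationConfig, *stream) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed % (2**31), *stream]))


# ---------------------------------------------------------------------------
# demographics & enrollment

def generate_demographics(config: SimulationConfig) -> pd.DataFrame:
    """Raw (un-recoded) demographics table for all enrolled participants."""
    rng = _rng(config, 1)
    n = config.n_participants
    ids = [f"P{i:04d}" for i in range(n)]
    cohort = np.where(rng.random(n) < config.cohort_fraction_c, "C", "B")
    gender = np.where(cohort == "C", "Female",
                      np.where(rng.random(n) < 0.5, "Female", "Male"))
    age = np.clip(np.round(rng.normal(38, 13, n)), 18, 79).astype(int)
    age = np.where(cohort == "C", np.clip(age, 18, 45), age)
    height = np.round(rng.normal(170, 9, n), 1)
    bmi = np.clip(rng.normal(23.5, 3.5, n), 16, 45)
    weight = np.round(bmi * (height / 100.0) ** 2, 1)
    income = np.round(rng.lognormal(np.log(8000), 0.45, n), 0)
    freq = rng.integers(0, 7, n)
    dur = np.where(freq > 0, np.clip(np.round(rng.normal(45, 15, n)), 10, 180), 0)
    return pd.DataFrame({
        "participant_id": ids,
        "cohort": cohort,
        "gender": gender,
        "age": age,
        "height_cm": height,
        "weight_kg": weight,
        "income_chf_month": income,
        "household": rng.choice(
            ["alone", "couple w. children", "couple w.out children", "other"],
            n, p=[0.18, 0.31, 0.35, 0.16]),
        "citizenship": rng.choice(["Swiss", "Binational", "Foreigner"],
                                  n, p=[0.52, 0.11, 0.37]),
        "education": rng.choice(
            ["mandatory", "primary school", "high school", "professional diploma",
             "university"], n, p=[0.01, 0.01, 0.12, 0.12, 0.74]),
        "smoking": rng.choice(["never", "former", "occasionally", "daily"],
                              n, p=[0.48, 0.42, 0.05, 0.05]),
        "health": rng.choice(
            ["not good", "average", "somewhat good", "good", "very good"],
            n, p=[0.01, 0.04, 0.04, 0.55, 0.36]),
        "urbanity": rng.choice(["urban", "rural"], n, p=[0.77, 0.23]),
        "linguistic_region": rng.choice(["German", "Latin"], n, p=[0.5, 0.5]),
        "exercise_freq_per_week": freq,
        "exercise_duration_min": dur,
        "dietary_restriction": rng.random(n) < 0.12,
        "phone_type": rng.choice(["Android", "iPhone"], n, p=[0.45, 0.55]),
    })


def generate_enrollment_ledger(config: SimulationConfig,
                               cohort: Sequence[str] | None = None) -> pd.DataFrame:
    """Walk each participant through the enrollment funnel.

    Phases are enrolled -> preparatory -> tracking -> completed; at each of
    the three transitions the participant exits with the configured
    probability and a sampled reason; completers carry ``not_applicable``.
    """
    for p in config.dropout_probs:
        if not 0.0 <= p <= 1.0:
            raise ConfigurationError(f"dropout probability {p} outside [0, 1]")
    rng = _rng(config, 2)
    n = config.n_participants
    if cohort is None:
        cohort = ["B"] * n
    rows = []
    for i in range(n):
        phase = "completed"
        reason = "not_applicable"
        for stage, p_exit in zip(PHASES[:3], config.dropout_probs):
            if rng.random() < p_exit:
                phase = stage
                reason = rng.choice(EXIT_REASONS, p=EXIT_REASON_PROBS)
                break
        rows.append((f"P{i:04d}", cohort[i], phase, reason))
    return pd.DataFrame(rows, columns=LEDGER_COLUMNS)


# ---------------------------------------------------------------------------
# meals & glucose

def _is_weekend(ts: pd.Timestamp) -> bool:
    return ts.weekday() >= 5


def generate_meal_schedule(start: pd.Timestamp, n_days: int,
                           config: SimulationConfig,
                           rng: np.random.Generator) -> pd.DataFrame:
    """Meal events for one participant's tracking window.

    Three main meals per day with Gaussian jitter around configured clock
    means plus Poisson snacks; on Saturdays and Sundays every intake-time
    mean (meals and snacks) is shifted later by ``weekend_meal_shift``.
    Energies are lognormal, truncated to [10, 3000] kcal.
    """
    start = pd.Timestamp(start).normalize()
    rows = []
    mu_m, sd_m = config.dish_kcal_lognormal
    mu_s, sd_s = config.snack_kcal_lognormal
    for d in range(n_days):
        day = start + pd.Timedelta(days=d)
        shift = config.weekend_meal_shift if _is_weekend(day) else 0.0
        minutes = [m + shift + rng.normal(0, config.meal_time_sd)
                   for m in config.meal_time_means]
        kcals = np.clip(rng.lognormal(mu_m, sd_m, len(minutes)), 10, 3000)
        kinds = ["meal"] * len(minutes)
        n_snacks = rng.poisson(config.snacks_per_day_rate)
        for _ in range(n_snacks):
            minutes.append(rng.uniform(540, 1380) + shift)
            kinds.append("snack")
        kcals = np.concatenate([
            kcals, np.clip(rng.lognormal(mu_s, sd_s, n_snacks), 10, 3000)])
        for m, kcal, kind in zip(minutes, kcals, kinds):
            m = float(np.clip(m, 0, 1439))
            ts = day + pd.Timedelta(minutes=round(m))
            scale = 1.0 if kind == "meal" else 0.3
            groups = {g: rng.gamma(1.2, scale * mean / 1.2)
                      for g, mean in _GROUP_MEANS.items()}
            rows.append({
                "timestamp": ts, "kcal": float(kcal), **groups,
                "method": rng.choice(["photo", "barcode", "manual"],
                                     p=[0.761, 0.133, 0.106]),
            })
    df = pd.DataFrame(rows, columns=DISH_COLUMNS[1:])
    return df.sort_values("timestamp").reset_index(drop=True)


def excursion_kernel(dt_minutes: np.ndarray, config: SimulationConfig) -> np.ndarray:
    """Unimodal gamma-shaped pulse, peak value 1 at ``excursion_peak_delay``.

    Zero for dt <= 0 and dt > excursion_duration; by construction the pulse
    has decayed to ~1% of its peak at the default duration.
    """
    m = config.excursion_peak_delay
    k = _KERNEL_SHAPE
    dt = np.asarray(dt_minutes, dtype=float)
    out = np.zeros_like(dt)
    mask = (dt > 0) & (dt <= config.excursion_duration)
    x = dt[mask] / m
    out[mask] = x ** (k - 1) * np.exp((k - 1) * (1 - x))
    return out


def generate_glucose_trace(start: pd.Timestamp, n_days: int,
                           meals: pd.DataFrame, config: SimulationConfig,
                           rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Uncensored 15-minute glucose trace over the tracking window.

    Baseline + sinusoidal circadian term + superposed per-meal excursion
    pulses (amplitude ``excursion_gain`` x kcal/100) + AR(1) noise; values
    clipped below at 2.5 mmol/L.  With ``rng=None`` the noise term is
    omitted (useful for closed-form checks).
    """
    start = pd.Timestamp(start).normalize()
    grid = pd.date_range(start, periods=n_days * 96, freq="15min")
    t_min = (grid - start) / pd.Timedelta(minutes=1)
    t_min = np.asarray(t_min, dtype=float)

    hours = (t_min / 60.0) % 24.0
    g = config.baseline_glucose + config.circadian_amplitude * np.sin(
        2 * np.pi * (hours - 10.0) / 24.0)

    if len(meals):
        meal_min = np.asarray(
            (pd.to_datetime(meals["timestamp"]) - start) / pd.Timedelta(minutes=1),
            dtype=float)
        amps = config.excursion_gain * np.asarray(meals["kcal"], dtype=float) / 100.0
        for tm, a in zip(meal_min, amps):
            g += a * excursion_kernel(t_min - tm, config)

    if rng is not None and config.noise_sd > 0:
        from scipy.signal import lfilter
        phi = config.noise_ar1
        innov_sd = config.noise_sd * np.sqrt(1 - phi ** 2)
        e = rng.normal(0, innov_sd, len(grid))
        g += lfilter([1.0], [1.0, -phi], e)

    g = np.maximum(g, 2.5)
    return pd.DataFrame({"timestamp": grid, "glucose_mmol_l": np.round(g, 4)})


def apply_sensor_censoring(trace: pd.DataFrame, config: SimulationConfig,
                           rng: np.random.Generator | None = None,
                           scan_times: Sequence[pd.Timestamp] | None = None,
                           ) -> pd.DataFrame:
    """Delete readings the sensor memory would have lost.

    The sensor holds ``sensor_memory`` hours of data; a reading survives
    only if some scan occurs within that window after it.  Scans are
    simulated as a renewal process with exponential gaps of mean
    ``scan_interval_mean`` hours unless explicit ``scan_times`` are given.
    Retained readings are returned unchanged (a subset of the input).
    """
    if trace.empty:
        return trace.copy()
    ts = pd.to_datetime(trace["timestamp"]).to_numpy()
    if scan_times is None:
        if rng is None:
            raise ConfigurationError("either rng or scan_times is required")
        t0, t1 = ts.min(), ts.max()
        horizon_h = (t1 - t0) / np.timedelta64(3600, "s")
        gaps = []
        total = 0.0
        # draw in blocks until the renewal process passes the wear end
        while total <= horizon_h:
            block = rng.exponential(config.scan_interval_mean, size=64)
            gaps.append(block)
            total += block.sum()
        scan_h = np.cumsum(np.concatenate(gaps))
        scan_h = scan_h[scan_h <= horizon_h]
        scan_arr = t0 + (scan_h * 3.6e12).astype("timedelta64[ns]")
    else:
        scan_arr = np.array(sorted(pd.to_datetime(scan_times)), dtype="datetime64[ns]")
    if len(scan_arr) == 0:
        return trace.iloc[0:0].copy()
    idx = np.searchsorted(scan_arr, ts, side="left")
    memory = np.timedelta64(int(config.sensor_memory * 3600), "s")
    keep = idx < len(scan_arr)
    gap = np.full(len(ts), np.timedelta64(10**9, "s"))
    gap[keep] = scan_arr[idx[keep]] - ts[keep]
    keep &= gap <= memory
    return trace.loc[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# sleep & activity

def generate_sleep_records(start: pd.Timestamp, n_days: int,
                           config: SimulationConfig,
                           rng: np.random.Generator) -> pd.DataFrame:
    """Nightly bed/wake records; nights keyed by wake date.

    Weekend (Saturday/Sunday wake) wake-time means are shifted later by
    ``weekend_wake_shift`` minutes; a ``sleep_missing_rate`` fraction of
    nights is dropped at random.
    """
    start = pd.Timestamp(start).normalize()
    rows = []
    for d in range(n_days):
        if rng.random() < config.sleep_missing_rate:
            continue
        wake_day = start + pd.Timedelta(days=d)
        shift = config.weekend_wake_shift if _is_weekend(wake_day) else 0.0
        bed_min = config.bedtime_mean + rng.normal(0, config.sleep_jitter_sd)
        wake_min = config.waketime_mean + shift + rng.normal(0, config.sleep_jitter_sd)
        if config.bedtime_mean >= 720:  # evening bedtime -> previous calendar day
            bed = wake_day - pd.Timedelta(days=1) + pd.Timedelta(minutes=round(bed_min))
        else:
            bed = wake_day + pd.Timedelta(minutes=round(bed_min))
        wake = wake_day + pd.Timedelta(minutes=round(wake_min))
        if wake <= bed:
            continue
        rows.append({
            "bedtime": bed, "waketime": wake,
            "source": rng.choice(["device", "self_report"], p=[0.2, 0.8]),
        })
    return pd.DataFrame(rows, columns=SLEEP_COLUMNS[1:])


def generate_activity_records(start: pd.Timestamp, n_days: int,
                              config: SimulationConfig,
                              rng: np.random.Generator) -> pd.DataFrame:
    start = pd.Timestamp(start).normalize()
    rows = []
    for d in range(n_days):
        if rng.random() >= config.activity_daily_prob:
            continue
        day = start + pd.Timedelta(days=d)
        begin = day + pd.Timedelta(minutes=round(1020 + rng.normal(0, 60)))
        dur = rng.uniform(20, 60)
        source = rng.choice(["device", "self_report"], p=[0.2, 0.8])
        rows.append({
            "start": begin, "end": begin + pd.Timedelta(minutes=round(dur)),
            "kind": rng.choice(["walking", "running", "cycling"]),
            "source": source,
            "calories": round(dur * 6.0, 1),
            "intensity": int(rng.integers(1, 4)) if source == "self_report" else np.nan,
        })
    return pd.DataFrame(rows, columns=ACTIVITY_COLUMNS[1:])


# ---------------------------------------------------------------------------
# microbiota

def _lineages(n_taxa: int, n_genera: int, rng: np.random.Generator) -> list[str]:
    phyla = [f"Phylum{i + 1}" for i in range(4)]
    genera = [f"Genus{i + 1:02d}" for i in range(n_genera)]
    out = []
    for j in range(n_taxa):
        p = phyla[j % len(phyla)]
        fam = f"Family{j % 10 + 1}"
        genus = genera[j % n_genera]
        if rng.random() < 0.08:  # unassigned genus, pooled per family downstream
            genus = ""
        out.append(f"Bacteria;{p};Class{j % 6 + 1};Order{j % 8 + 1};{fam};{genus}")
    return out


def generate_abundance_table(n_samples: int, n_taxa: int,
                             group_labels: Sequence[str],
                             config: SimulationConfig,
                             rng: np.random.Generator | None = None,
                             sample_ids: Sequence[str] | None = None,
                             ) -> AbundanceTable:
    """Compositional count table with per-group Dirichlet base compositions.

    Each group's mean composition is a shared lognormal base tilted by
    ``microbiota_group_offset`` in log space (groups coincide at offset 0);
    an infinite offset assigns disjoint round-robin taxon supports to the
    groups.  Per-sample depths are lognormal (default around 20,000 reads)
    and counts multinomial.
    """
    if n_taxa < 2:
        raise ConfigurationError("n_taxa must be at least 2")
    if len(group_labels) != n_samples:
        raise ConfigurationError("group_labels length must equal n_samples")
    if rng is None:
        rng = _rng(config, 3)
    lineages = _lineages(n_taxa, config.n_genera, rng)
    base = rng.lognormal(0, 1, n_taxa)
    base /= base.sum()
    labels = sorted(set(group_labels))
    offset = config.microbiota_group_offset
    means = {}
    for gi, lab in enumerate(labels):
        if np.isinf(offset):
            mask = (np.arange(n_taxa) % len(labels)) == gi
            m = base * mask
        else:
            tilt = rng.choice([-1.0, 1.0], n_taxa)
            m = base * np.exp(offset * tilt / 2.0)
        means[lab] = m / m.sum()
    mu_d, sd_d = config.depth_lognormal
    taxon_ids = [f"T{j:03d}" for j in range(n_taxa)]
    if sample_ids is None:
        sample_ids = [f"S{i:04d}" for i in range(n_samples)]
    mat = np.zeros((n_samples, n_taxa), dtype=int)
    for i, lab in enumerate(group_labels):
        m = means[lab]
        support = m > 0
        alpha = config.dirichlet_concentration * m[support]
        comp = np.zeros(n_taxa)
        comp[support] = rng.dirichlet(alpha)
        depth = max(1, int(round(rng.lognormal(mu_d, sd_d))))
        mat[i] = rng.multinomial(depth, comp)
    counts = pd.DataFrame(mat, index=list(sample_ids), columns=taxon_ids)
    return AbundanceTable(
        counts=counts,
        lineages=pd.Series(lineages, index=taxon_ids),
        groups=pd.Series(list(group_labels), index=list(sample_ids)),
    )


# ---------------------------------------------------------------------------
# top level

def generate_cohort(config: SimulationConfig) -> CohortDataset:
    """Generate the full synthetic cohort dataset; deterministic given seed.

    Modalities are generated for every participant whose ledger reaches the
    tracking phase; participants who exit during tracking get a truncated
    window.  The ``truth`` block records every planted parameter plus the
    per-participant-day energy totals.
    """
    demo = generate_demographics(config)
    ledger = generate_enrollment_ledger(config, cohort=list(demo["cohort"]))

    glucose, dishes, sleep, activity = [], [], [], []
    truth_windows: dict[str, list] = {}
    truth_kcal: dict[str, dict[str, float]] = {}
    start_rng = _rng(config, 4)

    tracking = ledger[ledger["phase"].isin(["tracking", "completed"])]
    for _, row in tracking.iterrows():
        pid = row["participant_id"]
        i = int(pid[1:])
        prng = np.random.default_rng(
            np.random.SeedSequence([config.seed % (2**31), 1000 + i]))
        days_full = (config.tracking_days_c if row["cohort"] == "C"
                     else config.tracking_days_b)
        if row["phase"] == "tracking":  # exited mid-tracking
            n_days = int(start_rng.integers(1, max(2, days_full)))
        else:
            n_days = days_full
        start = (pd.Timestamp(config.study_start)
                 + pd.Timedelta(days=int(start_rng.integers(0, 365))))
        truth_windows[pid] = [start.date().isoformat(), n_days]

        meals = generate_meal_schedule(start, n_days, config, prng)
        meals.insert(0, "participant_id", pid)
        dishes.append(meals)
        per_day = meals.groupby(meals["timestamp"].dt.date)["kcal"].sum()
        truth_kcal[pid] = {d.isoformat(): float(v) for d, v in per_day.items()}

        trace = generate_glucose_trace(start, n_days, meals, config, prng)
        trace = apply_sensor_censoring(trace, config, prng)
        trace.insert(0, "participant_id", pid)
        glucose.append(trace)

        srec = generate_sleep_records(start, n_days, config, prng)
        srec.insert(0, "participant_id", pid)
        sleep.append(srec)
        arec = generate_activity_records(start, n_days, config, prng)
        arec.insert(0, "participant_id", pid)
        activity.append(arec)

    def _cat(frames, cols):
        frames = [f for f in frames if len(f)]
        if not frames:
            return pd.DataFrame(columns=cols)
        return pd.concat(frames, ignore_index=True)

    completers = ledger[ledger["phase"] == "completed"]
    stool_rng = _rng(config, 5)
    donors = completers[stool_rng.random(len(completers)) < config.stool_sample_rate]
    abundances = None
    if len(donors):
        abundances = generate_abundance_table(
            len(donors), config.n_taxa, list(donors["cohort"]), config,
            rng=_rng(config, 6), sample_ids=list(donors["participant_id"]))

    truth = {
        "weekend_meal_shift": config.weekend_meal_shift,
        "weekend_wake_shift": config.weekend_wake_shift,
        "excursion_peak_delay": config.excursion_peak_delay,
        "dropout_probs": list(config.dropout_probs),
        "expected_completion_rate": float(
            np.prod([1 - p for p in config.dropout_probs])),
        "tracking_windows": truth_windows,
        "daily_kcal": truth_kcal,
    }
    return CohortDataset(
        participants=demo,
        ledger=ledger,
        glucose=_cat(glucose, GLUCOSE_COLUMNS),
        dishes=_cat(dishes, DISH_COLUMNS),
        sleep=_cat(sleep, SLEEP_COLUMNS),
        activity=_cat(activity, ACTIVITY_COLUMNS),
        abundances=abundances,
        truth=truth,
    )


def write_dataset(dataset: CohortDataset, outdir) -> None:
    """Serialize a cohort dataset to the plain-text file contracts."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    dataset.glucose.to_csv(out / "glucose.csv", index=False)
    dataset.dishes.to_csv(out / "dishes.csv", index=False)
    dataset.sleep.to_csv(out / "sleep.csv", index=False)
    dataset.activity.to_csv(out / "activity.csv", index=False)
    dataset.ledger.to_csv(out / "ledger.csv", index=False)
    dataset.participants.to_csv(out / "demographics.csv", index=False)
    if dataset.abundances is not None:
        tab = dataset.abundances
        wide = tab.counts.T.copy()
        wide.insert(0, "lineage", tab.lineages.reindex(wide.index))
        wide.to_csv(out / "abundance.tsv", sep="\t", index_label="taxon_id")
        tab.groups.rename("study_label").to_csv(
            out / "groups.csv", index_label="sample_id")
    with open(out / "truth.json", "w") as fh:
        json.dump(dataset.truth, fh, indent=1)
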