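"""Dietary-intake processing.

Dish-log aggregation to participant-days, the 1000-kcal low-intake day
filter, inverse-frequency (weekday x meteorological season) weighted
individual means, mealtime pattern statistics with a 04:00 day boundary,
logging-method breakdown, and stratified intake summaries in the style of
national nutrition surveys.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (FormatError, InsufficientDataError, UndefinedResultError,
                     ValidationError)

__all__ = [
    "DISH_METHODS", "FOOD_GROUPS", "read_dishes_csv", "season_of",
    "daily_intake", "filter_low_intake_days", "inverse_frequency_weighted_mean",
    "WeightedIntakeSummary", "mealtime_histogram", "mealtime_shift_test",
    "strata_summary", "logging_method_breakdown",
]

DISH_METHODS = frozenset({"photo", "barcode", "manual"})
FOOD_GROUPS = ["meat_g", "dairy_g", "water_ml", "fruitveg_g"]
INTAKE_COLUMNS = ["kcal"] + FOOD_GROUPS

#: clock boundary (minutes) separating "days" for mealtime statistics,
#: keeping post-midnight dinners with their calendar evening
MEALTIME_DAY_BOUNDARY_MIN = 240


@dataclass
class WeightedIntakeSummary:
    participant_id: str
    weighted_means: dict[str, float]  # kcal and each food group
    n_days_used: int
    n_days_removed_lowkcal: int


def read_dishes_csv(path) -> pd.DataFrame:
    """Read and validate dishes.csv into a dish table."""
    df = pd.read_csv(path, dtype={"participant_id": str})
    expected = set(["participant_id", "timestamp", "method"] + INTAKE_COLUMNS)
    if not expected.issubset(df.columns):
        raise FormatError(f"missing columns {expected - set(df.columns)}")
    ts = pd.to_datetime(df["timestamp"], format="ISO8601", errors="coerce")
    bad = ts.isna() & df["timestamp"].notna()
    if bad.any():
        raise FormatError("unparsable timestamp", line=int(bad.idxmax()) + 2)
    df = df.assign(timestamp=ts)
    if (pd.to_numeric(df["kcal"]) < 0).any():
        raise FormatError("negative kcal",
                          line=int((pd.to_numeric(df["kcal"]) < 0).idxmax()) + 2)
    unknown = set(df["method"].dropna()) - DISH_METHODS
    if unknown:
        raise ValidationError(f"unknown logging method(s): {sorted(unknown)}")
    return df


_SEASONS = {12: "DJF", 1: "DJF", 2: "DJF", 3: "MAM", 4: "MAM", 5: "MAM",
            6: "JJA", 7: "JJA", 8: "JJA", 9: "SON", 10: "SON", 11: "SON"}


def season_of(date) -> str:
    """Meteorological season: DJF, MAM, JJA, or SON."""
    month = pd.Timestamp(date).month if not isinstance(date, datetime.date) \
        else date.month
    return _SEASONS[month]


def daily_intake(dishes: pd.DataFrame) -> pd.DataFrame:
    """Aggregate dishes to one row per (participant, calendar date).

    Totals are plain sums of the participant-day's dishes; weekday is ISO
    (Monday=1) and season is the meteorological season of the date.
    """
    if dishes.empty:
        return pd.DataFrame(columns=["participant_id", "date", "weekday",
                                     "season"] + INTAKE_COLUMNS)
    d = dishes.copy()
    d["date"] = pd.to_datetime(d["timestamp"]).dt.date
    out = (d.groupby(["participant_id", "date"], as_index=False)[INTAKE_COLUMNS]
           .sum())
    dates = pd.to_datetime(out["date"])
    out.insert(2, "weekday", dates.dt.weekday + 1)
    out.insert(3, "season", dates.dt.month.map(_SEASONS))
    return out


def filter_low_intake_days(daily: pd.DataFrame, min_kcal: float = 1000.0,
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split participant-days into (kept, removed) at the energy floor.

    Removal is strict "below": a day at exactly ``min_kcal`` is kept.
    """
    mask = daily["kcal"] >= min_kcal
    return (daily[mask].reset_index(drop=True),
            daily[~mask].reset_index(drop=True))


def inverse_frequency_weighted_mean(daily_kept: pd.DataFrame,
                                    n_removed: int = 0,
                                    ) -> WeightedIntakeSummary:
    """Weighted mean intake for one participant's kept days.

    Each day in (weekday, season) cell c gets weight 1/n_c where n_c is the
    participant's count of kept days in that cell; the weighted mean is
    algebraically the unweighted mean of per-cell means, so rarer
    combinations carry more influence.
    """
    if daily_kept.empty:
        raise UndefinedResultError("no kept days for weighted mean")
    pids = daily_kept["participant_id"].unique()
    if len(pids) != 1:
        raise ValidationError("inverse_frequency_weighted_mean is per participant")
    cell = list(zip(daily_kept["weekday"], daily_kept["season"]))
    counts = pd.Series(cell).value_counts()
    w = np.array([1.0 / counts[c] for c in cell])
    means = {col: float(np.sum(w * daily_kept[col].to_numpy()) / w.sum())
             for col in INTAKE_COLUMNS}
    return WeightedIntakeSummary(
        participant_id=str(pids[0]),
        weighted_means=means,
        n_days_used=len(daily_kept),
        n_days_removed_lowkcal=int(n_removed),
    )


# ---------------------------------------------------------------------------
# mealtime patterns

def mealtime_histogram(dishes: pd.DataFrame) -> pd.DataFrame:
    """Dish counts by (ISO weekday 1-7, hour 0-23) across all participants."""
    out = pd.DataFrame(0, index=pd.RangeIndex(1, 8, name="weekday"),
                       columns=pd.RangeIndex(0, 24, name="hour"))
    if dishes.empty:
        return out
    ts = pd.to_datetime(dishes["timestamp"])
    counts = (pd.DataFrame({"weekday": ts.dt.weekday + 1, "hour": ts.dt.hour})
              .value_counts())
    for (wd, h), c in counts.items():
        out.loc[wd, h] = c
    return out


def _mealtime_minutes_and_daytype(ts: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    """Minutes since the 04:00 day boundary, and weekend flag of the shifted day."""
    ts = pd.to_datetime(ts)
    shifted = ts - pd.Timedelta(minutes=MEALTIME_DAY_BOUNDARY_MIN)
    minutes = (shifted.dt.hour * 60 + shifted.dt.minute
               + shifted.dt.second / 60.0).to_numpy()
    weekend = (shifted.dt.weekday >= 5).to_numpy()
    return minutes, weekend


def mealtime_shift_test(dishes: pd.DataFrame,
                        alternative: str = "greater") -> tuple[float, float]:
    """Weekend-vs-weekday mealtime shift across participants.

    For each participant the mean dish clock time (minutes past the 04:00
    boundary) is computed separately for weekdays and weekends; the
    returned difference is the across-participant mean of (weekend -
    weekday), and the p-value is the rank-sum test between the two sets of
    per-participant means (one-sided "weekend later" by default).
    Participants lacking either day type are excluded.
    """
    if dishes.empty:
        raise InsufficientDataError("no dishes")
    minutes, weekend = _mealtime_minutes_and_daytype(dishes["timestamp"])
    df = pd.DataFrame({"participant_id": dishes["participant_id"].to_numpy(),
                       "minutes": minutes, "weekend": weekend})
    means = (df.groupby(["participant_id", "weekend"])["minutes"].mean()
             .unstack("weekend"))
    if means.shape[1] < 2:
        raise InsufficientDataError("need both weekday and weekend dishes")
    means = means.dropna()
    if len(means) < 2:
        raise InsufficientDataError("fewer than 2 participants with both day types")
    diff = float((means[True] - means[False]).mean())
    p = float(stats.mannwhitneyu(means[True], means[False],
                                 alternative=alternative).pvalue)
    return diff, p


# ---------------------------------------------------------------------------
# strata summaries

def participant_weighted_means(daily: pd.DataFrame, min_kcal: float = 1000.0,
                               ) -> pd.DataFrame:
    """Per-participant inverse-frequency weighted means after the kcal filter."""
    kept, removed = filter_low_intake_days(daily, min_kcal)
    removed_counts = removed.groupby("participant_id").size()
    rows = []
    for pid, g in kept.groupby("participant_id"):
        s = inverse_frequency_weighted_mean(g, int(removed_counts.get(pid, 0)))
        rows.append({"participant_id": pid, **s.weighted_means,
                     "n_days_used": s.n_days_used,
                     "n_days_removed_lowkcal": s.n_days_removed_lowkcal})
    return pd.DataFrame(rows, columns=["participant_id"] + INTAKE_COLUMNS
                        + ["n_days_used", "n_days_removed_lowkcal"])


def strata_summary(daily_kept: pd.DataFrame, demographics: pd.DataFrame,
                   strata: Sequence[str] = ("gender",),
                   portion_g: float = 120.0,
                   min_kcal: float = 1000.0) -> pd.DataFrame:
    """Stratified intake summary in the nutrition-survey style.

    Per-participant weighted means are computed first, then averaged
    (unweighted) across the participants of each stratum level.  The
    fruit+vegetable column reports the proportion of participants whose
    weighted daily mean exceeds 5 portions of ``portion_g`` grams.
    """
    per = participant_weighted_means(daily_kept, min_kcal=min_kcal)
    merged = per.merge(demographics, on="participant_id", how="left")
    rows = []
    for stratum in strata:
        if stratum not in merged.columns:
            raise ValidationError(f"unknown stratum {stratum!r}")
        for level, g in merged.groupby(stratum, dropna=False):
            portions = g["fruitveg_g"] / portion_g
            rows.append({
                "stratum": stratum, "level": level, "n_participants": len(g),
                **{col: float(g[col].mean()) for col in INTAKE_COLUMNS},
                "prop_over_5_portions_fruitveg": float((portions > 5).mean()),
            })
    return pd.DataFrame(rows)


def logging_method_breakdown(dishes: pd.DataFrame) -> dict[str, float]:
    """Proportion of dishes logged by photo, barcode, and manual entry."""
    if dishes.empty:
        raise InsufficientDataError("no dishes to break down")
    counts = dishes["method"].value_counts()
    n = counts.sum()
    return {m: float(counts.get(m, 0)) / n for m in sorted(DISH_METHODS)}
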