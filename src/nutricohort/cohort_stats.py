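"""Demographic recoding, completion-rate tables, and adherence accounting.

Recoding follows survey conventions: monthly household income in four CHF
brackets, age classes 18-34/35-49/50-64/65+, education low/intermediate/
high, smoking nonsmoker/former/current (occasional smokers count as
current), binary self-rated health, WHO BMI classes with lower-bound-
inclusive cutoffs 18.5/25/30, and the WHO 75 min/week activity cutoff.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, ValidationError
from .sleep_activity import classify_activity_level

__all__ = [
    "recode_demographics", "bmi_classify", "completion_rates",
    "adherence_summary", "exit_reason_breakdown", "income_class", "age_class",
]

PHASE_ORDER = {"enrolled": 0, "preparatory": 1, "tracking": 2, "completed": 3}

_EDUCATION = {"mandatory": "low", "primary school": "low",
              "high school": "intermediate", "professional diploma": "intermediate",
              "university": "high"}
_SMOKING = {"never": "nonsmoker", "former": "former smoker",
            "occasionally": "current smoker", "daily": "current smoker"}
_HEALTH = {"not good": "Not good to average", "average": "Not good to average",
           "somewhat good": "Not good to average", "good": "Good to very good",
           "very good": "Good to very good"}
_HOUSEHOLD = {"alone": "Alone", "couple w. children": "Couple w. Children",
              "couple w.out children": "Couple w.out Children", "other": "Other"}
_CITIZENSHIP = {"Swiss": "Swiss", "Binational": "Binational",
                "Foreigner": "Foreigner"}


def income_class(chf_per_month: float) -> str:
    """Four brackets: <6000, 6000-8999, 9000-12999, >=13000 CHF/month."""
    if pd.isna(chf_per_month):
        return "missing"
    v = float(chf_per_month)
    if v < 6000:
        return "<6000"
    if v < 9000:
        return "6000-8999"
    if v < 13000:
        return "9000-12999"
    return ">=13000"


def age_class(age_years: float) -> str:
    """Lower-bound-inclusive classes 18-34, 35-49, 50-64, 65+."""
    a = float(age_years)
    if a < 18:
        raise ValidationError(f"age {a} below the inclusion minimum of 18")
    if a < 35:
        return "18-34"
    if a < 50:
        return "35-49"
    if a < 65:
        return "50-64"
    return "65+"


def bmi_classify(height_cm: float, weight_kg: float) -> tuple[float, str]:
    """BMI (kg/m^2) and WHO class with cutoffs 18.5/25/30, lower bound inclusive."""
    if height_cm <= 0 or weight_kg <= 0:
        raise ValidationError("height and weight must be positive")
    bmi = weight_kg / (height_cm / 100.0) ** 2
    if bmi < 18.5:
        cls = "Underweight"
    elif bmi < 25:
        cls = "Normal"
    elif bmi < 30:
        cls = "Overweight"
    else:
        cls = "Obese"
    return bmi, cls


def _map_or_raise(series: pd.Series, mapping: Mapping[str, str],
                  name: str) -> pd.Series:
    missing = series.isna()
    unknown = set(series.dropna()) - set(mapping)
    if unknown:
        raise ValidationError(f"unmappable {name} value(s): {sorted(unknown)}")
    out = series.map(mapping)
    if missing.any():
        warnings.warn(f"{int(missing.sum())} missing {name} value(s) kept as "
                      "'missing' (no imputation performed)")
        out = out.fillna("missing")
    return out


def recode_demographics(raw: pd.DataFrame) -> pd.DataFrame:
    """Recode a raw demographics table into analysis categories.

    Urbanity and linguistic region are accepted as precomputed columns and
    passed through.  Missing income/education become an explicit "missing"
    level with a warning.
    """
    out = raw.copy()
    out["income_class"] = raw["income_chf_month"].map(income_class)
    out["age_group"] = raw["age"].map(age_class)
    out["education_level"] = _map_or_raise(raw["education"], _EDUCATION, "education")
    out["smoking_status"] = _map_or_raise(raw["smoking"], _SMOKING, "smoking")
    out["health_status"] = _map_or_raise(raw["health"], _HEALTH, "health")
    out["household_type"] = _map_or_raise(raw["household"], _HOUSEHOLD, "household")
    out["citizenship_class"] = _map_or_raise(raw["citizenship"], _CITIZENSHIP,
                                             "citizenship")
    bmi_cls = [bmi_classify(h, w) for h, w in zip(raw["height_cm"],
                                                  raw["weight_kg"])]
    out["bmi"] = [round(b, 2) for b, _ in bmi_cls]
    out["bmi_class"] = [c for _, c in bmi_cls]
    weekly = raw["exercise_freq_per_week"] * raw["exercise_duration_min"]
    out["activity_level"] = weekly.map(classify_activity_level)
    return out


def completion_rates(ledger: pd.DataFrame, demographics: pd.DataFrame,
                     strata: Sequence[str]) -> pd.DataFrame:
    """Completion percentage and completer count per cohort x stratum level.

    Denominator is every ledger row (all enrolled); an empty cell yields a
    missing (NaN) rate, never 0.
    """
    missing = set(ledger["participant_id"]) - set(demographics["participant_id"])
    if missing:
        raise ValidationError(f"ledger ids missing demographics: {sorted(missing)[:5]}")
    merged = ledger.merge(demographics, on="participant_id",
                          suffixes=("", "_demo"))
    rows = []
    for stratum in strata:
        if stratum not in merged.columns:
            raise ValidationError(f"unknown stratum {stratum!r}")
        for (cohort, level), g in merged.groupby(["cohort", stratum],
                                                 dropna=False):
            n_enr = len(g)
            n_comp = int((g["phase"] == "completed").sum())
            rows.append({
                "stratum": stratum, "level": level, "cohort": cohort,
                "n_enrolled": n_enr, "n_completed": n_comp,
                "completion_pct": (100.0 * n_comp / n_enr if n_enr else np.nan),
            })
    return pd.DataFrame(rows)


def overall_completion_rate(ledger: pd.DataFrame) -> float:
    """Completers over all enrolled, in percent."""
    if ledger.empty:
        raise InsufficientDataError("empty ledger")
    return float(100.0 * (ledger["phase"] == "completed").mean())


def exit_reason_breakdown(ledger: pd.DataFrame) -> dict[str, float]:
    """Proportion of withdrawal reasons among non-completers."""
    withdrew = ledger[ledger["phase"] != "completed"]
    if withdrew.empty:
        raise InsufficientDataError("no withdrawers in ledger")
    counts = withdrew["exit_reason"].value_counts()
    n = counts.sum()
    return {r: float(counts.get(r, 0)) / n
            for r in ["time", "interest", "none", "other"]}


def adherence_summary(dataset, coverage_threshold: float = 0.9,
                      min_kcal: float = 1000.0) -> pd.DataFrame:
    """Per-participant tracking-day counts for each modality.

    CGM days are counted both as any-reading days and >=90%-covered days;
    food days as any-intake days and days above the kcal floor.  The
    ``qualifies_food`` flag marks participants with at least
    (tracking_days - 1) qualifying food days, the near-complete adherence
    target (13 of 14 for cohort B, 27 of 28 for cohort C).
    """
    from . import cgm as cgm_mod
    from . import food as food_mod

    truth_windows = dataset.truth.get("tracking_windows", {})
    traces = cgm_mod.traces_from_frame(dataset.glucose)
    daily = food_mod.daily_intake(dataset.dishes)

    rows = []
    tracked = dataset.ledger[
        dataset.ledger["phase"].isin(["tracking", "completed"])]
    for _, row in tracked.iterrows():
        pid = row["participant_id"]
        window = truth_windows.get(pid)
        if window is None:
            continue
        start = pd.Timestamp(window[0])
        n_days = int(window[1])
        end = start + pd.Timedelta(days=n_days) - pd.Timedelta(seconds=1)
        days_any = days_cov = 0
        if pid in traces:
            days_any, days_cov = cgm_mod.cgm_day_coverage(
                traces[pid], coverage_threshold)
        pdaily = daily[daily["participant_id"] == pid]
        food_any = int(len(pdaily))
        food_above = int((pdaily["kcal"] >= min_kcal).sum())
        sleep_days = 0
        if len(dataset.sleep):
            sleep_days = int(
                pd.to_datetime(dataset.sleep.loc[
                    dataset.sleep["participant_id"] == pid, "waketime"])
                .dt.date.nunique())
        act_days = 0
        if len(dataset.activity):
            act_days = int(
                pd.to_datetime(dataset.activity.loc[
                    dataset.activity["participant_id"] == pid, "start"])
                .dt.date.nunique())
        rows.append({
            "participant_id": pid, "cohort": row["cohort"],
            "tracking_days": n_days,
            "cgm_days_any": days_any, "cgm_days_covered": days_cov,
            "food_days_any": food_any, "food_days_above_kcal": food_above,
            "sleep_days": sleep_days, "activity_days": act_days,
            "qualifies_food": food_above >= n_days - 1,
        })
    return pd.DataFrame(rows)
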