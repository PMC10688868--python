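"""Sleep and physical-activity aggregation.

Implausible sleep durations (<4 h or >12 h) are excluded; nights are keyed
by the calendar day of the wake time, with Saturday/Sunday wakes counting
as weekend.  Clock-time means are computed on the circle to avoid the
midnight discontinuity.  The WHO 75 min/week cutoff classifies self-
reported activity into active/inactive.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, ValidationError

__all__ = [
    "filter_sleep_durations", "sleep_summary", "classify_activity_level",
    "modality_day_counts", "circular_mean_minutes",
]

WHO_ACTIVE_MINUTES_PER_WEEK = 75.0


def circular_mean_minutes(minutes: np.ndarray) -> float:
    """Mean clock time (minutes in [0, 1440)) computed on the circle."""
    minutes = np.asarray(minutes, dtype=float)
    ang = 2 * np.pi * minutes / 1440.0
    mean_ang = np.arctan2(np.sin(ang).mean(), np.cos(ang).mean())
    return float((mean_ang * 1440.0 / (2 * np.pi)) % 1440.0)


def _durations_h(records: pd.DataFrame) -> pd.Series:
    bed = pd.to_datetime(records["bedtime"])
    wake = pd.to_datetime(records["waketime"])
    if (wake <= bed).any():
        raise ValidationError("waketime must be after bedtime")
    return (wake - bed) / pd.Timedelta(hours=1)


def filter_sleep_durations(records: pd.DataFrame, min_h: float = 4.0,
                           max_h: float = 12.0,
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split records into (kept, removed); kept iff min_h <= duration <= max_h.

    Exclusion is strict "less than"/"more than", so the 4 h and 12 h
    boundaries themselves are kept.
    """
    if records.empty:
        return records.copy(), records.copy()
    dur = _durations_h(records)
    mask = (dur >= min_h) & (dur <= max_h)
    return (records[mask].reset_index(drop=True),
            records[~mask].reset_index(drop=True))


def sleep_summary(records: pd.DataFrame) -> dict:
    """Weekday/weekend sleep contrast across participants.

    Returns per-participant circular-mean bed/wake clock times and mean
    durations by day type, plus cohort paired t-tests on durations and wake
    times (weekend minus weekday) over participants having both day types.
    """
    if records.empty:
        raise InsufficientDataError("no sleep records")
    rec = records.copy()
    rec["bedtime"] = pd.to_datetime(rec["bedtime"])
    rec["waketime"] = pd.to_datetime(rec["waketime"])
    rec["duration_h"] = _durations_h(rec)
    rec["weekend"] = rec["waketime"].dt.weekday >= 5
    rec["bed_min"] = rec["bedtime"].dt.hour * 60 + rec["bedtime"].dt.minute
    rec["wake_min"] = rec["waketime"].dt.hour * 60 + rec["waketime"].dt.minute

    rows = []
    for (pid, wk), g in rec.groupby(["participant_id", "weekend"]):
        rows.append({
            "participant_id": pid, "weekend": wk, "n_nights": len(g),
            "mean_bedtime_min": circular_mean_minutes(g["bed_min"].to_numpy()),
            "mean_waketime_min": circular_mean_minutes(g["wake_min"].to_numpy()),
            "mean_duration_h": float(g["duration_h"].mean()),
        })
    per = pd.DataFrame(rows)
    wide_dur = per.pivot(index="participant_id", columns="weekend",
                         values="mean_duration_h").dropna()
    wide_wake = per.pivot(index="participant_id", columns="weekend",
                          values="mean_waketime_min").dropna()
    if len(wide_dur) < 2:
        raise InsufficientDataError(
            "fewer than 2 participants with both day types")
    # unwrap wake times onto a common branch before differencing
    wake_diff = (wide_wake[True] - wide_wake[False] + 720) % 1440 - 720
    dur_diff = wide_dur[True] - wide_dur[False]
    t_dur = stats.ttest_rel(wide_dur[True], wide_dur[False])
    t_wake = stats.ttest_1samp(wake_diff, 0.0)
    return {
        "per_participant": per,
        "mean_duration_h": float(rec["duration_h"].mean()),
        "duration_weekend_minus_weekday_h": float(dur_diff.mean()),
        "duration_p_value": float(t_dur.pvalue),
        "wake_shift_weekend_minus_weekday_min": float(wake_diff.mean()),
        "wake_shift_p_value": float(t_wake.pvalue),
        "n_participants": int(len(wide_dur)),
    }


def classify_activity_level(weekly_active_minutes: float) -> str:
    """WHO cutoff: >= 75 active minutes per week is "active"."""
    return ("active" if weekly_active_minutes >= WHO_ACTIVE_MINUTES_PER_WEEK
            else "inactive")


def modality_day_counts(records: pd.DataFrame, window_start, window_end,
                        timestamp_col: str = "waketime") -> int:
    """Distinct calendar days with any record inside [window_start, window_end]."""
    if records.empty:
        return 0
    ts = pd.to_datetime(records[timestamp_col])
    lo, hi = pd.Timestamp(window_start), pd.Timestamp(window_end)
    sel = ts[(ts >= lo) & (ts <= hi)]
    return int(sel.dt.date.nunique())
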