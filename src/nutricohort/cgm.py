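"""Glycemic analytics for 15-minute CGM traces.

Covers parsing/validation, day-coverage accounting, time-in-range at the
3.9/10 mmol/L consensus cutoffs, MAGE (mean amplitude of glycemic
excursions), local-maximum peak detection above a per-participant
percentile, the peak-to-meal matching experiment with its translated
control window, pooled diurnal mean curves, and the weekday/weekend
cross-correlation lag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (FormatError, InsufficientDataError, UndefinedResultError,
                     ValidationError)

__all__ = [
    "GlucoseTrace", "RangeThresholds", "GlycemicSummary", "PeakMatchParams",
    "MatchResult", "read_glucose_csv", "write_glucose_csv", "time_in_range",
    "mage", "detect_peaks", "match_peaks_to_meals", "peak_match_experiment",
    "diurnal_mean_curve", "weekday_weekend_lag", "cgm_day_coverage",
]

#: maximum neighbor gap for a reading to count as an interior grid point
MAX_NEIGHBOR_GAP_MIN = 30.0


@dataclass
class GlucoseTrace:
    """One participant's ordered CGM readings (mmol/L)."""

    participant_id: str
    readings: pd.Series  # values mmol/L, DatetimeIndex

    def __post_init__(self):
        idx = self.readings.index
        if len(idx) and not idx.is_monotonic_increasing:
            raise ValidationError(f"{self.participant_id}: timestamps not sorted")
        if len(idx) != len(idx.unique()):
            raise ValidationError(f"{self.participant_id}: duplicate timestamps")
        vals = self.readings.to_numpy(dtype=float)
        if len(vals) and ((vals <= 1.0) | (vals >= 30.0)).any():
            raise ValidationError(
                f"{self.participant_id}: glucose outside (1, 30) mmol/L")

    def __len__(self):
        return len(self.readings)


@dataclass(frozen=True)
class RangeThresholds:
    low: float = 3.9
    high: float = 10.0

    def __post_init__(self):
        if not self.low < self.high:
            raise ValidationError("RangeThresholds requires low < high")


@dataclass
class GlycemicSummary:
    participant_id: str
    pct_below: float
    pct_in: float
    pct_above: float
    mage: float
    n_readings: int


@dataclass(frozen=True)
class PeakMatchParams:
    """Parameters of the peak-meal matching experiment.

    The experimental window preceding a peak at t is (t-window, t]; the
    control window is the same window translated ``control_offset`` minutes
    earlier: (t-window-control_offset, t-control_offset].
    """

    peak_percentile: float = 90.0
    min_kcal: float = 50.0
    window: float = 90.0
    control_offset: float = 120.0

    def __post_init__(self):
        for name in ("peak_percentile", "min_kcal", "window", "control_offset"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")


@dataclass
class MatchResult:
    participant_id: str
    n_peaks: int
    prop_matched_experimental: float
    prop_matched_control: float


# ---------------------------------------------------------------------------
# i/o

def read_glucose_csv(path) -> dict[str, GlucoseTrace]:
    """Read glucose.csv (participant_id,timestamp,glucose_mmol_l) into traces."""
    df = pd.read_csv(path, dtype={"participant_id": str})
    expected = {"participant_id", "timestamp", "glucose_mmol_l"}
    if not expected.issubset(df.columns):
        raise FormatError(f"missing columns {expected - set(df.columns)}")
    ts = pd.to_datetime(df["timestamp"], format="ISO8601", errors="coerce")
    bad = ts.isna() & df["timestamp"].notna()
    if bad.any():
        raise FormatError("unparsable timestamp", line=int(bad.idxmax()) + 2)
    glu = pd.to_numeric(df["glucose_mmol_l"], errors="coerce")
    bad = glu.isna() & df["glucose_mmol_l"].notna()
    if bad.any():
        raise FormatError("non-numeric glucose", line=int(bad.idxmax()) + 2)
    if df.duplicated(["participant_id", "timestamp"]).any():
        raise ValidationError("duplicate (participant, timestamp) rows")
    df = df.assign(timestamp=ts, glucose_mmol_l=glu)
    out = {}
    for pid, g in df.groupby("participant_id", sort=True):
        g = g.sort_values("timestamp")
        out[pid] = GlucoseTrace(
            pid, pd.Series(g["glucose_mmol_l"].to_numpy(),
                           index=pd.DatetimeIndex(g["timestamp"])))
    return out


def write_glucose_csv(traces: Mapping[str, GlucoseTrace], path) -> None:
    frames = []
    for pid in sorted(traces):
        t = traces[pid]
        frames.append(pd.DataFrame({
            "participant_id": pid,
            "timestamp": t.readings.index,
            "glucose_mmol_l": t.readings.to_numpy(),
        }))
    df = (pd.concat(frames, ignore_index=True) if frames
          else pd.DataFrame(columns=["participant_id", "timestamp", "glucose_mmol_l"]))
    df.to_csv(path, index=False)


def traces_from_frame(df: pd.DataFrame) -> dict[str, GlucoseTrace]:
    """Group a long-format glucose frame into per-participant traces."""
    out = {}
    for pid, g in df.groupby("participant_id", sort=True):
        g = g.sort_values("timestamp")
        out[str(pid)] = GlucoseTrace(
            str(pid), pd.Series(g["glucose_mmol_l"].to_numpy(),
                                index=pd.DatetimeIndex(pd.to_datetime(g["timestamp"]))))
    return out


# ---------------------------------------------------------------------------
# summaries

def time_in_range(trace: GlucoseTrace,
                  thresholds: RangeThresholds = RangeThresholds(),
                  ) -> tuple[float, float, float]:
    """Percent of readings below, in, and above [low, high] (closed interval).

    Readings exactly at the cutoffs count as in-range ("below"/"above" are
    strict).  Percentages sum to 100 exactly.
    """
    if len(trace) == 0:
        raise UndefinedResultError("time_in_range undefined for empty trace")
    v = trace.readings.to_numpy(dtype=float)
    n = len(v)
    below = float((v < thresholds.low).sum()) / n * 100.0
    above = float((v > thresholds.high).sum()) / n * 100.0
    return below, 100.0 - below - above, above


def _smooth3(v: np.ndarray) -> np.ndarray:
    """Centered 3-point moving average with endpoint passthrough."""
    s = v.astype(float).copy()
    if len(v) >= 3:
        s[1:-1] = (v[:-2] + v[1:-1] + v[2:]) / 3.0
    return s


def _turning_points(s: np.ndarray) -> list[int]:
    """Indices of alternating local extrema of a series.

    Consecutive equal values are compressed to the midpoint of the run;
    a turning point is a sign change of the successive differences.
    """
    # compress runs of equal values, remembering run midpoints
    idx = [0]
    vals = [s[0]]
    run_start = 0
    for i in range(1, len(s)):
        if s[i] == vals[-1]:
            continue
        # close previous run: its representative index is the run midpoint
        idx[-1] = (run_start + i - 1) // 2
        idx.append(i)
        vals.append(s[i])
        run_start = i
    idx[-1] = (run_start + len(s) - 1) // 2
    turns = []
    for j in range(1, len(vals) - 1):
        d1 = vals[j] - vals[j - 1]
        d2 = vals[j + 1] - vals[j]
        if d1 * d2 < 0:
            turns.append(idx[j])
    return turns


def mage(trace: GlucoseTrace) -> float:
    """Mean amplitude of glycemic excursions (Service-style).

    Turning points are located on the 3-point moving average; amplitudes
    are taken between raw readings at successive turning points and
    qualify when exceeding one sample standard deviation of the whole raw
    trace.  Ascending and descending excursions are both averaged.
    Returns 0 (with a warning) when no excursion qualifies.
    """
    v = trace.readings.to_numpy(dtype=float)
    if len(v) < 3:
        warnings.warn(f"{trace.participant_id}: trace too short for MAGE")
        return 0.0
    sd = float(np.std(v, ddof=1))
    turns = _turning_points(_smooth3(v))
    amps = np.abs(np.diff(v[turns])) if len(turns) >= 2 else np.array([])
    amps = amps[amps > sd]
    if len(amps) == 0:
        warnings.warn(f"{trace.participant_id}: no qualifying glycemic excursion")
        return 0.0
    return float(amps.mean())


def mage_excursions(trace: GlucoseTrace) -> list[tuple[int, int, float]]:
    """Qualifying excursions as (from_index, to_index, amplitude) triples."""
    v = trace.readings.to_numpy(dtype=float)
    if len(v) < 3:
        return []
    sd = float(np.std(v, ddof=1))
    turns = _turning_points(_smooth3(v))
    out = []
    for a, b in zip(turns[:-1], turns[1:]):
        amp = abs(v[b] - v[a])
        if amp > sd:
            out.append((a, b, float(amp)))
    return out


# ---------------------------------------------------------------------------
# peaks & matching

def detect_peaks(trace: GlucoseTrace,
                 params: PeakMatchParams = PeakMatchParams(),
                 ) -> list[tuple[pd.Timestamp, float]]:
    """Local maxima strictly above the participant's empirical percentile.

    A reading is a local maximum if it is >= both temporal neighbors and >
    at least one of them; plateau runs collapse to their midpoint.  A
    reading whose neighbor gap exceeds 30 minutes on either side is
    ineligible (it sits at the edge of a sensor gap).
    """
    if len(trace) == 0:
        return []
    v = trace.readings.to_numpy(dtype=float)
    ts = trace.readings.index
    if len(v) < 3:
        return []
    thresh = float(np.percentile(v, params.peak_percentile))
    gaps = np.diff(ts.view("int64")) / 60e9  # minutes
    peaks = []
    i = 1
    n = len(v)
    while i < n - 1:
        # plateau run [i, j]
        j = i
        while j + 1 < n - 1 and v[j + 1] == v[i]:
            j += 1
        left, right = v[i - 1], v[j + 1]
        if (v[i] >= left and v[i] >= right and (v[i] > left or v[i] > right)
                and v[i] > thresh):
            mid = (i + j) // 2
            if gaps[mid - 1] <= MAX_NEIGHBOR_GAP_MIN and gaps[mid] <= MAX_NEIGHBOR_GAP_MIN:
                peaks.append((ts[mid], float(v[mid])))
        i = j + 1
    return peaks


def match_peaks_to_meals(peaks: Sequence[tuple[pd.Timestamp, float]],
                         dishes: pd.DataFrame,
                         params: PeakMatchParams = PeakMatchParams(),
                         participant_id: str = "",
                         ) -> MatchResult:
    """Proportion of peaks preceded by a qualifying dish, and control.

    A window matches when some dish with kcal >= min_kcal falls in it;
    windows are half-open (t-w, t] and (t-w-c, t-c].
    """
    qual = dishes.loc[pd.to_numeric(dishes["kcal"]) >= params.min_kcal]
    times = np.sort(pd.to_datetime(qual["timestamp"]).to_numpy())
    w = np.timedelta64(int(params.window * 60), "s")
    c = np.timedelta64(int(params.control_offset * 60), "s")

    def _any_in(lo, hi):  # (lo, hi]
        i = np.searchsorted(times, lo, side="right")
        j = np.searchsorted(times, hi, side="right")
        return j > i

    n_exp = n_ctl = 0
    for t, _ in peaks:
        t = np.datetime64(pd.Timestamp(t))
        n_exp += _any_in(t - w, t)
        n_ctl += _any_in(t - w - c, t - c)
    n = len(peaks)
    return MatchResult(
        participant_id=participant_id,
        n_peaks=n,
        prop_matched_experimental=(n_exp / n if n else float("nan")),
        prop_matched_control=(n_ctl / n if n else float("nan")),
    )


def peak_match_experiment(traces: Mapping[str, GlucoseTrace],
                          dishes: pd.DataFrame,
                          params: PeakMatchParams = PeakMatchParams(),
                          paired: bool = False) -> dict:
    """Cohort-level peak-meal matching experiment.

    Computes per-participant matched proportions for the experimental and
    control windows, their cohort medians, and the one-sided rank-sum
    p-value for experimental > control.  By default the independent
    two-sample (Wilcoxon rank-sum / Mann-Whitney) form is used; ``paired``
    switches to the signed-rank test on per-participant differences.
    """
    results = []
    for pid, trace in traces.items():
        d = dishes[dishes["participant_id"] == pid]
        peaks = detect_peaks(trace, params)
        res = match_peaks_to_meals(peaks, d, params, participant_id=pid)
        if res.n_peaks > 0:
            results.append(res)
    if len(results) < 2:
        raise InsufficientDataError(
            "peak_match_experiment needs >= 2 participants with peaks")
    exp = np.array([r.prop_matched_experimental for r in results])
    ctl = np.array([r.prop_matched_control for r in results])
    if paired:
        diff = exp - ctl
        if np.allclose(diff, 0):
            p = 1.0
        else:
            p = float(stats.wilcoxon(exp, ctl, alternative="greater").pvalue)
    elif np.ptp(np.concatenate([exp, ctl])) == 0:
        p = 0.5  # every observation tied: no evidence either way
    else:
        p = float(stats.mannwhitneyu(exp, ctl, alternative="greater").pvalue)
    return {
        "per_participant": results,
        "median_experimental": float(np.median(exp)),
        "median_control": float(np.median(ctl)),
        "p_value": p,
        "n_participants": len(results),
    }


# ---------------------------------------------------------------------------
# diurnal curves

def diurnal_mean_curve(traces: Mapping[str, GlucoseTrace] | Iterable[GlucoseTrace],
                       day_type: str = "weekday") -> pd.DataFrame:
    """96-bin pooled diurnal curve (mean, q25, q75) for weekday or weekend.

    Readings from all participants and all days of the requested type are
    binned by 15-minute clock slot; empty bins are NaN (missing), never 0.
    """
    if day_type not in ("weekday", "weekend"):
        raise ValidationError("day_type must be 'weekday' or 'weekend'")
    if isinstance(traces, Mapping):
        traces = traces.values()
    slots, values = [], []
    for t in traces:
        idx = t.readings.index
        wknd = idx.weekday >= 5
        sel = wknd if day_type == "weekend" else ~wknd
        sub = t.readings[sel]
        slots.append(sub.index.hour * 4 + sub.index.minute // 15)
        values.append(sub.to_numpy(dtype=float))
    slot = np.concatenate(slots) if slots else np.array([], dtype=int)
    val = np.concatenate(values) if values else np.array([])
    out = pd.DataFrame(index=pd.RangeIndex(96, name="slot"),
                       columns=["mean", "q25", "q75", "n"], dtype=float)
    df = pd.DataFrame({"slot": slot, "v": val})
    g = df.groupby("slot")["v"]
    agg = g.agg(["mean", "count"])
    out.loc[agg.index, "mean"] = agg["mean"]
    out.loc[agg.index, "n"] = agg["count"]
    out.loc[agg.index, "q25"] = g.quantile(0.25)
    out.loc[agg.index, "q75"] = g.quantile(0.75)
    return out


def weekday_weekend_lag(curve_wd: pd.DataFrame, curve_we: pd.DataFrame,
                        max_lag: float = 120.0) -> float:
    """Circular cross-correlation lag (minutes) between diurnal curves.

    Positive lag means the weekend curve runs later.  Raises when either
    curve has more than 25% missing bins.
    """
    wd = curve_wd["mean"].to_numpy(dtype=float)
    we = curve_we["mean"].to_numpy(dtype=float)
    for name, c in (("weekday", wd), ("weekend", we)):
        if np.isnan(c).mean() > 0.25:
            raise InsufficientDataError(f"{name} curve >25% missing bins")
    # fill residual missing bins by linear interpolation on the circle
    def _fill(c):
        s = pd.Series(np.concatenate([c, c, c]))
        s = s.interpolate(limit_direction="both")
        return s.to_numpy()[96:192]
    wd, we = _fill(wd), _fill(we)
    wd = wd - wd.mean()
    we = we - we.mean()
    max_bins = int(max_lag // 15)
    best_lag, best = 0, -np.inf
    for lag in range(-max_bins, max_bins + 1):
        r = float(np.dot(np.roll(we, -lag), wd))
        if r > best:
            best, best_lag = r, lag
    return best_lag * 15.0


def cgm_day_coverage(trace: GlucoseTrace,
                     coverage_threshold: float = 0.9) -> tuple[int, int]:
    """(days with any reading, days with >= threshold x 96 readings)."""
    if len(trace) == 0:
        return 0, 0
    counts = trace.readings.groupby(trace.readings.index.date).count()
    return int(len(counts)), int((counts >= coverage_threshold * 96).sum())


def glycemic_summary(trace: GlucoseTrace,
                     thresholds: RangeThresholds = RangeThresholds(),
                     ) -> GlycemicSummary:
    below, inr, above = time_in_range(trace, thresholds)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        m = mage(trace)
    return GlycemicSummary(trace.participant_id, below, inr, above, m, len(trace))
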