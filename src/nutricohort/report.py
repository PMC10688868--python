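"""End-to-end cohort report.

``run_pipeline`` reads whatever subset of the file contracts a directory
contains (glucose.csv, dishes.csv, sleep.csv, activity.csv, ledger.csv,
demographics.csv, abundance.tsv/groups.csv, truth.json), runs every stage
whose inputs exist, and returns a JSON-serializable report mirroring the
cohort-results structure: completion, adherence, glycemic summaries with
the peak-match experiment, intake summaries, mealtime/sleep shifts, and
the microbiota ordination.  Sections whose inputs are missing are marked
skipped with a reason.  The report is a pure function of inputs and
configuration.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import cgm as cgm_mod
from . import cohort_stats, food, microbiota, sleep_activity
from .errors import InsufficientDataError, NutricohortError, ValidationError

__all__ = ["run_pipeline", "write_report", "round_floats"]

REPORT_SCHEMA_VERSION = 1

DEFAULT_STRATA = ["gender", "age_group", "bmi_class", "phone_type",
                  "dietary_restriction"]


def round_floats(obj, sig: int = 6):
    """Recursively round floats to ``sig`` significant digits for stable diffs."""
    if isinstance(obj, float):
        if np.isnan(obj):
            return None
        return float(f"{obj:.{sig}g}")
    if isinstance(obj, (np.floating,)):
        return round_floats(float(obj), sig)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, dict):
        return {str(k): round_floats(v, sig) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [round_floats(v, sig) for v in obj]
    if isinstance(obj, np.ndarray):
        return round_floats(obj.tolist(), sig)
    return obj


def _skip(reason: str) -> dict:
    return {"skipped": True, "reason": reason}


def run_pipeline(data_dir, peak_params: cgm_mod.PeakMatchParams | None = None,
                 thresholds: cgm_mod.RangeThresholds | None = None,
                 min_kcal: float = 1000.0, portion_g: float = 120.0,
                 min_reads: float = 5000.0, axes: int = 2) -> dict:
    """Run every analysis stage whose inputs exist under ``data_dir``."""
    data_dir = Path(data_dir)
    peak_params = peak_params or cgm_mod.PeakMatchParams()
    thresholds = thresholds or cgm_mod.RangeThresholds()

    paths = {name: data_dir / name for name in [
        "glucose.csv", "dishes.csv", "sleep.csv", "activity.csv",
        "ledger.csv", "demographics.csv", "abundance.tsv", "groups.csv",
        "truth.json"]}
    present = {k: p.exists() for k, p in paths.items()}
    if not any(present[k] for k in ["glucose.csv", "dishes.csv", "sleep.csv",
                                    "ledger.csv", "abundance.tsv"]):
        raise ValidationError(f"no recognizable input file in {data_dir}")

    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "provenance": {
            "package_version": __version__,
            "data_dir": str(data_dir),
            "inputs_sha256": {
                k: hashlib.sha256(p.read_bytes()).hexdigest()[:16]
                for k, p in paths.items() if present[k]},
        },
    }

    demographics = None
    if present["demographics.csv"]:
        raw = pd.read_csv(paths["demographics.csv"],
                          dtype={"participant_id": str})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            demographics = cohort_stats.recode_demographics(raw)

    # completion & exit reasons
    if present["ledger.csv"] and demographics is not None:
        ledger = pd.read_csv(paths["ledger.csv"], dtype={"participant_id": str})
        table = cohort_stats.completion_rates(ledger, demographics,
                                              DEFAULT_STRATA)
        report["completion"] = {
            "overall_pct": cohort_stats.overall_completion_rate(ledger),
            "by_stratum": table.to_dict(orient="records"),
            "exit_reasons": cohort_stats.exit_reason_breakdown(ledger)
            if (ledger["phase"] != "completed").any() else {},
        }
    else:
        report["completion"] = _skip("ledger.csv and demographics.csv required")

    # glycemic analytics
    traces = None
    if present["glucose.csv"]:
        traces = cgm_mod.read_glucose_csv(paths["glucose.csv"])
        summaries = [asdict(cgm_mod.glycemic_summary(t, thresholds))
                     for t in traces.values()]
        glyc = {"per_participant": summaries,
                "mean_mage": float(np.mean([s["mage"] for s in summaries]))
                if summaries else None}
        try:
            wd = cgm_mod.diurnal_mean_curve(traces, "weekday")
            we = cgm_mod.diurnal_mean_curve(traces, "weekend")
            glyc["weekday_weekend_lag_min"] = cgm_mod.weekday_weekend_lag(wd, we)
        except InsufficientDataError as exc:
            glyc["weekday_weekend_lag_min"] = None
            glyc["lag_skip_reason"] = str(exc)
        report["glycemic"] = glyc
    else:
        report["glycemic"] = _skip("glucose.csv required")

    # peak-match experiment
    dishes = None
    if present["dishes.csv"]:
        dishes = food.read_dishes_csv(paths["dishes.csv"])
    if traces is not None and dishes is not None:
        try:
            exp = cgm_mod.peak_match_experiment(traces, dishes, peak_params)
            report["peak_match"] = {
                "median_experimental": exp["median_experimental"],
                "median_control": exp["median_control"],
                "p_value": exp["p_value"],
                "n_participants": exp["n_participants"],
            }
        except InsufficientDataError as exc:
            report["peak_match"] = _skip(str(exc))
    else:
        report["peak_match"] = _skip("glucose.csv and dishes.csv required")

    # dietary intake
    if dishes is not None:
        daily = food.daily_intake(dishes)
        intake: dict = {
            "logging_methods": food.logging_method_breakdown(dishes)
            if len(dishes) else {},
        }
        try:
            shift, p = food.mealtime_shift_test(dishes)
            intake["mealtime_shift_min"] = shift
            intake["mealtime_shift_p"] = p
        except InsufficientDataError as exc:
            intake["mealtime_shift_min"] = None
            intake["mealtime_shift_skip_reason"] = str(exc)
        if demographics is not None:
            strata = [s for s in ("gender", "age_group", "linguistic_region")
                      if s in demographics.columns]
            try:
                summary = food.strata_summary(daily, demographics, strata,
                                              portion_g=portion_g,
                                              min_kcal=min_kcal)
                intake["strata"] = summary.to_dict(orient="records")
            except (InsufficientDataError, ValidationError) as exc:
                intake["strata"] = _skip(str(exc))
        report["intake"] = intake
    else:
        report["intake"] = _skip("dishes.csv required")

    # sleep
    if present["sleep.csv"]:
        sleep = pd.read_csv(paths["sleep.csv"], dtype={"participant_id": str})
        kept, removed = sleep_activity.filter_sleep_durations(sleep)
        try:
            s = sleep_activity.sleep_summary(kept)
            report["sleep"] = {
                "n_records_kept": len(kept), "n_records_removed": len(removed),
                "mean_duration_h": s["mean_duration_h"],
                "duration_weekend_minus_weekday_h":
                    s["duration_weekend_minus_weekday_h"],
                "duration_p_value": s["duration_p_value"],
                "wake_shift_weekend_minus_weekday_min":
                    s["wake_shift_weekend_minus_weekday_min"],
                "wake_shift_p_value": s["wake_shift_p_value"],
            }
        except InsufficientDataError as exc:
            report["sleep"] = _skip(str(exc))
    else:
        report["sleep"] = _skip("sleep.csv required")

    # microbiota
    if present["abundance.tsv"]:
        tab = microbiota.read_abundance_tsv(
            paths["abundance.tsv"],
            paths["groups.csv"] if present["groups.csv"] else None)
        kept, removed = microbiota.filter_low_depth(tab, min_reads)
        if len(kept.counts) >= 3:
            rel = microbiota.relative_abundance(microbiota.aggregate_to_genus(kept))
            dist = microbiota.bray_curtis(rel)
            ord_ = microbiota.pcoa(dist, k=axes)
            report["microbiota"] = {
                "n_samples_kept": len(kept.counts),
                "n_samples_removed_lowdepth": len(removed.counts),
                "n_genera": rel.counts.shape[1],
                "proportion_explained": ord_.proportion_explained.tolist(),
                "coordinates": {
                    s: [float(v) for v in row]
                    for s, row in ord_.coordinates.iterrows()},
                "groups": {s: str(g) for s, g in kept.groups.items()},
            }
        else:
            report["microbiota"] = _skip("fewer than 3 samples above depth floor")
    else:
        report["microbiota"] = _skip("abundance.tsv required")

    return round_floats(report)


def write_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)


def make_plots(data_dir, out_dir) -> list:
    """Optional figures: mealtime heatmap, diurnal curves, match histogram, PCoA."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data_dir, out_dir = Path(data_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    if (data_dir / "dishes.csv").exists():
        dishes = food.read_dishes_csv(data_dir / "dishes.csv")
        hist = food.mealtime_histogram(dishes)
        fig, ax = plt.subplots(figsize=(8, 3))
        ax.imshow(hist.to_numpy(), aspect="auto", cmap="viridis")
        ax.set_xlabel("hour of day")
        ax.set_ylabel("weekday (Mon=1)")
        ax.set_yticks(range(7), labels=range(1, 8))
        fig.savefig(out_dir / "mealtime_heatmap.png", dpi=100,
                    bbox_inches="tight")
        plt.close(fig)
        written.append(out_dir / "mealtime_heatmap.png")
    if (data_dir / "glucose.csv").exists():
        traces = cgm_mod.read_glucose_csv(data_dir / "glucose.csv")
        fig, ax = plt.subplots(figsize=(8, 3))
        for day_type, color in (("weekday", "black"), ("weekend", "tab:blue")):
            c = cgm_mod.diurnal_mean_curve(traces, day_type)
            x = np.arange(96) / 4.0
            ax.plot(x, c["mean"], color=color, label=day_type)
            ax.fill_between(x, c["q25"].astype(float), c["q75"].astype(float),
                            color=color, alpha=0.2)
        ax.set_xlabel("hour of day")
        ax.set_ylabel("glucose (mmol/L)")
        ax.legend()
        fig.savefig(out_dir / "diurnal_curves.png", dpi=100,
                    bbox_inches="tight")
        plt.close(fig)
        written.append(out_dir / "diurnal_curves.png")
    if (data_dir / "abundance.tsv").exists():
        tab = microbiota.read_abundance_tsv(
            data_dir / "abundance.tsv",
            (data_dir / "groups.csv") if (data_dir / "groups.csv").exists()
            else None)
        kept, _ = microbiota.filter_low_depth(tab)
        if len(kept.counts) >= 3:
            rel = microbiota.relative_abundance(
                microbiota.aggregate_to_genus(kept))
            ord_ = microbiota.pcoa(microbiota.bray_curtis(rel), k=2)
            fig, ax = plt.subplots(figsize=(4, 4))
            for lab in sorted(set(kept.groups)):
                sel = kept.groups == lab
                pts = ord_.coordinates.loc[sel.index[sel]]
                ax.scatter(pts.iloc[:, 0], pts.iloc[:, 1], s=8, label=str(lab))
            ax.set_xlabel("PCo1")
            ax.set_ylabel("PCo2")
            ax.legend()
            fig.savefig(out_dir / "pcoa.png", dpi=100, bbox_inches="tight")
            plt.close(fig)
            written.append(out_dir / "pcoa.png")
    return written
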