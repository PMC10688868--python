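"""Simulation configuration.

All free parameters of the synthetic cohort generator live here.  The
defaults define the reference study conditions: a two-arm digital cohort
("B": 14 tracking days, anyone; "C": 28 days, women of reproductive age)
with 15-minute interstitial glucose sampling, meal-driven glucose
excursions, an 8-hour sensor memory that loses data between sparse scans,
weekday/weekend shifts in meal and wake times, phase-specific dropout, and
compositional gut-microbiota counts with a between-group offset.
"""

from __future__ import annotations

import datetime
import math
from typing import Tuple

from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from .errors import ConfigurationError

__all__ = ["SimulationConfig", "load_config_toml"]


class SimulationConfig(BaseModel):
    """Free parameters of the cohort generator.

    Durations are minutes unless the name says otherwise; clock times are
    minutes since local midnight; glucose is mmol/L.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    # cohort structure
    n_participants: int = Field(default=50, ge=0)
    cohort_fraction_c: float = Field(default=0.15, ge=0.0, le=1.0)
    tracking_days_b: int = Field(default=14, gt=0)
    tracking_days_c: int = Field(default=28, gt=0)
    study_start: datetime.date = datetime.date(2019, 1, 7)
    #: per-phase exit probabilities at enrollment, preparatory, tracking
    dropout_probs: Tuple[float, float, float] = (0.15, 0.12, 0.08)

    # glucose dynamics
    baseline_glucose: float = Field(default=5.0, gt=0)
    circadian_amplitude: float = Field(default=0.3, ge=0)
    excursion_gain: float = Field(default=0.25, ge=0)  # mmol/L per 100 kcal
    excursion_peak_delay: float = Field(default=45.0, gt=0)  # minutes
    excursion_duration: float = Field(default=150.0, gt=0)  # minutes
    noise_sd: float = Field(default=0.25, ge=0)
    noise_ar1: float = Field(default=0.6, ge=0, lt=1)

    # sensor scanning / memory censoring
    scan_interval_mean: float = Field(default=4.0, gt=0)  # hours
    sensor_memory: float = Field(default=8.0, gt=0)  # hours

    # meals
    meal_time_means: Tuple[float, float, float] = (480.0, 750.0, 1140.0)
    meal_time_sd: float = Field(default=30.0, ge=0)
    weekend_meal_shift: float = Field(default=30.0)  # minutes, later on Sat/Sun
    dish_kcal_lognormal: Tuple[float, float] = (6.2, 0.35)  # (mu, sigma), log-kcal
    snack_kcal_lognormal: Tuple[float, float] = (4.9, 0.5)
    snacks_per_day_rate: float = Field(default=1.0, ge=0)

    # sleep
    bedtime_mean: float = Field(default=1420.0, ge=0, lt=1440)  # 23:40
    waketime_mean: float = Field(default=450.0, ge=0, lt=1440)  # 07:30
    weekend_wake_shift: float = Field(default=30.0)  # minutes
    sleep_jitter_sd: float = Field(default=30.0, ge=0)
    sleep_missing_rate: float = Field(default=0.2, ge=0.0, le=1.0)

    # activity
    activity_daily_prob: float = Field(default=0.5, ge=0.0, le=1.0)

    # microbiota
    stool_sample_rate: float = Field(default=0.98, ge=0.0, le=1.0)
    n_taxa: int = Field(default=60, ge=2)
    n_genera: int = Field(default=25, ge=1)
    microbiota_group_offset: float = Field(default=0.8, ge=0)
    dirichlet_concentration: float = Field(default=50.0, gt=0)
    depth_lognormal: Tuple[float, float] = (math.log(20_000.0), 0.35)

    seed: int = 0

    @field_validator("dropout_probs")
    @classmethod
    def _probs_in_unit_interval(cls, v):
        for p in v:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"dropout probability {p} outside [0, 1]")
        return v

    @field_validator("dish_kcal_lognormal", "snack_kcal_lognormal", "depth_lognormal")
    @classmethod
    def _sigma_positive(cls, v):
        if v[1] <= 0:
            raise ValueError("lognormal sigma must be > 0")
        return v

    @model_validator(mode="after")
    def _coherent(self):
        if self.sensor_memory <= 0:
            raise ValueError("sensor_memory must be positive")
        return self


def validated_config(**kwargs) -> SimulationConfig:
    """Build a config, mapping pydantic failures to ConfigurationError naming the field."""
    try:
        return SimulationConfig(**kwargs)
    except Exception as exc:  # pydantic.ValidationError
        raise ConfigurationError(str(exc)) from exc


def load_config_toml(path) -> SimulationConfig:
    """Read a TOML file into a SimulationConfig; unknown keys are rejected."""
    import tomllib

    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    if "study_start" in raw and isinstance(raw["study_start"], str):
        raw["study_start"] = datetime.date.fromisoformat(raw["study_start"])
    return validated_config(**raw)
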