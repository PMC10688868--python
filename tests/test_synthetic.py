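"""Generator contracts: determinism, planted structure, censoring, funnel."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import nutricohort as nc
from nutricohort import synthetic
from nutricohort.errors import ConfigurationError

from oracles import censoring_retention_oracle


class TestDeterminismAndDegenerate:
    def test_fixed_seed_reproduces_dataset(self):
        cfg = nc.SimulationConfig(n_participants=10, seed=1)
        a = nc.generate_cohort(cfg)
        b = nc.generate_cohort(cfg)
        pd.testing.assert_frame_equal(a.glucose, b.glucose)
        pd.testing.assert_frame_equal(a.dishes, b.dishes)
        pd.testing.assert_frame_equal(a.sleep, b.sleep)
        pd.testing.assert_frame_equal(a.ledger, b.ledger)
        pd.testing.assert_frame_equal(a.participants, b.participants)
        assert a.truth == b.truth
        if a.abundances is not None:
            pd.testing.assert_frame_equal(a.abundances.counts,
                                          b.abundances.counts)

    def test_empty_cohort_yields_valid_empty_tables(self):
        ds = nc.generate_cohort(nc.SimulationConfig(n_participants=0, seed=0))
        assert len(ds.participants) == 0
        assert list(ds.glucose.columns) == synthetic.GLUCOSE_COLUMNS
        assert list(ds.dishes.columns) == synthetic.DISH_COLUMNS
        assert len(ds.ledger) == 0

    def test_invalid_config_names_field(self):
        with pytest.raises(Exception) as exc:
            nc.SimulationConfig(cohort_fraction_c=1.5)
        assert "cohort_fraction_c" in str(exc.value)

    def test_cohort_fraction_within_binomial_interval(self):
        cfg = nc.SimulationConfig(n_participants=200, seed=7,
                                  cohort_fraction_c=0.3)
        ds = nc.generate_cohort(cfg)
        k = int((ds.participants["cohort"] == "C").sum())
        lo, hi = stats.binom.interval(0.99, 200, 0.3)
        assert lo <= k <= hi

    def test_modalities_reference_known_participants(self, small_cohort):
        ids = set(small_cohort.participants["participant_id"])
        for df in (small_cohort.glucose, small_cohort.dishes,
                   small_cohort.sleep, small_cohort.activity):
            assert set(df["participant_id"]) <= ids


class TestMealSchedule:
    def test_zero_snack_rate_gives_three_dishes_per_day(self):
        cfg = nc.SimulationConfig(snacks_per_day_rate=0, seed=4)
        rng = np.random.default_rng(0)
        meals = synthetic.generate_meal_schedule("2021-06-07", 10, cfg, rng)
        per_day = meals.groupby(meals["timestamp"].dt.date).size()
        assert (per_day == 3).all()

    def test_kcal_truncated_to_range(self):
        cfg = nc.SimulationConfig(dish_kcal_lognormal=(9.0, 2.0), seed=4)
        rng = np.random.default_rng(1)
        meals = synthetic.generate_meal_schedule("2021-06-07", 30, cfg, rng)
        assert meals["kcal"].between(10, 3000).all()

    def test_null_weekend_shift_leaves_means_equal(self):
        cfg = nc.SimulationConfig(weekend_meal_shift=0, snacks_per_day_rate=0,
                                  meal_time_sd=0, seed=4)
        rng = np.random.default_rng(2)
        meals = synthetic.generate_meal_schedule("2021-06-07", 14, cfg, rng)
        mins = meals["timestamp"].dt.hour * 60 + meals["timestamp"].dt.minute
        weekend = meals["timestamp"].dt.weekday >= 5
        assert mins[weekend].mean() == mins[~weekend].mean()

    def test_planted_shift_recovered_over_many_days(self):
        # Monte-Carlo recovery of the planted 30-min weekend shift;
        # snacks off so the clock-mixture variance does not drown the shift
        cfg = nc.SimulationConfig(weekend_meal_shift=30, seed=4,
                                  snacks_per_day_rate=0)
        rng = np.random.default_rng(3)
        meals = synthetic.generate_meal_schedule("2021-01-04", 500, cfg, rng)
        mins = meals["timestamp"].dt.hour * 60 + meals["timestamp"].dt.minute
        weekend = meals["timestamp"].dt.weekday >= 5
        est = mins[weekend].mean() - mins[~weekend].mean()
        assert est == pytest.approx(30, abs=5)


class TestGlucoseTrace:
    def test_all_terms_off_gives_constant_baseline(self):
        cfg = nc.SimulationConfig(circadian_amplitude=0, noise_sd=0)
        df = synthetic.generate_glucose_trace("2021-06-07", 2,
                                              pd.DataFrame(), cfg, rng=None)
        assert len(df) == 2 * 96
        assert (df["glucose_mmol_l"] == cfg.baseline_glucose).all()

    def test_single_meal_peak_time_and_amplitude(self):
        cfg = nc.SimulationConfig(noise_sd=0)
        meals = pd.DataFrame({"timestamp": [pd.Timestamp("2021-06-07 12:00")],
                              "kcal": [500.0]})
        df = synthetic.generate_glucose_trace("2021-06-07", 1, meals, cfg,
                                              rng=None)
        peak = df.loc[df["glucose_mmol_l"].idxmax()]
        assert peak["timestamp"] == pd.Timestamp("2021-06-07 12:45")
        base = synthetic.generate_glucose_trace("2021-06-07", 1,
                                                pd.DataFrame(), cfg, rng=None)
        circ = base.loc[base["timestamp"] == peak["timestamp"],
                        "glucose_mmol_l"].iloc[0]
        assert peak["glucose_mmol_l"] - circ == pytest.approx(
            5 * cfg.excursion_gain, abs=1e-3)

    def test_two_meals_superpose_linearly(self):
        cfg = nc.SimulationConfig(noise_sd=0)
        m1 = pd.DataFrame({"timestamp": [pd.Timestamp("2021-06-07 08:00")],
                           "kcal": [400.0]})
        m2 = pd.DataFrame({"timestamp": [pd.Timestamp("2021-06-07 16:00")],
                           "kcal": [600.0]})
        both = pd.concat([m1, m2], ignore_index=True)
        f = lambda m: synthetic.generate_glucose_trace(
            "2021-06-07", 1, m, cfg, rng=None)["glucose_mmol_l"].to_numpy()
        base = f(pd.DataFrame())
        np.testing.assert_allclose(f(both), f(m1) + f(m2) - base, atol=1e-9)

    def test_trace_clipped_below(self):
        cfg = nc.SimulationConfig(baseline_glucose=2.0, circadian_amplitude=0,
                                  noise_sd=0)
        df = synthetic.generate_glucose_trace("2021-06-07", 1,
                                              pd.DataFrame(), cfg, rng=None)
        assert (df["glucose_mmol_l"] == 2.5).all()


class TestSensorCensoring:
    def _trace(self, n_days=2):
        cfg = nc.SimulationConfig(noise_sd=0)
        return synthetic.generate_glucose_trace("2021-06-07", n_days,
                                                pd.DataFrame(), cfg, rng=None)

    def test_saturated_scanning_deletes_nothing(self):
        cfg = nc.SimulationConfig()
        trace = self._trace()
        scans = list(pd.to_datetime(trace["timestamp"]))
        out = synthetic.apply_sensor_censoring(trace, cfg, scan_times=scans)
        pd.testing.assert_frame_equal(out, trace)

    def test_no_scans_empties_the_trace(self):
        out = synthetic.apply_sensor_censoring(self._trace(),
                                               nc.SimulationConfig(),
                                               scan_times=[])
        assert len(out) == 0

    def test_censoring_is_a_subset_and_unchanged(self):
        cfg = nc.SimulationConfig(scan_interval_mean=6)
        trace = self._trace(4)
        out = synthetic.apply_sensor_censoring(trace, cfg,
                                               rng=np.random.default_rng(5))
        merged = out.merge(trace, on=["timestamp", "glucose_mmol_l"])
        assert len(merged) == len(out) <= len(trace)

    def test_retained_fraction_matches_renewal_oracle(self):
        cfg = nc.SimulationConfig(scan_interval_mean=4)
        trace = self._trace(14)
        reps = 300
        rng = np.random.default_rng(6)
        kept = [len(synthetic.apply_sensor_censoring(trace, cfg, rng=rng))
                for _ in range(reps)]
        impl = np.mean(kept) / len(trace)
        oracle = censoring_retention_oracle(
            14, 4.0, 8.0, np.random.default_rng(7), reps)
        assert impl == pytest.approx(oracle, abs=0.01)


class TestSleepRecords:
    def test_noiseless_weekend_shift_exact(self):
        cfg = nc.SimulationConfig(sleep_jitter_sd=0, weekend_wake_shift=30,
                                  sleep_missing_rate=0)
        rec = synthetic.generate_sleep_records("2021-06-07", 14, cfg,
                                               np.random.default_rng(8))
        wake = pd.to_datetime(rec["waketime"])
        mins = wake.dt.hour * 60 + wake.dt.minute
        weekend = wake.dt.weekday >= 5
        assert (mins[weekend] == cfg.waketime_mean + 30).all()
        assert (mins[~weekend] == cfg.waketime_mean).all()

    def test_null_shift_equal_means(self):
        cfg = nc.SimulationConfig(sleep_jitter_sd=0, weekend_wake_shift=0,
                                  sleep_missing_rate=0)
        rec = synthetic.generate_sleep_records("2021-06-07", 14, cfg,
                                               np.random.default_rng(8))
        wake = pd.to_datetime(rec["waketime"])
        mins = wake.dt.hour * 60 + wake.dt.minute
        assert mins.nunique() == 1

    def test_missing_rate_drops_nights(self):
        cfg = nc.SimulationConfig(sleep_missing_rate=0.5)
        rec = synthetic.generate_sleep_records("2021-06-07", 200, cfg,
                                               np.random.default_rng(9))
        lo, hi = stats.binom.interval(0.999, 200, 0.5)
        assert lo <= len(rec) <= hi


class TestEnrollmentLedger:
    def test_zero_dropout_everyone_completes(self):
        cfg = nc.SimulationConfig(n_participants=50, dropout_probs=(0, 0, 0))
        ledger = synthetic.generate_enrollment_ledger(cfg)
        assert (ledger["phase"] == "completed").all()
        assert (ledger["exit_reason"] == "not_applicable").all()

    def test_certain_first_phase_exit_completes_nobody(self):
        cfg = nc.SimulationConfig(n_participants=50, dropout_probs=(1, 0, 0))
        ledger = synthetic.generate_enrollment_ledger(cfg)
        assert (ledger["phase"] == "enrolled").all()

    def test_funnel_counts_nonincreasing(self, small_cohort):
        order = {"enrolled": 0, "preparatory": 1, "tracking": 2, "completed": 3}
        reached = small_cohort.ledger["phase"].map(order)
        counts = [int((reached >= k).sum()) for k in range(4)]
        assert counts == sorted(counts, reverse=True)


class TestAbundanceGeneration:
    def test_zero_offset_groups_indistinguishable(self):
        cfg = nc.SimulationConfig(microbiota_group_offset=0.0)
        labels = ["A"] * 50 + ["B"] * 50
        tab = synthetic.generate_abundance_table(
            100, 40, labels, cfg, rng=np.random.default_rng(10))
        from nutricohort import microbiota as mb
        rel = mb.relative_abundance(tab)
        d = mb.bray_curtis(rel).to_numpy()
        grp = np.array(labels)
        same = grp[:, None] == grp[None, :]
        off = ~np.eye(100, dtype=bool)
        within = d[same & off].mean()
        between = d[~same].mean()
        assert abs(between - within) < 0.02

    def test_disjoint_support_gives_unit_distance(self):
        cfg = nc.SimulationConfig(microbiota_group_offset=np.inf)
        labels = ["A"] * 5 + ["B"] * 5
        tab = synthetic.generate_abundance_table(
            10, 20, labels, cfg, rng=np.random.default_rng(11))
        from nutricohort import microbiota as mb
        d = mb.bray_curtis(mb.relative_abundance(tab))
        grp = tab.groups.to_numpy()
        between = d.to_numpy()[grp[:, None] != grp[None, :]]
        np.testing.assert_allclose(between, 1.0)

    def test_lineages_have_six_ranks(self):
        cfg = nc.SimulationConfig()
        tab = synthetic.generate_abundance_table(
            3, 12, ["A"] * 3, cfg, rng=np.random.default_rng(12))
        assert all(len(l.split(";")) == 6 for l in tab.lineages)

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ConfigurationError):
            synthetic.generate_abundance_table(2, 1, ["A", "B"],
                                               nc.SimulationConfig())
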