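import datetime as dt
import math

import numpy as np
import pandas as pd
import pytest

from promine.cohort import Cohort, DailyMeasurements, SensorSample
from promine.features import (
    N_FEATURES,
    N_FEATURES_NO_CROSS,
    add_change_features,
    add_personalized_features,
    aggregate_day,
    build_feature_table,
    derive_features,
    feature_names,
    infer_provenance,
)

from conftest import table_from_array


def s(ts, **kw):
    return SensorSample(timestamp=ts, **kw)


class TestAggregateDay:
    def test_constant_channel(self):
        samples = [s(60.0 * i, body_temperature=36.5) for i in range(10)]
        agg = aggregate_day(samples, sample_interval_s=60)
        assert agg["body_temperature_avg"] == pytest.approx(36.5)
        assert agg["body_temperature_std"] == 0.0

    def test_heart_rate_from_rr(self):
        samples = [s(0.0, rr_interval=1000.0), s(60.0, rr_interval=750.0)]
        agg = aggregate_day(samples, sample_interval_s=60)
        assert agg["heart_rate_avg"] == pytest.approx(70.0)  # (60 + 80) / 2

    def test_per_activity_split(self):
        samples = [s(60.0 * i, body_temperature=36.0, activity="lying") for i in range(3)]
        samples += [s(60.0 * (3 + i), body_temperature=37.0, activity="moving") for i in range(3)]
        agg = aggregate_day(samples, sample_interval_s=60)
        assert agg["body_temperature_avg_lying"] == pytest.approx(36.0)
        assert agg["body_temperature_avg_moving"] == pytest.approx(37.0)
        assert agg["body_temperature_avg"] == pytest.approx(36.5)
        assert math.isnan(agg["body_temperature_avg_sitting"])
        assert agg["duration_lying"] == pytest.approx(180.0)

    def test_empty_input_all_missing(self):
        agg = aggregate_day([])
        assert all(math.isnan(v) for v in agg.values())


class TestDerivedFormulas:
    def test_rate_pressure_and_double_product(self):
        daily = DailyMeasurements(sbp=120.0, dbp=80.0)
        out = derive_features(daily, {"heart_rate_avg": 70.0})
        assert out["rpp"] == pytest.approx(8400.0)
        assert out["dop"] == pytest.approx(7000.0)
        assert out["bp_ratio"] == pytest.approx(1.5)

    def test_humidity_ratio_in_study_cutoff_regime(self):
        daily = DailyMeasurements(amb_hum=50.0)
        out = derive_features(daily, {"body_humidity_avg": 37.0})
        assert out["humidity_ratio"] == pytest.approx(0.74)

    def test_division_by_zero_yields_missing(self):
        daily = DailyMeasurements()
        daily.dbp = 0.0
        daily.sbp = 120.0
        out = derive_features(daily, {})
        assert math.isnan(out["bp_ratio"])

    def test_hr_nearest_to_bp_timestamp_within_window(self):
        daily = DailyMeasurements(sbp=100.0, dbp=60.0)
        samples = [s(100.0, rr_interval=1000.0), s(5000.0, rr_interval=750.0)]
        agg = {"heart_rate_avg": 70.0}
        near = derive_features(daily, agg, samples=samples, bp_timestamp=200.0)
        assert near["rpp"] == pytest.approx(100.0 * 60.0)  # beat at ts=100 wins
        far = derive_features(daily, agg, samples=samples, bp_timestamp=20000.0)
        assert far["rpp"] == pytest.approx(100.0 * 70.0)  # fallback: daily mean

    def test_missing_operand_propagates(self):
        out = derive_features(DailyMeasurements(dbp=80.0), {"heart_rate_avg": 70.0})
        assert math.isnan(out["rpp"]) and math.isnan(out["dop"])


class TestChangeFeatures:
    @staticmethod
    def _table(values_by_day):
        X = np.array([[v] for _, v in values_by_day], dtype=float)
        t = table_from_array(X, ["weight"])
        idx = pd.MultiIndex.from_tuples(
            [("P01", dt.date(2020, 1, 1) + dt.timedelta(days=d)) for d, _ in values_by_day],
            names=["patient_id", "date"],
        )
        t.df.index = idx
        return t

    def test_next_day_change(self):
        t = add_change_features(self._table([(0, 86.0), (1, 87.0)]))
        assert t.df["weight_chg"].tolist()[1] == pytest.approx(1.0)
        assert math.isnan(t.df["weight_chg"].iloc[0])  # first observed day

    def test_gap_of_four_days_is_stale(self):
        t = add_change_features(self._table([(0, 80.0), (4, 90.0)]))
        assert math.isnan(t.df["weight_chg"].iloc[1])

    def test_gap_of_exactly_three_days_allowed(self):
        t = add_change_features(self._table([(0, 80.0), (3, 90.0)]))
        assert t.df["weight_chg"].iloc[1] == pytest.approx(10.0)

    def test_skips_missing_intermediate_values(self):
        t = add_change_features(self._table([(0, 80.0), (1, np.nan), (2, 85.0)]))
        assert t.df["weight_chg"].iloc[2] == pytest.approx(5.0)

    def test_constant_series_changes_are_zero(self):
        t = add_change_features(self._table([(d, 70.0) for d in range(6)]))
        assert np.allclose(t.df["weight_chg"].iloc[1:], 0.0)


class TestPersonalizedFeatures:
    def test_constant_series_is_one(self):
        t = add_personalized_features(table_from_array([[100.0], [100.0], [100.0]], ["sbp"]))
        assert np.allclose(t.df["sbp_pers"], 1.0)

    def test_study_cutoff_regime(self):
        t = add_personalized_features(table_from_array([[108.0], [120.0], [132.0]], ["sbp"]))
        assert t.df["sbp_pers"].iloc[2] == pytest.approx(132.0 / 120.0)

    def test_single_day_patient_is_one(self):
        t = add_personalized_features(table_from_array([[87.3]], ["weight"]))
        assert t.df["weight_pers"].iloc[0] == pytest.approx(1.0)

    def test_per_patient_mean_is_one(self, small_table):
        pers = [c for c in small_table.columns if small_table.provenance[c].kind == "personalized"]
        pid = small_table.df.index.get_level_values("patient_id")
        means = small_table.df[pers].groupby(pid).mean()
        assert np.allclose(means.to_numpy()[~np.isnan(means.to_numpy())], 1.0, atol=1e-9)


class TestBuildFeatureTable:
    def test_canonical_enumeration_size(self, small_table):
        assert list(small_table.df.columns) == feature_names(include_cross_variants=False)
        assert small_table.df.shape[1] == N_FEATURES_NO_CROSS
        assert len(feature_names()) == N_FEATURES

    def test_empty_cohort_header_only(self):
        t = build_feature_table(Cohort([]))
        assert t.df.shape == (0, N_FEATURES)

    def test_determinism(self, small_synth):
        cohort, _ = small_synth
        t1 = build_feature_table(cohort, include_cross_variants=False)
        t2 = build_feature_table(cohort, include_cross_variants=False)
        pd.testing.assert_frame_equal(t1.df, t2.df)

    def test_activity_fractions_sum_to_one(self, small_table):
        frac = small_table.df[["time_frac_lying", "time_frac_sitting", "time_frac_moving"]]
        sums = frac.sum(axis=1, skipna=False).dropna()
        assert len(sums) > 0
        assert np.allclose(sums, 1.0, atol=1e-9)

    def test_vectorized_build_matches_per_day_reference(self, small_synth):
        """The cohort-level construction agrees with the per-day reference
        implementation on every base column."""
        cohort, _ = small_synth
        table = build_feature_table(cohort, include_cross_variants=False)
        rng_days = cohort.sorted().patient_days[:40]
        for day in rng_days:
            agg = aggregate_day(day.samples)
            ref = {**agg, **derive_features(day.daily, agg, samples=day.samples)}
            for f in ("sbp", "dbp", "spo2", "weight", "amb_temp", "amb_hum"):
                v = getattr(day.daily, f)
                ref[f] = np.nan if v is None else v
            row = table.df.loc[(day.patient_id, day.date)]
            for col, expected in ref.items():
                got = row[col]
                assert (math.isnan(expected) and math.isnan(got)) or got == pytest.approx(
                    expected, rel=1e-9
                ), col

    def test_provenance_inference_round_trip(self, small_table):
        inferred = infer_provenance(list(small_table.df.columns))
        assert inferred == small_table.provenance
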