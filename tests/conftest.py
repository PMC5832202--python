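import datetime as dt

import numpy as np
import pandas as pd
import pytest

from promine.cohort import Cohort, DailyMeasurements, PatientDay, SensorSample
from promine.features import FeatureTable, build_feature_table, infer_provenance
from promine.synthetic import GeneratorConfig, generate_cohort


def table_from_array(X, columns=None, patients=None) -> FeatureTable:
    """Wrap a plain matrix as a FeatureTable (one synthetic patient/day per row)."""
    X = np.asarray(X, dtype=float)
    columns = columns or [f"f{j}" for j in range(X.shape[1])]
    if patients is None:
        patients = ["P01"] * X.shape[0]
    idx = pd.MultiIndex.from_tuples(
        [(patients[i], dt.date(2020, 1, 1) + dt.timedelta(days=i)) for i in range(X.shape[0])],
        names=["patient_id", "date"],
    )
    return FeatureTable(pd.DataFrame(X, index=idx, columns=columns), infer_provenance(columns))


def make_day(pid, date, pro=None, samples=(), **daily):
    return PatientDay(
        patient_id=pid,
        date=date,
        daily=DailyMeasurements(**daily),
        samples=list(samples),
        pro=pro,
    )


@pytest.fixture(scope="session")
def tiny_cohort() -> Cohort:
    """Two patients, handcrafted values, one missing spo2 cell."""
    d = dt.date(2020, 3, 1)
    samples = [
        SensorSample(timestamp=100.0 + 60 * i, body_temperature=36.5, rr_interval=1000.0,
                     activity="lying", energy=1.0)
        for i in range(4)
    ]
    days = [
        make_day("A", d, pro=3, sbp=120.0, dbp=80.0, spo2=97.0, weight=80.0,
                 amb_temp=20.0, amb_hum=50.0, samples=samples),
        make_day("A", d + dt.timedelta(days=1), pro=2, sbp=125.0, dbp=82.0,
                 weight=81.0, amb_temp=21.0, amb_hum=52.0),
        make_day("B", d, pro=5, sbp=110.0, dbp=70.0, spo2=98.0, weight=60.0,
                 amb_temp=19.0, amb_hum=40.0),
    ]
    return Cohort(days)


@pytest.fixture(scope="session")
def small_synth():
    cfg = GeneratorConfig(n_patients=6, days_per_patient=25, seed=11)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_table(small_synth):
    cohort, _ = small_synth
    return build_feature_table(cohort, include_cross_variants=False)
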