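"""Domain types for daily telemonitoring data.

The unit of analysis is the *patient-day*: one calendar day of one patient,
carrying the once-daily measurements (blood pressure, SpO2, weight, ambient
temperature/humidity), the wearable-sensor sample stream recorded that day,
and the patient-reported outcome (PRO) — a 1..5 ordinal rating of how the
patient feels relative to the previous day (1 = much worse, 3 = same,
5 = much better).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace

from .errors import IntegrityError

#: Valid PRO label values (ordinal, relative to the previous day).
PRO_LABELS = frozenset({1, 2, 3, 4, 5})

#: Recognized physical-activity labels for sensor samples.
ACTIVITIES = ("lying", "sitting", "moving")

#: Continuous wearable channels (heart rate is derived as 60000 / rr_interval).
SENSOR_CHANNELS = (
    "body_humidity",
    "body_temperature",
    "pr_interval",
    "qrs_duration",
    "qt_interval",
    "rr_interval",
    "r_amplitude",
    "t_amplitude",
    "energy",
)

#: Once-daily measurement fields.
DAILY_FIELDS = ("sbp", "dbp", "spo2", "weight", "amb_temp", "amb_hum")


def validate_pro(value: int | None) -> int | None:
    """Validate a PRO label; ``None`` encodes an absent report."""
    if value is None:
        return None
    value = int(value)
    if value not in PRO_LABELS:
        raise IntegrityError(f"PRO label must be in 1..5, got {value}")
    return value


@dataclass
class DailyMeasurements:
    """Once-daily measurements; any field may be missing (None)."""

    sbp: float | None = None
    dbp: float | None = None
    spo2: float | None = None
    weight: float | None = None
    amb_temp: float | None = None
    amb_hum: float | None = None

    def validate(self) -> None:
        if self.sbp is not None and self.dbp is not None:
            if not (0 < self.dbp <= self.sbp < 300):
                raise IntegrityError(
                    f"blood pressure out of range: sbp={self.sbp}, dbp={self.dbp}"
                )
        if self.spo2 is not None and not (0 <= self.spo2 <= 100):
            raise IntegrityError(f"spo2 out of range: {self.spo2}")
        if self.amb_hum is not None and not (0 <= self.amb_hum <= 100):
            raise IntegrityError(f"ambient humidity out of range: {self.amb_hum}")
        if self.weight is not None and self.weight <= 0:
            raise IntegrityError(f"weight must be positive: {self.weight}")


@dataclass
class SensorSample:
    """One wearable-sensor sample; every channel may be missing per sample."""

    timestamp: float  # seconds within the day
    body_humidity: float | None = None
    body_temperature: float | None = None
    pr_interval: float | None = None
    qrs_duration: float | None = None
    qt_interval: float | None = None
    rr_interval: float | None = None
    r_amplitude: float | None = None
    t_amplitude: float | None = None
    activity: str | None = None
    energy: float | None = None

    def validate(self) -> None:
        if self.rr_interval is not None and self.rr_interval <= 0:
            raise IntegrityError(f"rr_interval must be positive: {self.rr_interval}")
        if self.activity is not None and self.activity not in ACTIVITIES:
            raise IntegrityError(f"unknown activity label: {self.activity!r}")

    @property
    def heart_rate(self) -> float | None:
        """Instantaneous heart rate in bpm (60000 / RR interval in ms)."""
        if self.rr_interval is None:
            return None
        return 60000.0 / self.rr_interval


@dataclass
class PatientDay:
    """One patient-calendar-day: daily measurements, sensor stream, PRO."""

    patient_id: str
    date: dt.date
    daily: DailyMeasurements = field(default_factory=DailyMeasurements)
    samples: list[SensorSample] = field(default_factory=list)
    pro: int | None = None

    def validate(self) -> None:
        validate_pro(self.pro)
        self.daily.validate()
        prev = None
        for s in self.samples:
            s.validate()
            if prev is not None and s.timestamp < prev:
                raise IntegrityError(
                    f"sensor timestamps not sorted for {self.patient_id} {self.date}"
                )
            prev = s.timestamp


@dataclass
class Cohort:
    """A collection of patient-days with unique (patient_id, date) keys."""

    patient_days: list[PatientDay] = field(default_factory=list)

    @property
    def patients(self) -> set[str]:
        return {pd_.patient_id for pd_ in self.patient_days}

    def __len__(self) -> int:
        return len(self.patient_days)

    def validate(self) -> None:
        seen: set[tuple[str, dt.date]] = set()
        for pd_ in self.patient_days:
            key = (pd_.patient_id, pd_.date)
            if key in seen:
                raise IntegrityError(f"duplicate patient-day {key}")
            seen.add(key)
            pd_.validate()

    def sorted(self) -> "Cohort":
        """Return a copy ordered by (patient_id, date) — the canonical order."""
        return Cohort(sorted(self.patient_days, key=lambda d: (d.patient_id, d.date)))

    def pro_sequences(self) -> dict[str, dict[dt.date, int | None]]:
        """Per-patient date -> PRO label mapping (absent labels as None)."""
        out: dict[str, dict[dt.date, int | None]] = {}
        for pd_ in self.patient_days:
            out.setdefault(pd_.patient_id, {})[pd_.date] = pd_.pro
        return out

    def copy(self) -> "Cohort":
        days = [
            replace(
                pd_,
                daily=replace(pd_.daily),
                samples=[replace(s) for s in pd_.samples],
            )
            for pd_ in self.patient_days
        ]
        return Cohort(days)
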