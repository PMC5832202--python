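"""Reading and writing the canonical CSV dialects.

Two plain-text formats are defined (RFC-4180, comma, UTF-8, header row):

* daily CSV — one row per patient-day:
  ``patient_id,date,sbp,dbp,spo2,weight,amb_temp,amb_hum,pro``
* sensor CSV — one row per wearable sample:
  ``patient_id,date,timestamp_s,<channels...>,activity,energy``

Missing values are empty cells; dates are ISO-8601. A best-effort ``s1``
dialect adapter loads an externally deposited study CSV through a
user-supplied column mapping (the real layout is not documented, so it is
configured, never guessed).
"""

from __future__ import annotations

import csv
import datetime as dt
from pathlib import Path
from typing import Mapping

from .cohort import (
    Cohort,
    DailyMeasurements,
    PatientDay,
    SensorSample,
    DAILY_FIELDS,
)
from .errors import IntegrityError, RowParseError, SchemaError

DAILY_HEADER = ["patient_id", "date"] + list(DAILY_FIELDS) + ["pro"]
SENSOR_CHANNEL_COLUMNS = [
    "body_humidity",
    "body_temperature",
    "pr_interval",
    "qrs_duration",
    "qt_interval",
    "rr_interval",
    "r_amplitude",
    "t_amplitude",
]
SENSOR_HEADER = (
    ["patient_id", "date", "timestamp_s"]
    + SENSOR_CHANNEL_COLUMNS
    + ["activity", "energy"]
)


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        return repr(value)  # shortest exactly round-trippable form
    return str(value)


def _parse_float(cell: str, column: str, line: int) -> float | None:
    cell = cell.strip()
    if cell == "":
        return None
    try:
        return float(cell)
    except ValueError:
        raise RowParseError(f"unparsable number in column {column!r}: {cell!r}", line)


def _parse_date(cell: str, line: int) -> dt.date:
    try:
        return dt.date.fromisoformat(cell.strip())
    except ValueError:
        raise RowParseError(f"unparsable ISO date: {cell!r}", line)


def read_daily_csv(
    path: str | Path,
    dialect: str = "canonical",
    s1_mapping: Mapping[str, str] | None = None,
) -> Cohort:
    """Read a daily-measurements CSV into a :class:`Cohort`.

    ``dialect='s1'`` reads an externally deposited long-format file through
    ``s1_mapping``, a mapping from canonical column names (``patient_id``,
    ``date``, ``sbp``, ... ``pro``) to the file's actual column names.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise SchemaError(f"{path}: empty file")
        if dialect == "canonical":
            colmap = {name: name for name in DAILY_HEADER}
        elif dialect == "s1":
            if s1_mapping is None:
                raise SchemaError("dialect 's1' requires an explicit column mapping")
            colmap = {canon: s1_mapping.get(canon, canon) for canon in DAILY_HEADER}
        else:
            raise SchemaError(f"unknown dialect {dialect!r}")
        index: dict[str, int] = {}
        for canon, actual in colmap.items():
            if actual not in header:
                raise SchemaError(f"{path}: missing expected column {actual!r}")
            index[canon] = header.index(actual)

        days: list[PatientDay] = []
        seen: set[tuple[str, dt.date]] = set()
        for lineno, row in enumerate(reader, start=2):
            if not row or all(c.strip() == "" for c in row):
                continue
            pid = row[index["patient_id"]].strip()
            date = _parse_date(row[index["date"]], lineno)
            if (pid, date) in seen:
                raise IntegrityError(f"duplicate (patient, date): ({pid}, {date})")
            seen.add((pid, date))
            daily = DailyMeasurements(
                **{
                    f: _parse_float(row[index[f]], f, lineno)
                    for f in DAILY_FIELDS
                }
            )
            pro_cell = row[index["pro"]].strip()
            pro = None
            if pro_cell != "":
                pro_val = _parse_float(pro_cell, "pro", lineno)
                pro = int(round(pro_val))
            days.append(PatientDay(patient_id=pid, date=date, daily=daily, pro=pro))
    cohort = Cohort(days).sorted()
    cohort.validate()
    return cohort


def write_daily_csv(cohort: Cohort, path: str | Path) -> Path:
    """Write the canonical daily CSV; rows sorted by (patient_id, date)."""
    path = Path(path)
    ordered = cohort.sorted()
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(DAILY_HEADER)
        for day in ordered.patient_days:
            writer.writerow(
                [day.patient_id, day.date.isoformat()]
                + [_fmt(getattr(day.daily, f)) for f in DAILY_FIELDS]
                + [_fmt(day.pro)]
            )
    return path


def read_sensor_csv(
    path: str | Path, resort: bool = False
) -> dict[tuple[str, dt.date], list[SensorSample]]:
    """Read the canonical sensor CSV, grouping samples per patient-day."""
    path = Path(path)
    groups: dict[tuple[str, dt.date], list[SensorSample]] = {}
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            return {}
        for col in SENSOR_HEADER:
            if col not in header:
                raise SchemaError(f"{path}: missing expected column {col!r}")
        idx = {col: header.index(col) for col in SENSOR_HEADER}
        for lineno, row in enumerate(reader, start=2):
            if not row or all(c.strip() == "" for c in row):
                continue
            pid = row[idx["patient_id"]].strip()
            date = _parse_date(row[idx["date"]], lineno)
            ts = _parse_float(row[idx["timestamp_s"]], "timestamp_s", lineno)
            if ts is None:
                raise RowParseError("missing timestamp_s", lineno)
            activity = row[idx["activity"]].strip() or None
            sample = SensorSample(
                timestamp=ts,
                activity=activity,
                energy=_parse_float(row[idx["energy"]], "energy", lineno),
                **{
                    ch: _parse_float(row[idx[ch]], ch, lineno)
                    for ch in SENSOR_CHANNEL_COLUMNS
                },
            )
            sample.validate()
            groups.setdefault((pid, date), []).append(sample)
    for key, samples in groups.items():
        ts = [s.timestamp for s in samples]
        if any(b < a for a, b in zip(ts, ts[1:])):
            if resort:
                samples.sort(key=lambda s: s.timestamp)
            else:
                raise IntegrityError(
                    f"out-of-order timestamps for {key}; pass resort=True to re-sort"
                )
    return groups


def write_sensor_csv(cohort: Cohort, path: str | Path) -> Path:
    """Write every patient-day's sample stream to the canonical sensor CSV."""
    path = Path(path)
    ordered = cohort.sorted()
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(SENSOR_HEADER)
        for day in ordered.patient_days:
            for s in day.samples:
                writer.writerow(
                    [day.patient_id, day.date.isoformat(), _fmt(s.timestamp)]
                    + [_fmt(getattr(s, ch)) for ch in SENSOR_CHANNEL_COLUMNS]
                    + [s.activity or "", _fmt(s.energy)]
                )
    return path


def attach_sensor_samples(
    cohort: Cohort, groups: dict[tuple[str, dt.date], list[SensorSample]]
) -> Cohort:
    """Attach sensor sample groups to the matching patient-days (in place)."""
    for day in cohort.patient_days:
        key = (day.patient_id, day.date)
        if key in groups:
            day.samples = groups[key]
    return cohort
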