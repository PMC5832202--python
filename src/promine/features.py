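"""Daily feature construction from telemonitoring data.

From each patient-day the module builds:

* per-channel aggregates — mean and standard deviation of every continuous
  wearable channel over the whole day and separately during each physical
  activity (lying, sitting, moving), plus per-activity durations;
* the once-daily measurements (blood pressure, SpO2, weight, ambient
  temperature and humidity) taken as-is;
* derived formulas — rate pressure product RPP = SBP * HR, double product
  DoP = ((SBP + DBP) / 2) * HR, SBP/DBP ratio, skin/ambient temperature and
  humidity ratios, heart-rate differences and ratios between activity pairs,
  activity-duration ratios and time fractions, and the mean per-sample
  heart-rate / energy-expenditure ratio;
* for every feature above, a *change* variant (today's value minus the most
  recent prior value at most 3 calendar days old) and a *personalized*
  variant (today's value divided by the patient's whole-period mean), and —
  by default — the two cross variants (change of personalized, personalized
  of change).

Standard deviations use the population formula (divide by n); this is an
arbitrary but frozen convention. Formulas with a missing operand yield a
missing cell; divisions by zero yield missing cells with a logged warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cohort import ACTIVITIES, Cohort, DailyMeasurements, SensorSample, DAILY_FIELDS

logger = logging.getLogger(__name__)

#: Continuous channels as daily-feature sources (heart rate replaces RR).
CHANNELS = (
    "body_humidity",
    "body_temperature",
    "pr_interval",
    "qrs_duration",
    "qt_interval",
    "heart_rate",
    "r_amplitude",
    "t_amplitude",
    "energy",
)

_ACTIVITY_PAIRS = (("lying", "sitting"), ("lying", "moving"), ("sitting", "moving"))

DERIVED_NAMES = (
    ("rpp", "sbp"),
    ("dop", "sbp"),
    ("bp_ratio", "sbp"),
    ("temp_ratio", "body_temperature"),
    ("humidity_ratio", "body_humidity"),
    ("hr_diff_lying_sitting", "heart_rate"),
    ("hr_diff_lying_moving", "heart_rate"),
    ("hr_diff_sitting_moving", "heart_rate"),
    ("hr_ratio_lying_sitting", "heart_rate"),
    ("hr_ratio_lying_moving", "heart_rate"),
    ("hr_ratio_sitting_moving", "heart_rate"),
    ("duration_ratio_lying_sitting", "activity"),
    ("duration_ratio_lying_moving", "activity"),
    ("duration_ratio_sitting_moving", "activity"),
    ("time_frac_lying", "activity"),
    ("time_frac_sitting", "activity"),
    ("time_frac_moving", "activity"),
    ("hr_per_energy", "heart_rate"),
)

_ACTIVITY_DERIVED = tuple(
    n
    for n, _ in DERIVED_NAMES
    if n.startswith(("hr_diff", "hr_ratio", "duration_ratio", "time_frac"))
)


@dataclass(frozen=True)
class Provenance:
    """Where a feature column comes from.

    kind is one of base / per_activity / derived / change / personalized;
    source names the underlying monitored parameter; parent names the column
    a change or personalized variant was built from; activity_related marks
    columns tied to specific physical activities (used by subset selection).
    """

    kind: str
    source: str
    parent: str | None = None
    activity_related: bool = False


def _base_provenance() -> dict[str, Provenance]:
    prov: dict[str, Provenance] = {}
    for f in DAILY_FIELDS:
        prov[f] = Provenance("base", f)
    for ch in CHANNELS:
        prov[f"{ch}_avg"] = Provenance("base", ch)
        prov[f"{ch}_std"] = Provenance("base", ch)
        for act in ACTIVITIES:
            prov[f"{ch}_avg_{act}"] = Provenance("per_activity", ch, activity_related=True)
            prov[f"{ch}_std_{act}"] = Provenance("per_activity", ch, activity_related=True)
    for act in ACTIVITIES:
        prov[f"duration_{act}"] = Provenance("per_activity", "activity", activity_related=True)
    for name, source in DERIVED_NAMES:
        prov[name] = Provenance(
            "derived", source, activity_related=name in _ACTIVITY_DERIVED
        )
    return prov


def base_feature_names() -> list[str]:
    """The canonical ordered enumeration of base (non-variant) features."""
    return list(_base_provenance())


def feature_names(include_cross_variants: bool = True) -> list[str]:
    """The full canonical feature enumeration, in deterministic order."""
    base = base_feature_names()
    names = list(base)
    names += [f"{b}_chg" for b in base]
    names += [f"{b}_pers" for b in base]
    if include_cross_variants:
        names += [f"{b}_pers_chg" for b in base]
        names += [f"{b}_chg_pers" for b in base]
    return names


N_BASE_FEATURES = len(base_feature_names())
N_FEATURES = len(feature_names(include_cross_variants=True))
N_FEATURES_NO_CROSS = len(feature_names(include_cross_variants=False))


@dataclass
class FeatureTable:
    """Patient-day x feature matrix with per-column provenance.

    ``df`` is indexed by a (patient_id, date) MultiIndex; missing cells are
    NaN. ``provenance`` maps every column to its :class:`Provenance`.
    """

    df: pd.DataFrame
    provenance: dict[str, Provenance] = field(default_factory=dict)

    @property
    def columns(self) -> list[str]:
        return list(self.df.columns)

    def missing_fraction(self) -> pd.Series:
        return self.df.isna().mean()

    def select(self, columns: list[str]) -> "FeatureTable":
        return FeatureTable(
            self.df[list(columns)].copy(),
            {c: self.provenance[c] for c in columns if c in self.provenance},
        )

    def restrict_rows(self, keys) -> "FeatureTable":
        return FeatureTable(self.df.loc[list(keys)].copy(), dict(self.provenance))

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.df.copy(), dict(self.provenance))


# ---------------------------------------------------------------------------
# per-day reference implementations


def _interval(samples: list[SensorSample]) -> float:
    ts = np.array([s.timestamp for s in samples], dtype=float)
    if ts.size < 2:
        return np.nan
    return float(np.median(np.diff(ts)))


def aggregate_day(
    samples: list[SensorSample], sample_interval_s: float | None = None
) -> dict[str, float]:
    """Per-channel mean/SD overall and per activity, plus activity durations.

    Channels with no present samples yield NaN. Activity durations are
    sample counts times the sampling interval (given, or the median
    timestamp spacing of the day); they are 0 for unobserved activities when
    any activity label is present on the day.
    """
    out: dict[str, float] = {}
    interval = sample_interval_s if sample_interval_s is not None else _interval(samples)

    def stats(values: list[float | None]) -> tuple[float, float]:
        arr = np.array([v for v in values if v is not None], dtype=float)
        if arr.size == 0:
            return np.nan, np.nan
        return float(arr.mean()), float(arr.std(ddof=0))

    for ch in CHANNELS:
        getter = (
            (lambda s: s.heart_rate) if ch == "heart_rate" else (lambda s: getattr(s, ch))
        )
        out[f"{ch}_avg"], out[f"{ch}_std"] = stats([getter(s) for s in samples])
        for act in ACTIVITIES:
            sub = [getter(s) for s in samples if s.activity == act]
            out[f"{ch}_avg_{act}"], out[f"{ch}_std_{act}"] = stats(sub)

    any_activity = any(s.activity is not None for s in samples)
    for act in ACTIVITIES:
        count = sum(1 for s in samples if s.activity == act)
        if not any_activity or not np.isfinite(interval):
            out[f"duration_{act}"] = np.nan
        else:
            out[f"duration_{act}"] = count * interval
    return out


def _safe_div(num: float, den: float, what: str) -> float:
    if not (np.isfinite(num) and np.isfinite(den)):
        return np.nan
    if den == 0:
        logger.warning("division by zero computing %s; cell left missing", what)
        return np.nan
    return num / den


def derive_features(
    day_daily: DailyMeasurements,
    aggregates: dict[str, float],
    samples: list[SensorSample] | None = None,
    bp_timestamp: float | None = None,
    bp_window_s: float = 1800.0,
) -> dict[str, float]:
    """Derived daily formulas from a day's measurements and aggregates.

    The heart rate entering RPP and DoP is the beat nearest in time to the
    blood-pressure reading when a BP timestamp is known and a beat lies
    within ``bp_window_s``; otherwise the daily mean heart rate.
    """
    g = lambda k: aggregates.get(k, np.nan)
    nan = np.nan
    sbp = day_daily.sbp if day_daily.sbp is not None else nan
    dbp = day_daily.dbp if day_daily.dbp is not None else nan
    amb_t = day_daily.amb_temp if day_daily.amb_temp is not None else nan
    amb_h = day_daily.amb_hum if day_daily.amb_hum is not None else nan

    hr = g("heart_rate_avg")
    if bp_timestamp is not None and samples:
        best, best_dt = nan, bp_window_s
        for s in samples:
            if s.rr_interval is None:
                continue
            d = abs(s.timestamp - bp_timestamp)
            if d <= best_dt:
                best, best_dt = s.heart_rate, d
        if np.isfinite(best):
            hr = best

    out: dict[str, float] = {}
    out["rpp"] = sbp * hr
    out["dop"] = (sbp + dbp) / 2.0 * hr
    out["bp_ratio"] = _safe_div(sbp, dbp, "bp_ratio")
    out["temp_ratio"] = _safe_div(g("body_temperature_avg"), amb_t, "temp_ratio")
    out["humidity_ratio"] = _safe_div(g("body_humidity_avg"), amb_h, "humidity_ratio")
    for a, b in _ACTIVITY_PAIRS:
        out[f"hr_diff_{a}_{b}"] = g(f"heart_rate_avg_{a}") - g(f"heart_rate_avg_{b}")
        out[f"hr_ratio_{a}_{b}"] = _safe_div(
            g(f"heart_rate_avg_{a}"), g(f"heart_rate_avg_{b}"), f"hr_ratio_{a}_{b}"
        )
        out[f"duration_ratio_{a}_{b}"] = _safe_div(
            g(f"duration_{a}"), g(f"duration_{b}"), f"duration_ratio_{a}_{b}"
        )
    total = sum(g(f"duration_{act}") for act in ACTIVITIES)
    for act in ACTIVITIES:
        out[f"time_frac_{act}"] = _safe_div(g(f"duration_{act}"), total, "time_frac")

    if samples:
        ratios = [
            s.heart_rate / s.energy
            for s in samples
            if s.rr_interval is not None and s.energy is not None and s.energy != 0
        ]
        out["hr_per_energy"] = float(np.mean(ratios)) if ratios else nan
    else:
        out["hr_per_energy"] = nan
    return out


# ---------------------------------------------------------------------------
# vectorized cohort-level construction


def _sensor_frame(cohort: Cohort) -> pd.DataFrame:
    rows = []
    for day in cohort.patient_days:
        for s in day.samples:
            rows.append(
                (
                    day.patient_id,
                    day.date,
                    s.timestamp,
                    s.body_humidity,
                    s.body_temperature,
                    s.pr_interval,
                    s.qrs_duration,
                    s.qt_interval,
                    60000.0 / s.rr_interval if s.rr_interval else np.nan,
                    s.r_amplitude,
                    s.t_amplitude,
                    s.energy,
                    s.activity,
                )
            )
    cols = ["patient_id", "date", "ts"] + [c for c in CHANNELS] + ["activity"]
    df = pd.DataFrame(rows, columns=cols)
    for c in CHANNELS:
        df[c] = pd.to_numeric(df[c], errors="coerce")
    return df


def _daily_frame(cohort: Cohort) -> pd.DataFrame:
    rows = [
        (day.patient_id, day.date) + tuple(
            getattr(day.daily, f) if getattr(day.daily, f) is not None else np.nan
            for f in DAILY_FIELDS
        )
        for day in cohort.patient_days
    ]
    df = pd.DataFrame(rows, columns=["patient_id", "date"] + list(DAILY_FIELDS))
    return df.set_index(["patient_id", "date"]).sort_index()


def _aggregate_frame(cohort: Cohort, sample_interval_s: float | None) -> pd.DataFrame:
    """Vectorized per-day channel aggregates and activity durations."""
    sf = _sensor_frame(cohort)
    index = pd.MultiIndex.from_tuples(
        sorted((d.patient_id, d.date) for d in cohort.patient_days),
        names=["patient_id", "date"],
    )
    cols = [
        f"{ch}_{st}{suffix}"
        for ch in CHANNELS
        for st in ("avg", "std")
        for suffix in ("", "_lying", "_sitting", "_moving")
    ] + [f"duration_{a}" for a in ACTIVITIES]
    if sf.empty:
        return pd.DataFrame(np.nan, index=index, columns=cols)

    keys = ["patient_id", "date"]
    g = sf.groupby(keys)
    overall_avg = g[list(CHANNELS)].mean()
    overall_std = g[list(CHANNELS)].std(ddof=0)
    ga = sf.dropna(subset=["activity"]).groupby(keys + ["activity"])
    act_avg = ga[list(CHANNELS)].mean().unstack("activity")
    act_std = ga[list(CHANNELS)].std(ddof=0).unstack("activity")

    if sample_interval_s is not None:
        interval = pd.Series(sample_interval_s, index=overall_avg.index)
    else:
        diffs = sf.sort_values(keys + ["ts"]).groupby(keys)["ts"].diff()
        interval = diffs.groupby([sf["patient_id"], sf["date"]]).median()
        interval.index.names = keys
    counts = (
        sf.dropna(subset=["activity"])
        .groupby(keys + ["activity"])
        .size()
        .unstack("activity")
    )

    out = pd.DataFrame(index=index)
    for ch in CHANNELS:
        out[f"{ch}_avg"] = overall_avg[ch]
        out[f"{ch}_std"] = overall_std[ch]
        for act in ACTIVITIES:
            key = (ch, act)
            out[f"{ch}_avg_{act}"] = act_avg[key] if key in act_avg.columns else np.nan
            out[f"{ch}_std_{act}"] = act_std[key] if key in act_std.columns else np.nan
    any_act = counts.sum(axis=1) > 0 if not counts.empty else pd.Series(dtype=float)
    for act in ACTIVITIES:
        cnt = counts[act] if act in getattr(counts, "columns", []) else pd.Series(dtype=float)
        dur = cnt.reindex(out.index).fillna(0.0) * interval.reindex(out.index)
        if not counts.empty:
            dur[~any_act.reindex(out.index).fillna(False)] = np.nan
        else:
            dur[:] = np.nan
        out[f"duration_{act}"] = dur
    return out[cols]


def _derived_frame(daily: pd.DataFrame, agg: pd.DataFrame, sf: pd.DataFrame) -> pd.DataFrame:
    out = pd.DataFrame(index=agg.index)
    with np.errstate(divide="ignore", invalid="ignore"):
        hr = agg["heart_rate_avg"]
        out["rpp"] = daily["sbp"] * hr
        out["dop"] = (daily["sbp"] + daily["dbp"]) / 2.0 * hr
        out["bp_ratio"] = daily["sbp"] / daily["dbp"].replace(0, np.nan)
        out["temp_ratio"] = agg["body_temperature_avg"] / daily["amb_temp"].replace(0, np.nan)
        out["humidity_ratio"] = agg["body_humidity_avg"] / daily["amb_hum"].replace(0, np.nan)
        for a, b in _ACTIVITY_PAIRS:
            out[f"hr_diff_{a}_{b}"] = agg[f"heart_rate_avg_{a}"] - agg[f"heart_rate_avg_{b}"]
            out[f"hr_ratio_{a}_{b}"] = agg[f"heart_rate_avg_{a}"] / agg[
                f"heart_rate_avg_{b}"
            ].replace(0, np.nan)
            out[f"duration_ratio_{a}_{b}"] = agg[f"duration_{a}"] / agg[
                f"duration_{b}"
            ].replace(0, np.nan)
        total = sum(agg[f"duration_{act}"] for act in ACTIVITIES)
        for act in ACTIVITIES:
            out[f"time_frac_{act}"] = agg[f"duration_{act}"] / total.replace(0, np.nan)
        if sf.empty:
            out["hr_per_energy"] = np.nan
        else:
            ratio = sf["heart_rate"] / sf["energy"].replace(0, np.nan)
            out["hr_per_energy"] = ratio.groupby(
                [sf["patient_id"], sf["date"]]
            ).mean().reindex(out.index)
    return out


def add_change_features(
    table: FeatureTable,
    columns: list[str] | None = None,
    max_gap_days: int = 3,
    suffix: str = "_chg",
) -> FeatureTable:
    """Append change columns: today's value minus the most recent prior
    present value of the same column, provided that value is at most
    ``max_gap_days`` calendar days old; otherwise missing."""
    cols = columns if columns is not None else list(table.df.columns)
    df = table.df
    ordinals = np.array([d.toordinal() for d in df.index.get_level_values("date")])
    pids = df.index.get_level_values("patient_id").to_numpy()
    values = df[cols].to_numpy(dtype=float)
    chg = np.full_like(values, np.nan)

    order = np.lexsort((ordinals, pids))
    last_val = np.full(len(cols), np.nan)
    last_day = np.full(len(cols), -(10**9), dtype=float)
    prev_pid = None
    for i in order:
        pid = pids[i]
        if pid != prev_pid:
            last_val[:] = np.nan
            last_day[:] = -(10**9)
            prev_pid = pid
        row = values[i]
        gap_ok = (ordinals[i] - last_day) <= max_gap_days
        valid = gap_ok & ~np.isnan(last_val) & ~np.isnan(row)
        chg[i, valid] = row[valid] - last_val[valid]
        present = ~np.isnan(row)
        last_val[present] = row[present]
        last_day[present] = ordinals[i]

    new = table.df.copy()
    prov = dict(table.provenance)
    for j, c in enumerate(cols):
        name = c + suffix
        new[name] = chg[:, j]
        p = table.provenance.get(c, Provenance("base", c))
        prov[name] = Provenance("change", p.source, parent=c, activity_related=p.activity_related)
    return FeatureTable(new, prov)


def add_personalized_features(
    table: FeatureTable, columns: list[str] | None = None, suffix: str = "_pers"
) -> FeatureTable:
    """Append personalized columns: daily value divided by the patient's
    whole-period mean of that column (missing when the mean is 0)."""
    cols = columns if columns is not None else list(table.df.columns)
    df = table.df
    pid = df.index.get_level_values("patient_id")
    means = df[cols].groupby(pid).transform("mean")
    with np.errstate(divide="ignore", invalid="ignore"):
        pers = df[cols] / means.replace(0, np.nan).to_numpy()
    new = df.copy()
    prov = dict(table.provenance)
    for c in cols:
        name = c + suffix
        new[name] = pers[c]
        p = table.provenance.get(c, Provenance("base", c))
        prov[name] = Provenance(
            "personalized", p.source, parent=c, activity_related=p.activity_related
        )
    return FeatureTable(new, prov)


def build_feature_table(
    cohort: Cohort,
    include_cross_variants: bool = True,
    sample_interval_s: float | None = None,
) -> FeatureTable:
    """Construct the full canonical feature table for a cohort.

    Column order is the deterministic canonical enumeration
    (:func:`feature_names`); columns that cannot be computed for any day are
    present and all-missing.
    """
    expected = feature_names(include_cross_variants)
    if not cohort.patient_days:
        idx = pd.MultiIndex.from_arrays([[], []], names=["patient_id", "date"])
        prov = infer_provenance(expected)
        return FeatureTable(pd.DataFrame(columns=expected, index=idx, dtype=float), prov)
    cohort = cohort.sorted()
    daily = _daily_frame(cohort)
    agg = _aggregate_frame(cohort, sample_interval_s)
    sf = _sensor_frame(cohort)
    derived = _derived_frame(daily, agg, sf)

    base_names = base_feature_names()
    base_df = pd.concat([daily, agg, derived], axis=1).reindex(columns=base_names)
    prov = _base_provenance()
    table = FeatureTable(base_df, dict(prov))

    table = add_change_features(table, columns=base_names)
    table = add_personalized_features(table, columns=base_names)
    if include_cross_variants:
        table = add_change_features(table, columns=[f"{b}_pers" for b in base_names])
        table = add_personalized_features(table, columns=[f"{b}_chg" for b in base_names])
    table.df = table.df[expected]
    return table


def write_feature_csv(table: FeatureTable, path) -> None:
    out = table.df.reset_index()
    out["date"] = out["date"].astype(str)
    out.to_csv(path, index=False)


def read_feature_csv(path) -> FeatureTable:
    import datetime as dt

    df = pd.read_csv(path)
    df["date"] = df["date"].map(dt.date.fromisoformat)
    df = df.set_index(["patient_id", "date"])
    prov = infer_provenance(list(df.columns))
    return FeatureTable(df, prov)


def infer_provenance(columns: list[str]) -> dict[str, Provenance]:
    """Reconstruct provenance from canonical column names."""
    base = _base_provenance()
    out: dict[str, Provenance] = {}
    for c in columns:
        name, kind, parent = c, None, None
        if name.endswith("_pers"):
            kind, parent = "personalized", name[: -len("_pers")]
        elif name.endswith("_chg"):
            kind, parent = "change", name[: -len("_chg")]
        if kind is None:
            out[c] = base.get(c, Provenance("base", c))
        else:
            root = parent
            while root.endswith(("_pers", "_chg")):
                root = root[: root.rfind("_")]
            p = base.get(root, Provenance("base", root))
            out[c] = Provenance(kind, p.source, parent=parent, activity_related=p.activity_related)
    return out
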