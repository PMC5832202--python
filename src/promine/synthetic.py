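"""Synthetic telemonitoring cohort generator.

Emulates the statistical structure the downstream analysis assumes: a small
chronic-heart-failure cohort (two dozen patients observed for a few weeks to
a few months), once-daily measurements plus wearable sample streams, an
ordinal PRO rated *relative to the previous day*, heavy per-activity
missingness, and configurable planted parameter -> PRO effects.

Generative model
----------------
Each patient draws a baseline level for every monitored parameter from a
plausible physiological range; daily values follow an AR(1) drift around the
baseline. Because the PRO compares today with yesterday, the latent
wellbeing *change* on day t is a linear combination of standardized
day-to-day parameter changes::

    dw(t) = sum_e  sign(e) * magnitude(e) * z(x_e(t) - x_e(t-1)) + noise

(sign is -1 for ``higher_is_bad``). PRO labels are the ordinal
discretization of dw with thresholds fitted by quantile matching so that
label frequencies match the configured marginals. Sensor streams are drawn
around the daily means with per-activity offsets (heart rate:
lying < sitting < moving). Missingness is applied completely at random per
targeted cell: a daily measurement, a channel-day (all of a channel's
samples that day), or a channel-activity-day.

Everything is reproducible from the config seed.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import ACTIVITIES, Cohort, DailyMeasurements, PatientDay, SensorSample, DAILY_FIELDS
from .errors import ConfigError

#: Plausible physiological ranges (documented constants; low, high).
PARAM_RANGES: dict[str, tuple[float, float]] = {
    "sbp": (95.0, 160.0),
    "dbp": (55.0, 100.0),
    "spo2": (90.0, 100.0),
    "weight": (50.0, 110.0),
    "amb_temp": (15.0, 30.0),
    "amb_hum": (25.0, 75.0),
    "body_humidity": (30.0, 60.0),
    "body_temperature": (35.8, 37.2),
    "pr_interval": (140.0, 200.0),
    "qrs_duration": (80.0, 110.0),
    "qt_interval": (350.0, 440.0),
    "heart_rate": (55.0, 95.0),
    "r_amplitude": (0.5, 1.5),
    "t_amplitude": (0.1, 0.5),
    "energy": (1.2, 2.8),
}

_PARAMS = tuple(PARAM_RANGES)

#: AR(1) persistence of daily values around the patient baseline.
AR1_PHI = 0.6
#: Daily innovation SD as a fraction of the parameter's range width.
INNOVATION_FRACTION = 0.08

_HR_ACTIVITY_OFFSET = {"lying": -8.0, "sitting": 0.0, "moving": 15.0}
_ENERGY_ACTIVITY_LEVEL = {"lying": 0.6, "sitting": 1.0, "moving": 2.5}
_ACTIVITY_PROBS = (0.45, 0.35, 0.20)

#: PRO label marginals of the study cohort (counts 30/73/795/148/40 of 1086).
STUDY_LABEL_MARGINALS = (30 / 1086, 73 / 1086, 795 / 1086, 148 / 1086, 40 / 1086)


@dataclass(frozen=True)
class EffectSpec:
    """A planted parameter -> wellbeing effect.

    magnitude is the contribution to the latent wellbeing change per 1 SD of
    the parameter's day-to-day change; direction says which way it acts.
    """

    feature_name: str
    direction: str  # "higher_is_bad" | "higher_is_good"
    magnitude: float

    def __post_init__(self):
        if self.feature_name not in PARAM_RANGES:
            raise ConfigError(f"unknown effect parameter {self.feature_name!r}")
        if self.direction not in ("higher_is_bad", "higher_is_good"):
            raise ConfigError(f"unknown direction {self.direction!r}")
        if self.magnitude < 0:
            raise ConfigError("effect magnitude must be >= 0")

    @property
    def sign(self) -> float:
        return -1.0 if self.direction == "higher_is_bad" else 1.0


def default_effects() -> list[EffectSpec]:
    """Default planted effects: directions seen in the study's tree relations,
    at modest magnitudes."""
    return [
        EffectSpec("amb_hum", "higher_is_bad", 0.8),
        EffectSpec("weight", "higher_is_bad", 0.5),
        EffectSpec("amb_temp", "higher_is_good", 0.5),
        EffectSpec("sbp", "higher_is_good", 0.4),
        EffectSpec("spo2", "higher_is_good", 0.5),
        EffectSpec("body_humidity", "higher_is_bad", 0.5),
        EffectSpec("qrs_duration", "higher_is_good", 0.3),
    ]


def default_missingness() -> dict[str, float]:
    """Missingness fractions shaped like the study profile: per-activity
    channel cells are the sparsest (>= 60 % missing once channel-day and
    channel-activity-day blanking combine), daily measurements the least."""
    frac = {
        "sbp": 0.10,
        "dbp": 0.10,
        "spo2": 0.12,
        "weight": 0.08,
        "amb_temp": 0.15,
        "amb_hum": 0.15,
        "body_humidity": 0.20,
        "body_temperature": 0.20,
        "pr_interval": 0.30,
        "qrs_duration": 0.30,
        "qt_interval": 0.30,
        "rr_interval": 0.15,
        "r_amplitude": 0.35,
        "t_amplitude": 0.35,
        "energy": 0.25,
    }
    for ch in (
        "body_humidity",
        "body_temperature",
        "pr_interval",
        "qrs_duration",
        "qt_interval",
        "rr_interval",
        "r_amplitude",
        "t_amplitude",
        "energy",
    ):
        for act in ACTIVITIES:
            frac[f"{ch}@{act}"] = 0.55
    return frac


@dataclass
class GeneratorConfig:
    n_patients: int = 24
    days_per_patient: int | tuple[int, int] = (10, 80)
    effects: list[EffectSpec] = field(default_factory=default_effects)
    label_marginals: tuple[float, ...] = STUDY_LABEL_MARGINALS
    missingness: dict[str, float] = field(default_factory=default_missingness)
    samples_per_day: int = 60
    sample_interval_s: float = 240.0
    noise_sd: float = 1.0
    start_date: dt.date = dt.date(2015, 1, 5)
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ConfigError("n_patients must be >= 1")
        m = np.asarray(self.label_marginals, dtype=float)
        if m.size != 5 or (m < 0).any() or not np.isclose(m.sum(), 1.0, atol=1e-6):
            raise ConfigError("label_marginals must be 5 non-negative values summing to 1")
        if m.max() == 0:
            raise ConfigError("label marginals have zero mass everywhere")
        for key, f in self.missingness.items():
            if not (0.0 <= f <= 1.0):
                raise ConfigError(f"missing fraction for {key!r} not in [0,1]")


@dataclass
class GroundTruth:
    """Latent wellbeing change per patient-day and the effects actually used."""

    latent_wellbeing: pd.Series  # indexed by (patient_id, date); NaN on first days
    planted_effects: list[EffectSpec]


_CHANNEL_SAMPLE_SD = {
    "body_humidity": 2.0,
    "body_temperature": 0.15,
    "pr_interval": 5.0,
    "qrs_duration": 3.0,
    "qt_interval": 8.0,
    "heart_rate": 4.0,
    "r_amplitude": 0.08,
    "t_amplitude": 0.04,
}


def generate_cohort(config: GeneratorConfig) -> tuple[Cohort, GroundTruth]:
    """Generate a cohort plus its ground truth, reproducibly from the seed."""
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))

    if isinstance(config.days_per_patient, int):
        days_per = [config.days_per_patient] * config.n_patients
    else:
        lo, hi = config.days_per_patient
        days_per = rng.integers(lo, hi + 1, size=config.n_patients).tolist()

    # --- daily parameter series per patient ---------------------------------
    series: dict[str, dict[str, np.ndarray]] = {}
    for p in range(config.n_patients):
        pid = f"P{p + 1:02d}"
        n = days_per[p]
        per_param: dict[str, np.ndarray] = {}
        for name in _PARAMS:
            lo, hi = PARAM_RANGES[name]
            width = hi - lo
            baseline = rng.uniform(lo + 0.2 * width, hi - 0.2 * width)
            sigma = INNOVATION_FRACTION * width
            x = np.empty(n)
            x[0] = baseline + rng.normal(0, sigma)
            for t in range(1, n):
                x[t] = baseline + AR1_PHI * (x[t - 1] - baseline) + rng.normal(0, sigma)
            per_param[name] = x
        # physiological consistency
        per_param["dbp"] = np.minimum(per_param["dbp"], per_param["sbp"] - 10.0)
        per_param["spo2"] = np.clip(per_param["spo2"], 0.0, 100.0)
        per_param["amb_hum"] = np.clip(per_param["amb_hum"], 0.0, 100.0)
        per_param["body_humidity"] = np.clip(per_param["body_humidity"], 0.0, 100.0)
        per_param["energy"] = np.maximum(per_param["energy"], 0.2)
        series[pid] = per_param

    # --- latent wellbeing change from standardized day-to-day changes -------
    diffs: dict[str, dict[str, np.ndarray]] = {
        pid: {name: np.diff(per[name]) for name in _PARAMS} for pid, per in series.items()
    }
    zstats: dict[str, tuple[float, float]] = {}
    for name in _PARAMS:
        pooled = np.concatenate([diffs[pid][name] for pid in diffs]) if diffs else np.array([0.0])
        sd = pooled.std(ddof=0) if pooled.size else 1.0
        zstats[name] = (pooled.mean() if pooled.size else 0.0, sd if sd > 0 else 1.0)

    latent: dict[str, np.ndarray] = {}
    for pid in series:
        n = len(next(iter(series[pid].values())))
        w = np.full(n, np.nan)
        noise = rng.normal(0.0, config.noise_sd, size=max(n - 1, 0))
        for t in range(1, n):
            acc = 0.0
            for e in config.effects:
                mu, sd = zstats[e.feature_name]
                z = (diffs[pid][e.feature_name][t - 1] - mu) / sd
                acc += e.sign * e.magnitude * z
            w[t] = acc + noise[t - 1]
        latent[pid] = w

    # --- ordinal labels by quantile matching --------------------------------
    all_w = np.concatenate([latent[pid][1:] for pid in latent if len(latent[pid]) > 1])
    marg = np.asarray(config.label_marginals, dtype=float)
    cuts = np.quantile(all_w, np.cumsum(marg)[:-1]) if all_w.size else np.zeros(4)
    labels: dict[str, np.ndarray] = {}
    for pid, w in latent.items():
        lab = np.full(len(w), 0, dtype=int)
        defined = ~np.isnan(w)
        lab[defined] = np.searchsorted(cuts, w[defined], side="left") + 1
        labels[pid] = lab

    # --- assemble patient-days with sensor streams --------------------------
    acts = np.array(ACTIVITIES)
    patient_days: list[PatientDay] = []
    truth_rows: list[tuple[str, dt.date, float]] = []
    for p in range(config.n_patients):
        pid = f"P{p + 1:02d}"
        n = days_per[p]
        start = config.start_date + dt.timedelta(days=int(rng.integers(0, 10)))
        per = series[pid]
        for t in range(n):
            date = start + dt.timedelta(days=t)
            daily = DailyMeasurements(
                sbp=float(per["sbp"][t]),
                dbp=float(per["dbp"][t]),
                spo2=float(per["spo2"][t]),
                weight=float(per["weight"][t]),
                amb_temp=float(per["amb_temp"][t]),
                amb_hum=float(per["amb_hum"][t]),
            )
            samples = []
            k = config.samples_per_day
            if k > 0:
                act_idx = rng.choice(3, size=k, p=_ACTIVITY_PROBS)
                t0 = 8 * 3600.0
                for j in range(k):
                    act = str(acts[act_idx[j]])
                    hr = (
                        per["heart_rate"][t]
                        + _HR_ACTIVITY_OFFSET[act]
                        + rng.normal(0, _CHANNEL_SAMPLE_SD["heart_rate"])
                    )
                    hr = max(hr, 30.0)
                    energy = max(
                        per["energy"][t] * _ENERGY_ACTIVITY_LEVEL[act]
                        + rng.normal(0, 0.15),
                        0.05,
                    )
                    samples.append(
                        SensorSample(
                            timestamp=t0 + j * config.sample_interval_s,
                            body_humidity=float(
                                np.clip(
                                    per["body_humidity"][t]
                                    + rng.normal(0, _CHANNEL_SAMPLE_SD["body_humidity"]),
                                    0.0,
                                    100.0,
                                )
                            ),
                            body_temperature=float(
                                per["body_temperature"][t]
                                + (0.2 if act == "moving" else 0.0)
                                + rng.normal(0, _CHANNEL_SAMPLE_SD["body_temperature"])
                            ),
                            pr_interval=float(
                                per["pr_interval"][t]
                                + rng.normal(0, _CHANNEL_SAMPLE_SD["pr_interval"])
                            ),
                            qrs_duration=float(
                                per["qrs_duration"][t]
                                + rng.normal(0, _CHANNEL_SAMPLE_SD["qrs_duration"])
                            ),
                            qt_interval=float(
                                per["qt_interval"][t]
                                + rng.normal(0, _CHANNEL_SAMPLE_SD["qt_interval"])
                            ),
                            rr_interval=float(60000.0 / hr),
                            r_amplitude=float(
                                per["r_amplitude"][t]
                                + rng.normal(0, _CHANNEL_SAMPLE_SD["r_amplitude"])
                            ),
                            t_amplitude=float(
                                per["t_amplitude"][t]
                                + rng.normal(0, _CHANNEL_SAMPLE_SD["t_amplitude"])
                            ),
                            activity=act,
                            energy=float(energy),
                        )
                    )
            pro = int(labels[pid][t]) if labels[pid][t] > 0 else None
            patient_days.append(
                PatientDay(patient_id=pid, date=date, daily=daily, samples=samples, pro=pro)
            )
            truth_rows.append((pid, date, float(latent[pid][t])))

    cohort = Cohort(patient_days).sorted()
    idx = pd.MultiIndex.from_tuples(
        [(r[0], r[1]) for r in sorted(truth_rows)], names=["patient_id", "date"]
    )
    truth = GroundTruth(
        latent_wellbeing=pd.Series(
            [r[2] for r in sorted(truth_rows)], index=idx, name="latent_wellbeing"
        ),
        planted_effects=list(config.effects),
    )
    cohort = apply_missingness(cohort, config.missingness, seed=config.seed + 1)
    return cohort, truth


def apply_missingness(
    cohort: Cohort, missingness: dict[str, float], seed: int
) -> Cohort:
    """Blank targeted cells completely at random at the configured fractions.

    Keys are daily measurement names (per-day cell), sensor channel names
    (all of the channel's samples that day), ``channel@activity`` (the
    channel's samples during one activity that day), or ``pro``.
    """
    channel_names = {
        "body_humidity",
        "body_temperature",
        "pr_interval",
        "qrs_duration",
        "qt_interval",
        "rr_interval",
        "r_amplitude",
        "t_amplitude",
        "energy",
    }
    for key in missingness:
        base, _, act = key.partition("@")
        if act and (base not in channel_names or act not in ACTIVITIES):
            raise ConfigError(f"unknown missingness target {key!r}")
        if not act and base not in set(DAILY_FIELDS) | channel_names | {"pro"}:
            raise ConfigError(f"unknown missingness target {key!r}")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    out = cohort.copy().sorted()
    items = sorted(missingness.items())
    for day in out.patient_days:
        for key, frac in items:
            if frac <= 0.0:
                continue
            hit = rng.random() < frac
            if not hit:
                continue
            base, _, act = key.partition("@")
            if key == "pro":
                day.pro = None
            elif base in DAILY_FIELDS and not act:
                setattr(day.daily, base, None)
            else:
                for s in day.samples:
                    if act and s.activity != act:
                        continue
                    setattr(s, base, None)
    return out
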