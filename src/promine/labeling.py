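"""Binary good/bad day labeling from ordinal PRO sequences.

The daily PRO is an ordinal self-rating relative to the previous day
(1 = much worse ... 5 = much better). For mining, days are collapsed to two
classes: a day rated 1 is always *bad* and a day rated 5 is always *good*;
the nine catalog definitions differ in when the weaker ratings 2 and 4 also
qualify — either always, or only when enough of the last n calendar days
(including the day itself) carried a worse/better rating, optionally
requiring a consecutive run. Days rated 3, unrated days, and days failing
the window rule are excluded from mining.

Windows are backward-looking in calendar days and end at the day being
classified, which itself must carry the weaker rating (2 resp. 4) for a
windowed assignment. Days without a qualifying label — unrated, out of the
observation range, or rated outside the set — count as not-in-set; with
``require_full_window=True`` a window reaching before the patient's first
observed day never qualifies.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import pandas as pd

from .cohort import Cohort
from .errors import ConfigError
from .features import FeatureTable

BAD, GOOD, EXCLUDED = "bad", "good", "excluded"


@dataclass(frozen=True)
class WindowRule:
    """Require ``k`` of the last ``n`` calendar days in the qualifying set
    (all ``n``, when ``consecutive``)."""

    k: int
    n: int
    consecutive: bool = False

    def __post_init__(self):
        if not (1 <= self.k <= self.n):
            raise ConfigError(f"window rule requires 1 <= k <= n, got k={self.k}, n={self.n}")
        if self.consecutive and self.k != self.n:
            raise ConfigError("consecutive window rule requires k == n")


@dataclass(frozen=True)
class ClassDefinition:
    """One catalog rule mapping PRO sequences to bad/good/excluded days."""

    name: str
    window_rule: WindowRule | None = None
    bad_core: frozenset = frozenset({1})
    good_core: frozenset = frozenset({5})
    bad_window_set: frozenset = frozenset({1, 2})
    good_window_set: frozenset = frozenset({4, 5})


def definition_catalog() -> list[ClassDefinition]:
    """The nine named class definitions, strictest to loosest window rules."""
    return [
        ClassDefinition("1 vs. 5"),
        ClassDefinition("1, 2 vs. 4, 5", WindowRule(1, 1)),
        ClassDefinition("1, 2 x (2/3) vs. 4 x (2/3), 5", WindowRule(2, 3)),
        ClassDefinition("1, 2 x (2/4) vs. 4 x (2/4), 5", WindowRule(2, 4)),
        ClassDefinition("1, 2 x (2/5) vs. 4 x (2/5), 5", WindowRule(2, 5)),
        ClassDefinition("1, 2 x (3/4) vs. 4 x (3/4), 5", WindowRule(3, 4)),
        ClassDefinition("1, 2 x (3/5) vs. 4 x (3/5), 5", WindowRule(3, 5)),
        ClassDefinition("1, 2 x 2 vs. 4 x 2, 5", WindowRule(2, 2, consecutive=True)),
        ClassDefinition("1, 2 x 3 vs. 4 x 3, 5", WindowRule(3, 3, consecutive=True)),
    ]


def get_definition(name: str) -> ClassDefinition:
    for d in definition_catalog():
        if d.name == name:
            return d
    raise ConfigError(f"unknown class definition {name!r}")


def _window_satisfied(
    labels: dict[dt.date, int | None],
    day: dt.date,
    rule: WindowRule,
    in_set: frozenset,
    first_day: dt.date,
    require_full_window: bool,
) -> bool:
    if require_full_window and (day - dt.timedelta(days=rule.n - 1)) < first_day:
        return False
    hits = 0
    for back in range(rule.n):
        lbl = labels.get(day - dt.timedelta(days=back))
        if lbl in in_set:
            hits += 1
        elif rule.consecutive:
            return False
    return hits >= rule.k


def assign_classes(
    pro_sequence: dict[dt.date, int | None],
    definition: ClassDefinition,
    require_full_window: bool = False,
) -> dict[dt.date, str]:
    """Assign bad/good/excluded to each day of one patient's PRO sequence."""
    days = sorted(pro_sequence)
    if not days:
        return {}
    first = days[0]
    out: dict[dt.date, str] = {}
    rule = definition.window_rule
    for day in days:
        lbl = pro_sequence[day]
        cls = EXCLUDED
        if lbl in definition.bad_core:
            cls = BAD
        elif lbl in definition.good_core:
            cls = GOOD
        elif rule is not None and lbl is not None:
            if lbl in definition.bad_window_set and _window_satisfied(
                pro_sequence, day, rule, definition.bad_window_set, first, require_full_window
            ):
                cls = BAD
            elif lbl in definition.good_window_set and _window_satisfied(
                pro_sequence, day, rule, definition.good_window_set, first, require_full_window
            ):
                cls = GOOD
        out[day] = cls
    return out


def assign_classes_cohort(
    cohort: Cohort, definition: ClassDefinition, require_full_window: bool = False
) -> pd.Series:
    """Per patient-day class assignments for a whole cohort, indexed by
    (patient_id, date)."""
    rows = {}
    for pid, seq in cohort.pro_sequences().items():
        for day, cls in assign_classes(seq, definition, require_full_window).items():
            rows[(pid, day)] = cls
    idx = pd.MultiIndex.from_tuples(sorted(rows), names=["patient_id", "date"])
    return pd.Series([rows[k] for k in idx], index=idx, name="class")


@dataclass
class LabeledDataset:
    """Feature rows restricted to bad/good days, with the class vector."""

    features: FeatureTable
    classes: pd.Series  # values in {"bad", "good"}
    definition: ClassDefinition

    @property
    def n_bad(self) -> int:
        return int((self.classes == BAD).sum())

    @property
    def n_good(self) -> int:
        return int((self.classes == GOOD).sum())

    def __len__(self) -> int:
        return len(self.classes)


def build_labeled_dataset(
    table: FeatureTable,
    cohort: Cohort,
    definition: ClassDefinition,
    require_full_window: bool = False,
) -> LabeledDataset:
    """Restrict a feature table to the days a definition assigns bad/good."""
    import logging

    assignments = assign_classes_cohort(cohort, definition, require_full_window)
    kept = assignments[assignments != EXCLUDED]
    kept = kept[kept.index.isin(table.df.index)]
    if kept.empty or (kept == BAD).sum() == 0 or (kept == GOOD).sum() == 0:
        logging.getLogger(__name__).warning(
            "definition %r yields an empty or one-class dataset", definition.name
        )
    features = FeatureTable(table.df.loc[kept.index].copy(), dict(table.provenance))
    return LabeledDataset(features, kept, definition)
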