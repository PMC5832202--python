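import datetime as dt

import numpy as np
import pytest

from promine.cohort import Cohort
from promine.errors import ConfigError
from promine.labeling import (
    BAD,
    EXCLUDED,
    GOOD,
    WindowRule,
    assign_classes,
    build_labeled_dataset,
    definition_catalog,
    get_definition,
)
from promine.features import build_feature_table

from conftest import make_day

D0 = dt.date(2021, 6, 1)


def seq(labels, gaps=None):
    """Dated sequence from a label list (None = unrated); gaps give day offsets."""
    if gaps is None:
        gaps = range(len(labels))
    return {D0 + dt.timedelta(days=g): l for g, l in zip(gaps, labels)}


def oracle_assign(labels: dict, definition) -> dict:
    """Independent exhaustive window checker."""
    out = {}
    rule = definition.window_rule
    for day, lbl in labels.items():
        cls = EXCLUDED
        if lbl == 1:
            cls = BAD
        elif lbl == 5:
            cls = GOOD
        elif rule is not None and lbl in (2, 4):
            want = {1, 2} if lbl == 2 else {4, 5}
            window = [labels.get(day - dt.timedelta(days=b)) for b in range(rule.n)]
            inside = [w in want for w in window]
            ok = all(inside) if rule.consecutive else sum(inside) >= rule.k
            if ok:
                cls = BAD if lbl == 2 else GOOD
        out[day] = cls
    return out


class TestCatalog:
    def test_exactly_nine_definitions_with_study_names(self):
        catalog = definition_catalog()
        assert len(catalog) == 9
        assert [d.name for d in catalog] == [
            "1 vs. 5",
            "1, 2 vs. 4, 5",
            "1, 2 x (2/3) vs. 4 x (2/3), 5",
            "1, 2 x (2/4) vs. 4 x (2/4), 5",
            "1, 2 x (2/5) vs. 4 x (2/5), 5",
            "1, 2 x (3/4) vs. 4 x (3/4), 5",
            "1, 2 x (3/5) vs. 4 x (3/5), 5",
            "1, 2 x 2 vs. 4 x 2, 5",
            "1, 2 x 3 vs. 4 x 3, 5",
        ]

    def test_core_only_definition_has_no_window(self):
        assert get_definition("1 vs. 5").window_rule is None

    def test_run_definitions_are_consecutive(self):
        d = get_definition("1, 2 x 2 vs. 4 x 2, 5")
        assert d.window_rule == WindowRule(2, 2, consecutive=True)
        d3 = get_definition("1, 2 x 3 vs. 4 x 3, 5")
        assert d3.window_rule == WindowRule(3, 3, consecutive=True)

    def test_unknown_name_rejected(self):
        with pytest.raises(ConfigError):
            get_definition("1 vs. 42")

    def test_invalid_window_rules_rejected(self):
        with pytest.raises(ConfigError):
            WindowRule(3, 2)
        with pytest.raises(ConfigError):
            WindowRule(1, 2, consecutive=True)


class TestAssignments:
    def test_core_labels_only(self):
        got = assign_classes(seq([3, 3, 5]), get_definition("1 vs. 5"))
        assert list(got.values()) == [EXCLUDED, EXCLUDED, GOOD]

    def test_all_same_yields_nothing(self):
        for d in definition_catalog():
            got = assign_classes(seq([3, 3, 3]), d)
            assert set(got.values()) == {EXCLUDED}

    def test_run_of_three_rule(self):
        got = assign_classes(seq([2, 2, 2, 3, 2]), get_definition("1, 2 x 3 vs. 4 x 3, 5"))
        assert [got[D0 + dt.timedelta(days=i)] for i in range(5)] == [
            EXCLUDED, EXCLUDED, BAD, EXCLUDED, EXCLUDED,
        ]

    def test_three_of_four_rule(self):
        got = assign_classes(seq([2, 2, 2, 3, 2]), get_definition("1, 2 x (3/4) vs. 4 x (3/4), 5"))
        assert [got[D0 + dt.timedelta(days=i)] for i in range(5)] == [
            EXCLUDED, EXCLUDED, BAD, EXCLUDED, BAD,
        ]

    def test_windows_count_calendar_days_not_rows(self):
        # labels 2 on days 0 and 4: a 2-of-3 window over calendar days fails
        got = assign_classes(seq([2, 2], gaps=[0, 4]), get_definition("1, 2 x (2/3) vs. 4 x (2/3), 5"))
        assert set(got.values()) == {EXCLUDED}

    def test_strict_history_switch(self):
        defn = get_definition("1, 2 x (3/4) vs. 4 x (3/4), 5")
        lenient = assign_classes(seq([2, 2, 2]), defn)
        strict = assign_classes(seq([2, 2, 2]), defn, require_full_window=True)
        assert lenient[D0 + dt.timedelta(days=2)] == BAD
        assert strict[D0 + dt.timedelta(days=2)] == EXCLUDED


def _random_sequences(n_seq=300, max_len=20, seed=0):
    rng = np.random.default_rng(seed)
    for _ in range(n_seq):
        length = int(rng.integers(1, max_len + 1))
        gaps = (np.cumsum(rng.integers(1, 4, size=length)) - 1).tolist()
        labels = [
            None if l == 0 else int(l)
            for l in rng.choice([0, 1, 2, 3, 4, 5], size=length,
                                p=[0.1, 0.1, 0.2, 0.2, 0.2, 0.2])
        ]
        yield seq(labels, gaps=gaps)


def test_oracle_equivalence_on_random_sequences():
    """Window assignments match an exhaustive reference on random sequences."""
    for labels in _random_sequences():
        for defn in definition_catalog():
            assert assign_classes(labels, defn) == oracle_assign(labels, defn), defn.name


def test_monotonicity_and_disjointness():
    loose_pairs = [
        ("1 vs. 5", "1, 2 vs. 4, 5"),
        ("1, 2 x (3/4) vs. 4 x (3/4), 5", "1, 2 x (2/4) vs. 4 x (2/4), 5"),
        ("1, 2 x (3/4) vs. 4 x (3/4), 5", "1, 2 x (3/5) vs. 4 x (3/5), 5"),
        ("1, 2 x (2/3) vs. 4 x (2/3), 5", "1, 2 x (2/5) vs. 4 x (2/5), 5"),
    ]
    for labels in _random_sequences(n_seq=150, seed=1):
        for defn in definition_catalog():
            got = assign_classes(labels, defn)
            assert not (set(v for v in got.values()) >= {BAD} and BAD == GOOD)
        for strict_name, loose_name in loose_pairs:
            strict = assign_classes(labels, get_definition(strict_name))
            loose = assign_classes(labels, get_definition(loose_name))
            for day, cls in strict.items():
                if cls != EXCLUDED:
                    assert loose[day] == cls, (strict_name, loose_name)


def test_build_labeled_dataset_counts(small_synth):
    cohort, _ = small_synth
    table = build_feature_table(cohort, include_cross_variants=False)
    for defn in definition_catalog():
        ds = build_labeled_dataset(table, cohort, defn)
        expected = {BAD: 0, GOOD: 0}
        for pid, labels in cohort.pro_sequences().items():
            for cls in oracle_assign(labels, defn).values():
                if cls != EXCLUDED:
                    expected[cls] += 1
        assert (ds.n_bad, ds.n_good) == (expected[BAD], expected[GOOD]), defn.name
        assert not (ds.classes == EXCLUDED).any()


def test_all_same_cohort_yields_empty_dataset():
    days = [make_day("A", D0 + dt.timedelta(days=i), pro=3, sbp=120.0, dbp=80.0)
            for i in range(5)]
    cohort = Cohort(days)
    table = build_feature_table(cohort)
    ds = build_labeled_dataset(table, cohort, get_definition("1, 2 vs. 4, 5"))
    assert len(ds) == 0


def test_study_marginal_counts_reproduce_core_definitions():
    """A cohort realizing the study's printed label counts (30/73/795/148/40)
    yields exactly 70 instances under '1 vs. 5' and 291 under '1, 2 vs. 4, 5'."""
    counts = {1: 30, 2: 73, 3: 795, 4: 148, 5: 40}
    labels = [l for l, c in counts.items() for _ in range(c)]
    rng = np.random.default_rng(0)
    rng.shuffle(labels)
    days, i = [], 0
    for p in range(24):
        for t in range(1086 // 24 + (1 if p < 1086 % 24 else 0)):
            days.append(make_day(f"P{p:02d}", D0 + dt.timedelta(days=t), pro=labels[i]))
            i += 1
    cohort = Cohort(days)
    table = build_feature_table(cohort)
    assert len(build_labeled_dataset(table, cohort, get_definition("1 vs. 5"))) == 70
    assert len(build_labeled_dataset(table, cohort, get_definition("1, 2 vs. 4, 5"))) == 291
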