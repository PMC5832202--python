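import itertools

import numpy as np
import pandas as pd
import pytest

from promine.errors import ConfigError, PromineError
from promine.evaluation import (
    CvScheme,
    auc_from_scores,
    evaluate_grid,
    make_classifier,
    repeated_cv,
    roc_auc,
    wilcoxon_compare,
)
from promine.labeling import LabeledDataset, get_definition

from conftest import table_from_array


def make_dataset(X, y, definition="1, 2 vs. 4, 5"):
    table = table_from_array(X)
    classes = pd.Series(np.asarray(y), index=table.df.index, name="class")
    return LabeledDataset(table, classes, get_definition(definition))


@pytest.fixture(scope="module")
def imbalanced_noise():
    rng = np.random.default_rng(0)
    y = np.array(["good"] * 73 + ["bad"] * 27)
    return make_dataset(rng.normal(size=(100, 5)), y)


class TestRepeatedCv:
    def test_majority_baseline_is_class_share(self, imbalanced_noise):
        cell = repeated_cv(imbalanced_noise, "majority", CvScheme(folds=10, repeats=3, seed=1))
        assert cell.mean_ca == pytest.approx(73.0)
        assert all(ca == pytest.approx(73.0) for ca in cell.ca_per_repeat)

    def test_threshold_separable_tree_is_perfect(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(80, 3))
        # wide margin around the class threshold so any fold's cut generalizes
        X[:, 1] = np.where(X[:, 1] > 0.2, X[:, 1] + 1.0, X[:, 1] - 1.0)
        y = np.where(X[:, 1] > 0.2, "bad", "good")
        cell = repeated_cv(make_dataset(X, y), "decision_tree", CvScheme(folds=10, repeats=2, seed=0))
        assert cell.mean_ca == pytest.approx(100.0)

    def test_fixed_seed_reproducible(self, imbalanced_noise):
        scheme = CvScheme(folds=5, repeats=3, seed=7)
        c1 = repeated_cv(imbalanced_noise, "random_forest", scheme)
        c2 = repeated_cv(imbalanced_noise, "random_forest", scheme)
        assert c1.ca_per_repeat == c2.ca_per_repeat

    def test_single_class_rejected(self):
        X = np.zeros((20, 2))
        with pytest.raises(PromineError):
            repeated_cv(make_dataset(X, ["good"] * 20), "majority", CvScheme(folds=2, repeats=1))

    def test_small_minority_reduces_folds(self):
        rng = np.random.default_rng(2)
        y = np.array(["bad"] * 4 + ["good"] * 46)
        cell = repeated_cv(
            make_dataset(rng.normal(size=(50, 3)), y), "majority",
            CvScheme(folds=10, repeats=1, seed=0),
        )
        assert cell.mean_ca == pytest.approx(92.0)

    def test_hyperparameters_recorded(self, imbalanced_noise):
        cell = repeated_cv(imbalanced_noise, "decision_tree", CvScheme(folds=5, repeats=1))
        assert "ccp_alpha" in cell.params

    def test_unknown_classifier(self):
        with pytest.raises(ConfigError):
            make_classifier("perceptron")


class TestRocAuc:
    def test_perfect_ranking_is_one(self):
        res = auc_from_scores(np.array([0, 0, 1, 1], bool), np.array([0.1, 0.2, 0.8, 0.9]))
        assert res.auc == pytest.approx(1.0)

    def test_agrees_with_pairwise_ranking_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            n = int(rng.integers(6, 30))
            is_pos = rng.random(n) < 0.5
            if is_pos.all() or not is_pos.any():
                continue
            scores = rng.choice([0.1, 0.25, 0.5, 0.7], size=n)  # ties included
            res = auc_from_scores(is_pos, scores)
            pos, neg = scores[is_pos], scores[~is_pos]
            wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
            assert res.auc == pytest.approx(wins / (len(pos) * len(neg)), abs=1e-9)

    def test_sign_reversal_flips_auc(self):
        rng = np.random.default_rng(5)
        is_pos = np.array([True] * 10 + [False] * 10)
        scores = rng.normal(size=20)
        a = auc_from_scores(is_pos, scores).auc
        b = auc_from_scores(is_pos, -scores).auc
        assert a + b == pytest.approx(1.0)

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(6)
        res = auc_from_scores(rng.random(2000) < 0.5, rng.normal(size=2000))
        assert 0.45 <= res.auc <= 0.55

    def test_classifier_roc_on_separable_data(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(60, 3))
        y = np.where(X[:, 0] > 0, "bad", "good")
        res = roc_auc(make_dataset(X, y), "random_forest", CvScheme(folds=5, repeats=1, seed=0))
        assert res.auc > 0.95

    def test_single_class_scores_error(self):
        with pytest.raises(PromineError):
            auc_from_scores(np.ones(5, bool), np.arange(5.0))


class TestWilcoxon:
    @staticmethod
    def _matrix(diffs):
        b = np.linspace(70, 80, len(diffs))
        return pd.DataFrame({"A": b + np.asarray(diffs, float), "B": b})

    def test_identical_vectors_p_one(self):
        res = wilcoxon_compare(self._matrix([0] * 6), [("A", "B")])[0]
        assert res.p_value == 1.0 and res.note == "all differences zero"

    def test_exact_one_sided_runs_enumeration_value(self):
        res = wilcoxon_compare(self._matrix([1, 2, 3, 4, 5, 6]), [("A", "B")])[0]
        assert res.p_value == pytest.approx(2 / 64)
        assert res.direction == "A"

    def test_sign_flip_enumeration_oracle(self):
        """Exact p matches brute-force enumeration over all sign assignments."""
        rng = np.random.default_rng(8)
        for _ in range(5):
            n = int(rng.integers(6, 12))
            d = np.round(rng.normal(0, 2, n), 2)
            d = np.where(d == 0, 0.5, d)
            while len(np.unique(np.abs(d))) < n:  # avoid rank ties for the oracle
                d = np.round(rng.normal(0, 2, n), 2)
                d = np.where(d == 0, 0.5, d)
            res = wilcoxon_compare(self._matrix(d), [("A", "B")])[0]
            ranks = pd.Series(np.abs(d)).rank().to_numpy()
            w_plus = ranks[d > 0].sum()
            dist = []
            for signs in itertools.product([0, 1], repeat=n):
                dist.append(sum(r for r, s in zip(ranks, signs) if s))
            dist = np.asarray(dist)
            w = min(w_plus, n * (n + 1) / 2 - w_plus)
            p = 2 * min((dist <= w).mean(), 1.0)
            p = min(p, 1.0)
            assert res.p_value == pytest.approx(p, abs=1e-12)

    def test_swapping_pair_keeps_p(self):
        m = self._matrix([1, -2, 3, 4, -5, 6])
        r1 = wilcoxon_compare(m, [("A", "B")])[0]
        r2 = wilcoxon_compare(m[["B", "A"]], [("B", "A")])[0]
        assert r1.p_value == pytest.approx(r2.p_value)
        assert r1.direction == r2.direction == "A"

    def test_short_vectors_rejected(self):
        with pytest.raises(ConfigError):
            wilcoxon_compare(self._matrix([1, 2, 3]), [("A", "B")])


class TestGrid:
    def test_cardinality_and_majority_cells(self, small_synth, small_table):
        cohort, _ = small_synth
        grid = evaluate_grid(
            small_table,
            cohort,
            subsets=["No_activities_avg_and_std_dev", "Expert_selection"],
            imputations=["none", "mean"],
            definitions=["1, 2 vs. 4, 5"],
            classifiers=["majority", "decision_tree"],
            scheme=CvScheme(folds=5, repeats=1, seed=0),
        )
        assert len(grid.cells) == 8
        ok = [c for c in grid.cells if c.error is None]
        assert len(ok) == 8
        from promine.labeling import build_labeled_dataset, get_definition

        ds = build_labeled_dataset(small_table, cohort, get_definition("1, 2 vs. 4, 5"))
        maj = 100 * max(ds.n_bad, ds.n_good) / len(ds)
        for cell in ok:
            if cell.classifier == "majority":
                assert cell.mean_ca == pytest.approx(maj)

    def test_pivot_equals_recomputed_mean(self, small_synth, small_table):
        cohort, _ = small_synth
        grid = evaluate_grid(
            small_table, cohort,
            subsets=["Expert_selection"], imputations=["none"],
            definitions=["1, 2 vs. 4, 5", "1 vs. 5"],
            classifiers=["majority", "naive_bayes"],
            scheme=CvScheme(folds=3, repeats=1, seed=0),
        )
        pivot = grid.pivot_by_classifier()
        frame = grid.to_frame()
        for clf in ("majority", "naive_bayes"):
            expected = frame[frame.classifier == clf]["mean_ca"].mean()
            assert pivot[clf] == pytest.approx(expected)

    def test_failures_recorded_not_raised(self, small_synth, small_table):
        cohort, _ = small_synth
        grid = evaluate_grid(
            small_table, cohort,
            subsets=["Expert_selection"], imputations=["none"],
            definitions=["1 vs. 5"], classifiers=["majority"],
            scheme=CvScheme(folds=50, repeats=1, seed=0),  # more folds than instances
        )
        assert len(grid.cells) == 1
        assert grid.cells[0].error is not None
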