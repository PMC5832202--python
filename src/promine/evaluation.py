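"""Classifier evaluation: repeated stratified cross-validation, ROC/AUC,
the full comparison grid, and Wilcoxon signed-rank classifier comparisons.

Five classifiers are available behind short names — random_forest,
decision_tree, naive_bayes, svm_smo (a linear-kernel SVM), and the majority
baseline — instantiated from scikit-learn with frozen default
hyperparameters that are recorded into every evaluation cell. Accuracy for
one repeat pools held-out predictions over the folds of that repeat; the
reported CA is the mean over repeats, in percent.

Cells reaching a classifier with residual missing values are mean-filled
from the training fold only (a minimal shim: the standard classifiers do
not accept missing values). When an imputation method is evaluated
fold-safely, the training fold is imputed with the method and held-out rows
receive training-fold column means; the global mode instead imputes
the whole table up front, which leaks across folds but mirrors the original
experimental setup.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import clone
from sklearn.dummy import DummyClassifier
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_curve
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .errors import ConfigError, PromineError
from .imputation import impute
from .labeling import LabeledDataset

logger = logging.getLogger(__name__)

CLASSIFIER_NAMES = ("random_forest", "decision_tree", "naive_bayes", "svm_smo", "majority")


def make_classifier(name: str, seed: int = 0):
    if name == "random_forest":
        return RandomForestClassifier(n_estimators=100, random_state=seed, n_jobs=1)
    if name == "decision_tree":
        # pruned CART, approximating the pruned-C4.5 defaults of the
        # original toolkit family (an unpruned tree memorizes noise)
        return DecisionTreeClassifier(min_samples_leaf=2, ccp_alpha=0.01, random_state=seed)
    if name == "naive_bayes":
        return GaussianNB()
    if name == "svm_smo":
        # linear SVM on standardized inputs (the classical SMO-trained
        # classifier normalizes its inputs by default)
        return make_pipeline(StandardScaler(), SVC(kernel="linear", C=1.0, random_state=seed))
    if name == "majority":
        return DummyClassifier(strategy="most_frequent")
    raise ConfigError(f"unknown classifier {name!r}")


@dataclass
class CvScheme:
    folds: int = 10
    repeats: int = 30
    stratified: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.folds < 2 or self.repeats < 1:
            raise ConfigError("CvScheme requires folds >= 2 and repeats >= 1")

    def split_seed(self, repeat: int) -> int:
        return int(np.random.SeedSequence((self.seed, repeat)).generate_state(1)[0] % 2**31)


@dataclass
class EvaluationCell:
    classifier: str
    subset: str = ""
    imputation: str = "none"
    definition: str = ""
    mean_ca: float = np.nan  # percent
    ca_per_repeat: list[float] = field(default_factory=list)
    params: dict = field(default_factory=dict)
    auc: float | None = None
    error: str | None = None


def _splitter(scheme: CvScheme, y: np.ndarray, repeat: int):
    folds = scheme.folds
    if scheme.stratified:
        counts = pd.Series(y).value_counts()
        if counts.min() < folds:
            folds = max(2, int(counts.min()))
            logger.warning(
                "reducing folds from %d to %d: smallest class has %d instances",
                scheme.folds, folds, int(counts.min()),
            )
        return StratifiedKFold(n_splits=folds, shuffle=True, random_state=scheme.split_seed(repeat))
    return KFold(n_splits=folds, shuffle=True, random_state=scheme.split_seed(repeat))


def _fold_fill(train_X: np.ndarray, test_X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean-fill residual missing cells using training-fold statistics only."""
    with np.errstate(invalid="ignore"):
        means = np.nanmean(train_X, axis=0)
    means = np.where(np.isfinite(means), means, 0.0)
    tr = np.where(np.isnan(train_X), means, train_X)
    te = np.where(np.isnan(test_X), means, test_X)
    return tr, te


def _fold_impute(
    features, train_idx: np.ndarray, test_idx: np.ndarray, imputation: str, kwargs: dict
) -> tuple[np.ndarray, np.ndarray]:
    from .features import FeatureTable

    if imputation == "none":
        X = features.df.to_numpy(dtype=float)
        return _fold_fill(X[train_idx], X[test_idx])
    sub = FeatureTable(features.df.iloc[train_idx].copy(), dict(features.provenance))
    imputed, _ = impute(sub, imputation, **kwargs)
    tr = imputed.df.to_numpy(dtype=float)
    te = features.df.iloc[test_idx].to_numpy(dtype=float)
    return _fold_fill(tr, te)


def repeated_cv(
    dataset: LabeledDataset,
    classifier: str,
    scheme: CvScheme,
    imputation: str = "none",
    imputation_kwargs: dict | None = None,
) -> EvaluationCell:
    """Repeated stratified k-fold CV accuracy of one classifier.

    ``imputation`` other than "none" is applied fold-safely (see module
    docstring); pre-imputed tables should pass "none" here.
    """
    y = dataset.classes.to_numpy()
    if len(np.unique(y)) < 2:
        raise PromineError("repeated_cv requires both classes present")
    if len(y) < scheme.folds:
        raise PromineError("fewer instances than folds")
    est = make_classifier(classifier, seed=scheme.seed)
    cell = EvaluationCell(
        classifier=classifier,
        imputation=imputation,
        definition=dataset.definition.name,
        params={k: repr(v) for k, v in est.get_params().items()},
    )
    cas = []
    for r in range(scheme.repeats):
        correct = 0
        for train_idx, test_idx in _splitter(scheme, y, r).split(np.zeros(len(y)), y):
            tr, te = _fold_impute(
                dataset.features, train_idx, test_idx, imputation, imputation_kwargs or {}
            )
            model = clone(est)
            model.fit(tr, y[train_idx])
            correct += int((model.predict(te) == y[test_idx]).sum())
        cas.append(100.0 * correct / len(y))
    cell.ca_per_repeat = cas
    cell.mean_ca = float(np.mean(cas))
    return cell


@dataclass
class RocResult:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def auc_from_scores(is_positive: np.ndarray, scores: np.ndarray) -> RocResult:
    """ROC points by threshold sweep and AUC by the trapezoid rule."""
    is_positive = np.asarray(is_positive, dtype=bool)
    if is_positive.all() or not is_positive.any():
        raise PromineError("ROC needs both positive and negative scores")
    fpr, tpr, _ = roc_curve(is_positive, np.asarray(scores, dtype=float))
    return RocResult(fpr, tpr, float(np.trapezoid(tpr, fpr)))


def roc_auc(
    dataset: LabeledDataset,
    classifier: str,
    scheme: CvScheme,
    positive: str = "bad",
    imputation: str = "none",
) -> RocResult:
    """ROC curve and trapezoid AUC from held-out scores pooled over the folds
    of one repeat."""
    y = dataset.classes.to_numpy()
    if len(np.unique(y)) < 2:
        raise PromineError("ROC requires both classes present")
    est = make_classifier(classifier, seed=scheme.seed)
    scores = np.empty(len(y))
    for train_idx, test_idx in _splitter(scheme, y, 0).split(np.zeros(len(y)), y):
        tr, te = _fold_impute(dataset.features, train_idx, test_idx, imputation, {})
        model = clone(est)
        model.fit(tr, y[train_idx])
        if hasattr(model, "predict_proba"):
            pos = list(model.classes_).index(positive)
            scores[test_idx] = model.predict_proba(te)[:, pos]
        elif hasattr(model, "decision_function"):
            s = model.decision_function(te)
            if model.classes_[1] != positive:
                s = -s
            scores[test_idx] = s
        else:
            raise PromineError(f"classifier {classifier!r} yields no scores")
    return auc_from_scores(y == positive, scores)


# ---------------------------------------------------------------------------
# grid


@dataclass
class GridResult:
    cells: list[EvaluationCell]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "classifier": c.classifier,
                    "subset": c.subset,
                    "imputation": c.imputation,
                    "definition": c.definition,
                    "mean_ca": c.mean_ca,
                    "error": c.error,
                }
                for c in self.cells
            ]
        )

    def _pivot(self, index: str) -> pd.DataFrame:
        df = self.to_frame()
        df = df[df["error"].isna()]
        return df.pivot_table(index=index, columns="classifier", values="mean_ca", aggfunc="mean")

    def pivot_by_classifier(self) -> pd.Series:
        df = self.to_frame()
        return df[df["error"].isna()].groupby("classifier")["mean_ca"].mean()

    def pivot_by_imputation(self) -> pd.DataFrame:
        return self._pivot("imputation")

    def pivot_by_subset(self) -> pd.DataFrame:
        return self._pivot("subset")

    def pivot_by_definition(self) -> pd.DataFrame:
        return self._pivot("definition")


def evaluate_grid(
    table,
    cohort,
    subsets: list[str],
    imputations: list[str],
    definitions: list,
    classifiers: list[str],
    scheme: CvScheme,
    expert_list: list[str] | None = None,
    global_imputation: bool = False,
) -> GridResult:
    """Evaluate the full cartesian product of subsets x imputations x class
    definitions x classifiers; failures are recorded per cell and the grid
    continues."""
    from .features import FeatureTable
    from .labeling import ClassDefinition, build_labeled_dataset, get_definition
    from .subsets import resolve_subset

    cells: list[EvaluationCell] = []
    for defn in definitions:
        if not isinstance(defn, ClassDefinition):
            defn = get_definition(defn)
        ds = build_labeled_dataset(table, cohort, defn)
        for subset_name in subsets:
            try:
                spec = resolve_subset(
                    subset_name, ds.features, classes=ds.classes, expert_list=expert_list
                )
            except Exception as exc:  # record and continue
                for imp in imputations:
                    for clf in classifiers:
                        cells.append(
                            EvaluationCell(
                                clf, subset_name, imp, defn.name, error=str(exc)
                            )
                        )
                continue
            sub_features = ds.features.select(spec.columns)
            for imp in imputations:
                if global_imputation and imp != "none":
                    feats, _ = impute(sub_features, imp)
                    fold_imp = "none"
                else:
                    feats, fold_imp = sub_features, imp
                sub_ds = LabeledDataset(feats, ds.classes, defn)
                for clf in classifiers:
                    try:
                        cell = repeated_cv(sub_ds, clf, scheme, imputation=fold_imp)
                        cell.subset = subset_name
                        cell.imputation = imp
                    except Exception as exc:
                        cell = EvaluationCell(clf, subset_name, imp, defn.name, error=str(exc))
                        logger.warning("grid cell failed: %s", exc)
                    cells.append(cell)
    return GridResult(cells)


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank comparison


@dataclass
class ComparisonResult:
    pair: tuple[str, str]
    statistic: float
    p_value: float
    direction: str  # which member had higher accuracies on average
    n: int
    note: str | None = None


def wilcoxon_compare(
    accuracy_matrix: pd.DataFrame, pairs: list[tuple[str, str]]
) -> list[ComparisonResult]:
    """Two-sided Wilcoxon signed-rank tests on paired per-subset accuracies.

    ``accuracy_matrix`` has one row per data subset and one column per
    classifier. Zero differences are dropped; the exact null distribution is
    used for n <= 25 pairs, the normal approximation with continuity
    correction above.
    """
    out: list[ComparisonResult] = []
    for a, b in pairs:
        x = accuracy_matrix[a].to_numpy(dtype=float)
        z = accuracy_matrix[b].to_numpy(dtype=float)
        ok = ~np.isnan(x) & ~np.isnan(z)
        x, z = x[ok], z[ok]
        if len(x) < 5:
            raise ConfigError("wilcoxon_compare requires paired vectors of length >= 5")
        d = x - z
        nz = d[d != 0]
        direction = a if d.mean() > 0 else (b if d.mean() < 0 else "tie")
        if nz.size == 0:
            out.append(ComparisonResult((a, b), 0.0, 1.0, "tie", 0, "all differences zero"))
            continue
        method = "exact" if nz.size <= 25 else "approx"
        try:
            res = stats.wilcoxon(
                x, z, zero_method="wilcox", correction=True, method=method,
                alternative="two-sided",
            )
        except ValueError:
            res = stats.wilcoxon(
                x, z, zero_method="wilcox", correction=True, method="approx",
                alternative="two-sided",
            )
        out.append(
            ComparisonResult((a, b), float(res.statistic), float(res.pvalue), direction, int(nz.size))
        )
    return out
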