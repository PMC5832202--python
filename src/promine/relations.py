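"""Interpretable relation mining from decision trees, and the
class-separation density analysis.

Each internal node of a fitted decision tree is a statement "feature f at
cut-off c": comparing the bad-class proportion of the below-threshold
subtree with the above-threshold subtree assigns a direction (small values
good and large bad, or the reverse). Relations from several trees (one per
feature subset) are merged by underlying monitored parameter and direction,
with occurrence counts and the observed cut-off range — the interpretable
catalog a clinician can annotate (correct / wrong / novel / unrelated /
unknown; the annotation is expert input, never computed).

The separation analysis asks whether good/bad days really differ from
feeling-the-same days: features are z-scored, and the mean absolute
standardized difference over mutually observed features is computed for
every pair of feeling-same days (within-population) and every
(feeling-same, good-or-bad) pair (between-population); both difference
populations are binned into ten shared bins and normalized to unit area.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

from .errors import PromineError
from .features import FeatureTable, infer_provenance
from .labeling import BAD, GOOD, ClassDefinition, assign_classes

logger = logging.getLogger(__name__)

SMALL_GOOD_LARGE_BAD = "small_good_large_bad"
SMALL_BAD_LARGE_GOOD = "small_bad_large_good"


@dataclass
class Relation:
    """One mined tree statement: a feature, a direction, a cut-off."""

    feature: str
    direction: str
    cutoff: float
    subset: str = ""


def _node_class_proportion(value_row: np.ndarray, cls_idx: int) -> float:
    v = np.asarray(value_row, dtype=float).ravel()
    total = v.sum()
    return float(v[cls_idx] / total) if total > 0 else np.nan


def extract_relations(
    tree: DecisionTreeClassifier, feature_names: list[str], subset: str = ""
) -> list[Relation]:
    """Extract one relation per informative internal node of a fitted tree.

    The direction compares the bad-class proportion of the two subtrees
    under the node's threshold split; nodes with equal proportions yield no
    relation.
    """
    if not hasattr(tree, "tree_"):
        raise PromineError("extract_relations requires a fitted decision tree")
    t = tree.tree_
    classes = list(tree.classes_)
    if BAD not in classes:
        raise PromineError("tree was not fitted on bad/good classes")
    bad_idx = classes.index(BAD)
    out: list[Relation] = []
    for node in range(t.node_count):
        left, right = t.children_left[node], t.children_right[node]
        if left == -1:
            continue
        p_left = _node_class_proportion(t.value[left], bad_idx)
        p_right = _node_class_proportion(t.value[right], bad_idx)
        if not (np.isfinite(p_left) and np.isfinite(p_right)) or p_left == p_right:
            continue
        direction = SMALL_GOOD_LARGE_BAD if p_left < p_right else SMALL_BAD_LARGE_GOOD
        out.append(
            Relation(
                feature=feature_names[t.feature[node]],
                direction=direction,
                cutoff=float(t.threshold[node]),
                subset=subset,
            )
        )
    return out


def _variant_tag(name: str) -> str:
    if name.endswith("_chg"):
        return "chg"
    if name.endswith("_pers"):
        return "pers"
    if "_std" in name:
        return "std"
    return "avg"


def aggregate_relations(
    relations: list[Relation], min_occurrences: int = 2
) -> pd.DataFrame:
    """Merge relations by (underlying parameter, direction).

    Returns a table with the parameter, the variant tags seen (avg / std /
    chg / pers), the direction, the cut-off range, and the total occurrence
    count, sorted by occurrences descending; groups below
    ``min_occurrences`` are dropped.
    """
    if not relations:
        return pd.DataFrame(
            columns=["parameter", "variants", "direction", "cutoff_min", "cutoff_max", "occurrences"]
        )
    prov = infer_provenance(sorted({r.feature for r in relations}))
    groups: dict[tuple[str, str], list[Relation]] = {}
    for r in relations:
        key = (prov[r.feature].source, r.direction)
        groups.setdefault(key, []).append(r)
    rows = []
    for (param, direction), rels in groups.items():
        if len(rels) < min_occurrences:
            continue
        cutoffs = [r.cutoff for r in rels]
        variants = sorted({_variant_tag(r.feature) for r in rels})
        rows.append(
            {
                "parameter": param,
                "variants": " and ".join(variants),
                "direction": direction,
                "cutoff_min": min(cutoffs),
                "cutoff_max": max(cutoffs),
                "occurrences": len(rels),
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(
            columns=["parameter", "variants", "direction", "cutoff_min", "cutoff_max", "occurrences"]
        )
    return df.sort_values(
        ["occurrences", "parameter", "direction"], ascending=[False, True, True]
    ).reset_index(drop=True)


def mine_relations(
    table: FeatureTable,
    cohort,
    definition: ClassDefinition,
    subset_names: list[str],
    expert_list: list[str] | None = None,
    min_occurrences: int = 2,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[Relation]]:
    """Fit one decision tree per named feature subset on the full labeled
    dataset and aggregate the mined relations."""
    from .evaluation import make_classifier
    from .labeling import build_labeled_dataset
    from .subsets import resolve_subset

    ds = build_labeled_dataset(table, cohort, definition)
    all_relations: list[Relation] = []
    for name in subset_names:
        spec = resolve_subset(name, ds.features, classes=ds.classes, expert_list=expert_list)
        sub = ds.features.select(spec.columns)
        X = sub.df.to_numpy(dtype=float)
        means = np.nanmean(np.where(np.isnan(X), np.nan, X), axis=0)
        means = np.where(np.isfinite(means), means, 0.0)
        X = np.where(np.isnan(X), means, X)
        # same pruned tree as the evaluation stage: the interpretable
        # classifier whose accuracy the grid reports is the one mined
        clf = make_classifier("decision_tree", seed=seed)
        clf.fit(X, ds.classes.to_numpy())
        all_relations.extend(extract_relations(clf, spec.columns, subset=name))
    return aggregate_relations(all_relations, min_occurrences), all_relations


# ---------------------------------------------------------------------------
# separation densities


@dataclass
class SeparationDensities:
    bin_edges: np.ndarray
    within_density: np.ndarray
    between_density: np.ndarray
    within_mean: float
    between_mean: float
    n_within_pairs: int
    n_between_pairs: int


def _pair_differences(Z: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray | None) -> np.ndarray:
    """Mean absolute standardized differences over mutually observed features
    for all pairs within idx_a (idx_b None) or across idx_a x idx_b."""
    diffs = []
    if idx_b is None:
        for pos, i in enumerate(idx_a[:-1]):
            rest = idx_a[pos + 1 :]
            with np.errstate(invalid="ignore"):
                d = np.abs(Z[rest] - Z[i])
            ok = ~np.isnan(d)
            cnt = ok.sum(axis=1)
            vals = np.where(cnt > 0, np.nansum(np.where(ok, d, 0.0), axis=1) / np.maximum(cnt, 1), np.nan)
            diffs.append(vals)
    else:
        for i in idx_a:
            with np.errstate(invalid="ignore"):
                d = np.abs(Z[idx_b] - Z[i])
            ok = ~np.isnan(d)
            cnt = ok.sum(axis=1)
            vals = np.where(cnt > 0, np.nansum(np.where(ok, d, 0.0), axis=1) / np.maximum(cnt, 1), np.nan)
            diffs.append(vals)
    if not diffs:
        return np.array([])
    out = np.concatenate(diffs)
    return out[~np.isnan(out)]


def separation_densities(
    table: FeatureTable,
    pro_labels: pd.Series,
    definition: ClassDefinition,
    bins: int = 10,
    max_pairs: int | None = 200_000,
    seed: int = 0,
) -> SeparationDensities:
    """Density histograms of mean standardized feature differences for
    (same, same) day pairs vs (same, good-or-bad) day pairs."""
    assignments: dict[tuple[str, dt.date], str] = {}
    for pid, grp in pro_labels.groupby(level="patient_id"):
        seq = {d: (None if pd.isna(v) else int(v)) for (_, d), v in grp.items()}
        for d, cls in assign_classes(seq, definition).items():
            assignments[(pid, d)] = cls

    index = table.df.index
    same_mask = np.array(
        [pro_labels.get(key, np.nan) == 3 for key in index], dtype=bool
    )
    gb_mask = np.array(
        [assignments.get(key) in (BAD, GOOD) for key in index], dtype=bool
    )
    same_idx = np.flatnonzero(same_mask)
    gb_idx = np.flatnonzero(gb_mask)
    if same_idx.size < 2 or gb_idx.size < 1:
        raise PromineError("separation analysis needs >=2 feeling-same days and >=1 good/bad day")

    included = np.concatenate([same_idx, gb_idx])
    X = table.df.to_numpy(dtype=float)
    sub = X[included]
    mu = np.nanmean(sub, axis=0)
    sd = np.nanstd(sub, axis=0)
    sd = np.where((sd == 0) | ~np.isfinite(sd), np.nan, sd)
    Z = (X - mu) / sd

    within = _pair_differences(Z, same_idx, None)
    between = _pair_differences(Z, same_idx, gb_idx)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    if max_pairs is not None:
        if within.size > max_pairs:
            within = rng.choice(within, size=max_pairs, replace=False)
        if between.size > max_pairs:
            between = rng.choice(between, size=max_pairs, replace=False)
    if within.size == 0 or between.size == 0:
        raise PromineError("no computable pair differences")

    pooled = np.concatenate([within, between])
    n_distinct = np.unique(pooled).size
    if n_distinct < bins:
        logger.warning("only %d distinct differences; using %d bins", n_distinct, n_distinct)
        bins = max(n_distinct, 1)
    edges = np.linspace(pooled.min(), pooled.max(), bins + 1)
    if edges[0] == edges[-1]:
        edges = np.array([edges[0] - 0.5, edges[0] + 0.5])
    within_density, _ = np.histogram(within, bins=edges, density=True)
    between_density, _ = np.histogram(between, bins=edges, density=True)
    return SeparationDensities(
        bin_edges=edges,
        within_density=within_density,
        between_density=between_density,
        within_mean=float(within.mean()),
        between_mean=float(between.mean()),
        n_within_pairs=int(within.size),
        n_between_pairs=int(between.size),
    )
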