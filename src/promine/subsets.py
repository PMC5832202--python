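"""Feature-subset selection.

Nine named subsets are supported: everything; CFS (correlation-based feature
subset selection by best-first search on the merit
``k * r_cf / sqrt(k + k(k-1) * r_ff)``); a configurable expert list;
activity-exclusion families; and sparsity thresholds that keep only columns
whose missing fraction is below a cut (defaults 0.17 and 0.27, chosen as
inputs, not detected). RelieF relevance scores are also implemented and
exposed, but no named subset consumes them by default.

Feature-class correlation is point-biserial (Pearson against a 0/1 class
encoding); feature-feature correlations are absolute Pearson on
pairwise-complete observations. Undefined correlations (constant columns,
fewer than 3 complete pairs) are treated as 0.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError
from .features import FeatureTable

logger = logging.getLogger(__name__)

SUBSET_NAMES = (
    "All",
    "CFS_feature_selection",
    "Expert_selection",
    "No_activities",
    "No_activities_avg_and_std_dev",
    "No_activities_personalised",
    "No_activities_changes",
    "No_sparse_features_0.17",
    "No_sparse_features_0.27",
)

#: Default expert list: clinically prominent parameters and their change /
#: personalized variants (blood pressure, SpO2, weight, ambient conditions,
#: sweating index, heart rate, QRS duration).
DEFAULT_EXPERT_FEATURES = [
    name + suffix
    for name in (
        "sbp",
        "dbp",
        "spo2",
        "weight",
        "amb_temp",
        "amb_hum",
        "humidity_ratio",
        "heart_rate_avg",
        "qrs_duration_avg",
    )
    for suffix in ("", "_chg", "_pers")
]


@dataclass
class FeatureSubsetSpec:
    """A named subset resolved to a concrete column list."""

    name: str
    columns: list[str]


def _encode_classes(classes) -> np.ndarray:
    y = np.asarray(classes)
    if y.dtype.kind in "OUS":
        y = (y == "bad").astype(float)
    return y.astype(float)


def _pearson_abs(a: np.ndarray, b: np.ndarray) -> float:
    ok = ~np.isnan(a) & ~np.isnan(b)
    if ok.sum() < 3:
        return 0.0
    x, z = a[ok], b[ok]
    sx, sz = x.std(), z.std()
    if sx == 0 or sz == 0:
        return 0.0
    return float(abs(np.mean((x - x.mean()) * (z - z.mean())) / (sx * sz)))


# ---------------------------------------------------------------------------
# RelieF


def relieff_scores(
    table: FeatureTable,
    classes,
    m: int | None = None,
    k_neighbors: int = 10,
    seed: int = 0,
) -> pd.Series:
    """RelieF relevance weights for binary classes.

    For each of ``m`` sampled instances the ``k_neighbors`` nearest same-class
    (hits) and different-class (misses) instances are found under a distance
    that averages absolute max-min-scaled differences over mutually observed
    features; weights increase with miss differences and decrease with hit
    differences. Features missing everywhere are excluded with a warning.
    """
    y = _encode_classes(classes)
    if min((y == 0).sum(), (y == 1).sum()) < 2:
        raise ConfigError("RelieF requires at least 2 instances per class")
    df = table.df
    all_missing = df.columns[df.isna().all()].tolist()
    if all_missing:
        logger.warning("RelieF: excluding all-missing features %s", all_missing)
    cols = [c for c in df.columns if c not in all_missing]
    X = df[cols].to_numpy(dtype=float)
    n, f = X.shape
    lo = np.nanmin(X, axis=0)
    rng_width = np.nanmax(X, axis=0) - lo
    rng_width[rng_width == 0] = 1.0
    Z = (X - lo) / rng_width
    obs = ~np.isnan(Z)

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    m = n if m is None else min(m, n)
    picks = rng.choice(n, size=m, replace=False) if m <= n else rng.choice(n, size=m)

    W = np.zeros(f)
    for i in picks:
        diff = np.abs(Z - Z[i])  # (n, f), nan where either missing
        shared = obs & obs[i]
        with np.errstate(invalid="ignore"):
            dist = np.where(
                shared.sum(axis=1) > 0,
                np.nansum(np.where(shared, diff, 0.0), axis=1)
                / np.maximum(shared.sum(axis=1), 1),
                np.inf,
            )
        dist[i] = np.inf
        same = y == y[i]
        for is_hit in (True, False):
            pool = np.flatnonzero(same if is_hit else ~same)
            pool = pool[np.isfinite(dist[pool])]
            if pool.size == 0:
                continue
            order = pool[np.lexsort((pool, dist[pool]))][:k_neighbors]
            contrib = np.nan_to_num(diff[order], nan=0.0).sum(axis=0) / (
                m * max(len(order), 1)
            )
            W += -contrib if is_hit else contrib
    return pd.Series(W, index=cols, name="relieff_weight")


# ---------------------------------------------------------------------------
# CFS


class _CorrelationCache:
    def __init__(self, X: np.ndarray, y: np.ndarray):
        self.X = X
        self.y = y
        self.rcf = np.array([_pearson_abs(X[:, j], y) for j in range(X.shape[1])])
        self._ff: dict[tuple[int, int], float] = {}

    def ff(self, i: int, j: int) -> float:
        key = (i, j) if i < j else (j, i)
        if key not in self._ff:
            self._ff[key] = _pearson_abs(self.X[:, key[0]], self.X[:, key[1]])
        return self._ff[key]


def cfs_merit(subset: tuple[int, ...], cache: _CorrelationCache) -> float:
    """CFS merit of a feature subset: k * mean feature-class correlation over
    sqrt(k + k(k-1) * mean feature-feature correlation)."""
    k = len(subset)
    if k == 0:
        return 0.0
    rcf = float(np.mean(cache.rcf[list(subset)]))
    if k == 1:
        return rcf
    pairs = [(a, b) for ai, a in enumerate(subset) for b in subset[ai + 1 :]]
    rff = float(np.mean([cache.ff(a, b) for a, b in pairs]))
    return k * rcf / np.sqrt(k + k * (k - 1) * rff)


def cfs_select(
    table: FeatureTable,
    classes,
    max_nonimproving: int = 5,
    name: str = "CFS_feature_selection",
) -> FeatureSubsetSpec:
    """Best-first CFS search, stopping after ``max_nonimproving`` consecutive
    expansions that fail to improve the best merit found."""
    df = table.df
    X = df.to_numpy(dtype=float)
    y = _encode_classes(classes)
    cache = _CorrelationCache(X, y)
    if np.all(cache.rcf == 0):
        raise ConfigError("CFS: all feature-class correlations are undefined")

    nf = X.shape[1]
    counter = 0
    heap: list[tuple[float, int, tuple[int, ...]]] = [(-0.0, counter, ())]
    visited = {()}
    best_merit, best_subset = -np.inf, ()
    stale = 0
    while heap and stale < max_nonimproving:
        neg_merit, _, subset = heapq.heappop(heap)
        merit = -neg_merit
        if merit > best_merit + 1e-10:
            best_merit, best_subset = merit, subset
            stale = 0
        else:
            stale += 1
        for j in range(nf):
            if j in subset:
                continue
            child = tuple(sorted(subset + (j,)))
            if child in visited:
                continue
            visited.add(child)
            counter += 1
            heapq.heappush(heap, (-cfs_merit(child, cache), counter, child))
    cols = [df.columns[j] for j in best_subset]
    return FeatureSubsetSpec(name, cols)


# ---------------------------------------------------------------------------
# named subsets


def missingness_profile(table: FeatureTable) -> pd.Series:
    """Per-feature missing fractions, sorted descending."""
    return table.missing_fraction().sort_values(ascending=False, kind="stable")


def plot_missingness_profile(profile: pd.Series, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 3))
    ax.plot(100 * profile.to_numpy(), lw=1)
    ax.set_xlabel("features sorted by missingness")
    ax.set_ylabel("% missing")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def resolve_subset(
    name: str,
    table: FeatureTable,
    classes=None,
    expert_list: list[str] | None = None,
    sparse_thresholds: dict[str, float] | None = None,
) -> FeatureSubsetSpec:
    """Resolve one of the nine named subsets to a concrete column list."""
    prov = table.provenance
    cols = list(table.df.columns)
    no_act = [c for c in cols if not prov[c].activity_related]
    thresholds = {"No_sparse_features_0.17": 0.17, "No_sparse_features_0.27": 0.27}
    if sparse_thresholds:
        thresholds.update(sparse_thresholds)

    if name == "All":
        return FeatureSubsetSpec(name, cols)
    if name == "CFS_feature_selection":
        if classes is None:
            raise ConfigError("CFS subset requires class labels")
        return cfs_select(table, classes)
    if name == "Expert_selection":
        wanted = expert_list if expert_list is not None else DEFAULT_EXPERT_FEATURES
        unknown = [c for c in wanted if c not in table.df.columns]
        if unknown:
            raise ConfigError(f"expert list names unknown columns: {unknown}")
        return FeatureSubsetSpec(name, list(wanted))
    if name == "No_activities":
        return FeatureSubsetSpec(name, no_act)
    if name == "No_activities_avg_and_std_dev":
        return FeatureSubsetSpec(name, [c for c in no_act if prov[c].kind == "base"])
    if name == "No_activities_personalised":
        return FeatureSubsetSpec(name, [c for c in no_act if prov[c].kind == "personalized"])
    if name == "No_activities_changes":
        return FeatureSubsetSpec(name, [c for c in no_act if prov[c].kind == "change"])
    if name in thresholds:
        tau = thresholds[name]
        frac = table.missing_fraction()
        return FeatureSubsetSpec(name, [c for c in cols if frac[c] < tau])
    raise ConfigError(f"unknown subset name {name!r}")
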