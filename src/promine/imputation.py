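"""Missing-value imputation: k-nearest-neighbour, chained-equations, and
SVD with expectation-maximization, plus a masking benchmark harness.

All methods leave observed cells bit-identical and only fill missing ones.
Columns observed nowhere cannot be imputed and are left missing with a
warning. Features are standardized (z-scored on observed cells) before
distance computation / decomposition by default; imputed values are
returned on the original scale. The SVD-EM total-change convergence
threshold (default 0.01) is measured on the working (standardized, unless
disabled) scale, summing absolute cell changes between successive
iterations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, PromineError
from .features import FeatureTable

logger = logging.getLogger(__name__)


@dataclass
class ImputationReport:
    method: str
    cells_imputed: int
    iterations: int = 0
    converged: bool = True
    rmse: float | None = None
    per_feature_rmse: pd.Series | None = None


@dataclass
class SvdImputeConfig:
    """Configuration of SVD-EM imputation.

    ``k`` is the number of leading eigengenes (right-singular vectors)
    retained; when None, the smallest k explaining at least ``energy`` of the
    squared singular-value mass is used, capped at ``k_cap``.
    """

    k: int | None = None
    tol: float = 0.01
    max_iter: int = 100
    standardize: bool = True
    energy: float = 0.90
    k_cap: int = 10

    def validate(self) -> None:
        if self.k is not None and self.k < 1:
            raise ConfigError("k must be >= 1")
        if self.tol <= 0:
            raise ConfigError("tol must be positive")


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = np.nanmean(X, axis=0)
    sd = np.nanstd(X, axis=0)
    sd = np.where((sd == 0) | ~np.isfinite(sd), 1.0, sd)
    mu = np.where(np.isfinite(mu), mu, 0.0)
    return (X - mu) / sd, mu, sd


def _imputable_columns(df: pd.DataFrame) -> list[str]:
    bad = df.columns[df.isna().all()].tolist()
    if bad:
        logger.warning("cannot impute all-missing columns %s; left missing", bad)
    return [c for c in df.columns if c not in bad]


def impute_knn(
    table: FeatureTable, k: int = 5, standardize: bool = True
) -> tuple[FeatureTable, ImputationReport]:
    """kNN imputation: row distance is the mean absolute difference over
    mutually observed (standardized) features; a missing cell becomes the
    mean of the k nearest rows that observe that feature (ties broken by row
    order)."""
    df = table.df
    cols = _imputable_columns(df)
    X = df[cols].to_numpy(dtype=float)
    n = X.shape[0]
    Z = _standardize(X)[0] if standardize else X
    obs = ~np.isnan(X)
    out = X.copy()
    imputed = 0
    for i in range(n):
        miss = np.flatnonzero(~obs[i])
        if miss.size == 0:
            continue
        shared = obs & obs[i]
        counts = shared.sum(axis=1)
        with np.errstate(invalid="ignore"):
            diff = np.abs(Z - Z[i])
        dist = np.where(
            counts > 0,
            np.nansum(np.where(shared, diff, 0.0), axis=1) / np.maximum(counts, 1),
            np.inf,
        )
        dist[i] = np.inf
        order = np.lexsort((np.arange(n), dist))
        order = order[np.isfinite(dist[order])]
        for j in miss:
            donors = order[obs[order, j]][:k]
            if donors.size:
                out[i, j] = X[donors, j].mean()
                imputed += 1
    new = df.copy()
    new[cols] = out
    return FeatureTable(new, dict(table.provenance)), ImputationReport("knn", imputed)


def impute_chained(
    table: FeatureTable, n_iter: int = 10, seed: int = 0, ridge: float = 1e-6
) -> tuple[FeatureTable, ImputationReport]:
    """Chained-equations (single) imputation.

    Missing cells start at column means and stay marked; each sweep
    re-estimates every marked cell by least-squares linear regression of its
    feature on all others, fitted on the rows where the target is observed.
    Deterministic: sweeps visit columns then rows in order (the seed is
    accepted for interface uniformity). Singular designs fall back to a
    small ridge penalty with a warning.
    """
    df = table.df
    cols = _imputable_columns(df)
    X = df[cols].to_numpy(dtype=float)
    mask = np.isnan(X)
    col_means = np.nanmean(X, axis=0)
    filled = np.where(mask, col_means, X)
    n, f = filled.shape
    for _ in range(n_iter):
        for j in range(f):
            rows = np.flatnonzero(mask[:, j])
            if rows.size == 0:
                continue
            train = ~mask[:, j]
            others = [c for c in range(f) if c != j]
            A = np.column_stack([np.ones(int(train.sum())), filled[train][:, others]])
            b = filled[train, j]
            if A.shape[0] < 2:
                continue
            sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
            if rank < A.shape[1]:
                logger.warning("chained imputation: singular design for column "
                               "%s; using ridge fallback", cols[j])
                G = A.T @ A + ridge * np.eye(A.shape[1])
                sol = np.linalg.solve(G, A.T @ b)
            Ap = np.column_stack([np.ones(rows.size), filled[rows][:, others]])
            filled[rows, j] = Ap @ sol
    new = df.copy()
    new[cols] = filled
    return (
        FeatureTable(new, dict(table.provenance)),
        ImputationReport("mice", int(mask.sum()), iterations=n_iter),
    )


def impute_svd(
    table: FeatureTable, config: SvdImputeConfig | None = None
) -> tuple[FeatureTable, ImputationReport]:
    """SVD imputation with expectation-maximization.

    Missing cells start at row averages; each iteration decomposes the
    working matrix, keeps the k leading eigengenes (rows of V^T), and
    re-estimates every missing cell (i, j) from a regression of row i on the
    eigengenes fitted without position j. Iteration stops when the total
    absolute change of the matrix falls below ``tol`` or at ``max_iter``.
    """
    config = config or SvdImputeConfig()
    config.validate()
    df = table.df
    cols = _imputable_columns(df)
    X = df[cols].to_numpy(dtype=float)
    mask = np.isnan(X)
    if not mask.any():
        new = df.copy()
        return FeatureTable(new, dict(table.provenance)), ImputationReport("svd", 0, 0)
    if np.all(np.isnan(X), axis=1).any():
        raise PromineError("SVD imputation requires at least one observed value per row")

    if config.standardize:
        Z, mu, sd = _standardize(X)
    else:
        Z, mu, sd = X.copy(), np.zeros(X.shape[1]), np.ones(X.shape[1])
    row_avg = np.nanmean(Z, axis=1)
    A = np.where(mask, row_avg[:, None], Z)

    iters = 0
    converged = False
    while iters < config.max_iter:
        iters += 1
        _, s, vt = np.linalg.svd(A, full_matrices=False)
        if config.k is not None:
            k = min(config.k, len(s))
        else:
            sq = s**2
            frac = np.cumsum(sq) / sq.sum() if sq.sum() > 0 else np.ones_like(sq)
            k = min(int(np.searchsorted(frac, config.energy) + 1), config.k_cap, len(s))
        G = vt[:k]  # (k, n_features)
        A_new = A.copy()
        for i in np.flatnonzero(mask.any(axis=1)):
            miss = np.flatnonzero(mask[i])
            for j in miss:
                use = np.ones(A.shape[1], dtype=bool)
                use[j] = False
                coef, *_ = np.linalg.lstsq(G[:, use].T, A[i, use], rcond=None)
                A_new[i, j] = coef @ G[:, j]
        change = float(np.abs(A_new - A).sum())
        A = A_new
        if change < config.tol:
            converged = True
            break
    if not converged:
        logger.warning("SVD-EM did not converge in %d iterations", config.max_iter)

    out = np.where(mask, A * sd + mu, X)
    new = df.copy()
    new[cols] = out
    return (
        FeatureTable(new, dict(table.provenance)),
        ImputationReport("svd", int(mask.sum()), iterations=iters, converged=converged),
    )


IMPUTERS = {
    "none": lambda t, **kw: (t.copy(), ImputationReport("none", 0)),
    "mean": None,  # filled below
    "knn": lambda t, **kw: impute_knn(t, **kw),
    "mice": lambda t, **kw: impute_chained(t, **kw),
    "svd": lambda t, **kw: impute_svd(t, kw.pop("config", None)),
}


def _impute_mean(table: FeatureTable, **kw) -> tuple[FeatureTable, ImputationReport]:
    df = table.df
    cols = _imputable_columns(df)
    X = df[cols].to_numpy(dtype=float)
    mask = np.isnan(X)
    filled = np.where(mask, np.nanmean(X, axis=0), X)
    new = df.copy()
    new[cols] = filled
    return FeatureTable(new, dict(table.provenance)), ImputationReport("mean", int(mask.sum()))


IMPUTERS["mean"] = _impute_mean


def impute(table: FeatureTable, method: str, **kwargs) -> tuple[FeatureTable, ImputationReport]:
    """Dispatch to one of the registered imputation methods."""
    if method not in IMPUTERS:
        raise ConfigError(f"unknown imputation method {method!r}")
    return IMPUTERS[method](table, **kwargs)


def benchmark_imputation(
    complete_table: FeatureTable,
    mask_fraction: float,
    methods: list[str],
    seed: int = 0,
    method_kwargs: dict[str, dict] | None = None,
    max_retries: int = 100,
) -> dict[str, ImputationReport]:
    """Mask cells of a complete table MCAR, impute with each method, and
    report the root-mean-square error against the hidden truth."""
    df = complete_table.df
    if df.isna().any().any():
        raise ConfigError("benchmark requires a complete table")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    X = df.to_numpy(dtype=float)
    for _ in range(max_retries):
        mask = rng.random(X.shape) < mask_fraction
        if mask_fraction == 0 or not np.all(mask, axis=1).any():
            break
    else:
        raise PromineError("could not draw a mask leaving every row non-empty")

    arr = df.to_numpy(dtype=float, copy=True)
    arr[mask] = np.nan
    masked = pd.DataFrame(arr, index=df.index, columns=df.columns)
    masked_table = FeatureTable(masked, dict(complete_table.provenance))
    reports: dict[str, ImputationReport] = {}
    for method in methods:
        kw = (method_kwargs or {}).get(method, {})
        imputed, report = impute(masked_table, method, **kw)
        Y = imputed.df.to_numpy(dtype=float)
        if mask.any():
            filled = mask & ~np.isnan(Y)
            err = (Y - X)[filled]
            report.rmse = float(np.sqrt(np.mean(err**2))) if filled.any() else None
            per = []
            for jc, c in enumerate(df.columns):
                sel = filled[:, jc]
                per.append(
                    float(np.sqrt(np.mean((Y[sel, jc] - X[sel, jc]) ** 2)))
                    if sel.any()
                    else np.nan
                )
            report.per_feature_rmse = pd.Series(per, index=df.columns)
        else:
            report.rmse = 0.0
        reports[method] = report
    return reports
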