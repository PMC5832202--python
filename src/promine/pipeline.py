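"""End-to-end pipeline orchestration from a single YAML config.

One global seed deterministically derives per-stage seeds (via
``numpy.random.SeedSequence`` spawning), so a rerun with the same config
reproduces every artifact. Stage outputs are written as plain CSV next to a
JSON manifest recording the config hash, stage seeds, and library versions.
"""

from __future__ import annotations

import datetime as dt
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError
from .evaluation import CvScheme, evaluate_grid, wilcoxon_compare
from .features import build_feature_table, write_feature_csv
from .io import write_daily_csv, write_sensor_csv
from .labeling import get_definition
from .relations import mine_relations, separation_densities
from .synthetic import EffectSpec, GeneratorConfig, generate_cohort

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    seed: int = 0
    generator: dict = field(default_factory=dict)
    subsets: list[str] = field(
        default_factory=lambda: ["All", "No_activities", "No_sparse_features_0.17"]
    )
    expert_features: list[str] | None = None
    imputations: list[str] = field(default_factory=lambda: ["none", "knn"])
    definitions: list[str] = field(
        default_factory=lambda: ["1, 2 vs. 4, 5", "1, 2 x (3/4) vs. 4 x (3/4), 5"]
    )
    cv: dict = field(default_factory=lambda: {"folds": 10, "repeats": 5})
    classifiers: list[str] = field(
        default_factory=lambda: ["random_forest", "decision_tree", "naive_bayes", "majority"]
    )
    relations_definition: str = "1, 2 x (3/4) vs. 4 x (3/4), 5"
    min_occurrences: int = 2
    include_cross_variants: bool = True
    global_imputation: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown pipeline config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        from .labeling import definition_catalog
        from .subsets import SUBSET_NAMES
        from .evaluation import CLASSIFIER_NAMES
        from .imputation import IMPUTERS

        names = {d.name for d in definition_catalog()}
        for d in list(self.definitions) + [self.relations_definition]:
            if d not in names:
                raise ConfigError(f"unknown class definition {d!r}")
        for s in self.subsets:
            if s not in SUBSET_NAMES:
                raise ConfigError(f"unknown subset {s!r}")
        for c in self.classifiers:
            if c not in CLASSIFIER_NAMES:
                raise ConfigError(f"unknown classifier {c!r}")
        for i in self.imputations:
            if i not in IMPUTERS:
                raise ConfigError(f"unknown imputation {i!r}")

    def generator_config(self, seed: int) -> GeneratorConfig:
        raw = dict(self.generator)
        effects = raw.pop("effects", None)
        if effects is not None:
            raw["effects"] = [EffectSpec(**e) for e in effects]
        if "days_per_patient" in raw and isinstance(raw["days_per_patient"], list):
            raw["days_per_patient"] = tuple(raw["days_per_patient"])
        return GeneratorConfig(seed=seed, **raw)


def _stage_seeds(seed: int, n: int = 8) -> list[int]:
    return [int(s % 2**31) for s in np.random.SeedSequence(seed).generate_state(n)]


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run generate -> features -> label -> evaluate -> relations, writing all
    artifacts under ``out_dir``; returns the manifest dict."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)

    gen_cfg = config.generator_config(seeds[0])
    cohort, truth = generate_cohort(gen_cfg)
    write_daily_csv(cohort, out / "daily.csv")
    write_sensor_csv(cohort, out / "sensors.csv")
    truth.latent_wellbeing.reset_index().to_csv(out / "truth.csv", index=False)

    table = build_feature_table(cohort, include_cross_variants=config.include_cross_variants)
    write_feature_csv(table, out / "features.csv")

    from .subsets import missingness_profile

    profile = missingness_profile(table)
    profile.rename("missing_fraction").reset_index().to_csv(
        out / "missingness_profile.csv", index=False
    )

    scheme = CvScheme(seed=seeds[1], **config.cv)
    grid = evaluate_grid(
        table,
        cohort,
        subsets=config.subsets,
        imputations=config.imputations,
        definitions=config.definitions,
        classifiers=config.classifiers,
        scheme=scheme,
        expert_list=config.expert_features,
        global_imputation=config.global_imputation,
    )
    grid.to_frame().to_csv(out / "cells.csv", index=False)
    pivots = out / "pivots"
    pivots.mkdir(exist_ok=True)
    grid.pivot_by_classifier().to_csv(pivots / "by_classifier.csv")
    grid.pivot_by_imputation().to_csv(pivots / "by_imputation.csv")
    grid.pivot_by_subset().to_csv(pivots / "by_subset.csv")
    grid.pivot_by_definition().to_csv(pivots / "by_definition.csv")

    acc = grid.to_frame()
    acc = acc[acc["error"].isna()]
    comparisons = []
    if {"random_forest", "naive_bayes"} <= set(config.classifiers) and len(config.subsets) >= 5:
        mat = acc.pivot_table(
            index=["definition", "subset", "imputation"], columns="classifier", values="mean_ca"
        )
        pairs = [
            (a, b)
            for a in ("random_forest", "decision_tree")
            for b in ("naive_bayes", "svm_smo")
            if a in mat.columns and b in mat.columns
        ]
        if pairs:
            comparisons = wilcoxon_compare(mat, pairs)
            pd.DataFrame(
                [
                    {
                        "a": c.pair[0],
                        "b": c.pair[1],
                        "statistic": c.statistic,
                        "p_value": c.p_value,
                        "direction": c.direction,
                        "n": c.n,
                    }
                    for c in comparisons
                ]
            ).to_csv(out / "comparisons.csv", index=False)

    rel_def = get_definition(config.relations_definition)
    rel_table, _ = mine_relations(
        table,
        cohort,
        rel_def,
        subset_names=config.subsets,
        expert_list=config.expert_features,
        min_occurrences=config.min_occurrences,
        seed=seeds[2],
    )
    rel_table.to_csv(out / "relations.csv", index=False)

    pro = pd.Series(
        {(d.patient_id, d.date): (np.nan if d.pro is None else d.pro) for d in cohort.patient_days}
    )
    pro.index.names = ["patient_id", "date"]
    try:
        dens = separation_densities(table, pro, rel_def, seed=seeds[3])
        pd.DataFrame(
            {
                "bin_left": dens.bin_edges[:-1],
                "bin_right": dens.bin_edges[1:],
                "within_density": dens.within_density,
                "between_density": dens.between_density,
            }
        ).to_csv(out / "densities.csv", index=False)
    except Exception as exc:
        logger.warning("separation density stage skipped: %s", exc)

    manifest = {
        "created": dt.datetime.now().isoformat(timespec="seconds"),
        "seed": config.seed,
        "stage_seeds": {
            "generator": seeds[0],
            "cv": seeds[1],
            "relations": seeds[2],
            "densities": seeds[3],
        },
        "config_hash": hashlib.sha256(
            json.dumps(asdict(config), sort_keys=True, default=str).encode()
        ).hexdigest(),
        "config": asdict(config),
        "versions": _versions(),
        "n_patient_days": len(cohort),
        "n_cells": len(grid.cells),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _versions() -> dict:
    import sklearn
    import scipy

    return {
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scikit-learn": sklearn.__version__,
        "scipy": scipy.__version__,
    }
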