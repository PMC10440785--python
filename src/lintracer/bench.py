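"""End-to-end in silico benchmarking: simulate colonies, train the per-level
classifiers, reconstruct held-out colonies with both the ML assembly and the
maximum-parsimony baseline, and score every reconstruction against its
ground truth with all four tree metrics.

The default shallow configuration mirrors the three-state recorder study
conditions: editing rate 0.15, uniform edit-state probabilities, colony
depths uniform on 2..6 (colony sizes 4-64).  Scale (training and test tree
counts, units, states) is set by the config.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .features import build_training_table
from .matrix import Alphabet
from .model import Hyperparams, LevelModel, train_level_model
from .parsimony import parsimony_reconstruct
from .reconstruct import reconstruct_tree, tune_merge_threshold
from .scores import score_all
from .simulate import Colony, SimConfig, sample_experiment

METRICS = ("rf", "trp", "qrt", "cli")


@dataclass
class BenchmarkConfig:
    n_edit_states: int = 2
    n_units: int = 10
    n_train: int = 200
    n_test: int = 30
    depth_choices: tuple[int, ...] = (2, 3, 4, 5, 6)
    mu_choices: tuple[float, ...] = (0.15,)
    seed: int = 0
    methods: tuple[str, ...] = ("ml", "parsimony")
    validation_fraction: float = 0.1
    ratchet_iterations: int = 100
    hyperparams: Hyperparams = field(default_factory=Hyperparams)

    def __post_init__(self):
        if self.n_test < 1:
            raise ValueError("n_test must be >= 1")
        if not self.methods:
            raise ValueError("at least one method required")
        unknown = set(self.methods) - {"ml", "parsimony"}
        if unknown:
            raise ValueError(f"unknown methods {unknown}")

    def sim_config(self, n_colonies: int) -> SimConfig:
        return SimConfig(
            n_units=self.n_units,
            depth_choices=self.depth_choices,
            mu_choices=self.mu_choices,
            alphabet=Alphabet.with_n_edits(self.n_edit_states),
            n_colonies=n_colonies,
        )

    def hash(self) -> str:
        payload = {k: v for k, v in asdict(self).items()}
        return hashlib.sha1(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:12]


def train_pipeline(
    train_colonies: list[Colony],
    hp: Hyperparams | None = None,
    seed: int = 0,
    validation: list[Colony] | None = None,
) -> tuple[dict[int, LevelModel], dict[int, float], list[str]]:
    """Train one classifier per relationship level present in the training
    trees; returns (models, thresholds, failure messages).  A level whose
    training fails (e.g. a single-class label column) is recorded and
    skipped."""
    # at level d every pair of a depth-d tree meets at the root, so the
    # deepest informative level is max_depth - 1; reconstruction reuses the
    # deepest model above that
    max_depth = max(max(c.depths.values()) for c in train_colonies)
    levels = list(range(1, max(max_depth, 2)))
    table = build_training_table(train_colonies, levels)
    models: dict[int, LevelModel] = {}
    failures: list[str] = []
    for t in levels:
        try:
            models[t] = train_level_model(table, level=t, hp=hp, seed=seed + t)
        except ValueError as exc:
            failures.append(f"level {t}: {exc}")
    if not models:
        raise RuntimeError(f"no level model could be trained: {failures}")
    if validation:
        thresholds = tune_merge_threshold(models, validation)
    else:
        thresholds = {t: 0.5 for t in models}
    return models, thresholds, failures


def run_benchmark(config: BenchmarkConfig) -> dict:
    """Run one full benchmark configuration.

    Returns a dict with the per-tree results table, per-method means, the
    relative improvement of ML over parsimony on each metric (positive =
    ML better), per-tree paired differences, and run provenance.
    """
    rng = np.random.default_rng(config.seed)
    train_colonies = sample_experiment(config.sim_config(config.n_train), rng)
    test_colonies = sample_experiment(config.sim_config(config.n_test), rng)
    score_rng = np.random.default_rng(config.seed + 1)

    failures: list[str] = []
    models: dict[int, LevelModel] = {}
    thresholds: dict[int, float] = {}
    if "ml" in config.methods:
        n_val = max(1, int(round(config.validation_fraction * len(train_colonies))))
        fit_set = train_colonies[:-n_val] if len(train_colonies) > n_val else train_colonies
        val_set = train_colonies[-n_val:] if len(train_colonies) > n_val else None
        models, thresholds, failures = train_pipeline(
            fit_set, hp=config.hyperparams, seed=config.seed, validation=val_set
        )

    rows = []
    for i, colony in enumerate(test_colonies):
        for method in config.methods:
            if method == "ml":
                pred = reconstruct_tree(colony.barcodes, models, thresholds)
            else:
                pred = parsimony_reconstruct(
                    colony.barcodes,
                    iterations=config.ratchet_iterations,
                    rng=np.random.default_rng(config.seed + 1000 + i),
                )
            report = score_all(colony.tree, pred, rng=score_rng)
            rows.append(
                {"tree": i, "n_cells": colony.barcodes.n_cells, "method": method,
                 **report.as_dict()}
            )
    results = pd.DataFrame(rows)

    means = results.groupby("method")[list(METRICS)].mean()
    summary: dict = {"means": means.to_dict(orient="index")}
    if {"ml", "parsimony"} <= set(config.methods):
        improvement = {}
        paired = {}
        for m in METRICS:
            mp = means.loc["parsimony", m]
            ml = means.loc["ml", m]
            improvement[m] = float("nan") if mp == 0 else 100.0 * (mp - ml) / mp
            wide = results.pivot(index="tree", columns="method", values=m)
            paired[m] = (wide["parsimony"] - wide["ml"]).tolist()
        summary["improvement_pct"] = improvement
        summary["paired_differences"] = paired
    summary["training_failures"] = failures
    summary["thresholds"] = thresholds
    summary["provenance"] = {"seed": config.seed, "config_hash": config.hash()}
    return {"results": results, "summary": summary, "models": models}
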