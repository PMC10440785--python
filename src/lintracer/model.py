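"""Per-level boosted classifiers for pairwise relatedness.

One gradient-boosted decision-tree ensemble is trained per relationship
level t, predicting from a pair's feature vector the probability that the
two cells share their level-t ancestor.  The backend is LightGBM configured
to the classic GBM recipe: Bernoulli (logistic) loss, up to 1000 trees,
tree depth capped at 10, at least 5 observations per leaf, the number of
trees selected by 5-fold cross-validated loss, and the model fitted on a
random half of the rows.  The learning rate (shrinkage) defaults to 0.1.

Interpretation helpers expose split-count relative importance (how often a
feature is selected, normalized to percentages), gain importance, partial
dependence curves, and the individual conditional expectation curves they
average.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import lightgbm as lgb
import numpy as np
import pandas as pd


@dataclass(frozen=True)
class Hyperparams:
    n_trees: int = 1000
    max_depth: int = 10          # interaction-depth analogue: per-tree depth cap
    min_obs_per_leaf: int = 5
    cv_folds: int = 5
    train_fraction: float = 0.5
    learning_rate: float = 0.1
    early_stopping_rounds: int = 50

    def __post_init__(self):
        if not 0 < self.train_fraction <= 1:
            raise ValueError("train_fraction must be in (0, 1]")
        if min(self.n_trees, self.max_depth, self.min_obs_per_leaf, self.cv_folds) < 1:
            raise ValueError("hyperparameters must be positive")

    def lgb_params(self, seed: int) -> dict:
        return {
            "objective": "binary",
            "learning_rate": self.learning_rate,
            "max_depth": self.max_depth,
            "num_leaves": min(1 << self.max_depth, 1024),
            "min_data_in_leaf": self.min_obs_per_leaf,
            "seed": seed,
            "deterministic": True,
            "force_row_wise": True,
            "num_threads": 1,
            "verbosity": -1,
        }


@dataclass
class LevelModel:
    """Trained classifier for one relationship level."""

    level: int
    booster: lgb.Booster
    feature_names: list[str]
    n_trees_used: int
    seed: int
    hyperparams: Hyperparams = field(default_factory=Hyperparams)

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = {
            "level": self.level,
            "feature_names": self.feature_names,
            "n_trees_used": self.n_trees_used,
            "seed": self.seed,
            "hyperparams": asdict(self.hyperparams),
            "backend": "lightgbm",
            "hyperparam_mapping": {
                "interaction_depth_10": "max_depth=10 (per-tree depth cap)",
                "n_minobsinnode_5": "min_data_in_leaf=5",
                "bernoulli": "objective=binary (logistic loss)",
            },
        }
        (directory / f"level{self.level}.json").write_text(json.dumps(meta, indent=1))
        self.booster.save_model(str(directory / f"level{self.level}.txt"))

    @classmethod
    def load(cls, directory, level: int) -> "LevelModel":
        directory = Path(directory)
        meta = json.loads((directory / f"level{level}.json").read_text())
        booster = lgb.Booster(model_file=str(directory / f"level{level}.txt"))
        return cls(
            level=meta["level"],
            booster=booster,
            feature_names=meta["feature_names"],
            n_trees_used=meta["n_trees_used"],
            seed=meta["seed"],
            hyperparams=Hyperparams(**meta["hyperparams"]),
        )


def _design(table: pd.DataFrame, names: list[str]) -> np.ndarray:
    missing = [n for n in names if n not in table.columns]
    if missing:
        raise ValueError(f"missing feature columns {missing}")
    return table[names].to_numpy(dtype=np.float64)


def train_level_model(
    table: pd.DataFrame,
    level: int,
    hp: Hyperparams | None = None,
    seed: int = 0,
) -> LevelModel:
    """Train the level-t classifier on the rows of ``table`` at that level.

    The iteration count is chosen by ``cv_folds``-fold cross-validated
    logistic loss (with early stopping) on a random ``train_fraction`` of the
    rows, then the final ensemble is refitted on that subset.  Reproducible
    given ``seed``.
    """
    hp = hp or Hyperparams()
    sub = table[table["level"] == level] if "level" in table.columns else table
    names = [c for c in sub.columns if c.startswith("F") and c[1:].isdigit()]
    if not names:
        raise ValueError("no feature columns (F1..Fk) in table")
    y = sub["label"].to_numpy(dtype=np.int8)
    if len(np.unique(y)) < 2:
        raise ValueError(f"level {level}: single-class training data")
    if len(y) < 2 * hp.cv_folds:
        raise ValueError(f"level {level}: need at least {2 * hp.cv_folds} rows")
    X = _design(sub, names)

    rng = np.random.default_rng(seed)
    if hp.train_fraction < 1.0:
        n_keep = max(2 * hp.cv_folds, int(round(hp.train_fraction * len(y))))
        keep = rng.permutation(len(y))[:n_keep]
        # guarantee both classes survive the subsample
        if len(np.unique(y[keep])) < 2:
            keep = np.concatenate([keep, [int(np.flatnonzero(y != y[keep][0])[0])]])
        X, y = X[keep], y[keep]

    params = hp.lgb_params(seed)
    data = lgb.Dataset(X, label=y, feature_name=names, free_raw_data=False)
    cv = lgb.cv(
        params,
        data,
        num_boost_round=hp.n_trees,
        nfold=hp.cv_folds,
        stratified=True,
        seed=seed,
        callbacks=[lgb.early_stopping(hp.early_stopping_rounds, verbose=False)],
    )
    loss_curve = cv["valid binary_logloss-mean"]
    best_iter = int(np.argmin(loss_curve)) + 1
    booster = lgb.train(params, data, num_boost_round=best_iter)
    return LevelModel(
        level=level,
        booster=booster,
        feature_names=names,
        n_trees_used=best_iter,
        seed=seed,
        hyperparams=hp,
    )


def predict_pair_probability(model: LevelModel, features) -> np.ndarray:
    """Probability that pairs share their level-t ancestor.

    ``features`` may be a DataFrame with named F-columns (any column order),
    a dict, or an array already in the model's feature order.
    """
    if isinstance(features, dict):
        features = pd.DataFrame([features])
    if isinstance(features, pd.DataFrame):
        X = _design(features, model.feature_names)
    else:
        X = np.atleast_2d(np.asarray(features, dtype=np.float64))
        if X.shape[1] != len(model.feature_names):
            raise ValueError("feature vector length mismatch")
    return model.booster.predict(X)


def interpret_model(
    model: LevelModel,
    table: pd.DataFrame,
    grid_points: int = 20,
    max_ice: int = 200,
    rng: np.random.Generator | None = None,
) -> dict:
    """Relative importance plus PDP/ICE curves.

    Importance is split-count based (number of times a feature is selected),
    normalized to percentages summing to 100; gain-based importance is
    reported alongside.  For each feature, ICE curves are per-row predictions
    with that feature swept over an observed-value grid, and the PDP is their
    pointwise mean.
    """
    if table.empty:
        raise ValueError("empty table")
    splits = model.booster.feature_importance(importance_type="split").astype(float)
    gains = model.booster.feature_importance(importance_type="gain").astype(float)

    def _pct(v: np.ndarray) -> np.ndarray:
        return 100.0 * v / v.sum() if v.sum() > 0 else np.full_like(v, 100.0 / len(v))

    X = _design(table, model.feature_names)
    if len(X) > max_ice:
        rng = rng or np.random.default_rng(0)
        X = X[rng.choice(len(X), size=max_ice, replace=False)]

    pdp: dict[str, dict] = {}
    ice: dict[str, dict] = {}
    for j, name in enumerate(model.feature_names):
        values = np.unique(X[:, j])
        if len(values) > grid_points:
            values = np.quantile(values, np.linspace(0, 1, grid_points))
        curves = np.empty((len(X), len(values)))
        for g, v in enumerate(values):
            Xg = X.copy()
            Xg[:, j] = v
            curves[:, g] = model.booster.predict(Xg)
        pdp[name] = {"grid": values, "mean": curves.mean(axis=0)}
        ice[name] = {"grid": values, "curves": curves}

    return {
        "relative_importance": dict(zip(model.feature_names, _pct(splits))),
        "gain_importance": dict(zip(model.feature_names, _pct(gains))),
        "pdp": pdp,
        "ice": ice,
    }
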