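"""Gradient-boosted regression of questionnaire scores from log features.

Six stochastic gradient-boosted regression forests (GBRFs) — one per label
(ATT, HQ, HQ-I, HQ-S, PQ, SUS) — map the 238-column feature table to
questionnaire scores.  Hyperparameters come from an exhaustive grid search
(default grid: 20,480 combinations over five axes) scored by eight-fold
cross-validated Huber deviance on a random 4:1 train/test split.

SUS prediction adds a two-stage feature selection: the best 1% (205) of
grid-search estimators vote on feature importance with 1/loss weights; the
top 25 features are kept and the grid search is repeated on that reduced
table.  Predictions are clipped to the label's valid range ([0, 100] for
SUS, [1, 7] otherwise).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lightgbm import LGBMRegressor
from sklearn.model_selection import KFold

__all__ = [
    "LABELS",
    "LABEL_RANGES",
    "GridSpec",
    "DEFAULT_GRID",
    "DEMO_GRID",
    "RankedConfig",
    "TrainedPredictor",
    "split_train_test",
    "grid_search",
    "sus_feature_selection",
    "train_label",
    "train_all",
    "predict_scores",
    "evaluate_errors",
    "huber_deviance",
]

LABELS = ["ATT", "HQ", "HQ-I", "HQ-S", "PQ", "SUS"]
LABEL_RANGES = {"SUS": (0.0, 100.0), **{k: (1.0, 7.0) for k in ("ATT", "HQ", "HQ-I", "HQ-S", "PQ")}}

#: Voting pool size for the SUS feature selection (1% of the default grid).
N_VOTING_ESTIMATORS = 205
#: Features retained by the importance vote.
N_SELECTED_FEATURES = 25


@dataclass(frozen=True)
class GridSpec:
    """Named hyperparameter axes of an exhaustive grid."""

    axes: dict[str, tuple]

    @property
    def n_combinations(self) -> int:
        out = 1
        for v in self.axes.values():
            out *= len(v)
        return out

    def combinations(self):
        names = list(self.axes)
        for values in itertools.product(*(self.axes[n] for n in names)):
            yield dict(zip(names, values))


#: Full default grid: 8 * 8 * 8 * 8 * 5 = 20,480 combinations.
DEFAULT_GRID = GridSpec({
    "n_estimators": (25, 50, 75, 100, 150, 200, 300, 400),
    "learning_rate": (0.005, 0.01, 0.02, 0.05, 0.1, 0.15, 0.2, 0.3),
    "max_depth": (1, 2, 3, 4, 5, 6, 7, 8),
    "subsample": (0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 0.95, 1.0),
    "min_child_samples": (1, 2, 3, 5, 8),
})

#: Reduced grid for fast end-to-end runs: 4 * 4 * 4 * 2 * 2 = 256.
DEMO_GRID = GridSpec({
    "n_estimators": (25, 50, 75, 100),
    "learning_rate": (0.02, 0.05, 0.1, 0.2),
    "max_depth": (1, 2, 3, 4),
    "subsample": (0.8, 1.0),
    "min_child_samples": (1, 3),
})


def huber_deviance(y_true: np.ndarray, y_pred: np.ndarray, delta: float = 1.0) -> float:
    """Mean Huber deviance of residuals (quadratic below delta, linear above)."""
    r = np.abs(np.asarray(y_true, float) - np.asarray(y_pred, float))
    return float(np.mean(np.where(r <= delta, 0.5 * r ** 2, delta * (r - 0.5 * delta))))


def _make_estimator(params: dict, seed: int) -> LGBMRegressor:
    """Stochastic gradient-boosted regression forest with Huber loss.

    Row subsampling per stage plus per-tree feature subsetting are the
    stochastic "forest" ingredients.  Settings are tuned for very small
    tables (tens of samples): no minimum bin population, no split-gain
    threshold.
    """
    params = dict(params)
    depth = params.pop("max_depth")
    return LGBMRegressor(
        objective="huber", max_depth=depth, num_leaves=2 ** min(depth, 10),
        subsample_freq=1, colsample_bytree=0.3, importance_type="gain",
        min_split_gain=0.0, min_data_in_bin=1,
        random_state=seed, n_jobs=1, deterministic=True, force_row_wise=True,
        verbose=-1, **params)


def split_train_test(table: pd.DataFrame, labels: pd.Series, ratio: float = 0.2,
                     rng_seed: int = 0):
    """Reproducible random split; test size = round(n * ratio) (4:1 default).

    Returns ``(X_train, X_test, y_train, y_test)``.
    """
    n = len(table)
    if n < 10:
        raise ValueError("need at least 10 samples to split")
    labels = labels.loc[table.index]
    rng = np.random.default_rng(rng_seed)
    perm = rng.permutation(n)
    n_test = max(1, int(round(n * ratio)))
    test_idx, train_idx = perm[:n_test], perm[n_test:]
    return (table.iloc[train_idx], table.iloc[test_idx],
            labels.iloc[train_idx], labels.iloc[test_idx])


@dataclass
class RankedConfig:
    params: dict
    mean_deviance: float
    importances: np.ndarray  # fold-averaged feature importances


def grid_search(table: pd.DataFrame, labels: pd.Series, grid: GridSpec = DEMO_GRID,
                folds: int = 8, rng_seed: int = 0) -> list[RankedConfig]:
    """Exhaustive grid search scored by k-fold cross-validated Huber deviance.

    Every configuration is fitted on each fold's training part; held-out
    deviances are averaged and configurations returned ranked ascending.
    Fold-averaged feature importances are retained for the voting step.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if grid.n_combinations < 1:
        raise ValueError("grid must be non-empty")
    X = table.to_numpy(dtype=float)
    y = labels.loc[table.index].to_numpy(dtype=float)
    if folds > len(X):
        raise ValueError("more folds than samples")
    kf = KFold(n_splits=folds, shuffle=True, random_state=rng_seed % (2 ** 31))
    splits = list(kf.split(X))
    ranked = []
    for k, params in enumerate(grid.combinations()):
        devs = []
        imps = np.zeros(X.shape[1])
        for tr, te in splits:
            est = _make_estimator(params, seed=(rng_seed + k) % (2 ** 31))
            est.fit(X[tr], y[tr])
            devs.append(huber_deviance(y[te], est.predict(X[te])))
            fi = np.asarray(est.feature_importances_, dtype=float)
            total = fi.sum()
            imps += fi / total if total > 0 else fi
        ranked.append(RankedConfig(params, float(np.mean(devs)), imps / len(splits)))
    ranked.sort(key=lambda rc: rc.mean_deviance)
    return ranked


def sus_feature_selection(ranked: list[RankedConfig], table: pd.DataFrame,
                          n_voters: int = N_VOTING_ESTIMATORS,
                          n_features: int = N_SELECTED_FEATURES
                          ) -> tuple[list[str], bool]:
    """Importance vote of the best grid-search estimators.

    The ``n_voters`` lowest-deviance configurations contribute their
    feature importances weighted by 1/loss; the ``n_features`` highest-voted
    feature names are returned.  Returns ``(names, flagged)`` where
    ``flagged`` marks a voter pool smaller than requested.
    """
    if not ranked:
        raise ValueError("no ranked configurations")
    flagged = len(ranked) < n_voters
    voters = ranked[:n_voters]
    eps = 1e-12
    votes = np.zeros(len(table.columns))
    for rc in voters:
        votes += rc.importances / max(rc.mean_deviance, eps)
    order = np.argsort(-votes, kind="stable")[:n_features]
    return [table.columns[i] for i in order], flagged


@dataclass
class TrainedPredictor:
    """Fitted per-label models with their CV scores and feature subsets."""

    models: dict[str, LGBMRegressor] = field(default_factory=dict)
    cv_deviance: dict[str, float] = field(default_factory=dict)
    best_params: dict[str, dict] = field(default_factory=dict)
    feature_subset: dict[str, list[str]] = field(default_factory=dict)
    sus_selected: list[str] | None = None


def train_label(X_train: pd.DataFrame, y_train: pd.Series, label: str,
                grid: GridSpec = DEMO_GRID, folds: int = 8, rng_seed: int = 0,
                feature_selection: bool | None = None
                ) -> tuple[LGBMRegressor, dict]:
    """Grid-search and fit one label's estimator on the training split.

    ``feature_selection`` defaults to True for SUS (the two-stage
    importance-voting reduction) and False otherwise.  Returns the fitted
    model and metadata (best params, CV deviance, feature subset).
    """
    if feature_selection is None:
        feature_selection = label == "SUS"
    ranked = grid_search(X_train, y_train, grid, folds, rng_seed)
    meta = {"feature_subset": list(X_train.columns), "sus_selected": None}
    if feature_selection:
        selected, flagged = sus_feature_selection(ranked, X_train)
        meta["sus_selected"] = selected
        meta["selection_flagged"] = flagged
        X_train = X_train[selected]
        ranked = grid_search(X_train, y_train, grid, folds, rng_seed + 1)
        meta["feature_subset"] = selected
    best = ranked[0]
    meta["best_params"] = best.params
    meta["cv_deviance"] = best.mean_deviance
    model = _make_estimator(best.params, seed=rng_seed % (2 ** 31))
    model.fit(X_train.to_numpy(dtype=float), y_train.to_numpy(dtype=float))
    return model, meta


def train_all(X_train: pd.DataFrame, y_train: pd.DataFrame,
              grid: GridSpec = DEMO_GRID, folds: int = 8,
              rng_seed: int = 0, labels: list[str] = LABELS) -> TrainedPredictor:
    """Train one estimator per questionnaire label."""
    tp = TrainedPredictor()
    for i, label in enumerate(labels):
        model, meta = train_label(X_train, y_train[label], label, grid, folds,
                                  rng_seed=rng_seed + 101 * i)
        tp.models[label] = model
        tp.cv_deviance[label] = meta["cv_deviance"]
        tp.best_params[label] = meta["best_params"]
        tp.feature_subset[label] = meta["feature_subset"]
        if label == "SUS":
            tp.sus_selected = meta["sus_selected"]
    return tp


def predict_scores(predictor: TrainedPredictor, X: pd.DataFrame) -> pd.DataFrame:
    """Range-clipped predictions for every trained label."""
    out = {}
    for label, model in predictor.models.items():
        cols = predictor.feature_subset[label]
        missing = [c for c in cols if c not in X.columns]
        if missing:
            raise KeyError(f"missing feature columns: {missing[:5]}")
        lo, hi = LABEL_RANGES[label]
        out[label] = np.clip(model.predict(X[cols].to_numpy(dtype=float)), lo, hi)
    return pd.DataFrame(out, index=X.index)


def evaluate_errors(predictor: TrainedPredictor, X_test: pd.DataFrame,
                    y_test: pd.DataFrame) -> pd.DataFrame:
    """Relative absolute prediction error summary per label.

    ``|y_hat − y| / y`` per test sample, summarized by mean, median and
    standard deviation; samples with a zero true label are excluded.
    Rows: Mean, Median, Std; columns: the trained labels.
    """
    if len(X_test) == 0:
        raise ValueError("empty test set")
    preds = predict_scores(predictor, X_test)
    summary = {}
    for label in preds.columns:
        y = y_test[label].to_numpy(dtype=float)
        keep = y != 0
        rel = np.abs(preds[label].to_numpy()[keep] - y[keep]) / y[keep]
        summary[label] = {"Mean": float(rel.mean()), "Median": float(np.median(rel)),
                          "Std": float(rel.std())}
    return pd.DataFrame(summary).loc[["Mean", "Median", "Std"]]
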