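"""Random-forest prevalence estimation with cross-validated evaluation.

A random-forest regressor maps the per-tract feature vector to prevalence
percent.  Evaluation is k-fold cross-validation (default 5): tracts are
randomly partitioned, each fold is predicted by a model trained on the
rest, and Pearson correlation plus mean absolute error are computed on the
pooled out-of-fold predictions (per-fold metrics are reported alongside).
Feature importances are impurity (variance) decreases summed over splits
and averaged over trees — "node purity" in random-forest parlance.

Forest hyperparameters follow regression conventions: 500 trees,
ceil(p/3) features per split, minimum leaf size 5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold

from .errors import (
    AlignmentError,
    InvalidParameterError,
    MissingDataError,
    ModelStateError,
    UndefinedCorrelationError,
)
from .feature_engineering import FeatureTable
from .synthetic_city import PrevalenceTable


@dataclass
class ModelConfig:
    """Forest and cross-validation settings."""

    n_trees: int = 500
    features_per_split: str | int = "third"  # "third" => ceil(p/3)
    min_leaf: int = 5
    seed: int = 0
    k_folds: int = 5

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise InvalidParameterError("n_trees must be at least 1")
        if self.k_folds < 2:
            raise InvalidParameterError("k_folds must be at least 2")
        if self.min_leaf < 1:
            raise InvalidParameterError("min_leaf must be at least 1")

    def max_features(self, p: int) -> int:
        if self.features_per_split == "third":
            return max(1, math.ceil(p / 3))
        return max(1, min(int(self.features_per_split), p))


@dataclass
class FittedModel:
    """Handle over a fitted forest: supports predict and importance queries."""

    forest: RandomForestRegressor
    feature_names: list[str]
    outcome: str

    def predict(self, features: FeatureTable) -> pd.Series:
        X = features.data[self.feature_names].to_numpy(dtype=float)
        return pd.Series(self.forest.predict(X), index=features.data.index,
                         name=f"predicted_{self.outcome}")


@dataclass
class CVResult:
    """Pooled and per-fold cross-validation outputs."""

    outcome: str
    fold_assignment: dict[str, int]
    predictions: pd.Series          # out-of-fold, index tract_id
    actuals: pd.Series
    correlation: float
    mae: float
    per_fold: pd.DataFrame          # fold, n, correlation, mae
    importances: pd.Series          # feature -> mean importance over folds, desc

    def predictions_frame(self) -> pd.DataFrame:
        """tract_id, fold, actual, predicted — the persisted prediction file."""
        return pd.DataFrame({
            "tract_id": self.predictions.index,
            "fold": [self.fold_assignment[t] for t in self.predictions.index],
            "actual": self.actuals.to_numpy(),
            "predicted": self.predictions.to_numpy(),
        })


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def pearson_correlation(pred, actual) -> float:
    """Sample Pearson product-moment correlation of two equal-length vectors."""
    p = np.asarray(pred, dtype=float)
    a = np.asarray(actual, dtype=float)
    if p.shape != a.shape or p.ndim != 1:
        raise AlignmentError("vectors must be 1-D with equal length")
    if p.size < 2:
        raise InvalidParameterError("correlation needs at least 2 observations")
    if np.std(p) == 0.0 or np.std(a) == 0.0:
        raise UndefinedCorrelationError("correlation undefined for zero-variance vector")
    return float(stats.pearsonr(p, a).statistic)


def spearman_correlation(pred, actual) -> float:
    """Rank correlation, available as an alternative to Pearson."""
    p = np.asarray(pred, dtype=float)
    a = np.asarray(actual, dtype=float)
    if p.shape != a.shape or p.ndim != 1:
        raise AlignmentError("vectors must be 1-D with equal length")
    return float(stats.spearmanr(p, a).statistic)


def mean_absolute_error(pred, actual) -> float:
    """Mean of |pred - actual| on the percentage-point scale."""
    p = np.asarray(pred, dtype=float)
    a = np.asarray(actual, dtype=float)
    if p.shape != a.shape or p.ndim != 1:
        raise AlignmentError("vectors must be 1-D with equal length")
    if p.size < 1:
        raise InvalidParameterError("MAE needs at least 1 observation")
    return float(np.mean(np.abs(p - a)))


# ---------------------------------------------------------------------------
# Fitting and cross-validation
# ---------------------------------------------------------------------------

def _aligned_xy(features: FeatureTable, targets: PrevalenceTable, outcome: str):
    if outcome not in targets.data.columns:
        raise InvalidParameterError(f"unknown outcome {outcome!r}")
    f_ids = set(features.tract_ids)
    t_ids = set(targets.data.index)
    if f_ids != t_ids:
        raise AlignmentError(
            f"feature rows and target rows differ "
            f"({len(f_ids - t_ids)} feature-only, {len(t_ids - f_ids)} target-only)"
        )
    X = features.data.to_numpy(dtype=float)
    if np.isnan(X).any():
        bad = features.data.columns[features.data.isna().any()].tolist()
        raise MissingDataError(f"missing cells in feature columns: {bad[:5]}")
    y = targets.data.loc[features.tract_ids, outcome].to_numpy(dtype=float)
    return X, y


def fit_forest(
    features: FeatureTable,
    targets: PrevalenceTable,
    outcome: str,
    config: ModelConfig | None = None,
) -> FittedModel:
    """Fit the random forest on all rows; deterministic given config.seed."""
    config = config or ModelConfig()
    X, y = _aligned_xy(features, targets, outcome)
    forest = RandomForestRegressor(
        n_estimators=config.n_trees,
        max_features=config.max_features(X.shape[1]),
        min_samples_leaf=config.min_leaf,
        random_state=config.seed,
        n_jobs=1,
    )
    forest.fit(X, y)
    return FittedModel(forest, list(features.data.columns), outcome)


def feature_importance(model: FittedModel) -> pd.Series:
    """Node-purity importances, descending, ties broken lexicographically."""
    forest = model.forest
    if not hasattr(forest, "estimators_"):
        raise ModelStateError("model handle is not fitted")
    imp = pd.Series(forest.feature_importances_, index=model.feature_names)
    order = sorted(imp.index, key=lambda f: (-imp[f], f))
    return imp.loc[order]


def cross_validate(
    features: FeatureTable,
    targets: PrevalenceTable,
    outcome: str,
    config: ModelConfig | None = None,
) -> CVResult:
    """k-fold CV with pooled out-of-fold metrics.

    Tracts are partitioned uniformly at random (seeded, fold sizes within
    1 of each other); each tract is predicted exactly once, by a forest
    that never saw its target.  Importances are averaged over the k
    per-fold forests.
    """
    config = config or ModelConfig()
    X, y = _aligned_xy(features, targets, outcome)
    n = X.shape[0]
    if n < config.k_folds:
        raise InvalidParameterError(f"need at least k_folds={config.k_folds} rows, got {n}")

    ids = features.tract_ids
    kf = KFold(n_splits=config.k_folds, shuffle=True, random_state=config.seed)
    oof = np.full(n, np.nan)
    fold_of = np.full(n, -1)
    per_fold_rows = []
    imp_acc = np.zeros(X.shape[1])

    for fold, (tr, te) in enumerate(kf.split(X)):
        forest = RandomForestRegressor(
            n_estimators=config.n_trees,
            max_features=config.max_features(X.shape[1]),
            min_samples_leaf=config.min_leaf,
            random_state=config.seed + fold,
            n_jobs=1,
        )
        forest.fit(X[tr], y[tr])
        pred = forest.predict(X[te])
        oof[te] = pred
        fold_of[te] = fold
        imp_acc += forest.feature_importances_
        fold_r = pearson_correlation(pred, y[te]) if np.std(pred) > 0 and np.std(y[te]) > 0 else float("nan")
        per_fold_rows.append({
            "fold": fold,
            "n": len(te),
            "correlation": fold_r,
            "mae": mean_absolute_error(pred, y[te]),
        })

    assert not np.isnan(oof).any() and (fold_of >= 0).all()
    imp = pd.Series(imp_acc / config.k_folds, index=features.data.columns)
    order = sorted(imp.index, key=lambda f: (-imp[f], f))

    return CVResult(
        outcome=outcome,
        fold_assignment={t: int(f) for t, f in zip(ids, fold_of)},
        predictions=pd.Series(oof, index=pd.Index(ids, name="tract_id"), name="predicted"),
        actuals=pd.Series(y, index=pd.Index(ids, name="tract_id"), name="actual"),
        correlation=pearson_correlation(oof, y),
        mae=mean_absolute_error(oof, y),
        per_fold=pd.DataFrame(per_fold_rows),
        importances=imp.loc[order],
    )
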