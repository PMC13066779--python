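"""Distribution-capturing random-forest regression.

A standard random forest reports the mean of per-tree predictions.  Here
every prediction additionally exposes the full pooled multiset of training
targets found in the terminal leaves the query row reaches — one leaf per
tree, raw values concatenated across trees.  The pooled mean is the point
prediction, the pooled (population) standard deviation is the uncertainty,
and empirical quantiles of the pool give prediction intervals, in the
spirit of quantile regression forests.

The pooling is deliberately unweighted: a large leaf contributes more
values than a small one.  A Meinshausen-style variant that reweights each
leaf's values by the inverse leaf size is available via ``weighted=True``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from socsnr.features import FeatureMatrix

DEFAULT_HYPERPARAMS = {
    "n_estimators": 200,
    "max_features": "sqrt",
    "max_depth": None,
    "min_samples_leaf": 5,
}


@dataclass
class PredictionDistribution:
    """Pooled terminal-leaf training values for one query row."""

    values: np.ndarray
    weights: np.ndarray | None = None  # None = uniform pooling

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size == 0:
            raise ValueError("empty prediction distribution")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            self.weights = self.weights / self.weights.sum()

    @property
    def mean(self) -> float:
        if self.weights is None:
            return float(self.values.mean())
        return float(np.sum(self.weights * self.values))

    @property
    def sd(self) -> float:
        """Population standard deviation (ddof = 0) of the pool."""
        if self.weights is None:
            return float(self.values.std(ddof=0))
        m = self.mean
        return float(np.sqrt(np.sum(self.weights * (self.values - m) ** 2)))

    def quantile(self, q: float | np.ndarray) -> float | np.ndarray:
        """Empirical quantile, inclusive (type-7) convention."""
        if self.weights is None:
            out = np.quantile(self.values, q)
        else:
            order = np.argsort(self.values)
            v, w = self.values[order], self.weights[order]
            cdf = np.cumsum(w)
            out = np.interp(np.atleast_1d(q), cdf, v)
            out = out if np.ndim(q) else float(out[0])
        return float(out) if np.ndim(q) == 0 else np.asarray(out)

    def interval(self, level: float) -> tuple[float, float]:
        """Symmetric central interval with nominal coverage ``level``."""
        if not (0.0 < level < 1.0):
            raise ValueError(f"level must be in (0, 1), got {level}")
        lo = (1.0 - level) / 2.0
        return (float(self.quantile(lo)), float(self.quantile(1.0 - lo)))

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw n values from the pool (uniform over pooled values)."""
        if self.weights is None:
            return rng.choice(self.values, size=n, replace=True)
        return rng.choice(self.values, size=n, replace=True, p=self.weights)


@dataclass
class FittedModel:
    """A trained distribution-capturing forest with a frozen feature schema."""

    ensemble: RandomForestRegressor
    feature_names: tuple[str, ...]
    target_kind: str
    seed: int
    hyperparams: dict = field(default_factory=dict)
    # per tree: mapping leaf id -> training target values in that leaf
    leaf_values: list[dict[int, np.ndarray]] = field(default_factory=list)

    def _check_schema(self, X: pd.DataFrame) -> None:
        if tuple(X.columns) != self.feature_names:
            raise ValueError(
                f"feature schema mismatch: expected {list(self.feature_names)}, "
                f"got {list(X.columns)}"
            )


def fit_forest(
    matrix: FeatureMatrix,
    hyperparams: dict | None = None,
    seed: int = 0,
    min_rows: int = 10,
) -> FittedModel:
    """Train the forest and index training targets by terminal leaf.

    Reproducible under seed.  Stores, for every tree, the multiset of
    training-target values per leaf so that full prediction distributions
    can be queried later.
    """
    if len(matrix.X) < min_rows:
        raise ValueError(f"need >= {min_rows} rows, got {len(matrix.X)}")
    hp = dict(DEFAULT_HYPERPARAMS)
    hp.update(hyperparams or {})
    rf = RandomForestRegressor(random_state=seed, n_jobs=1, **hp)
    y = matrix.y.to_numpy(dtype=float)
    rf.fit(matrix.X, y)

    leaves = rf.apply(matrix.X)  # (n_rows, n_trees) terminal-leaf ids
    leaf_values: list[dict[int, np.ndarray]] = []
    for t in range(leaves.shape[1]):
        col = leaves[:, t]
        d: dict[int, np.ndarray] = {}
        order = np.argsort(col, kind="stable")
        sorted_ids = col[order]
        bounds = np.flatnonzero(np.diff(sorted_ids)) + 1
        for chunk in np.split(order, bounds):
            d[int(col[chunk[0]])] = y[chunk]
        leaf_values.append(d)

    return FittedModel(
        ensemble=rf,
        feature_names=tuple(matrix.X.columns),
        target_kind=matrix.target_kind,
        seed=seed,
        hyperparams=hp,
        leaf_values=leaf_values,
    )


def predict_distribution(
    model: FittedModel, X: pd.DataFrame, weighted: bool = False
) -> list[PredictionDistribution]:
    """Pooled-leaf prediction distributions for each row of X.

    For every row: find the terminal leaf it reaches in each tree,
    concatenate the raw training-target values of those leaves.  With
    weighted=True each leaf's values carry weight 1/(n_trees * leaf_size)
    instead of uniform pooling.
    """
    model._check_schema(X)
    leaves = model.ensemble.apply(X)
    n_trees = leaves.shape[1]
    out: list[PredictionDistribution] = []
    for i in range(leaves.shape[0]):
        vals = [model.leaf_values[t][int(leaves[i, t])] for t in range(n_trees)]
        pooled = np.concatenate(vals)
        if weighted:
            w = np.concatenate(
                [np.full(len(v), 1.0 / (n_trees * len(v))) for v in vals]
            )
            out.append(PredictionDistribution(pooled, w))
        else:
            out.append(PredictionDistribution(pooled))
    return out


def predict_interval(
    model: FittedModel, X: pd.DataFrame, level: float, weighted: bool = False
) -> np.ndarray:
    """(n, 2) array of symmetric quantile intervals at nominal coverage level."""
    dists = predict_distribution(model, X, weighted=weighted)
    return np.array([d.interval(level) for d in dists])


def predict_mean(model: FittedModel, X: pd.DataFrame) -> np.ndarray:
    """Pooled-distribution means (the model's point prediction)."""
    return np.array([d.mean for d in predict_distribution(model, X)])
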