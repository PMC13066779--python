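"""Training-matrix construction and feature selection.

The state model learns SOC concentration c from covariates aligned on
(site, year).  The change models learn delta and beta from engineered
features that summarize each annual covariate over three periods of a
target's time window: the change interval itself, the years preceding it
(from 2000), and the full span — with mean, standard deviation and OLS
slope per period (nine features per dynamic covariate).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from socsnr.data_model import DeltaTarget, SlopeTarget, SocSeries

PERIODS = ("interval", "pre", "full")
STATS = ("mean", "sd", "slope")
EPOCH_YEAR = 2000  # earliest common year of the annual covariate record


@dataclass
class FeatureMatrix:
    """A training matrix with per-column provenance.

    X holds the named numeric features, y the target (c, delta or beta),
    keys the row identity (site_id plus year or window), provenance maps
    each column to 'static', 'annual' or 'engineered:<period>:<stat>'.
    """

    X: pd.DataFrame
    y: pd.Series
    keys: pd.DataFrame
    target_kind: str  # c | delta | beta
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.X) != len(self.y) or len(self.X) != len(self.keys):
            raise ValueError("X, y and keys must have equal length")
        if self.X.isna().any().any():
            bad = self.X.columns[self.X.isna().any()].tolist()
            raise ValueError(f"missing values in feature columns {bad}")

    @property
    def columns(self) -> list[str]:
        return list(self.X.columns)

    def select(self, columns: Sequence[str]) -> "FeatureMatrix":
        return FeatureMatrix(
            self.X[list(columns)].copy(),
            self.y,
            self.keys,
            self.target_kind,
            {c: self.provenance.get(c, "") for c in columns},
        )

    def to_csv(self, path, schema_path=None) -> None:
        out = pd.concat(
            [self.keys.reset_index(drop=True), self.X.reset_index(drop=True)], axis=1
        )
        out[self.target_kind] = self.y.to_numpy()
        out.to_csv(path, index=False)
        if schema_path is not None:
            import json

            with open(schema_path, "w") as fh:
                json.dump(
                    {"target": self.target_kind, "provenance": self.provenance}, fh,
                    indent=1,
                )


def build_state_matrix(
    samples_df: pd.DataFrame, covariates: pd.DataFrame
) -> FeatureMatrix:
    """One row per site-visit, target = c.

    samples_df needs columns site_id, year, soc; covariates needs site_id,
    year plus feature columns (static columns are simply replicated across
    years by the covariate table).  A visit without covariate values for
    its (site, year) is an error listing the offenders.
    """
    feat_cols = [c for c in covariates.columns if c not in ("site_id", "year")]
    merged = samples_df[["site_id", "year", "soc"]].merge(
        covariates, on=["site_id", "year"], how="left", validate="many_to_one"
    )
    missing = merged[merged[feat_cols].isna().any(axis=1)]
    if len(missing):
        offenders = missing[["site_id", "year"]].drop_duplicates().head(10)
        raise ValueError(
            f"missing covariates for {len(missing)} visit(s); first offenders:\n"
            f"{offenders.to_string(index=False)}"
        )
    prov = {
        c: ("static" if c.startswith("static") else "annual") for c in feat_cols
    }
    return FeatureMatrix(
        X=merged[feat_cols],
        y=merged["soc"].rename("c"),
        keys=merged[["site_id", "year"]],
        target_kind="c",
        provenance=prov,
    )


def _period_stats(years: np.ndarray, values: np.ndarray) -> tuple[float, float, float]:
    """Mean, SD (population) and OLS slope of one period's values."""
    m = float(values.mean())
    if len(values) == 1:
        return m, 0.0, 0.0
    sd = float(values.std(ddof=0))
    t = years - years.mean()
    denom = float((t * t).sum())
    slope = float((t * (values - m)).sum() / denom) if denom > 0 else 0.0
    return m, sd, slope


def engineer_change_features(
    covariate_series: pd.Series, start: int, end: int, name: str = "cov"
) -> dict[str, float]:
    """Summaries of one annual covariate over the three standard periods.

    covariate_series is indexed by year and must cover 2000..end.  Periods
    are inclusive on both ends: interval [start, end], pre [2000, start],
    full [2000, end].  Emits mean, sd and OLS slope per period — nine
    features, keyed '<name>__<period>_<stat>'.
    """
    if start >= end:
        raise ValueError("start must precede end")
    years = covariate_series.index.to_numpy(dtype=float)
    if years.min() > EPOCH_YEAR or years.max() < end:
        raise ValueError(
            f"annual series must cover {EPOCH_YEAR}..{end}, "
            f"got {int(years.min())}..{int(years.max())}"
        )
    vals = covariate_series.to_numpy(dtype=float)
    windows = {
        "interval": (start, end),
        "pre": (EPOCH_YEAR, start),
        "full": (EPOCH_YEAR, end),
    }
    out: dict[str, float] = {}
    for period, (lo, hi) in windows.items():
        mask = (years >= lo) & (years <= hi)
        if not mask.any():
            raise ValueError(f"period {period} [{lo}, {hi}] holds no values")
        m, sd, slope = _period_stats(years[mask], vals[mask])
        out[f"{name}__{period}_mean"] = m
        out[f"{name}__{period}_sd"] = sd
        out[f"{name}__{period}_slope"] = slope
    return out


def build_change_matrix(
    targets: Sequence[DeltaTarget] | Sequence[SlopeTarget],
    covariates: pd.DataFrame,
) -> FeatureMatrix:
    """One row per change target with engineered dynamic features.

    Delta targets use (t0, t1) as the feature window; slope targets use
    the first and last year of their series.  Annual covariate columns
    (prefix 'annual_' or 'noise_') are expanded into the nine period
    statistics; static columns pass through unchanged.
    """
    if not targets:
        raise ValueError("no targets supplied")
    is_delta = isinstance(targets[0], DeltaTarget)
    feat_cols = [c for c in covariates.columns if c not in ("site_id", "year")]
    static_cols = [c for c in feat_cols if c.startswith("static")]
    annual_cols = [c for c in feat_cols if c not in static_cols]

    by_site = {sid: g.set_index("year") for sid, g in covariates.groupby("site_id")}

    rows: list[dict[str, float]] = []
    keys: list[dict] = []
    ys: list[float] = []
    for t in targets:
        if is_delta:
            start, end, y_val = t.t0, t.t1, t.delta
            key = {"site_id": t.site_id, "start": start, "end": end, "lc": t.lc_pair}
        else:
            start, end, y_val = t.years[0], t.years[-1], t.beta
            key = {"site_id": t.site_id, "start": start, "end": end, "lc": t.lc_series}
        g = by_site.get(t.site_id)
        if g is None:
            raise ValueError(f"no covariates for site {t.site_id}")
        row: dict[str, float] = {}
        for c in annual_cols:
            row.update(engineer_change_features(g[c], start, end, name=c))
        first = g.iloc[0]
        for c in static_cols:
            row[c] = float(first[c])
        rows.append(row)
        keys.append(key)
        ys.append(y_val)

    X = pd.DataFrame(rows)
    prov: dict[str, str] = {c: "static" for c in static_cols}
    for c in X.columns:
        if "__" in c:
            _, tail = c.split("__", 1)
            period, stat = tail.rsplit("_", 1)
            prov[c] = f"engineered:{period}:{stat}"
    kind = "delta" if is_delta else "beta"
    return FeatureMatrix(
        X=X,
        y=pd.Series(ys, name=kind),
        keys=pd.DataFrame(keys),
        target_kind=kind,
        provenance=prov,
    )


def select_features_rscfi(
    matrix: FeatureMatrix,
    n_rounds: int = 10,
    subsample_frac: float = 0.5,
    keep_frac: float = 0.95,
    seed: int = 0,
    n_trees: int = 50,
) -> list[str]:
    """Repeated-subsampling cumulative feature importance selection.

    Fits a small random forest on a row subsample n_rounds times,
    accumulates impurity importances across rounds, ranks columns by
    cumulative importance and keeps the smallest top set whose cumulative
    share reaches keep_frac.  Deterministic under seed.
    """
    if len(matrix.columns) < 2:
        raise ValueError("need at least two candidate columns")
    y = matrix.y.to_numpy()
    if np.ptp(y) == 0:
        raise ValueError("constant target; importance is undefined")
    rng = np.random.default_rng(seed)
    n = len(matrix.X)
    k = max(2, int(round(subsample_frac * n)))
    cum = np.zeros(len(matrix.columns))
    for _ in range(n_rounds):
        idx = rng.choice(n, size=k, replace=False)
        rf = RandomForestRegressor(
            n_estimators=n_trees,
            random_state=int(rng.integers(2**31 - 1)),
            n_jobs=1,
        )
        rf.fit(matrix.X.iloc[idx], y[idx])
        cum += rf.feature_importances_
    order = np.argsort(cum)[::-1]
    share = np.cumsum(cum[order]) / cum.sum()
    n_keep = int(np.searchsorted(share, keep_frac) + 1)
    n_keep = min(n_keep, len(order))
    kept_idx = sorted(order[:n_keep].tolist())
    return [matrix.columns[i] for i in kept_idx]
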