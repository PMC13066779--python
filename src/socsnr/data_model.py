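"""Domain types, CSV ingestion, series assembly, quality filtering and
observed change targets.

The unit of analysis is the SOC time series: repeated topsoil measurements
(g/kg, harmonized to 10 cm depth) at a revisited site.  Series are filtered
on three quality criteria (visit count, relocation distance, C/N stability)
before observed change targets are built: pairwise differences ``delta``
(g/kg over an interval) and Theil-Sen trend slopes ``beta`` (g/kg/yr).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

LAND_COVERS = ("B", "C", "G", "S", "W")
"""Closed land-cover vocabulary, ordered by increasing vegetation content:
Bareland, Cropland, Grassland, Shrubland, Woodland."""

EARTH_RADIUS_M = 6_371_008.8  # WGS84 mean radius

REQUIRED_COLUMNS = (
    "site_id",
    "lon",
    "lat",
    "year",
    "depth_top",
    "depth_bottom",
    "soc",
    "cn_ratio",
    "land_cover",
)


class SchemaError(ValueError):
    """A required column is absent from an input table."""


@dataclass(frozen=True)
class SoilSample:
    """One SOC measurement at a site visit.

    soc is the concentration in g/kg for the layer [depth_top, depth_bottom]
    cm; cn_ratio may be None when carbon/nitrogen was not determined.
    """

    site_id: str
    lon: float
    lat: float
    year: int
    depth_top: float
    depth_bottom: float
    soc: float
    cn_ratio: float | None
    land_cover: str

    def __post_init__(self) -> None:
        if not (-180.0 <= self.lon <= 180.0) or not (-90.0 <= self.lat <= 90.0):
            raise ValueError(f"coordinates out of range: ({self.lon}, {self.lat})")
        if not (0.0 <= self.depth_top < self.depth_bottom <= 100.0):
            raise ValueError(
                f"invalid depth interval [{self.depth_top}, {self.depth_bottom}] cm"
            )
        if self.soc < 0.0:
            raise ValueError(f"soc must be >= 0 g/kg, got {self.soc}")
        if self.cn_ratio is not None and self.cn_ratio <= 0.0:
            raise ValueError(f"cn_ratio must be > 0, got {self.cn_ratio}")
        if self.land_cover not in LAND_COVERS:
            raise ValueError(
                f"unknown land cover {self.land_cover!r}; expected one of {LAND_COVERS}"
            )


@dataclass(frozen=True)
class Visit:
    """A site visit with SOC harmonized to the 10 cm reference depth."""

    year: int
    soc: float
    lon: float
    lat: float
    cn_ratio: float | None
    land_cover: str


@dataclass(frozen=True)
class SocSeries:
    """Ordered revisits of a single site; the unit of filtering and targets."""

    site_id: str
    visits: tuple[Visit, ...]

    def __post_init__(self) -> None:
        years = [v.year for v in self.visits]
        if any(b <= a for a, b in zip(years, years[1:])):
            raise ValueError(f"visit years must strictly increase, got {years}")
        if any(v.soc < 0 for v in self.visits):
            raise ValueError("soc must be >= 0 at every visit")

    @property
    def n_visits(self) -> int:
        return len(self.visits)

    @property
    def years(self) -> tuple[int, ...]:
        return tuple(v.year for v in self.visits)

    @property
    def lc_code(self) -> str:
        return "".join(v.land_cover for v in self.visits)


@dataclass(frozen=True)
class DeltaTarget:
    """Net SOC difference delta = soc(t1) - soc(t0), g/kg, with its
    land-cover transition code (first-letter, last-letter)."""

    site_id: str
    t0: int
    t1: int
    delta: float
    lc_pair: str

    def __post_init__(self) -> None:
        if self.t1 <= self.t0:
            raise ValueError("t0 must precede t1")

    @property
    def interval(self) -> int:
        return self.t1 - self.t0


@dataclass(frozen=True)
class SlopeTarget:
    """Theil-Sen trend beta in g/kg/yr over the series' full window."""

    site_id: str
    years: tuple[int, ...]
    beta: float
    lc_series: str


@dataclass(frozen=True)
class FilterRejection:
    site_id: str
    reason: str  # first failed criterion: visits | distance | cn_sd


def haversine_m(lon1: float, lat1: float, lon2: float, lat2: float) -> float:
    """Great-circle distance in meters (haversine, WGS84 mean radius)."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dphi = p2 - p1
    dlam = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dlam / 2) ** 2
    return 2.0 * EARTH_RADIUS_M * math.asin(min(1.0, math.sqrt(a)))


def read_samples(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
) -> tuple[list[SoilSample], list[str]]:
    """Read point samples from a CSV with header.

    dialect maps source column names onto the canonical schema, e.g.
    ``{"OC": "soc"}`` for LUCAS-style headers.  Returns the parsed samples
    and a list of row-level error messages (line number + cause); rows that
    fail type or range checks are reported, never silently dropped.
    Raises :class:`SchemaError` if a required column is missing entirely.
    """
    df = pd.read_csv(path)
    if dialect:
        df = df.rename(columns=dict(dialect))
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns and c != "cn_ratio"]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")

    samples: list[SoilSample] = []
    errors: list[str] = []
    for idx, row in df.iterrows():
        line = int(idx) + 2  # header is line 1
        try:
            cn = row.get("cn_ratio", None)
            cn_val = None if cn is None or pd.isna(cn) else float(cn)
            samples.append(
                SoilSample(
                    site_id=str(row["site_id"]),
                    lon=float(row["lon"]),
                    lat=float(row["lat"]),
                    year=int(row["year"]),
                    depth_top=float(row["depth_top"]),
                    depth_bottom=float(row["depth_bottom"]),
                    soc=float(row["soc"]),
                    cn_ratio=cn_val,
                    land_cover=str(row["land_cover"]),
                )
            )
        except (ValueError, TypeError) as exc:
            errors.append(f"line {line}: {exc}")
    return samples, errors


def write_samples(samples: Iterable[SoilSample], path: str | Path) -> None:
    pd.DataFrame([vars(s) for s in samples]).to_csv(path, index=False)


def standardize_depth(
    profile: Sequence[tuple[float, float, float]],
    target_depth: float = 10.0,
) -> float:
    """Interpolate a multi-layer profile to a single reference depth.

    Knots sit at layer midpoints; a shape-preserving cubic Hermite
    interpolant (PCHIP) is evaluated at target_depth, so the result never
    overshoots the range of the layer values.  A single layer covering the
    target depth is returned unchanged.  Requests outside the knot span
    raise rather than extrapolate.
    """
    if not profile:
        raise ValueError("profile must contain at least one layer")
    layers = sorted(profile, key=lambda t: t[0])
    for (t0, b0, _), (t1, _b1, _) in zip(layers, layers[1:]):
        if t1 < b0:
            raise ValueError("layers overlap")
    if len(layers) == 1:
        top, bottom, soc = layers[0]
        if not (top <= target_depth <= bottom):
            raise ValueError(
                f"single layer [{top}, {bottom}] does not cover {target_depth} cm"
            )
        return float(soc)

    mids = np.array([(t + b) / 2.0 for t, b, _ in layers])
    vals = np.array([s for _, _, s in layers], dtype=float)
    if not (mids[0] <= target_depth <= mids[-1]):
        raise ValueError(
            f"target depth {target_depth} outside knot span "
            f"[{mids[0]}, {mids[-1]}]; refusing to extrapolate"
        )
    return float(PchipInterpolator(mids, vals)(target_depth))


def assemble_series(samples: Iterable[SoilSample], target_depth: float = 10.0) -> list[SocSeries]:
    """Group samples by site, harmonize depths per visit, order by year.

    Visits whose profile cannot be interpolated to the reference depth are
    dropped from the series (a site keeps its remaining visits).
    """
    by_site: dict[str, dict[int, list[SoilSample]]] = {}
    for s in samples:
        by_site.setdefault(s.site_id, {}).setdefault(s.year, []).append(s)

    series: list[SocSeries] = []
    for site_id in sorted(by_site):
        visits: list[Visit] = []
        for year in sorted(by_site[site_id]):
            rows = by_site[site_id][year]
            profile = [(r.depth_top, r.depth_bottom, r.soc) for r in rows]
            try:
                soc10 = standardize_depth(profile, target_depth)
            except ValueError:
                continue
            ref = rows[0]
            visits.append(
                Visit(year, soc10, ref.lon, ref.lat, ref.cn_ratio, ref.land_cover)
            )
        if visits:
            series.append(SocSeries(site_id, tuple(visits)))
    return series


def max_pairwise_distance_m(series: SocSeries) -> float:
    """Maximum great-circle distance between any two visits of a series."""
    best = 0.0
    for a, b in itertools.combinations(series.visits, 2):
        best = max(best, haversine_m(a.lon, a.lat, b.lon, b.lat))
    return best


def filter_series(
    series: Iterable[SocSeries],
    min_visits: int = 3,
    max_dist_m: float = 30.0,
    max_cn_sd: float = 3.8,
    cn_ddof: int = 1,
    require_cn: bool = True,
) -> tuple[list[SocSeries], list[FilterRejection]]:
    """Quality-filter SOC time series on three criteria.

    A series is kept when (1) it has at least min_visits observations,
    (2) the maximum pairwise relocation distance does not exceed
    max_dist_m meters, and (3) the standard deviation (sample estimator,
    ddof configurable) of the C/N ratio across visits is below max_cn_sd.
    Rejections are tagged with the first failed criterion.  Series lacking
    C/N values fail criterion 3 conservatively unless require_cn=False,
    in which case the criterion is skipped for them.
    """
    kept: list[SocSeries] = []
    rejected: list[FilterRejection] = []
    for s in series:
        if s.n_visits < min_visits:
            rejected.append(FilterRejection(s.site_id, "visits"))
            continue
        if max_pairwise_distance_m(s) > max_dist_m:
            rejected.append(FilterRejection(s.site_id, "distance"))
            continue
        cns = [v.cn_ratio for v in s.visits]
        if any(c is None for c in cns):
            if require_cn:
                rejected.append(FilterRejection(s.site_id, "cn_sd"))
                continue
        else:
            if float(np.std(np.asarray(cns, dtype=float), ddof=cn_ddof)) >= max_cn_sd:
                rejected.append(FilterRejection(s.site_id, "cn_sd"))
                continue
        kept.append(s)
    return kept, rejected


def make_delta_targets(series: SocSeries) -> list[DeltaTarget]:
    """All ordered visit pairs of one series as observed delta targets.

    An n-visit series yields n(n-1)/2 targets: every step-to-step and
    longer-interval difference.  The land-cover pair takes the codes of
    the two endpoint visits.
    """
    out: list[DeltaTarget] = []
    for a, b in itertools.combinations(series.visits, 2):
        out.append(
            DeltaTarget(
                site_id=series.site_id,
                t0=a.year,
                t1=b.year,
                delta=b.soc - a.soc,
                lc_pair=a.land_cover + b.land_cover,
            )
        )
    return out


def theil_sen_slope(points: Sequence[tuple[float, float]]) -> float:
    """Median of all pairwise slopes (classic Theil-Sen estimator).

    Robust to outliers: up to ~29% gross errors leave the estimate
    unaffected.  Duplicate abscissae are rejected.
    """
    if len(points) < 2:
        raise ValueError("need at least two points")
    xs = [p[0] for p in points]
    if len(set(xs)) != len(xs):
        raise ValueError("duplicate years in Theil-Sen input")
    slopes = [
        (y2 - y1) / (x2 - x1)
        for (x1, y1), (x2, y2) in itertools.combinations(points, 2)
    ]
    return float(np.median(slopes))


def make_slope_targets(series: Iterable[SocSeries]) -> list[SlopeTarget]:
    """One Theil-Sen slope target per series, over its full window."""
    out: list[SlopeTarget] = []
    for s in series:
        beta = theil_sen_slope([(v.year, v.soc) for v in s.visits])
        out.append(SlopeTarget(s.site_id, s.years, beta, s.lc_code))
    return out


def split_test(
    series: Sequence[SocSeries], n_test: int, seed: int
) -> tuple[list[SocSeries], list[SocSeries]]:
    """Reproducible train/test split by whole series (site-wise)."""
    if n_test > len(series):
        raise ValueError(f"n_test={n_test} exceeds {len(series)} series")
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(series))
    test_idx = set(idx[:n_test].tolist())
    train = [s for i, s in enumerate(series) if i not in test_idx]
    test = [s for i, s in enumerate(series) if i in test_idx]
    return train, test


def targets_to_frame(
    targets: Sequence[DeltaTarget] | Sequence[SlopeTarget],
) -> pd.DataFrame:
    """Serialize targets to a flat table (one row per target)."""
    if not targets:
        return pd.DataFrame()
    if isinstance(targets[0], DeltaTarget):
        return pd.DataFrame(
            {
                "site_id": [t.site_id for t in targets],
                "t0": [t.t0 for t in targets],
                "t1": [t.t1 for t in targets],
                "interval": [t.interval for t in targets],
                "delta": [t.delta for t in targets],
                "lc_pair": [t.lc_pair for t in targets],
            }
        )
    return pd.DataFrame(
        {
            "site_id": [t.site_id for t in targets],
            "year_first": [t.years[0] for t in targets],
            "year_last": [t.years[-1] for t in targets],
            "beta": [t.beta for t in targets],
            "lc_series": [t.lc_series for t in targets],
        }
    )
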