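"""Synthetic repeated soil surveys with known ground truth.

Emulates the structure of a LUCAS-like monitoring campaign: sites on a
bounded domain, contiguous land-cover patches, a spatially autocorrelated
baseline SOC field with land-cover-dependent means, slow linear per-site
trends, and three survey rounds with visit-level relocation and analytical
noise.  The generator returns a truth table (baseline, true trend) so that
every downstream stage — filtering, target construction, model fitting, SNR
and aggregation — can be tested for parameter recovery without any real
data download.

Coordinates: sites are simulated on a planar (x_km, y_km) domain and mapped
to lon/lat around a reference point at 50 deg N, so that geodesic distances
computed downstream agree with the planar layout to well under a percent at
survey extents.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from socsnr.data_model import LAND_COVERS, SoilSample

REF_LON = 10.0
REF_LAT = 50.0
KM_PER_DEG_LAT = 111.1949  # WGS84 mean-radius arc length


@dataclass
class SimConfig:
    """Study-design parameters of the simulated survey.

    Defaults describe a LUCAS-like campaign: three rounds over nine years,
    land-cover mean SOC increasing with vegetation content (bareland to
    woodland), decadal trends of a few tenths of g/kg/yr, relocation of a
    few meters between revisits, and visit-level noise of a few g/kg.
    """

    n_sites: int = 500
    rounds: tuple[int, ...] = (2009, 2015, 2018)
    extent_km: float = 100.0
    spatial_range_km: float = 20.0
    lc_means: dict[str, float] = field(
        default_factory=lambda: {"B": 10.0, "C": 15.0, "G": 22.0, "S": 28.0, "W": 40.0}
    )
    baseline_log_sd: float = 0.45  # log-scale sd of the multiplicative anomaly
    trend_sd: float = 0.25  # g/kg/yr
    relocation_sd_m: float = 5.0
    noise_sd: float = 2.0  # g/kg, analytical + micro-scale
    cn_mean: float = 12.0
    cn_sd: float = 2.0
    cn_visit_jitter: float = 0.5
    n_lc_patches: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("baseline_log_sd", "trend_sd", "relocation_sd_m", "noise_sd", "cn_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if any(b <= a for a, b in zip(self.rounds, self.rounds[1:])):
            raise ValueError("rounds must strictly increase")
        means = [self.lc_means[c] for c in LAND_COVERS if c in self.lc_means]
        if any(b <= a for a, b in zip(means, means[1:])):
            raise ValueError("lc_means must increase along the B->C->G->S->W gradient")


def _km_to_lonlat(x_km: np.ndarray, y_km: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    lat = REF_LAT + y_km / KM_PER_DEG_LAT
    lon = REF_LON + x_km / (KM_PER_DEG_LAT * np.cos(np.radians(REF_LAT)))
    return lon, lat


def _gaussian_field(
    coords_km: np.ndarray, range_km: float, rng: np.random.Generator
) -> np.ndarray:
    """Zero-mean unit-variance GRF with exponential correlation
    exp(-3h/range) (range = effective range), by Cholesky factorization."""
    n = len(coords_km)
    if range_km <= 0:
        return rng.standard_normal(n)
    h = cdist(coords_km, coords_km)
    corr = np.exp(-3.0 * h / range_km)
    corr[np.diag_indices_from(corr)] += 1e-9  # numerical jitter
    L = np.linalg.cholesky(corr)
    return L @ rng.standard_normal(n)


def simulate_survey(config: SimConfig) -> tuple[list[SoilSample], pd.DataFrame]:
    """Simulate a repeated survey; return samples and the truth table.

    Per site: land cover by nearest-seed (Voronoi) patch assignment;
    baseline SOC = land-cover mean times a spatially correlated lognormal
    anomaly (exponential covariance on the log scale, mean-corrected —
    survey SOC is strongly right-skewed); true trend beta* ~
    N(0, trend_sd^2), bounded below so the noise-free path stays positive
    over the campaign; visit
    SOC = baseline + beta*(year - first round) + N(0, noise_sd^2),
    truncated at zero; per-visit coordinate jitter of relocation_sd_m.
    Samples carry a single 0-20 cm layer.  The truth table has one row per
    site with columns site_id, x_km, y_km, lon, lat, land_cover, baseline,
    beta_true, cn_site.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_sites

    xy = rng.uniform(0.0, config.extent_km, size=(n, 2))
    seeds = rng.uniform(0.0, config.extent_km, size=(config.n_lc_patches, 2))
    seed_lc = rng.choice(len(LAND_COVERS), size=config.n_lc_patches)
    lc_idx = seed_lc[np.argmin(cdist(xy, seeds), axis=1)]
    lc = np.array(LAND_COVERS)[lc_idx]

    # multiplicative lognormal anomaly: survey SOC is strongly right-skewed,
    # and it keeps every baseline positive; mean-corrected so that
    # E[baseline] equals the land-cover mean
    field_z = _gaussian_field(xy, config.spatial_range_km, rng)
    anomaly = np.exp(config.baseline_log_sd * field_z - config.baseline_log_sd**2 / 2)
    baseline = np.array([config.lc_means[c] for c in lc]) * anomaly
    beta_true = rng.normal(0.0, config.trend_sd, size=n)
    # a site cannot lose more carbon than it holds: bound the true trend so
    # the noise-free path stays positive over the campaign
    duration = config.rounds[-1] - config.rounds[0]
    if duration > 0:
        beta_true = np.maximum(beta_true, -0.95 * baseline / duration)
    cn_site = rng.normal(config.cn_mean, config.cn_sd, size=n)
    cn_site = np.maximum(cn_site, 1.0)

    lon0, lat0 = _km_to_lonlat(xy[:, 0], xy[:, 1])

    samples: list[SoilSample] = []
    n_truncated = 0
    t0 = config.rounds[0]
    for i in range(n):
        site_id = f"site_{i:05d}"
        for year in config.rounds:
            soc = baseline[i] + beta_true[i] * (year - t0)
            soc += rng.normal(0.0, config.noise_sd) if config.noise_sd > 0 else 0.0
            if soc < 0:
                soc = 0.0
                n_truncated += 1
            jitter_km = rng.normal(0.0, config.relocation_sd_m / 1000.0, size=2)
            lon_j, lat_j = _km_to_lonlat(
                np.array([xy[i, 0] + jitter_km[0]]), np.array([xy[i, 1] + jitter_km[1]])
            )
            cn = cn_site[i] + (
                rng.normal(0.0, config.cn_visit_jitter)
                if config.cn_visit_jitter > 0
                else 0.0
            )
            samples.append(
                SoilSample(
                    site_id=site_id,
                    lon=float(lon_j[0]),
                    lat=float(lat_j[0]),
                    year=int(year),
                    depth_top=0.0,
                    depth_bottom=20.0,
                    soc=float(soc),
                    cn_ratio=float(max(cn, 0.5)),
                    land_cover=str(lc[i]),
                )
            )

    n_visits = n * len(config.rounds)
    if n_visits and n_truncated / n_visits > 0.01:
        warnings.warn(
            f"{n_truncated}/{n_visits} visit SOC values truncated at 0; "
            "configured noise is large relative to the land-cover means",
            stacklevel=2,
        )

    truth = pd.DataFrame(
        {
            "site_id": [f"site_{i:05d}" for i in range(n)],
            "x_km": xy[:, 0],
            "y_km": xy[:, 1],
            "lon": lon0,
            "lat": lat0,
            "land_cover": lc,
            "baseline": baseline,
            "beta_true": beta_true,
            "cn_site": cn_site,
        }
    )
    return samples, truth


def simulate_covariates(
    samples: list[SoilSample],
    truth: pd.DataFrame,
    config: SimConfig,
    corr_state: float = 0.9,
    n_state: int = 3,
    corr_change: float = 0.9,
    n_annual: int = 3,
    n_noise: int = 4,
    first_year: int = 2000,
) -> pd.DataFrame:
    """Site-year covariate table for the feature-engineering stage.

    Emits three covariate kinds: ``static_*`` columns correlated with the
    baseline SOC (correlation corr_state), ``annual_*`` columns whose
    yearly values track the true SOC state (so their within-window linear
    trend correlates with beta*, strength corr_change), and ``noise_*``
    columns of pure iid noise.  Years run from first_year through the last
    survey round.  Setting corr_state = corr_change = 1 with noise columns
    off makes the state perfectly recoverable; setting both to 0 leaves no
    usable signal, so downstream change-model SNR concentrates below 1.
    """
    rng = np.random.default_rng(config.seed + 1)
    years = np.arange(first_year, config.rounds[-1] + 1)
    n = len(truth)
    t0 = config.rounds[0]

    z_base = (truth["baseline"] - truth["baseline"].mean()).to_numpy()
    sd_b = z_base.std() or 1.0
    z_base = z_base / sd_b

    rows: dict[str, np.ndarray] = {
        "site_id": np.repeat(truth["site_id"].to_numpy(), len(years)),
        "year": np.tile(years, n),
    }
    a = float(np.clip(corr_state, -1, 1))
    for j in range(n_state):
        static = a * z_base + np.sqrt(1 - a * a) * rng.standard_normal(n)
        rows[f"static_{j}"] = np.repeat(static, len(years))

    # true state on the full annual axis, standardized per column
    state = (
        truth["baseline"].to_numpy()[:, None]
        + truth["beta_true"].to_numpy()[:, None] * (years[None, :] - t0)
    )
    z_state = (state - state.mean()) / (state.std() or 1.0)
    b = float(np.clip(corr_change, -1, 1))
    for j in range(n_annual):
        noise = rng.standard_normal((n, len(years)))
        rows[f"annual_{j}"] = (b * z_state + np.sqrt(1 - b * b) * noise).ravel()

    for j in range(n_noise):
        rows[f"noise_{j}"] = rng.standard_normal(n * len(years))

    return pd.DataFrame(rows)


def simulate_error_field(
    grid_km: np.ndarray,
    variogram: "VariogramModel",
    sd_field: np.ndarray | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Standardized prediction errors on a pixel set with a prescribed
    spatial correlation.

    Draws a zero-mean unit-variance Gaussian field whose correlation at
    separation h equals rho(h) = (sill - gamma(h)) / sill from the given
    variogram: a nugget fraction of the variance is spatially independent,
    the rest follows the variogram's structured shape.  Multiplying by
    sd_field turns standardized errors into raw errors.
    """
    from socsnr.aggregation import VariogramModel  # local import, avoids cycle

    if not isinstance(variogram, VariogramModel):
        raise TypeError("variogram must be a VariogramModel")
    n = len(grid_km)
    if n > 20000:
        raise ValueError("pixel sets above 20k not supported by dense factorization")
    rng = np.random.default_rng(seed)
    sill = variogram.sill
    if sill <= 0:
        raise ValueError("variogram sill must be > 0")
    nug_frac = variogram.nugget / sill
    struct_frac = 1.0 - nug_frac

    white = rng.standard_normal(n)
    if struct_frac <= 0:
        field = white
    else:
        h = cdist(grid_km, grid_km)
        corr = variogram.correlation_shape(h)
        corr[np.diag_indices_from(corr)] = 1.0 + 1e-9
        try:
            L = np.linalg.cholesky(corr)
        except np.linalg.LinAlgError as exc:
            raise ValueError("requested correlation is not positive definite") from exc
        smooth = L @ rng.standard_normal(n)
        field = np.sqrt(nug_frac) * white + np.sqrt(struct_frac) * smooth
    if sd_field is not None:
        field = field * np.asarray(sd_field, dtype=float)
    return field
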