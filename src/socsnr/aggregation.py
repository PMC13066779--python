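"""Spatial aggregation of prediction uncertainty.

Averaging predictions over an area of interest is trivial; averaging their
uncertainty is not, because prediction errors are spatially correlated.
The route taken here: standardize cross-validation errors by their
predicted uncertainty, fit a variogram gamma(h) to the standardized errors,
convert it to a correlation function rho(h) = (sill - gamma(h)) / sill, and
propagate per-pixel standard deviations through the discretized
block-average variance

    sd_AOI = (1/B) * sqrt( sum_s sum_u  sd_s * sd_u * rho(h_su) )

with rho(0) = 1 on the diagonal and B the number of discretization pixels.
Uncorrelated errors shrink as 1/sqrt(B); perfectly correlated errors do not
shrink at all.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.spatial.distance import pdist

VARIOGRAM_FAMILIES = ("exponential", "spherical")


@dataclass(frozen=True)
class VariogramModel:
    """A bounded variogram of standardized errors.

    gamma(0) = 0, gamma rises to sill = nugget + partial_sill; range_km is
    the effective range (for the exponential family, the distance at which
    gamma reaches 95% of its structured rise; exact for the spherical).
    """

    family: str
    nugget: float
    partial_sill: float
    range_km: float
    pure_nugget: bool = False

    def __post_init__(self) -> None:
        if self.family not in VARIOGRAM_FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.nugget < 0 or self.partial_sill < 0:
            raise ValueError("nugget and partial sill must be >= 0")
        if self.range_km <= 0:
            raise ValueError("range must be > 0")

    @property
    def sill(self) -> float:
        return self.nugget + self.partial_sill

    def correlation_shape(self, h: np.ndarray) -> np.ndarray:
        """Unit-sill structured correlation shape (no nugget), in [0, 1]."""
        h = np.asarray(h, dtype=float)
        if self.family == "exponential":
            return np.exp(-3.0 * h / self.range_km)
        frac = np.clip(h / self.range_km, 0.0, 1.0)
        return 1.0 - (1.5 * frac - 0.5 * frac**3)

    def gamma(self, h: np.ndarray | float) -> np.ndarray | float:
        """Semivariance at separation h (km); gamma(0) = 0 exactly."""
        h_arr = np.atleast_1d(np.asarray(h, dtype=float))
        out = np.where(
            h_arr == 0.0,
            0.0,
            self.nugget + self.partial_sill * (1.0 - self.correlation_shape(h_arr)),
        )
        return float(out[0]) if np.ndim(h) == 0 else out


def standardized_errors(
    cv_pred: np.ndarray, cv_sd: np.ndarray, obs: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """e* = (obs - pred) / sd from cross-validation output.

    Returns (errors, valid_mask); entries with sd = 0 are excluded (NaN in
    errors, False in mask) with a warning.
    """
    cv_pred = np.asarray(cv_pred, dtype=float)
    cv_sd = np.asarray(cv_sd, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if not (len(cv_pred) == len(cv_sd) == len(obs)):
        raise ValueError("cv_pred, cv_sd and obs must have equal length")
    valid = cv_sd > 0
    if (~valid).any():
        warnings.warn(
            f"{int((~valid).sum())} site(s) with zero prediction sd excluded",
            stacklevel=2,
        )
    err = np.full(len(obs), np.nan)
    err[valid] = (obs[valid] - cv_pred[valid]) / cv_sd[valid]
    return err, valid


def empirical_variogram(
    coords_km: np.ndarray,
    values: np.ndarray,
    n_bins: int = 15,
    max_lag_km: float | None = None,
) -> pd.DataFrame:
    """Matheron semivariance estimator by distance bin.

    Bins are equal-width in [0, max_lag] (default max_lag = half the
    maximum pairwise distance).  Pairs at exactly zero separation
    (duplicate coordinates) fall in the first bin.  Returns a frame with
    bin center, semivariance and pair count.
    """
    coords_km = np.asarray(coords_km, dtype=float)
    values = np.asarray(values, dtype=float)
    d = pdist(coords_km)
    sq = pdist(values[:, None], metric="sqeuclidean") / 2.0  # (zi - zj)^2 / 2
    if max_lag_km is None:
        max_lag_km = float(d.max()) / 2.0
    edges = np.linspace(0.0, max_lag_km, n_bins + 1)
    idx = np.digitize(d, edges[1:-1])
    keep = d <= max_lag_km
    gamma = np.full(n_bins, np.nan)
    counts = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        m = keep & (idx == b)
        counts[b] = int(m.sum())
        if counts[b]:
            gamma[b] = float(sq[m].mean())
    centers = 0.5 * (edges[:-1] + edges[1:])
    return pd.DataFrame({"lag_km": centers, "gamma": gamma, "n_pairs": counts})


def fit_variogram(
    coords_km: np.ndarray,
    values: np.ndarray,
    family: str = "exponential",
    n_bins: int = 15,
    max_lag_km: float | None = None,
    min_pairs_per_bin: int = 30,
) -> VariogramModel:
    """Weighted-least-squares variogram fit to standardized errors.

    Empirical semivariances (Matheron) are fitted with Cressie weights
    n_pairs / gamma_model^2.  A fit whose structured component is
    negligible (partial sill < 5% of the sill, or range collapsing below
    the first bin) is flagged pure_nugget, signalling spatially
    uncorrelated errors.  Deterministic.
    """
    emp = empirical_variogram(coords_km, values, n_bins, max_lag_km)
    emp = emp[(emp["n_pairs"] >= min_pairs_per_bin) & emp["gamma"].notna()]
    if len(emp) < 4:
        raise ValueError(
            f"only {len(emp)} usable bins (min {min_pairs_per_bin} pairs each); "
            "not enough structure to fit"
        )
    h = emp["lag_km"].to_numpy()
    g = emp["gamma"].to_numpy()
    npairs = emp["n_pairs"].to_numpy(dtype=float)
    var_tot = float(np.nanvar(np.asarray(values, dtype=float)))

    def model(theta: np.ndarray) -> np.ndarray:
        nug, ps, rng_ = theta
        m = VariogramModel(family, max(nug, 0.0), max(ps, 0.0), max(rng_, 1e-6))
        return np.asarray(m.gamma(h))

    def resid(theta: np.ndarray) -> np.ndarray:
        gm = model(theta)
        w = np.sqrt(npairs) / np.maximum(gm, 1e-8)
        return w * (gm - g)

    x0 = np.array([0.5 * var_tot, 0.5 * var_tot, h[len(h) // 2]])
    bounds = ([0.0, 0.0, 1e-6], [np.inf, np.inf, 10.0 * h[-1]])
    sol = least_squares(resid, x0, bounds=bounds, max_nfev=5000)
    if not sol.success:
        raise RuntimeError(
            f"variogram fit did not converge: {sol.message}\nbins:\n{emp.to_string()}"
        )
    nug, ps, rng_ = sol.x
    sill = nug + ps
    pure = bool(sill > 0 and (ps / sill < 0.05 or rng_ < h[0]))
    return VariogramModel(family, float(nug), float(ps), float(max(rng_, 1e-6)), pure)


def correlation_from_variogram(
    model: VariogramModel, h: np.ndarray | float
) -> np.ndarray | float:
    """rho(h) = (sill - gamma(h)) / sill; rho(0) = 1 since gamma(0) = 0."""
    if model.sill <= 0:
        raise ValueError("sill must be > 0 to define a correlation")
    h_arr = np.atleast_1d(np.asarray(h, dtype=float))
    if (h_arr < 0).any():
        raise ValueError("separation distances must be >= 0")
    rho = (model.sill - np.asarray(model.gamma(h_arr))) / model.sill
    rho = np.clip(rho, 0.0, 1.0)
    return float(rho[0]) if np.ndim(h) == 0 else rho


@dataclass
class GridUnit:
    """One aggregation cell: discretization pixels with prediction and sd."""

    cell_id: str
    support_km: float
    pixels_km: np.ndarray  # (B, 2) centers
    predictions: np.ndarray  # (B,) signal component
    sds: np.ndarray  # (B,) per-pixel uncertainty

    def __post_init__(self) -> None:
        self.pixels_km = np.asarray(self.pixels_km, dtype=float)
        self.predictions = np.asarray(self.predictions, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        if len(self.pixels_km) < 1:
            raise ValueError("a grid unit needs at least one pixel")
        if (self.sds < 0).any():
            raise ValueError("pixel sds must be >= 0")

    @property
    def B(self) -> int:
        return len(self.pixels_km)


def aggregate_signal(unit: GridUnit) -> float:
    """Arithmetic mean of pixel predictions (the block average)."""
    return float(unit.predictions.mean())


def _rho_fn(model) -> "callable":
    """Accept a VariogramModel or a plain correlation function h -> rho."""
    if isinstance(model, VariogramModel):
        return lambda h: np.asarray(correlation_from_variogram(model, h))
    if callable(model):
        return lambda h: np.asarray(model(np.asarray(h, dtype=float)))
    raise TypeError("model must be a VariogramModel or a callable rho(h)")


def aggregate_sd(
    unit: GridUnit,
    model: VariogramModel,
    max_exact_b: int = 50_000,
    n_pair_samples: int = 2_000_000,
    seed: int = 0,
    chunk: int = 1_000,
) -> float:
    """Block-aggregate uncertainty via the discretized double sum.

    sd_AOI = (1/B) sqrt(sum_s sum_u sd_s sd_u rho(h_su)), rho(0) = 1 on
    the diagonal.  model is a VariogramModel or any correlation function
    h -> rho.  Exact (chunked) evaluation up to max_exact_b pixels; beyond
    that the off-diagonal sum is estimated by uniform random pair
    subsampling under the given seed.
    """
    rho_of = _rho_fn(model)
    B = unit.B
    sd = unit.sds
    if B == 1:
        return float(sd[0])
    if B <= max_exact_b:
        total = 0.0
        for i0 in range(0, B, chunk):
            i1 = min(i0 + chunk, B)
            d = np.sqrt(
                ((unit.pixels_km[i0:i1, None, :] - unit.pixels_km[None, :, :]) ** 2).sum(
                    axis=2
                )
            )
            rho = rho_of(d.ravel()).reshape(d.shape)
            # exact rho(0)=1 on the true diagonal
            for r in range(i0, i1):
                rho[r - i0, r] = 1.0
            total += float(sd[i0:i1] @ rho @ sd)
        return math.sqrt(max(total, 0.0)) / B
    # subsampled estimator of the off-diagonal mean
    rng = np.random.default_rng(seed)
    ii = rng.integers(0, B, size=n_pair_samples)
    jj = rng.integers(0, B, size=n_pair_samples)
    off = ii != jj
    ii, jj = ii[off], jj[off]
    d = np.sqrt(((unit.pixels_km[ii] - unit.pixels_km[jj]) ** 2).sum(axis=1))
    rho = rho_of(d)
    mean_off = float(np.mean(sd[ii] * sd[jj] * rho))
    total = float((sd**2).sum()) + B * (B - 1) * mean_off
    return math.sqrt(max(total, 0.0)) / B


def snr_grid(
    pixels: pd.DataFrame,
    model: VariogramModel,
    supports_km: list[float],
    pixel_size_km: float,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Multi-support aggregation of a regular prediction grid.

    pixels: columns x_km, y_km, prediction, sd on a regular grid of the
    given pixel size.  For each support the domain is tiled into square
    cells; per cell the aggregate signal |mean prediction|, aggregate
    noise (block sd) and their ratio are computed.  Returns (per-cell
    table, per-support summary with median and IQR).
    """
    for s in supports_km:
        if s < pixel_size_km:
            raise ValueError(
                f"support {s} km smaller than pixel size {pixel_size_km} km"
            )
    x = pixels["x_km"].to_numpy(dtype=float)
    y = pixels["y_km"].to_numpy(dtype=float)
    pred = pixels["prediction"].to_numpy(dtype=float)
    sd = pixels["sd"].to_numpy(dtype=float)
    x0, y0 = x.min(), y.min()

    cells = []
    for support in supports_km:
        cx = np.floor((x - x0) / support).astype(int)
        cy = np.floor((y - y0) / support).astype(int)
        for (i, j) in sorted(set(zip(cx.tolist(), cy.tolist()))):
            m = (cx == i) & (cy == j)
            unit = GridUnit(
                cell_id=f"s{support:g}_{i}_{j}",
                support_km=support,
                pixels_km=np.column_stack([x[m], y[m]]),
                predictions=pred[m],
                sds=sd[m],
            )
            signal = abs(aggregate_signal(unit))
            noise = aggregate_sd(unit, model, seed=seed)
            cells.append(
                {
                    "cell_id": unit.cell_id,
                    "support_km": support,
                    "B": unit.B,
                    "signal": signal,
                    "noise": noise,
                    "snr": signal / noise if noise > 0 else np.inf,
                }
            )
    table = pd.DataFrame(cells)
    summary = (
        table.groupby("support_km")
        .agg(
            n_cells=("cell_id", "size"),
            median_B=("B", "median"),
            snr_median=("snr", "median"),
            snr_q25=("snr", lambda v: v.quantile(0.25)),
            snr_q75=("snr", lambda v: v.quantile(0.75)),
            noise_median=("noise", "median"),
            signal_median=("signal", "median"),
        )
        .reset_index()
    )
    return table, summary
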