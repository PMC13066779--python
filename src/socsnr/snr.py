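"""The signal-to-noise engine.

SNR = |predicted value| / modeled prediction uncertainty, an internal
detectability diagnostic: SNR > 1 means the modeled change exceeds its own
uncertainty.  Five scenarios are covered.  Change-first: the change model's
own pooled-leaf distribution supplies both signal (mean) and noise (sd) —
this applies identically to the c, delta and beta models predicting their
direct target.  State-first: change is derived from state predictions;
noise for delta propagates the two state variances under independence,
noise for beta comes from a Monte-Carlo over slopes fitted to values drawn
from each time step's prediction distribution.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from socsnr.data_model import LAND_COVERS
from socsnr.forest import PredictionDistribution

_GRADIENT = {c: i for i, c in enumerate(LAND_COVERS)}  # B < C < G < S < W


class DegenerateDistributionError(ValueError):
    """Zero-spread prediction distribution: SNR is undefined."""


@dataclass(frozen=True)
class SnrResult:
    target_kind: str  # c | delta | beta
    approach: str  # direct | state_first
    signal: float
    noise: float
    snr: float
    site_id: str | None = None
    window: tuple[int, ...] | None = None
    lc_code: str | None = None
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.signal < 0:
            raise ValueError("signal must be >= 0 (absolute magnitude)")
        if not self.degenerate and self.noise <= 0:
            raise ValueError("noise must be > 0 for a non-degenerate result")


def _result(target, approach, signal, noise, allow_degenerate, **meta) -> SnrResult:
    if noise <= 0:
        if not allow_degenerate:
            raise DegenerateDistributionError(
                f"{approach} {target}: zero noise, SNR undefined"
            )
        return SnrResult(target, approach, signal, 0.0, math.inf, degenerate=True, **meta)
    return SnrResult(target, approach, signal, noise, signal / noise, **meta)


def snr_direct(
    dist: PredictionDistribution,
    target_kind: str = "c",
    allow_degenerate: bool = False,
    **meta,
) -> SnrResult:
    """SNR of a model predicting its direct target.

    Signal = |pooled mean|, noise = pooled standard deviation.  Applies to
    the state, pairwise-change and slope models alike (the diagonal of the
    scenario table).
    """
    return _result(
        target_kind, "direct", abs(dist.mean), dist.sd, allow_degenerate, **meta
    )


def snr_state_first_delta(
    dist_t0: PredictionDistribution,
    dist_t1: PredictionDistribution,
    allow_degenerate: bool = False,
    **meta,
) -> SnrResult:
    """SNR of a state-derived pairwise change.

    Signal = |mean(t1) - mean(t0)|; noise = sqrt(sd0^2 + sd1^2), treating
    the two state predictions as independent.
    """
    signal = abs(dist_t1.mean - dist_t0.mean)
    noise = math.hypot(dist_t0.sd, dist_t1.sd)
    return _result("delta", "state_first", signal, noise, allow_degenerate, **meta)


def _ols_slope(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    return float((xc @ (y - y.mean())) / (xc @ xc))


def snr_state_first_beta(
    dists: Sequence[PredictionDistribution],
    years: Sequence[float],
    n_draws: int = 200,
    seed: int = 0,
    allow_degenerate: bool = False,
    **meta,
) -> SnrResult:
    """SNR of a state-derived trend slope with Monte-Carlo noise.

    Signal = |OLS slope through the per-step distribution means|.  Noise:
    repeat n_draws times — draw one value uniformly at random from each
    step's pooled values, fit an OLS slope — and take the standard
    deviation of the resulting slope sample.
    """
    if len(dists) < 3:
        raise ValueError("state-first beta needs >= 3 time steps")
    years_arr = np.asarray(years, dtype=float)
    if len(set(years_arr.tolist())) != len(years_arr):
        raise ValueError("years must be distinct")
    if len(years_arr) != len(dists):
        raise ValueError("one distribution per time step required")

    means = np.array([d.mean for d in dists])
    signal = abs(_ols_slope(years_arr, means))

    rng = np.random.default_rng(seed)
    draws = np.column_stack([d.sample(n_draws, rng) for d in dists])
    xc = years_arr - years_arr.mean()
    sxx = float(xc @ xc)
    slopes = (draws - draws.mean(axis=1, keepdims=True)) @ xc / sxx
    noise = float(slopes.std(ddof=1))
    return _result("beta", "state_first", signal, noise, allow_degenerate, **meta)


def relative_absolute_error(pred: float, obs: float) -> float:
    """|pred - obs| / |obs|; undefined at obs = 0."""
    if obs == 0:
        raise ValueError("RAE undefined for a zero observation")
    return abs(pred - obs) / abs(obs)


def batch_rae(pred: np.ndarray, obs: np.ndarray) -> np.ndarray:
    """Vectorized RAE; zero observations are excluded (NaN) with a warning."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    out = np.full(len(obs), np.nan)
    nz = obs != 0
    if (~nz).any():
        warnings.warn(
            f"{int((~nz).sum())} zero observation(s) excluded from RAE",
            stacklevel=2,
        )
    out[nz] = np.abs(pred[nz] - obs[nz]) / np.abs(obs[nz])
    return out


def snr_rae_association(
    snr_values: Sequence[float],
    rae_values: Sequence[float],
    rae_threshold: float = 1.0,
) -> dict:
    """Spearman rank correlation between SNR and RAE plus quadrant counts.

    Quadrants split at SNR = 1 (detectable vs not) and a configurable RAE
    threshold (accurate vs not); ties in ranks use average ranks.
    """
    snr_arr = np.asarray(snr_values, dtype=float)
    rae_arr = np.asarray(rae_values, dtype=float)
    ok = np.isfinite(snr_arr) & np.isfinite(rae_arr)
    snr_arr, rae_arr = snr_arr[ok], rae_arr[ok]
    if len(snr_arr) < 3:
        raise ValueError("need >= 3 finite (SNR, RAE) pairs")
    rho, pval = stats.spearmanr(snr_arr, rae_arr)
    hi_snr = snr_arr >= 1.0
    hi_rae = rae_arr >= rae_threshold
    quadrants = {
        "high_snr_high_rae": int(np.sum(hi_snr & hi_rae)),
        "high_snr_low_rae": int(np.sum(hi_snr & ~hi_rae)),
        "low_snr_high_rae": int(np.sum(~hi_snr & hi_rae)),
        "low_snr_low_rae": int(np.sum(~hi_snr & ~hi_rae)),
    }
    return {"spearman_rho": float(rho), "p_value": float(pval), "quadrants": quadrants}


def transition_group(lc_code: str) -> str:
    """Classify a land-cover code along the vegetation gradient.

    Same letters throughout -> 'no_change'; an endpoint later in the
    B->C->G->S->W ordering than the start -> 'increasing'; earlier ->
    'decreasing'.  Unknown letters raise.
    """
    for ch in lc_code:
        if ch not in _GRADIENT:
            raise ValueError(f"unknown land-cover code {ch!r} in {lc_code!r}")
    first, last = _GRADIENT[lc_code[0]], _GRADIENT[lc_code[-1]]
    if len(set(lc_code)) == 1:
        return "no_change"
    if last > first:
        return "increasing"
    if last < first:
        return "decreasing"
    return "no_change"  # e.g. CGC: endpoints equal


def stratify_by_landcover(
    results: Sequence[SnrResult], mode: str = "pair"
) -> pd.DataFrame:
    """Grouped summaries of signal, noise and SNR.

    mode='state' groups by the single land-cover letter; 'pair' and
    'series' group by the vegetation-gradient transition category derived
    from the code's endpoints.  Per group: count, median and 5th/95th
    percentiles of signal, noise and SNR (degenerate results excluded from
    SNR statistics).
    """
    if mode not in ("state", "pair", "series"):
        raise ValueError(f"unknown mode {mode!r}")
    rows = []
    for r in results:
        if r.lc_code is None:
            raise ValueError("results must carry lc_code for stratification")
        group = r.lc_code if mode == "state" else transition_group(r.lc_code)
        rows.append(
            {
                "group": group,
                "lc_code": r.lc_code,
                "signal": r.signal,
                "noise": r.noise,
                "snr": r.snr if not r.degenerate else np.nan,
            }
        )
    df = pd.DataFrame(rows)
    agg = df.groupby("group").agg(
        count=("signal", "size"),
        signal_median=("signal", "median"),
        signal_q5=("signal", lambda v: v.quantile(0.05)),
        signal_q95=("signal", lambda v: v.quantile(0.95)),
        noise_median=("noise", "median"),
        noise_q5=("noise", lambda v: v.quantile(0.05)),
        noise_q95=("noise", lambda v: v.quantile(0.95)),
        snr_median=("snr", "median"),
        snr_q5=("snr", lambda v: v.quantile(0.05)),
        snr_q95=("snr", lambda v: v.quantile(0.95)),
    )
    return agg.reset_index()
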