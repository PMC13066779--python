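"""Accuracy and uncertainty-calibration diagnostics.

Point accuracy: MAE, bias and Lin's concordance correlation coefficient.
Calibration of the pooled-leaf uncertainty: PICP (fraction of observations
inside symmetric prediction intervals, per nominal level) and QCP (fraction
of observations at or below single predicted quantiles, probing asymmetry),
plus interval sharpness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_LEVELS = tuple(np.round(np.arange(0.05, 0.96, 0.05), 2))


@dataclass(frozen=True)
class CalibrationCurve:
    """Observed coverage against nominal levels for one diagnostic."""

    levels: tuple[float, ...]
    coverage: tuple[float, ...]
    n: int
    kind: str  # PICP | QCP

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.levels, self.levels[1:])):
            raise ValueError("levels must strictly increase")
        if any(not (0.0 <= c <= 1.0) for c in self.coverage):
            raise ValueError("coverage must lie in [0, 1]")

    def rms_deviation(self) -> float:
        """Root-mean-square distance of the curve from the diagonal."""
        lv = np.asarray(self.levels)
        cv = np.asarray(self.coverage)
        return float(np.sqrt(np.mean((cv - lv) ** 2)))


def accuracy_metrics(pred: np.ndarray, obs: np.ndarray) -> dict[str, float]:
    """MAE, bias (pred - obs) and concordance correlation coefficient.

    CCC = 2 cov(pred, obs) / (var(pred) + var(obs) + (mean difference)^2)
    with population moments; it penalizes both scatter and systematic
    location/scale shifts, so CCC = 1 only on the identity line.
    """
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if len(pred) != len(obs) or len(pred) < 2:
        raise ValueError("need >= 2 paired values")
    mae = float(np.mean(np.abs(pred - obs)))
    bias = float(np.mean(pred - obs))
    vp, vo = pred.var(ddof=0), obs.var(ddof=0)
    dm = pred.mean() - obs.mean()
    denom = vp + vo + dm * dm
    if denom == 0:
        raise ValueError("CCC undefined: both sequences constant and equal")
    cov = float(np.mean((pred - pred.mean()) * (obs - obs.mean())))
    return {"MAE": mae, "bias": bias, "CCC": float(2.0 * cov / denom)}


def picp(
    intervals_per_level: dict[float, np.ndarray], obs: np.ndarray
) -> CalibrationCurve:
    """Prediction-interval coverage probability per nominal level.

    intervals_per_level maps a nominal coverage level to an (n, 2) array of
    [lower, upper]; coverage counts observations inside the closed interval
    (ties covered — relevant for discrete pooled distributions).
    """
    obs = np.asarray(obs, dtype=float)
    levels = sorted(intervals_per_level)
    coverage = []
    for lv in levels:
        iv = np.asarray(intervals_per_level[lv], dtype=float)
        if iv.shape != (len(obs), 2):
            raise ValueError(
                f"level {lv}: expected {(len(obs), 2)} interval array, got {iv.shape}"
            )
        inside = (obs >= iv[:, 0]) & (obs <= iv[:, 1])
        coverage.append(float(inside.mean()))
    return CalibrationCurve(tuple(levels), tuple(coverage), len(obs), "PICP")


def qcp(quantiles_per_q: dict[float, np.ndarray], obs: np.ndarray) -> CalibrationCurve:
    """Quantile coverage probability: share of observations <= the
    predicted q-quantile, per q.  Deviations asymmetric around q = 0.5
    reveal skewed uncertainty distributions."""
    obs = np.asarray(obs, dtype=float)
    qs = sorted(quantiles_per_q)
    coverage = []
    for q in qs:
        pred_q = np.asarray(quantiles_per_q[q], dtype=float)
        if len(pred_q) != len(obs):
            raise ValueError(f"q={q}: length mismatch {len(pred_q)} vs {len(obs)}")
        coverage.append(float((obs <= pred_q).mean()))
    return CalibrationCurve(tuple(qs), tuple(coverage), len(obs), "QCP")


def sharpness(intervals: np.ndarray) -> dict[str, float]:
    """Mean and SD of interval widths at one nominal level."""
    iv = np.asarray(intervals, dtype=float)
    if iv.ndim != 2 or iv.shape[1] != 2:
        raise ValueError("expected an (n, 2) interval array")
    widths = iv[:, 1] - iv[:, 0]
    return {"mean_width": float(widths.mean()), "sd_width": float(widths.std(ddof=0))}
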