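"""Cohort statistics: correlations with Fisher-z intervals, correlation
comparison, linear calibration and Bland–Altman agreement summaries.

The Fisher z transform z = atanh(r) is approximately normal with standard
error 1/√(n−3), giving the confidence interval
tanh(atanh(r) ± z_q/√(n−3)) and the two-sample comparison statistic
z = (atanh r₁ − atanh r₂)/√(1/(n₁−3) + 1/(n₂−3)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import AnalysisError

__all__ = [
    "CohortResult",
    "pearson_with_ci",
    "fisher_ci",
    "compare_correlations_fisher",
    "linear_calibration",
    "bland_altman",
    "summarize_cohort",
]


def pearson_with_ci(
    x: np.ndarray, y: np.ndarray, confidence: float = 95.0
) -> tuple[float, float, float]:
    """Pearson r with a Fisher-z confidence interval.

    ``confidence`` is a percentage (default 95). Requires n >= 4, finite
    values and nonzero variance in both arrays. For |r| = 1 the interval
    collapses onto r.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise AnalysisError("x and y must be equal-length 1-D arrays")
    if x.size < 4:
        raise AnalysisError("need at least 4 pairs for a Fisher-z interval")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise AnalysisError("inputs must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        raise AnalysisError("correlation undefined for zero-variance input")
    r = float(stats.pearsonr(x, y).statistic)
    if abs(r) >= 1.0:
        return r, r, r
    zq = float(stats.norm.ppf(0.5 + confidence / 200.0))
    se = 1.0 / math.sqrt(x.size - 3)
    z = math.atanh(r)
    return r, math.tanh(z - zq * se), math.tanh(z + zq * se)


def fisher_ci(r: float, n: int, confidence: float = 95.0) -> tuple[float, float]:
    """Fisher-z confidence interval for a given r and sample size."""
    if not -1.0 < r < 1.0:
        raise AnalysisError("r must lie strictly inside (-1, 1)")
    if n <= 3:
        raise AnalysisError("need n > 3")
    zq = float(stats.norm.ppf(0.5 + confidence / 200.0))
    se = 1.0 / math.sqrt(n - 3)
    z = math.atanh(r)
    return math.tanh(z - zq * se), math.tanh(z + zq * se)


def compare_correlations_fisher(
    r1: float, n1: int, r2: float, n2: int
) -> tuple[float, float]:
    """Two-sided Fisher z-test for the difference of two correlations.

    Returns (z statistic, two-sided p). Antisymmetric in the pair order;
    p is unchanged under a swap.
    """
    for r, n in ((r1, n1), (r2, n2)):
        if not -1.0 < r < 1.0:
            raise AnalysisError("correlations must lie strictly inside (-1, 1)")
        if n <= 3:
            raise AnalysisError("need n > 3 in both samples")
    z = (math.atanh(r1) - math.atanh(r2)) \
        / math.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    p = float(2.0 * stats.norm.sf(abs(z)))
    return z, p


def linear_calibration(
    predicted: np.ndarray, observed: np.ndarray
) -> tuple[float, float, np.ndarray]:
    """Ordinary least squares observed ~ predicted; returns
    (slope, intercept, corrected) with corrected = slope·predicted + intercept.

    In practice the torque model would be calibrated against bench data; this
    is that in-sample calibration step.
    """
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape or predicted.size < 2:
        raise AnalysisError("need >= 2 equal-length pairs")
    slope, intercept = np.polyfit(predicted, observed, 1)
    return float(slope), float(intercept), slope * predicted + intercept


def bland_altman(
    a: np.ndarray, b: np.ndarray, relative: bool = False
) -> dict[str, float]:
    """Bland–Altman agreement of paired measurements ``a`` (estimate) vs.
    ``b`` (reference).

    Differences are a − b, or 100·(a − b)/mean(a, b) in relative mode (the
    conventional percentage-of-pair-mean form). Returns bias, 1.96·SD limits
    of agreement, and the mean absolute relative error in percent with the
    *reference* as denominator (mean |a − b| / b · 100) — reported separately
    because the two relative conventions differ.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size == 0:
        raise AnalysisError("a and b must be equal-length 1-D arrays")
    diff = a - b
    if relative:
        pair_mean = (a + b) / 2.0
        if np.any(pair_mean == 0):
            raise AnalysisError("relative mode requires nonzero pair means")
        diff = 100.0 * diff / pair_mean
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1)) if diff.size > 1 else 0.0
    if np.any(b <= 0):
        raise AnalysisError("reference values must be > 0 for relative error")
    mare = float(np.mean(np.abs(a - b) / b) * 100.0)
    return {
        "bias": bias,
        "loa_low": bias - 1.96 * sd,
        "loa_high": bias + 1.96 * sd,
        "mean_abs_relative_error_pct": mare,
    }


@dataclass
class CohortResult:
    """Per-insertion records plus the summary statistics of a cohort run."""

    records: pd.DataFrame
    summary: dict[str, Any] = field(default_factory=dict)
    failures: list[dict[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        required = {"material", "sigma_hat", "tau_pred_no_kt",
                    "tau_pred_kt", "tau_true"}
        missing = required - set(self.records.columns)
        if missing:
            raise AnalysisError(f"records missing columns {sorted(missing)}")


def summarize_cohort(records: pd.DataFrame,
                     confidence: float = 95.0) -> dict[str, Any]:
    """Summary statistics for a cohort of predicted vs. measured torques.

    Computes Pearson r with Fisher-z CI, an in-sample linear calibration of
    the uncorrected prediction, and Bland–Altman summaries of the calibrated
    prediction against the measured stripping torque (absolute and relative).
    """
    pred = records["tau_pred_no_kt"].to_numpy(dtype=float)
    true = records["tau_true"].to_numpy(dtype=float)
    r, lo, hi = pearson_with_ci(pred, true, confidence)
    slope, intercept, corrected = linear_calibration(pred, true)
    ba_abs = bland_altman(corrected, true, relative=False)
    ba_rel = bland_altman(corrected, true, relative=True)
    return {
        "n": int(len(records)),
        "r": r,
        "r_ci_low": lo,
        "r_ci_high": hi,
        "confidence_pct": confidence,
        "calibration_slope": slope,
        "calibration_intercept": intercept,
        "mean_abs_relative_error_pct": ba_abs["mean_abs_relative_error_pct"],
        "bland_altman_absolute": ba_abs,
        "bland_altman_relative": ba_rel,
    }
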