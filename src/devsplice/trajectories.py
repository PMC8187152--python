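"""PSI trajectory fitting, dPSI, and temporal pattern classification.

PSI as a function of log-age is smoothed with a cubic B-spline basis of
four degrees of freedom (one interior knot at the median age, plus
intercept).  dPSI is the max - min of the predictions at the sampled ages.
Patterns are derived from the fitted curve evaluated on a 1,000-point
evenly spaced grid over the observed age range: the sums of positive and
negative step changes ("up"/"down"), their age-weighted mean timings, and
threshold rules on up/(up+down) yield the classes up, down, up-down and
down-up.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

__all__ = [
    "PatternStats",
    "TrajectoryFit",
    "birth_timing",
    "call_devas",
    "call_devas_dpsi_only",
    "classify_pattern",
    "fit_psi_spline",
    "stage_change_counts",
]

#: Number of evenly spaced grid points used for pattern statistics.
PATTERN_GRID_POINTS = 1000


class InsufficientDataError(ValueError):
    pass


@dataclass
class TrajectoryFit:
    """Least-squares cubic-spline fit of PSI on log-age."""

    knots: np.ndarray
    coefficients: np.ndarray
    a_min: float
    a_max: float
    sample_ages: np.ndarray
    predictions: np.ndarray  # clipped predictions at the sample ages

    @property
    def dpsi(self) -> float:
        return float(self.predictions.max() - self.predictions.min())

    def predict(self, ages: Sequence[float]) -> np.ndarray:
        ages = np.clip(np.asarray(ages, dtype=float), self.a_min, self.a_max)
        spl = BSpline(self.knots, self.coefficients, 3, extrapolate=False)
        return np.clip(spl(ages), 0.0, 1.0)


@dataclass
class PatternStats:
    up: float
    down: float
    up_timing: float  # nan when up == 0
    down_timing: float  # nan when down == 0
    pattern: str  # up | down | up-down | down-up | none

    @property
    def ratio(self) -> float:
        total = self.up + self.down
        return self.up / total if total > 0 else math.nan


def _spline_basis(ages: np.ndarray, knots: np.ndarray) -> np.ndarray:
    return BSpline.design_matrix(ages, knots, 3, extrapolate=False).toarray()


def fit_psi_spline(
    psi: Sequence[float],
    ages: Sequence[float],
    interior_knots: Optional[Sequence[float]] = None,
) -> TrajectoryFit:
    """Fit PSI on a cubic B-spline basis with 4 df (default: 1 interior knot
    at the median age).

    Requires >= 5 defined PSI points over >= 2 distinct ages.  Predictions
    are clipped to [0, 1].
    """
    psi = np.asarray(psi, dtype=float)
    ages = np.asarray(ages, dtype=float)
    mask = ~np.isnan(psi)
    psi, ages = psi[mask], ages[mask]
    if psi.size < 5:
        raise InsufficientDataError("at least 5 defined PSI points required")
    if np.unique(ages).size < 2:
        raise InsufficientDataError("at least 2 distinct ages required")
    a_min, a_max = float(ages.min()), float(ages.max())
    if interior_knots is None:
        interior_knots = [float(np.median(ages))]
    interior = sorted(float(k) for k in interior_knots)
    if any(not (a_min < k < a_max) for k in interior):
        # degenerate designs (median at a boundary): drop offending knots
        interior = [k for k in interior if a_min < k < a_max]
    knots = np.concatenate([[a_min] * 4, interior, [a_max] * 4])
    B = _spline_basis(ages, knots)
    coef, *_ = np.linalg.lstsq(B, psi, rcond=None)
    fit = TrajectoryFit(
        knots=knots,
        coefficients=coef,
        a_min=a_min,
        a_max=a_max,
        sample_ages=ages,
        predictions=np.empty(0),
    )
    fit.predictions = fit.predict(ages)
    return fit


def classify_pattern(
    fit: TrajectoryFit, n_grid: int = PATTERN_GRID_POINTS
) -> PatternStats:
    """Derive up/down amounts, timings and the temporal pattern class.

    The fitted curve is evaluated at ``n_grid`` evenly spaced log-ages over
    the observed range.  Step changes between consecutive grid points are
    split into positive and negative sums; timings are the age-weighted
    means of the steps (weights at each step's right endpoint).  Rules:
    up/(up+down) < 0.3 -> down; > 0.7 -> up; otherwise up-down when
    up_timing < down_timing, else down-up.  Flat curves (up+down = 0) are
    reported as pattern "none".
    """
    grid = np.linspace(fit.a_min, fit.a_max, n_grid)
    vals = fit.predict(grid)
    steps = np.diff(vals)
    ages = grid[1:]
    pos = steps > 0
    neg = steps < 0
    up = float(steps[pos].sum())
    down = float(-steps[neg].sum())
    up_timing = float((steps[pos] * ages[pos]).sum() / up) if up > 0 else math.nan
    down_timing = (
        float((-steps[neg] * ages[neg]).sum() / down) if down > 0 else math.nan
    )
    if up + down < 1e-9:  # numerically flat fit
        up = down = 0.0
        up_timing = down_timing = math.nan
    total = up + down
    if total == 0:
        pattern = "none"
    else:
        ratio = up / total
        if ratio < 0.3:
            pattern = "down"
        elif ratio > 0.7:
            pattern = "up"
        elif up_timing < down_timing:
            pattern = "up-down"
        else:
            pattern = "down-up"
    return PatternStats(
        up=up, down=down, up_timing=up_timing, down_timing=down_timing, pattern=pattern
    )


def call_devas(padj: float, dpsi: float, alpha: float = 0.05, min_dpsi: float = 0.2) -> bool:
    """devAS call: adjusted p < alpha AND dPSI strictly greater than min_dpsi."""
    return padj < alpha and dpsi > min_dpsi


def call_devas_dpsi_only(dpsi: float, threshold: float = 0.0) -> bool:
    """Test-free devAS variant: dPSI strictly greater than the threshold."""
    return dpsi > threshold


def birth_timing(psi_earliest: float, psi_newborn: float, psi_last: float) -> str:
    """Classify whether the bulk of PSI change happens before or after birth.

    "before_birth" iff |newborn - earliest| is strictly greater than
    |last - newborn|.
    """
    before = abs(psi_newborn - psi_earliest)
    after = abs(psi_last - psi_newborn)
    return "before_birth" if before > after else "after_birth"


def stage_change_counts(
    stage_psi: pd.DataFrame, min_change: float = 0.2
) -> pd.Series:
    """Count devAS exons changing between consecutive developmental stages.

    ``stage_psi`` is exons x ordered stages (columns in developmental
    order), entries = per-stage mean PSI.  For each consecutive stage pair
    the number of exons with |delta PSI| strictly greater than
    ``min_change`` is returned, indexed "stage1->stage2".
    """
    cols = list(stage_psi.columns)
    counts = {}
    for s1, s2 in zip(cols, cols[1:]):
        delta = (stage_psi[s2] - stage_psi[s1]).abs()
        counts[f"{s1}->{s2}"] = int((delta > min_change).sum())
    return pd.Series(counts)
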