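"""Survival statistics on empirical or simulated data.

Includes the median survival age (T50) by interpolation of a life
table, the Smurf Increase Rate (SIR) — the ordinary least-squares slope
of the per-vial living phase-2 proportion against chronological age —
its model-implied theoretical counterpart, a slope-equality test
between two SIR regressions, rank tests on median lifespans, and
population-mean biomarker trajectories implied by two-phase mixing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .lifetable import LifeTable
from .model import smurf_count, total_survival
from .params import ModelParams

__all__ = [
    "SIRResult",
    "empirical_t50",
    "sir",
    "theoretical_sir",
    "compare_sir",
    "mixture_trajectory",
    "compare_medians",
]


@dataclass(frozen=True)
class SIRResult:
    """OLS regression of living phase-2 proportion on age.

    ``slope`` is the Smurf Increase Rate (per day). The sufficient
    statistics ``sxx`` (centered sum of squares of age) and ``ss_res``
    (residual sum of squares) are retained so that two regressions can
    be compared without the raw points.
    """

    slope: float
    stderr: float
    intercept: float
    r_squared: float
    n_points: int
    sxx: float
    ss_res: float
    pearson_p: float = math.nan

    def __post_init__(self) -> None:
        if self.n_points < 3:
            raise ValueError("SIR regression needs >= 3 points")
        if self.stderr < 0:
            raise ValueError("stderr must be non-negative")


def empirical_t50(table: LifeTable) -> float:
    """Median survival age of the pooled population, days.

    Linear interpolation between the two observed ages bracketing the
    50% survival fraction. Raises if survival never reaches 50%.
    """
    pooled = table.pooled_survival()
    ages = pooled["age"].to_numpy()
    frac = pooled["fraction"].to_numpy()
    below = np.nonzero(frac <= 0.5)[0]
    if len(below) == 0:
        raise ValueError("survival never reaches 50%; T50 is right-censored")
    j = below[0]
    if frac[j] == 0.5 or j == 0:
        return float(ages[j])
    i = j - 1
    return float(ages[i] + (0.5 - frac[i]) * (ages[j] - ages[i]) / (frac[j] - frac[i]))


def _ols(x: np.ndarray, y: np.ndarray, flag_zero: bool = True) -> SIRResult:
    n = len(x)
    if n < 3:
        raise ValueError(f"regression needs >= 3 points, got {n}")
    res = stats.linregress(x, y)
    pred = res.intercept + res.slope * x
    ss_res = float(np.sum((y - pred) ** 2))
    sxx = float(np.sum((x - x.mean()) ** 2))
    if np.allclose(y, 0) and flag_zero:
        # all-zero proportions: slope 0, no information about onset
        return SIRResult(slope=0.0, stderr=float(res.stderr), intercept=0.0,
                         r_squared=0.0, n_points=n, sxx=sxx, ss_res=ss_res, pearson_p=1.0)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return SIRResult(
        slope=float(res.slope),
        stderr=float(res.stderr),
        intercept=float(res.intercept),
        r_squared=r2,
        n_points=n,
        sxx=sxx,
        ss_res=ss_res,
        pearson_p=float(res.pvalue),
    )


def sir(table: LifeTable) -> SIRResult:
    """Smurf Increase Rate from per-vial proportions.

    Each (vial, age) pair contributes one point: the proportion of
    living flies in that vial that are phase-2 at that age. The slope
    of the OLS regression of proportion on age is the SIR; the Pearson
    test p-value for a nonzero slope is attached.
    """
    pts = table.smurf_proportion_points()
    if len(pts) < 3:
        raise ValueError(f"need >= 3 (vial, age) proportion points, got {len(pts)}")
    return _ols(pts["age"].to_numpy(dtype=float), pts["proportion"].to_numpy(dtype=float))


def theoretical_sir(params: ModelParams, ages=None, survival_floor: float = 0.10) -> SIRResult:
    """Model-implied SIR from the deterministic two-phase solution.

    Evaluates S(t)/(N(t)+S(t)) on the given ages and regresses against
    age exactly as :func:`sir` does. By default the ages are daily from
    the onset age ``t0`` until total survivorship falls below
    ``survival_floor`` (10%), spanning the observable assay window.
    """
    if ages is None:
        ages_list = []
        t = float(params.t0)
        while total_survival(t, params) >= survival_floor:
            ages_list.append(t)
            t += 1.0
            if t > params.t0 + 500:  # pragma: no cover - runaway guard
                break
        ages = np.array(ages_list)
    else:
        ages = np.asarray(ages, dtype=float)
    if len(ages) < 3:
        raise ValueError("age window too short for a regression")
    pi = np.array([total_survival(t, params) for t in ages])
    s = np.array([smurf_count(t, params) for t in ages])
    if np.any(pi <= 0):
        raise ValueError("population extinct within the requested age window")
    return _ols(ages, s / pi)


def compare_sir(res1: SIRResult, res2: SIRResult):
    """Two-sided test of slope equality between two SIR regressions.

    Classical two-regression (ANCOVA-style) t-test with pooled residual
    variance and ``n1 + n2 - 4`` degrees of freedom. Returns
    ``(statistic, p_value)``.
    """
    df = res1.n_points + res2.n_points - 4
    if df < 1:
        raise ValueError("insufficient points to compare slopes")
    pooled_var = (res1.ss_res + res2.ss_res) / df
    se_diff = math.sqrt(pooled_var * (1.0 / res1.sxx + 1.0 / res2.sxx))
    if se_diff == 0:
        stat = 0.0 if res1.slope == res2.slope else math.inf
    else:
        stat = (res1.slope - res2.slope) / se_diff
    p = 2.0 * stats.t.sf(abs(stat), df)
    return float(stat), float(min(p, 1.0))


def mixture_trajectory(params: ModelParams, level_phase1: float, level_phase2: float, ages):
    """Population-mean biomarker level implied by two-phase mixing.

    If phase-1 individuals express a marker at level ``m1`` and phase-2
    individuals at ``m2``, the population mean among the living is
    ``M(t) = (N*m1 + S*m2)/(N + S)`` — so an apparently progressive
    marker increase can arise purely from the changing phase
    composition. Monotone non-decreasing when ``m2 > m1``.
    """
    if not (np.isfinite(level_phase1) and np.isfinite(level_phase2)):
        raise ValueError("marker levels must be finite")
    ages = np.asarray(ages, dtype=float)
    s = np.array([smurf_count(t, params) for t in ages])
    pi = np.array([total_survival(t, params) for t in ages])
    if np.any(pi <= 0):
        raise ZeroDivisionError("no living individuals at a requested age")
    n = pi - s
    return (n * level_phase1 + s * level_phase2) / pi


def compare_medians(samples1, samples2):
    """Two-sided Wilcoxon rank-sum test on two lifespan samples.

    Exact null distribution for small samples without ties, normal
    approximation with tie correction otherwise. Returns
    ``(statistic, p_value)``.
    """
    x = np.asarray(samples1, dtype=float)
    y = np.asarray(samples2, dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("need >= 3 observations per sample")
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto",
                             use_continuity=False)
    return float(res.statistic), float(res.pvalue)
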