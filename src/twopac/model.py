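"""Deterministic continuous-time solution of the two-phase aging model.

In shifted time ``u = t - t0`` the coupled dynamics are

    dN/du = -a*u * N,            N(0) = P0
    dS/du = -k*S + a*u * N,      S(0) = 0

giving the closed form ``N(u) = P0 * exp(-a*u**2/2)`` and an integral
representation for the living phase-2 count,

    S(u) = P0 * a * int_0^u v * exp(-a*v**2/2) * exp(-k*(u - v)) dv,

which is evaluated here by adaptive Gauss-Kronrod quadrature. The
analytically reduced closed form of S involves catastrophic cancellation
of scaled error functions at double precision for realistic parameters,
so it is deliberately not used.

All public interfaces take absolute age in days; the shift to the onset
age ``t0`` is internal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

from .params import ModelParams

__all__ = [
    "Trajectory",
    "transition_hazard",
    "nonsmurf_survival",
    "smurf_count",
    "total_survival",
    "t50",
    "apparent_mortality",
    "evaluate_trajectory",
]

_QUAD_EPSABS = 1e-10
_QUAD_EPSREL = 1e-8


class QuadratureError(RuntimeError):
    """Raised when adaptive quadrature fails to converge."""


@dataclass(frozen=True)
class Trajectory:
    """Time course of the population composition on an age grid.

    Attributes
    ----------
    times : ndarray
        Strictly increasing absolute ages, days.
    n_nonsmurf, n_smurf_alive, n_alive, n_dead_cumulative : ndarray
        Phase-1 count N(t), living phase-2 count S(t), total alive
        pi(t) = N + S, and cumulative deaths, all in units of ``p0``.
    p0 : float
        Initial population size; N + S + dead = p0 at every grid point.
    """

    times: np.ndarray
    n_nonsmurf: np.ndarray
    n_smurf_alive: np.ndarray
    n_alive: np.ndarray
    n_dead_cumulative: np.ndarray
    p0: float = 1.0

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t.ndim != 1 or t.size < 1:
            raise ValueError("times must be a 1-D array")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")

    def smurf_proportion(self) -> np.ndarray:
        """Living phase-2 fraction S/(N+S) per grid point."""
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.n_alive > 0, self.n_smurf_alive / self.n_alive, np.nan)


def transition_hazard(t, params: ModelParams):
    """Phase-1 to phase-2 transition hazard at absolute age ``t``.

    Zero up to the onset age ``t0``, then ``a*(t - t0)`` per day
    (the linear law ``a*t + b`` expressed in shifted time); continuous
    at ``t0``. As a rate it may exceed 1 at late ages.
    """
    t = np.asarray(t, dtype=float)
    _check_nonneg_age(t)
    out = params.a * np.maximum(t - params.t0, 0.0)
    return out.item() if out.ndim == 0 else out


def nonsmurf_survival(t, params: ModelParams):
    """Fraction of the initial population still in phase 1 at age ``t``.

    ``exp(-a*u**2/2)`` with ``u = t - t0``; 1 before onset.
    """
    t = np.asarray(t, dtype=float)
    _check_nonneg_age(t)
    u = np.maximum(t - params.t0, 0.0)
    out = np.exp(-params.a * u * u / 2.0)
    return out.item() if out.ndim == 0 else out


def _smurf_fraction_scalar(u: float, a: float, k: float) -> float:
    if u <= 0.0:
        return 0.0
    # integrand a*v*exp(-a v^2/2) * exp(-k (u-v)): smooth, unimodal
    val, err = quad(
        lambda v: a * v * np.exp(-a * v * v / 2.0 - k * (u - v)),
        0.0,
        u,
        epsabs=_QUAD_EPSABS,
        epsrel=_QUAD_EPSREL,
        limit=200,
    )
    if not np.isfinite(val) or err > max(_QUAD_EPSABS, 1e-6 * max(abs(val), 1e-12)) * 1e4:
        raise QuadratureError(f"quadrature failed at u={u}: value={val}, err={err}")
    return max(val, 0.0)


def smurf_count(t, params: ModelParams):
    """Living phase-2 count at age ``t`` as a fraction of ``p0``.

    Evaluates the convolution integral of newly transitioned cohorts
    against their exponential phase-2 survival by adaptive quadrature;
    0 at and before onset.
    """
    t = np.asarray(t, dtype=float)
    _check_nonneg_age(t)
    u = t - params.t0
    if t.ndim == 0:
        return _smurf_fraction_scalar(float(u), params.a, params.k)
    return np.array([_smurf_fraction_scalar(float(ui), params.a, params.k) for ui in u])


def total_survival(t, params: ModelParams):
    """Total fraction alive pi(t)/p0 = phase-1 plus living phase-2."""
    return nonsmurf_survival(t, params) + smurf_count(t, params)


def t50(params: ModelParams, t_max: float | None = None) -> float:
    """Median survival age: the root of ``total_survival(t) = 0.5``.

    Unique because pi is strictly decreasing after ``t0``. The bracket's
    upper bound grows geometrically from ``t0 + 1/k`` and is capped at
    ``t0 + 10*sqrt(2*ln(1e6)/a)``, beyond which phase 1 is extinct to
    one part in 1e6 and pi can only still exceed 0.5 in the degenerate
    near-immortal-phase-2 regime.
    """
    # phase 1 is extinct to 1e-6 within 10*sqrt(2 ln 1e6/a) of onset; the
    # 20/k term covers the residual phase-2 decay down to 0.5 after that
    cap = params.t0 + 10.0 * np.sqrt(2.0 * np.log(1e6) / params.a) + 20.0 / params.k
    if t_max is not None:
        cap = min(cap, t_max)
    hi = min(params.t0 + 1.0 / params.k, cap)
    while total_survival(hi, params) > 0.5:
        if hi >= cap:
            raise ValueError(
                "survival never reaches 50% on the search interval "
                f"[0, {cap:.3g}] (k may be too small)"
            )
        hi = min(hi * 2.0, cap)
    lo = 0.0
    return float(brentq(lambda t: total_survival(t, params) - 0.5, lo, hi, xtol=1e-6))


def apparent_mortality(traj: Trajectory) -> np.ndarray:
    """Population-level mortality rate ``-(1/pi) dpi/dt`` per day.

    Central finite differences on the trajectory grid (one-sided at the
    ends). This is the hazard an observer blind to the two-phase
    structure would measure: it rises with age even though each phase-2
    individual dies at the constant rate ``k``.
    """
    if traj.times.size < 2:
        raise ValueError("need at least 2 grid points")
    pi = np.asarray(traj.n_alive, dtype=float)
    if np.any(pi <= 0):
        raise ZeroDivisionError("population size is zero on the evaluated range")
    dpi = np.gradient(pi, np.asarray(traj.times, dtype=float))
    return -dpi / pi


def evaluate_trajectory(params: ModelParams, times) -> Trajectory:
    """Evaluate the continuous model on an age grid, in counts of ``p0``."""
    times = np.asarray(times, dtype=float)
    n = nonsmurf_survival(times, params) * params.p0
    s = smurf_count(times, params) * params.p0
    alive = n + s
    return Trajectory(
        times=times,
        n_nonsmurf=n,
        n_smurf_alive=s,
        n_alive=alive,
        n_dead_cumulative=params.p0 - alive,
        p0=params.p0,
    )


def _check_nonneg_age(t: np.ndarray) -> None:
    if np.any(t < 0):
        raise ValueError("ages must be non-negative")
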