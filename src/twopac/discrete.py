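"""Iterative (spreadsheet-style) implementation of the two-phase model.

Time advances in fixed steps. At each step the per-step transition
probability is evaluated at the step midpoint, the newly transitioned
cohort is removed from phase 1, and every living phase-2 cohort decays
by ``exp(-k*dt)``. With ``dt = 1`` this is exactly the daily scheme
``N_t = N_{t-1} - p_(t-0.5) * N_{t-1}``; smaller steps converge to the
continuous solution.

Because ``k`` is age-independent, phase-2 cohorts are exchangeable and
the per-cohort bookkeeping is mathematically identical to multiplying a
single aggregated phase-2 compartment by ``exp(-k*dt)``. Both modes are
implemented; they agree to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import Trajectory
from .params import ModelParams

__all__ = ["DiscreteConfig", "evolve", "survivorship_curve"]


@dataclass(frozen=True)
class DiscreteConfig:
    """Settings for the discrete-time scheme.

    dt : step size, days (1.0 reproduces the daily scheme).
    t_max : final age, days; evolution also stops once fewer than
        1e-6 * p0 individuals remain alive.
    clamp : clamp the per-step transition probability to [0, 1]. The
        continuous hazard is unbounded; a per-step *probability* is not.
    track_cohorts : keep each phase-2 cohort by birth step instead of a
        single aggregated compartment (same result, more memory).
    """

    dt: float = 1.0
    t_max: float = 120.0
    clamp: bool = True
    track_cohorts: bool = False

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if not self.t_max > 0:
            raise ValueError(f"t_max must be positive, got {self.t_max}")


def evolve(params: ModelParams, config: DiscreteConfig | None = None) -> Trajectory:
    """Run the iterative scheme and return the step-by-step trajectory.

    Cumulative deaths are accounted exactly: the survivor count is p0
    minus the phase-2 deaths accumulated so far, and
    ``N + S + dead = p0`` holds to machine precision at every step.
    """
    if config is None:
        config = DiscreteConfig()
    if config.t_max <= params.t0:
        raise ValueError(f"t_max={config.t_max} must exceed t0={params.t0}")
    dt = config.dt
    n_steps = int(np.ceil(config.t_max / dt - 1e-12))
    decay = np.exp(-params.k * dt)

    times = [0.0]
    n_hist = [params.p0]
    s_hist = [0.0]
    dead_hist = [0.0]

    n = params.p0
    dead = 0.0
    cohorts: list[float] = []  # per-cohort living counts, oldest first
    s_agg = 0.0

    for step in range(1, n_steps + 1):
        t = step * dt
        t_mid = t - 0.5 * dt
        # per-step transition probability: hazard at midpoint times dt
        p = params.a * max(t_mid - params.t0, 0.0) * dt
        if config.clamp:
            p = min(p, 1.0)
        newly = p * n
        n -= newly
        if config.track_cohorts:
            died = sum(cohorts) * (1.0 - decay)
            cohorts = [c * decay for c in cohorts]
            cohorts.append(newly)
            s = sum(cohorts)
        else:
            died = s_agg * (1.0 - decay)
            s_agg = s_agg * decay + newly
            s = s_agg
        dead += died
        times.append(t)
        n_hist.append(n)
        s_hist.append(s)
        dead_hist.append(dead)
        if n + s < 1e-6 * params.p0:
            break

    times = np.array(times)
    n_arr = np.array(n_hist)
    s_arr = np.array(s_hist)
    dead_arr = np.array(dead_hist)
    return Trajectory(
        times=times,
        n_nonsmurf=n_arr,
        n_smurf_alive=s_arr,
        n_alive=n_arr + s_arr,
        n_dead_cumulative=dead_arr,
        p0=params.p0,
    )


def survivorship_curve(traj: Trajectory, ages):
    """Export a life table from a trajectory at the requested ages.

    Returns a LifeTable with one pooled "vial": fraction alive and the
    phase-2 fraction among the living, linearly interpolated on the
    trajectory grid.
    """
    from .lifetable import LifeTable

    ages = np.asarray(ages, dtype=float)
    tmin, tmax = traj.times[0], traj.times[-1]
    if np.any(ages < tmin) or np.any(ages > tmax):
        raise ValueError(f"requested ages outside trajectory grid [{tmin}, {tmax}]")
    alive = np.interp(ages, traj.times, traj.n_alive)
    smurf = np.interp(ages, traj.times, traj.n_smurf_alive)
    return LifeTable.from_counts(
        ages=ages, n_alive=alive, n_smurf=smurf, p0=traj.p0, label="simulated"
    )
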