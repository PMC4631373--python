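"""Parameter estimation from life tables.

The estimation strategy mirrors how the model is meant to be used on
longitudinal assay data:

1. ``fit_k`` — the phase-2 death rate constant is estimated first, from
   the pooled phase-2 survival curve (time measured from the phase-1/
   phase-2 transition), by least squares against ``exp(-k*t)`` with the
   amplitude fixed at 1 (all phase-2 individuals are alive at onset).
2. ``fit_2pac`` — with ``k`` held fixed, the hazard slope ``a`` and
   onset age ``t0`` are then found by maximizing the R^2 between the
   observed whole-population survival fractions and the deterministic
   model curve, using a deterministic coarse grid followed by
   Nelder-Mead refinement.

Gompertz and Weibull survival-curve fits are provided as classical
comparators, and ``fit_shared_k`` fits several genotypes under one
common ``k``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy import optimize, stats

from .lifetable import LifeTable
from .model import nonsmurf_survival, total_survival
from .params import ModelParams

__all__ = [
    "FitResult",
    "ClassicFitResult",
    "fit_k",
    "fit_2pac",
    "fit_gompertz",
    "fit_weibull",
    "fit_shared_k",
]


class FitError(RuntimeError):
    """Raised when a fit cannot be performed or does not converge."""


@dataclass
class FitResult:
    """Estimated parameters with goodness of fit.

    ``params`` maps parameter names to point estimates; ``ci`` maps a
    subset of them to (low, high) bootstrap 95% intervals. ``trace``
    summarizes the optimizer (evaluations, final simplex spread).
    """

    params: dict
    r_squared: float
    n_points: int
    converged: bool = True
    ci: dict = field(default_factory=dict)
    trace: dict = field(default_factory=dict)
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.ci.items():
            est = self.params[name]
            if not (lo <= est <= hi):
                raise ValueError(f"CI for {name} does not contain the estimate")


@dataclass
class ClassicFitResult:
    """Two-parameter classical survival-model fit (Gompertz or Weibull)."""

    model: str
    scale: float  # Gompertz A (initial hazard) or Weibull a (scale coefficient)
    shape: float  # Gompertz k (hazard doubling rate) or Weibull k (shape)
    r_squared: float
    n_points: int

    def __post_init__(self) -> None:
        if self.model not in ("gompertz", "weibull"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.scale <= 0 or self.shape <= 0:
            raise ValueError("classical model parameters must be positive")


def _r_squared(obs: np.ndarray, pred: np.ndarray) -> float:
    ss_res = float(np.sum((obs - pred) ** 2))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else 0.0
    return 1.0 - ss_res / ss_tot


# ---------------------------------------------------------------------------
# phase-2 decay: k

def _fit_k_fractions(t: np.ndarray, frac: np.ndarray) -> float:
    def sse(logk):
        return float(np.sum((frac - np.exp(-np.exp(logk) * t)) ** 2))

    res = optimize.minimize_scalar(sse, bounds=(np.log(1e-4), np.log(1e2)), method="bounded",
                                   options={"xatol": 1e-12})
    return float(np.exp(res.x))


def fit_k(smurf_survival: LifeTable, lifetimes=None, n_boot: int = 0, seed: int | None = None) -> FitResult:
    """Estimate the phase-2 death rate constant ``k``.

    ``smurf_survival`` holds pooled phase-2 survival counts with age
    measured from the transition (so the fraction at age 0 is 1). The
    model is the one-phase exponential decay ``exp(-k*t)`` with no free
    amplitude. If individual phase-2 ``lifetimes`` are supplied and
    ``n_boot > 0``, a nonparametric bootstrap over individuals yields a
    95% CI for ``k``.
    """
    pooled = smurf_survival.pooled_survival()
    t = pooled["age"].to_numpy()
    frac = pooled["fraction"].to_numpy()
    if len(t) < 3:
        raise FitError(f"need >= 3 points to fit k, got {len(t)}")
    if np.allclose(frac, frac[0]):
        raise FitError("survival fractions are constant; k is unidentifiable")
    k_hat = _fit_k_fractions(t, frac)
    r2 = _r_squared(frac, np.exp(-k_hat * t))

    ci = {}
    if n_boot > 0:
        if lifetimes is None:
            raise FitError("bootstrap CI requires individual lifetimes")
        lifetimes = np.asarray(lifetimes, dtype=float)
        rng = np.random.default_rng(seed)
        reps = np.empty(n_boot)
        n = len(lifetimes)
        for b in range(n_boot):
            resampled = lifetimes[rng.integers(0, n, size=n)]
            n_alive = (resampled[None, :] > t[:, None]).sum(axis=1)
            fb = n_alive / n
            reps[b] = _fit_k_fractions(t, fb)
        lo, hi = np.percentile(reps, [2.5, 97.5])
        ci["k"] = (min(float(lo), k_hat), max(float(hi), k_hat))

    return FitResult(params={"k": k_hat}, r_squared=r2, n_points=len(t), ci=ci)


# ---------------------------------------------------------------------------
# whole-population fit with k fixed: a and t0

_GL_NODES = 128
_gl_x, _gl_w = leggauss(_GL_NODES)


def _smurf_fraction_batch(u: np.ndarray, a: float, k: float) -> np.ndarray:
    """Fixed-order Gauss-Legendre evaluation of the phase-2 integral.

    Vectorized over ages for the fitting hot loop; agrees with the
    adaptive quadrature in :mod:`twopac.model` to ~1e-10 for the smooth
    moderate-``k`` regime where fitting operates.
    """
    u = np.asarray(u, dtype=float)
    pos = u > 0
    out = np.zeros_like(u)
    if not pos.any():
        return out
    up = u[pos]
    # map nodes from [-1, 1] to [0, u] for each age
    v = 0.5 * up[:, None] * (_gl_x[None, :] + 1.0)
    integrand = a * v * np.exp(-a * v * v / 2.0 - k * (up[:, None] - v))
    out[pos] = 0.5 * up * (integrand @ _gl_w)
    return out


def _model_survival_batch(ages: np.ndarray, a: float, t0: float, k: float) -> np.ndarray:
    u = ages - t0
    n = np.exp(-a * np.maximum(u, 0.0) ** 2 / 2.0)
    return n + _smurf_fraction_batch(u, a, k)


def fit_2pac(pop_survival: LifeTable, k_fixed: float, a_bounds=(1e-5, 1.0),
             forward_dt: float | None = None) -> FitResult:
    """Fit the hazard slope ``a`` and onset age ``t0`` with ``k`` fixed.

    Maximizes R^2 on survival fractions (equivalently minimizes the
    residual sum of squares) over ``a > 0`` and ``t0 >= 0``. A coarse
    deterministic grid — log-spaced in ``a`` over ``a_bounds``, linear
    in ``t0`` from 0 to the first observed-death age — seeds a
    Nelder-Mead refinement in ``(log a, t0)``. Deterministic given the
    data.

    ``forward_dt=None`` (default) evaluates the continuous model, the
    right choice for event-level data. Passing a step size instead uses
    the discrete iterative scheme as the forward model, matching data
    produced by (or equivalent to) the daily spreadsheet scheme, whose
    O(dt) bias would otherwise leak into the estimates.
    """
    if k_fixed <= 0:
        raise FitError(f"k_fixed must be positive, got {k_fixed}")
    pooled = pop_survival.pooled_survival()
    ages = pooled["age"].to_numpy()
    frac = pooled["fraction"].to_numpy()
    if len(ages) < 4:
        raise FitError(f"need >= 4 points to fit (a, t0), got {len(ages)}")
    if frac.min() > 0.5:
        raise FitError("survival never falls below 50%; (a, t0) are poorly identified")

    below = ages[frac < 1.0 - 1e-12]
    t0_hi = float(below[0]) if len(below) else float(ages[-1])

    if forward_dt is None:
        def predict(a: float, t0: float) -> np.ndarray:
            return _model_survival_batch(ages, a, t0, k_fixed)
    else:
        from .discrete import DiscreteConfig, evolve

        t_max = float(ages[-1]) + forward_dt

        def predict(a: float, t0: float) -> np.ndarray:
            if t_max <= t0:
                return np.ones_like(ages)
            traj = evolve(ModelParams(a=a, t0=t0, k=k_fixed),
                          DiscreteConfig(dt=forward_dt, t_max=t_max))
            return np.interp(ages, traj.times, traj.n_alive, right=0.0)

    def sse(log_a: float, t0: float) -> float:
        pred = predict(np.exp(log_a), t0)
        return float(np.sum((frac - pred) ** 2))

    log_a_grid = np.log(np.geomspace(a_bounds[0], a_bounds[1], 25))
    t0_grid = np.linspace(0.0, max(t0_hi, 1e-6), 12)
    best = min(
        ((sse(la, t0), la, t0) for la in log_a_grid for t0 in t0_grid),
        key=lambda x: x[0],
    )

    def objective(x):
        log_a, t0 = x
        if t0 < 0 or not (np.log(a_bounds[0]) - 2 <= log_a <= np.log(a_bounds[1]) + 2):
            return 1e6
        return sse(log_a, t0)

    res = optimize.minimize(
        objective,
        x0=[best[1], best[2]],
        method="Nelder-Mead",
        options={"xatol": 1e-9, "fatol": 1e-12, "maxiter": 2000},
    )
    log_a, t0 = res.x
    a_hat = float(np.exp(log_a))
    t0_hat = float(max(t0, 0.0))
    r2 = _r_squared(frac, predict(a_hat, t0_hat))
    if not res.success:
        raise FitError(f"optimizer did not converge: {res.message}")
    return FitResult(
        params={"a": a_hat, "t0": t0_hat, "b": -a_hat * t0_hat, "k": k_fixed},
        r_squared=r2,
        n_points=len(ages),
        converged=bool(res.success),
        trace={"n_evals": int(res.nfev), "grid_best_sse": best[0], "final_sse": float(res.fun)},
    )


# ---------------------------------------------------------------------------
# classical comparators

def _gompertz_survival(t, A, k):
    return np.exp(-(A / k) * (np.exp(k * t) - 1.0))


def _weibull_survival(t, a, k):
    t = np.asarray(t, dtype=float)
    return np.exp(-a * np.power(t, k, where=t > 0, out=np.zeros_like(t)))


def _classic_fit(name, func, t, frac, p0) -> ClassicFitResult:
    try:
        popt, _ = optimize.curve_fit(
            func, t, frac, p0=p0, bounds=([1e-10, 1e-6], [10.0, 20.0]), maxfev=20000
        )
    except RuntimeError as exc:  # pragma: no cover - diagnostic path
        raise FitError(f"{name} fit did not converge: {exc}") from exc
    r2 = _r_squared(frac, func(t, *popt))
    return ClassicFitResult(model=name, scale=float(popt[0]), shape=float(popt[1]),
                            r_squared=r2, n_points=len(t))


def fit_gompertz(pop_survival: LifeTable) -> ClassicFitResult:
    """Least-squares Gompertz fit ``S(t) = exp(-(A/k)(e^{kt} - 1))``."""
    pooled = pop_survival.pooled_survival()
    t = pooled["age"].to_numpy()
    frac = pooled["fraction"].to_numpy()
    return _classic_fit("gompertz", _gompertz_survival, t, frac, p0=(0.005, 0.1))


def fit_weibull(pop_survival: LifeTable) -> ClassicFitResult:
    """Least-squares Weibull fit ``S(t) = exp(-a t^k)``.

    Initial values come from the linearization
    ``log(-log S) = log a + k log t`` on interior points.
    """
    pooled = pop_survival.pooled_survival()
    t = pooled["age"].to_numpy()
    frac = pooled["fraction"].to_numpy()
    interior = (frac > 1e-6) & (frac < 1 - 1e-6) & (t > 0)
    if interior.sum() >= 3:
        lin = stats.linregress(np.log(t[interior]), np.log(-np.log(frac[interior])))
        p0 = (float(np.exp(np.clip(lin.intercept, -20, 2))), float(np.clip(lin.slope, 0.1, 15)))
    else:
        p0 = (1e-3, 2.0)
    return _classic_fit("weibull", _weibull_survival, t, frac, p0=p0)


# ---------------------------------------------------------------------------
# multi-genotype fitting under a common k

def fit_shared_k(curves, k_fixed: float):
    """Fit several longevity curves under one common phase-2 rate ``k``.

    Applies :func:`fit_2pac` to each life table with the shared ``k``
    and attaches the implied theoretical phase-2 increase-rate slope to
    each result (``extras['sir_slope']``). Per-curve failures are
    recorded as ``extras['error']`` without aborting the batch; failed
    entries are ``FitResult`` objects with ``converged=False``.
    """
    from .survstats import theoretical_sir

    results = []
    for table in curves:
        try:
            fit = fit_2pac(table, k_fixed=k_fixed)
            p = ModelParams(a=fit.params["a"], t0=fit.params["t0"], k=k_fixed)
            fit.extras["sir_slope"] = theoretical_sir(p).slope
            fit.extras["label"] = table.label
        except FitError as exc:
            fit = FitResult(params={}, r_squared=0.0, n_points=0, converged=False,
                            extras={"error": str(exc), "label": table.label})
        results.append(fit)
    return results
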