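"""Individual-based stochastic generator of two-phase assay cohorts.

Each individual draws a continuous phase-1/phase-2 transition age by
inverse transform from the phase-1 survival ``exp(-a*u**2/2)`` (so
``u = sqrt(-2*ln(U)/a)``), then an exponential phase-2 lifetime with
rate ``k``. Every individual therefore dies in phase 2, mirroring the
longitudinal assay the model describes. Event times are continuous;
observation happens at a finite resolution (daily by default), the
status flipping at the first assay age at or after the event.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lifetable import LifeTable
from .params import ModelParams

__all__ = ["AssayDesign", "CohortEvents", "sample_cohort", "to_life_table"]


@dataclass(frozen=True)
class AssayDesign:
    """Design of a longitudinal assay.

    n_individuals flies split round-robin over n_vials replicate vials,
    scored every ``resolution`` days; ``assay_ages`` are the ages at
    which phase-2 proportions are tabulated. ``censor_age`` truncates
    follow-up (off by default: cohorts are followed to death).
    """

    n_individuals: int
    n_vials: int = 1
    assay_ages: tuple = ()
    resolution: float = 1.0
    seed: int | None = None
    censor_age: float | None = None

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        if self.n_vials < 1:
            raise ValueError("n_vials must be >= 1")
        ages = np.asarray(self.assay_ages, dtype=float)
        if ages.size > 1 and not np.all(np.diff(ages) > 0):
            raise ValueError("assay_ages must be strictly increasing")
        if not self.resolution > 0:
            raise ValueError("resolution must be positive")


@dataclass
class CohortEvents:
    """Individual-level event records.

    ``data`` columns: ``id``, ``vial``, ``transition_age`` and
    ``death_age`` (continuous days; ``death_age > transition_age``),
    ``obs_transition_age`` / ``obs_death_age`` (as scored at the assay
    resolution), and ``censor_age`` (NaN when followed to death; a
    censored individual has NaN event times after its censor age).
    """

    data: pd.DataFrame
    params: ModelParams | None = None

    def __post_init__(self) -> None:
        df = self.data
        needed = {"id", "vial", "transition_age", "death_age"}
        missing = needed - set(df.columns)
        if missing:
            raise ValueError(f"event table missing columns: {sorted(missing)}")
        both = df["transition_age"].notna() & df["death_age"].notna()
        bad = df.loc[both & (df["death_age"] <= df["transition_age"]), "id"]
        if len(bad):
            raise ValueError(f"death before transition for id {bad.iloc[0]}")

    @property
    def n(self) -> int:
        return len(self.data)

    def smurf_lifetimes(self) -> np.ndarray:
        """Observed phase-2 sojourn times (death - transition), days."""
        df = self.data.dropna(subset=["transition_age", "death_age"])
        return (df["death_age"] - df["transition_age"]).to_numpy()


def sample_cohort(params: ModelParams, design: AssayDesign) -> CohortEvents:
    """Draw a reproducible synthetic cohort under the two-phase model."""
    rng = np.random.default_rng(design.seed)
    n = design.n_individuals
    u_trans = np.sqrt(-2.0 * np.log(rng.uniform(size=n)) / params.a)
    transition = params.t0 + u_trans
    lifetime = rng.exponential(scale=1.0 / params.k, size=n)
    death = transition + lifetime
    vials = np.array([f"v{i % design.n_vials + 1}" for i in range(n)])

    res = design.resolution
    obs_transition = np.ceil(transition / res) * res
    obs_death = np.ceil(death / res) * res

    df = pd.DataFrame(
        {
            "id": np.arange(n),
            "vial": vials,
            "transition_age": transition,
            "death_age": death,
            "obs_transition_age": obs_transition,
            "obs_death_age": obs_death,
            "censor_age": np.nan,
        }
    )
    if design.censor_age is not None:
        c = float(design.censor_age)
        censored = df["death_age"] > c
        df.loc[censored, "censor_age"] = c
        for col in ("transition_age", "obs_transition_age"):
            df.loc[censored & (df[col] > c), col] = np.nan
        df.loc[censored, ["death_age", "obs_death_age"]] = np.nan
    return CohortEvents(data=df, params=params)


def to_life_table(events: CohortEvents, ages, observed: bool = True) -> LifeTable:
    """Tabulate counts alive and living phase-2 per vial at given ages.

    ``observed=True`` uses the daily-resolution scored event times (the
    assay's view); ``observed=False`` uses the exact continuous times.
    An individual is alive at age t when its death age exceeds t, and a
    living phase-2 individual additionally has transition age <= t.
    """
    ages = np.asarray(ages, dtype=float)
    df = events.data
    tcol = "obs_transition_age" if observed else "transition_age"
    dcol = "obs_death_age" if observed else "death_age"
    if df["censor_age"].notna().any():
        raise ValueError("life-table export requires uncensored cohorts")
    rows = []
    for vial, grp in df.groupby("vial"):
        trans = grp[tcol].to_numpy()
        death = grp[dcol].to_numpy()
        for age in ages:
            alive = death > age
            rows.append(
                (age, vial, int(alive.sum()), int((alive & (trans <= age)).sum()))
            )
    table = pd.DataFrame(rows, columns=["age", "vial", "n_alive", "n_smurf"])
    p0 = df.groupby("vial").size().astype(float).to_dict()
    return LifeTable(data=table, p0=p0, label="synthetic cohort")


def smurf_survival_table(events: CohortEvents, max_days: int = 30) -> LifeTable:
    """Pooled phase-2 survival vs days since transition, daily grid.

    This emulates pooling every individual's phase-2 sojourn into one
    average phase-2 survival curve, the input for estimating ``k``.
    """
    lifetimes = events.smurf_lifetimes()
    days = np.arange(0, max_days + 1, dtype=float)
    n_alive = np.array([(lifetimes > d).sum() for d in days], dtype=float)
    keep = n_alive > 0
    return LifeTable.from_counts(
        ages=days[keep],
        n_alive=n_alive[keep],
        p0=float(len(lifetimes)),
        vial="pooled",
        label="phase-2 survival (time since transition)",
    )
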