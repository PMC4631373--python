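"""Empirical life tables: counts alive (and living phase-2 individuals)
per age and replicate vial. The common input to fitting and survival
statistics."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["LifeTable"]


@dataclass
class LifeTable:
    """Survival/phase-2 counts per age and replicate vial.

    ``data`` has columns ``age`` (days), ``vial`` (label), ``n_alive``
    and optionally ``n_smurf`` (living phase-2 count; NaN when the assay
    did not score it). ``p0`` maps each vial to its initial population
    size; when omitted it is inferred as the vial's maximum ``n_alive``.
    """

    data: pd.DataFrame
    p0: dict = field(default_factory=dict)
    label: str = ""

    def __post_init__(self) -> None:
        df = self.data.copy()
        required = {"age", "vial", "n_alive"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"life table missing columns: {sorted(missing)}")
        if "n_smurf" not in df.columns:
            df["n_smurf"] = np.nan
        df = df.sort_values(["vial", "age"], kind="stable").reset_index(drop=True)
        if (df["n_alive"] < 0).any():
            bad = df.index[df["n_alive"] < 0][0]
            raise ValueError(f"negative n_alive in row {bad}")
        smurf = df["n_smurf"].to_numpy(dtype=float)
        alive = df["n_alive"].to_numpy(dtype=float)
        scored = ~np.isnan(smurf)
        if (smurf[scored] < 0).any() or (smurf[scored] > alive[scored] + 1e-9).any():
            raise ValueError("n_smurf must satisfy 0 <= n_smurf <= n_alive")
        self.data = df
        if not self.p0:
            self.p0 = df.groupby("vial")["n_alive"].max().to_dict()
        for vial, grp in df.groupby("vial"):
            if grp["n_alive"].max() > self.p0[vial] + 1e-9:
                raise ValueError(f"n_alive exceeds p0 for vial {vial!r}")

    # -- derived views ------------------------------------------------

    @property
    def has_smurf(self) -> bool:
        """Whether any row carries a living phase-2 count."""
        return bool(self.data["n_smurf"].notna().any())

    @property
    def total_p0(self) -> float:
        return float(sum(self.p0.values()))

    def check_monotone(self) -> list[str]:
        """Return vial labels whose alive counts ever increase with age."""
        bad = []
        for vial, grp in self.data.groupby("vial"):
            if np.any(np.diff(grp["n_alive"].to_numpy()) > 1e-9):
                bad.append(vial)
        return bad

    def pooled_survival(self) -> pd.DataFrame:
        """Survival fraction vs age, pooled across vials.

        Columns ``age`` and ``fraction`` = (sum alive)/(sum p0) over the
        vials reporting at that age.
        """
        rows = []
        for age, grp in self.data.groupby("age"):
            denom = sum(self.p0[v] for v in grp["vial"])
            rows.append((age, grp["n_alive"].sum() / denom))
        return pd.DataFrame(rows, columns=["age", "fraction"]).sort_values("age").reset_index(drop=True)

    def smurf_proportion_points(self) -> pd.DataFrame:
        """Per-vial living phase-2 proportions: one row per (vial, age).

        The denominator is the number of *living* flies in the vial at
        that age; ages where a vial has no survivors or was not scored
        are dropped.
        """
        df = self.data
        mask = df["n_smurf"].notna() & (df["n_alive"] > 0)
        out = df.loc[mask, ["age", "vial"]].copy()
        out["proportion"] = (df.loc[mask, "n_smurf"] / df.loc[mask, "n_alive"]).to_numpy()
        return out.reset_index(drop=True)

    # -- constructors -------------------------------------------------

    @classmethod
    def from_counts(cls, ages, n_alive, n_smurf=None, vial="all", p0=None, label="") -> "LifeTable":
        """Build a single-vial table from parallel arrays."""
        ages = np.asarray(ages, dtype=float)
        df = pd.DataFrame(
            {
                "age": ages,
                "vial": vial,
                "n_alive": np.asarray(n_alive, dtype=float),
                "n_smurf": np.nan if n_smurf is None else np.asarray(n_smurf, dtype=float),
            }
        )
        p0map = {vial: float(p0)} if p0 is not None else {}
        return cls(data=df, p0=p0map, label=label)
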