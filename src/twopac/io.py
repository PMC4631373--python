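"""CSV dialects for life tables and individual event tables.

See FORMATS.md at the repository root for the column-by-column
description. Both dialects are plain UTF-8 CSV with a header row and
"." as the decimal separator; ages are floating-point days.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .cohort import CohortEvents
from .lifetable import LifeTable

__all__ = ["read_life_table", "write_life_table", "read_events", "write_events"]

_LT_COLUMNS = ["age", "vial", "n_alive", "n_smurf"]
_EV_COLUMNS = ["id", "vial", "transition_age", "death_age", "censor_age"]


class FormatError(ValueError):
    """Malformed input file; the message names the offending row."""


def read_life_table(path, strict_monotone: bool = False) -> LifeTable:
    """Read a life-table CSV (columns age, vial, n_alive[, n_smurf]).

    A vial whose alive count ever increases with age triggers a warning
    (or :class:`FormatError` with ``strict_monotone=True``).
    """
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"{path}: {exc}") from exc
    missing = {"age", "vial", "n_alive"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    for col in ("age", "n_alive") + (("n_smurf",) if "n_smurf" in df.columns else ()):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            # +2: one for the header, one for 1-based numbering
            raise FormatError(f"{path}: non-numeric {col} at line {bad.idxmax() + 2}")
        df[col] = coerced
    neg = df.index[df["n_alive"] < 0]
    if len(neg):
        raise FormatError(f"{path}: negative n_alive at line {neg[0] + 2}")
    try:
        table = LifeTable(data=df)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    bad_vials = table.check_monotone()
    if bad_vials:
        msg = f"{path}: alive counts increase with age in vial(s) {bad_vials}"
        if strict_monotone:
            raise FormatError(msg)
        warnings.warn(msg, stacklevel=2)
    return table


def write_life_table(table: LifeTable, path) -> None:
    df = table.data.reindex(columns=_LT_COLUMNS)
    if not table.has_smurf:
        df = df.drop(columns=["n_smurf"])
    df.to_csv(path, index=False)


def read_events(path) -> CohortEvents:
    """Read an event-table CSV (id, vial, transition_age, death_age[, censor_age])."""
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"{path}: {exc}") from exc
    missing = {"id", "vial", "transition_age", "death_age"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    if "censor_age" not in df.columns:
        df["censor_age"] = np.nan
    for col in ("transition_age", "death_age", "censor_age"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    both = df["transition_age"].notna() & df["death_age"].notna()
    bad = df.loc[both & (df["death_age"] <= df["transition_age"]), "id"]
    if len(bad):
        raise FormatError(f"{path}: death_age <= transition_age for id {bad.iloc[0]}")
    # scored-at-resolution columns are optional on disk
    for col in ("obs_transition_age", "obs_death_age"):
        if col not in df.columns:
            df[col] = np.ceil(df[col.removeprefix("obs_")])
    return CohortEvents(data=df)


def write_events(events: CohortEvents, path) -> None:
    events.data.reindex(columns=_EV_COLUMNS).to_csv(path, index=False)
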