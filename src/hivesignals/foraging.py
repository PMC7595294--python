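"""Foraging-behavior metrics and pesticide dose accounting.

Quantities computed from per-bee feeder visit logs and per-day feeder
consumption tables:

* **foraging span** — days between a bee's marking day at the feeder and
  its last day of *uninterrupted* daily visiting;
* **visits per hour** — completed entry/exit pairs at the feeder box;
* **daily dose** — ng of insecticide collected per bee per day, from the
  volume consumed, the solution concentration (ppb, read as ng/mL) and the
  number of active foragers;
* **dose per trip** and the µl-of-solution equivalent;
* **crop assimilation** — the upper-bound acute dose a bee assimilates
  from its crop content while waiting before a release.

Conventions (documented, switchable where noted): ppb means ng of compound
per mL of final solution (solution density ~1 ignored); a completed visit
is ``min(entries, exits)``; the group median uses the lower of the two
middle values for even n.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FeederDay",
    "foraging_span",
    "group_span_summary",
    "visits_per_hour",
    "daily_dose",
    "dose_per_trip",
    "ng_to_ul",
    "ul_to_ng",
    "crop_assimilation",
    "read_visit_log",
    "read_feeder_days",
]

VISIT_LOG_COLUMNS = ["bee_id", "feeder_id", "date", "visits"]
FEEDER_DAY_COLUMNS = [
    "feeder_id", "date", "volume_ml", "sucrose_M", "clothianidin_ppb",
    "n_bees", "entries", "exits", "obs_hours",
]


@dataclass(frozen=True)
class FeederDay:
    """One feeder-day: consumption, concentration and activity."""

    feeder_id: str
    date: object
    volume_ml: float
    sucrose_molarity: float
    clothianidin_ppb: float
    n_active_bees: int
    entries: int = 0
    exits: int = 0
    obs_hours: float = 0.0

    def __post_init__(self) -> None:
        if self.volume_ml < 0:
            raise ValueError("volume_ml must be non-negative")
        if self.clothianidin_ppb < 0:
            raise ValueError("clothianidin_ppb must be non-negative")
        if self.n_active_bees < 0 or self.entries < 0 or self.exits < 0:
            raise ValueError("counts must be non-negative")


def _visit_days(log: pd.DataFrame, bee_id) -> np.ndarray:
    """Sorted unique visit days (integer day ordinals) of one bee."""
    rows = log[log["bee_id"] == bee_id]
    if rows.empty:
        raise KeyError(f"bee {bee_id!r} not present in the visit log")
    if "visits" in rows.columns:
        rows = rows[rows["visits"].fillna(0) > 0]
    dates = pd.to_datetime(rows["date"])
    days = np.unique(dates.map(pd.Timestamp.toordinal).to_numpy())
    return days


def foraging_span(log: pd.DataFrame, bee_id, strict: bool = False) -> int | None:
    """Foraging span of one bee in whole days.

    The span is ``last_day - first_day`` only when the bee visited on
    every calendar day in between.  On broken continuity the default
    returns the span of the longest run of consecutive visit days starting
    at the marking day; ``strict=True`` instead returns ``None`` (the bee
    is dropped from the analysis).
    """
    days = _visit_days(log, bee_id)
    if days.size == 0:
        return None if strict else 0
    full_span = int(days[-1] - days[0])
    if days.size == full_span + 1:  # visited every day in between
        return full_span
    if strict:
        return None
    # longest consecutive prefix from the marking day
    span = 0
    for k in range(1, days.size):
        if days[k] == days[k - 1] + 1:
            span = int(days[k] - days[0])
        else:
            break
    return span


def group_span_summary(
    log: pd.DataFrame,
    feeder_id: str | None = None,
    strict: bool = False,
) -> dict:
    """Median (lower middle for even n) and range of spans in a group."""
    sub = log if feeder_id is None else log[log["feeder_id"] == feeder_id]
    if sub.empty:
        raise ValueError(f"no visit records for feeder {feeder_id!r}")
    spans = []
    for bee in sub["bee_id"].unique():
        s = foraging_span(sub, bee, strict=strict)
        if s is not None:
            spans.append(s)
    if not spans:
        raise ValueError("no bee has a defined span in this group")
    spans.sort()
    n = len(spans)
    return {
        "n": n,
        "median": spans[(n - 1) // 2],  # lower-middle convention
        "min": spans[0],
        "max": spans[-1],
    }


def visits_per_hour(entry_count: int, exit_count: int, observation_hours: float) -> float:
    """Completed feeder visits per hour.

    One visit is one completed entry–exit pair; the conservative count is
    ``min(entries, exits)`` since the sensor cannot resolve direction
    errors.
    """
    if entry_count < 0 or exit_count < 0:
        raise ValueError("counts must be non-negative")
    if observation_hours <= 0:
        raise ValueError("observation_hours must be positive")
    return min(entry_count, exit_count) / observation_hours


def daily_dose(day: FeederDay) -> float:
    """ng of insecticide collected per bee on one feeder-day.

    ``volume (mL) * concentration (ng/mL) / active bees``.
    """
    if day.n_active_bees <= 0:
        raise ValueError("n_active_bees must be positive to attribute a dose")
    return day.volume_ml * day.clothianidin_ppb / day.n_active_bees


def dose_per_trip(daily_ng: float, trips_per_day: float) -> float:
    """ng collected on a single foraging trip."""
    if daily_ng < 0:
        raise ValueError("daily_ng must be non-negative")
    if trips_per_day <= 0:
        raise ValueError("trips_per_day must be positive")
    return daily_ng / trips_per_day


def ng_to_ul(ng: float, conc_ppb: float) -> float:
    """µl of solution carrying *ng* of compound at *conc_ppb* (ng/mL)."""
    if conc_ppb <= 0:
        raise ValueError("concentration must be positive")
    return ng / conc_ppb * 1000.0


def ul_to_ng(ul: float, conc_ppb: float) -> float:
    """ng of compound in *ul* of solution at *conc_ppb* (ng/mL)."""
    if conc_ppb < 0:
        raise ValueError("concentration must be non-negative")
    return ul * conc_ppb / 1000.0


def crop_assimilation(
    wait_minutes: float,
    conc_ppb: float,
    assimilation_ul_per_50min: float = 8.0,
) -> float:
    """Upper-bound ng assimilated from the crop while waiting before release.

    Linear in waiting time: ``(wait/50) * assimilated µl * conc / 1000``.
    The default 8 µl per 50 min is the published crop-emptying upper bound.
    """
    if wait_minutes < 0 or conc_ppb < 0 or assimilation_ul_per_50min < 0:
        raise ValueError("inputs must be non-negative")
    ul = wait_minutes / 50.0 * assimilation_ul_per_50min
    return ul_to_ng(ul, conc_ppb)


def read_visit_log(path) -> pd.DataFrame:
    """Read a visit-log CSV with columns ``bee_id,feeder_id,date,visits``."""
    df = pd.read_csv(path)
    missing = set(VISIT_LOG_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"visit log missing columns: {sorted(missing)}")
    return df


def read_feeder_days(path) -> list[FeederDay]:
    """Read a feeder-day CSV (schema in :data:`FEEDER_DAY_COLUMNS`)."""
    df = pd.read_csv(path)
    missing = set(FEEDER_DAY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"feeder-day table missing columns: {sorted(missing)}")
    return [
        FeederDay(
            feeder_id=str(r.feeder_id), date=r.date, volume_ml=float(r.volume_ml),
            sucrose_molarity=float(r.sucrose_M), clothianidin_ppb=float(r.clothianidin_ppb),
            n_active_bees=int(r.n_bees), entries=int(r.entries), exits=int(r.exits),
            obs_hours=float(r.obs_hours),
        )
        for r in df.itertuples()
    ]
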