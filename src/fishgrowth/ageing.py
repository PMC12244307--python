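"""Scale-reading ageing: pooled mean ages, calendar fractions, cohort tables.

Ages from scales arrive as integer annulus counts, nominally from two
independent readers each reading three scales per fish.  The pooled
arithmetic mean of all readings is the fish's annulus age; a decimal age
is then obtained by adding the fraction of the year elapsed since a
nominal hatching date (April 1, the middle of the spawning window).
"""

from __future__ import annotations

from dataclasses import dataclass
import datetime as _dt
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ScaleReadingSet",
    "mean_age",
    "fractional_age",
    "cohort_summary",
    "read_scale_readings_csv",
    "ages_from_readings",
]

HATCH_MONTH_DAY = (4, 1)
DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class ScaleReadingSet:
    """All annulus counts recorded for one fish plus its capture date."""

    fish_id: str
    readings: tuple[int, ...]
    capture_date: _dt.date

    def __post_init__(self) -> None:
        if len(self.readings) == 0:
            raise ValueError("at least one reading is required")
        if any((not isinstance(r, (int, np.integer))) or r < 0 for r in self.readings):
            raise ValueError("readings must be non-negative integers")


def mean_age(rs: ScaleReadingSet) -> float:
    """Pooled arithmetic mean of all annulus counts (readers weighted equally)."""
    return float(np.mean(rs.readings))


def fractional_age(
    mean_annuli: float,
    capture_date: _dt.date,
    hatch_month_day: tuple[int, int] = HATCH_MONTH_DAY,
) -> float:
    """Decimal age: annulus age plus the year fraction since the hatch date.

    The fraction counts days from the most recent hatch anniversary on or
    before the capture date, divided by 365.25, so it is always in
    ``[0, 1)``: a fish captured on March 31 carries almost a full year's
    fraction from the previous April 1.
    """
    if not isinstance(capture_date, _dt.date):
        raise ValueError(f"capture_date must be a date, got {capture_date!r}")
    month, day = hatch_month_day
    anniversary = _dt.date(capture_date.year, month, day)
    if anniversary > capture_date:
        anniversary = _dt.date(capture_date.year - 1, month, day)
    frac = (capture_date - anniversary).days / DAYS_PER_YEAR
    return float(mean_annuli) + frac


def ages_from_readings(
    reading_sets: list[ScaleReadingSet],
    hatch_month_day: tuple[int, int] = HATCH_MONTH_DAY,
) -> pd.DataFrame:
    """Mean annulus age and decimal age per fish, one row each."""
    rows = []
    for rs in reading_sets:
        m = mean_age(rs)
        rows.append(
            {
                "fish_id": rs.fish_id,
                "mean_annuli": m,
                "age": fractional_age(m, rs.capture_date, hatch_month_day),
                "capture_date": rs.capture_date.isoformat(),
            }
        )
    return pd.DataFrame(rows)


def cohort_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Per-integer-age-class summary of lengths.

    ``records`` needs columns ``age`` (decimal years) and ``length``
    (mm).  The age class is ``floor(age)`` — the "0+ … 7+" labelling.
    Returns one row per occupied class with n, min, max, range
    (max - min), mean, and SD of length; empty classes are omitted.
    """
    if len(records) == 0:
        raise ValueError("records must be non-empty")
    df = records.copy()
    df["age_class"] = np.floor(df["age"].to_numpy(dtype=float)).astype(int)
    g = df.groupby("age_class")["length"]
    out = pd.DataFrame(
        {
            "n": g.size(),
            "min": g.min(),
            "max": g.max(),
            "mean": g.mean(),
            "sd": g.std(ddof=1),
        }
    )
    out["range"] = out["max"] - out["min"]
    out = out[["n", "min", "max", "range", "mean", "sd"]]
    out.index.name = "age_class"
    return out.reset_index()


def read_scale_readings_csv(path) -> list[ScaleReadingSet]:
    """Read a readings CSV (fish_id, reader, scale_index, annuli, capture_date).

    One row per (reader, scale); readings are pooled per fish.
    """
    df = pd.read_csv(path)
    required = {"fish_id", "reader", "scale_index", "annuli", "capture_date"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    sets = []
    for fish_id, grp in df.groupby("fish_id", sort=False):
        dates = grp["capture_date"].unique()
        if len(dates) != 1:
            raise ValueError(f"{path}: fish {fish_id} has inconsistent capture dates")
        sets.append(
            ScaleReadingSet(
                fish_id=str(fish_id),
                readings=tuple(int(a) for a in grp["annuli"]),
                capture_date=_dt.date.fromisoformat(str(dates[0])),
            )
        )
    return sets
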