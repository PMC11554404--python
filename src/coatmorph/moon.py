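"""Lunar illumination model and night classification.

The temporal analysis only needs a full/new dichotomy (> 80% vs < 20%
illuminated), so the moon is modelled by its age within a mean synodic month:

    fraction(t) = (1 - cos(2*pi * age(t) / P)) / 2,

with age measured from a reference new moon (2000-01-06 18:14 UTC) modulo the
mean synodic period P = 29.530588 d. Near the 20%/80% thresholds this mean
model can differ from a full ephemeris by a few hours; an external ephemeris
table (CSV of date,fraction) can be substituted for exactness.

Nights are evaluated at local midnight of the capture date in a single
configured survey timezone (default UTC+10, eastern Australia).
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

SYNODIC_MONTH_DAYS = 29.530588
REFERENCE_NEW_MOON = dt.datetime(2000, 1, 6, 18, 14, tzinfo=dt.timezone.utc)

FULL = "full"
NEW = "new"
EXCLUDED = "excluded"


@dataclass(frozen=True)
class LunarConfig:
    full_threshold: float = 0.80
    new_threshold: float = 0.20
    reference_new_moon: dt.datetime = REFERENCE_NEW_MOON
    synodic_period_days: float = SYNODIC_MONTH_DAYS
    utc_offset_hours: float = 10.0
    #: optional exact ephemeris: {date -> illuminated fraction}
    ephemeris: dict | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not 0 <= self.new_threshold < self.full_threshold <= 1:
            raise ValueError("need 0 <= new_threshold < full_threshold <= 1")


def illuminated_fraction(when: dt.datetime, config: LunarConfig = LunarConfig()) -> float:
    """Illuminated fraction of the moon in [0, 1] at an instant.

    Continuous and periodic in the synodic month; 0 at the reference new
    moon, 1 half a period later.
    """
    if when.tzinfo is None:
        when = when.replace(tzinfo=dt.timezone.utc)
    age = (when - config.reference_new_moon).total_seconds() / 86400.0
    age %= config.synodic_period_days
    return (1.0 - math.cos(2.0 * math.pi * age / config.synodic_period_days)) / 2.0


def classify_night(date, config: LunarConfig = LunarConfig()) -> str:
    """Classify a night as 'full', 'new' or 'excluded'.

    The fraction is evaluated at local midnight of the date; > full_threshold
    is full, < new_threshold is new, and the strict boundaries fall into
    'excluded' with the middle of the range.
    """
    date = pd.Timestamp(date).date()
    if config.ephemeris is not None:
        frac = float(config.ephemeris[date])
    else:
        midnight = dt.datetime(
            date.year,
            date.month,
            date.day,
            tzinfo=dt.timezone(dt.timedelta(hours=config.utc_offset_hours)),
        )
        frac = illuminated_fraction(midnight, config)
    if frac > config.full_threshold:
        return FULL
    if frac < config.new_threshold:
        return NEW
    return EXCLUDED


def classify_range(start, end, config: LunarConfig = LunarConfig()) -> pd.DataFrame:
    """Classify every date in [start, end]; returns date, fraction, moon_class."""
    dates = pd.date_range(pd.Timestamp(start), pd.Timestamp(end), freq="D")
    rows = []
    for ts in dates:
        d = ts.date()
        midnight = dt.datetime(
            d.year, d.month, d.day,
            tzinfo=dt.timezone(dt.timedelta(hours=config.utc_offset_hours)),
        )
        frac = (
            float(config.ephemeris[d])
            if config.ephemeris is not None
            else illuminated_fraction(midnight, config)
        )
        rows.append({"date": ts, "fraction": frac, "moon_class": classify_night(d, config)})
    return pd.DataFrame(rows)


def load_ephemeris(path: str | Path) -> dict:
    """Read a date,fraction CSV into an ephemeris override mapping."""
    df = pd.read_csv(path)
    if not {"date", "fraction"} <= set(df.columns):
        raise ValueError("ephemeris file needs columns: date, fraction")
    df["date"] = pd.to_datetime(df["date"]).dt.date
    bad = ~df["fraction"].between(0, 1)
    if bad.any():
        raise ValueError(f"{int(bad.sum())} ephemeris fractions outside [0, 1]")
    return dict(zip(df["date"], df["fraction"]))
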