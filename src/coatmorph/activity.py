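"""Proportion of dates with events (PDE) and its bootstrap standard error.

PDE is a simple camera-trap activity index: the percentage of camera
operating nights on which at least one cat event was captured,

    PDE = 100 * nights_with_captures / operating_nights.

Standard errors come from a nonparametric bootstrap that resamples *camera
sites* with replacement, because nights within a site are dependent. The
pooled estimator (total capture nights over total operating nights) is
primary; the unweighted mean of per-site PDEs is also reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class PDEResult:
    stratum: str
    pde_percent: float
    se: float
    mean_site_pde: float
    mean_site_se: float
    n_sites: int
    bootstrap_reps: int
    seed: int


def pde(nights_with_captures: int, operating_nights: int) -> float:
    """Activity index in percent; requires captures <= operating nights > 0."""
    if operating_nights <= 0:
        raise ValueError("operating_nights must be positive")
    if not 0 <= nights_with_captures <= operating_nights:
        raise ValueError("nights_with_captures must lie in [0, operating_nights]")
    return 100.0 * nights_with_captures / operating_nights


def site_night_table(nights: pd.DataFrame, daily: pd.DataFrame) -> pd.DataFrame:
    """Per-site, per-moon-stratum operating and capture night counts.

    ``nights``: camera-nights with site_id, date, moon_class.
    ``daily``: daily event records (site_id, date, category); a night counts
    as captured when any category was recorded.
    """
    nights = nights.copy()
    nights["date"] = pd.to_datetime(nights["date"]).dt.normalize()
    cap = daily[["site_id", "date"]].copy()
    cap["date"] = pd.to_datetime(cap["date"]).dt.normalize()
    cap = cap.drop_duplicates()
    cap["captured"] = 1
    merged = nights.merge(cap, on=["site_id", "date"], how="left")
    merged["captured"] = merged["captured"].fillna(0).astype(int)
    out = (
        merged.groupby(["site_id", "moon_class"])
        .agg(operating_nights=("date", "size"), capture_nights=("captured", "sum"))
        .reset_index()
    )
    return out


def bootstrap_pde(
    table: pd.DataFrame,
    stratum: str = "all",
    B: int = 1000,
    seed: int | None = None,
) -> PDEResult:
    """Pooled PDE for a moon stratum with a site-resampling bootstrap SE.

    ``table`` is the output of :func:`site_night_table`. ``stratum`` is
    'full', 'new' or 'all' (pooling both). The seed fully determines the
    resamples, so results are bit-identical across runs.
    """
    if seed is None:
        raise ValueError("a bootstrap seed is required for reproducibility")
    if stratum != "all":
        table = table[table["moon_class"] == stratum]
    grouped = (
        table.groupby("site_id")
        .agg(operating_nights=("operating_nights", "sum"), capture_nights=("capture_nights", "sum"))
        .reset_index()
    )
    n_sites = len(grouped)
    if n_sites < 2:
        raise ValueError("bootstrap SE needs at least two sites in the stratum")
    nights = grouped["operating_nights"].to_numpy(dtype=float)
    caps = grouped["capture_nights"].to_numpy(dtype=float)

    point = 100.0 * caps.sum() / nights.sum()
    site_pde = 100.0 * caps / nights
    mean_site = float(site_pde.mean())

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n_sites, size=(B, n_sites))
    rep_pooled = 100.0 * caps[idx].sum(axis=1) / nights[idx].sum(axis=1)
    rep_mean = site_pde[idx].mean(axis=1)
    return PDEResult(
        stratum=stratum,
        pde_percent=float(point),
        se=float(rep_pooled.std(ddof=1)),
        mean_site_pde=mean_site,
        mean_site_se=float(rep_mean.std(ddof=1)),
        n_sites=n_sites,
        bootstrap_reps=B,
        seed=int(seed),
    )
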