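"""Detections -> events -> daily records -> retained sites -> site summaries.

A *detection* is one camera image with coat labels and an optional individual
identity. An *event* is a burst of images of one cat separated by no more
than a fixed gap (default 60 s). A *daily event* is a camera-date on which at
least one event of a given coat category occurred. Sites are retained when
they either detected a cat or operated long enough for an absence to be
credible; the operating-day threshold is the empirical 95th percentile of
first-detection latencies across cameras.

Solid black cats carry no individually identifying markings, so their
abundance is estimated from the survey-wide images-per-identified-cat ratio
rather than counted directly.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .taxonomy import (
    DETECTION_COLUMNS,
    MODEL_CATEGORIES,
    CoatValidationError,
    ModelCategory,
    coat_from_labels,
    to_model_category,
)

logger = logging.getLogger(__name__)

_UNKNOWN_ID = ""


class SchemaError(ValueError):
    """An input table violates its documented schema."""


# --------------------------------------------------------------------------
# Ingest


def read_detections(path_or_df) -> pd.DataFrame:
    """Load and validate a detection table.

    Expected columns: site_id, timestamp (ISO-8601), pattern, colour,
    white (0/1), individual_id (empty = unknown). Adds a ``category`` column
    with the modelling category of each image. Illegal coat labels are
    reported with their row numbers.
    """
    if isinstance(path_or_df, pd.DataFrame):
        df = path_or_df.copy()
    else:
        df = pd.read_csv(path_or_df, dtype={"site_id": str, "individual_id": str})
    missing = [c for c in DETECTION_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"detection table missing columns: {missing}")
    df["site_id"] = df["site_id"].astype(str)
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    df["individual_id"] = df["individual_id"].fillna(_UNKNOWN_ID).astype(str)

    categories = []
    bad_rows: list[tuple[int, str]] = []
    for row in df.itertuples(index=True):
        try:
            coat = coat_from_labels(row.pattern, row.colour, row.white)
        except CoatValidationError as exc:
            bad_rows.append((row.Index, str(exc)))
            continue
        categories.append(to_model_category(coat).value)
    if bad_rows:
        head = "; ".join(f"row {i}: {msg}" for i, msg in bad_rows[:5])
        raise SchemaError(f"{len(bad_rows)} invalid detection rows ({head})")
    df["category"] = categories
    return df


def read_deployments(path_or_df) -> pd.DataFrame:
    """Load a deployment table (site_id, start_date, end_date[, outage_days]).

    ``operating_days`` = inclusive day span minus any outage days.
    """
    if isinstance(path_or_df, pd.DataFrame):
        df = path_or_df.copy()
    else:
        df = pd.read_csv(path_or_df, dtype={"site_id": str})
    for col in ("site_id", "start_date", "end_date"):
        if col not in df.columns:
            raise SchemaError(f"deployment table missing column: {col}")
    df["site_id"] = df["site_id"].astype(str)
    df["start_date"] = pd.to_datetime(df["start_date"]).dt.normalize()
    df["end_date"] = pd.to_datetime(df["end_date"]).dt.normalize()
    outages = df["outage_days"] if "outage_days" in df.columns else 0
    df["operating_days"] = (df["end_date"] - df["start_date"]).dt.days + 1 - outages
    if (df["operating_days"] < 1).any():
        bad = df.loc[df["operating_days"] < 1, "site_id"].tolist()
        raise SchemaError(f"deployments with < 1 operating day: {bad}")
    return df


def category_image_counts(detections: pd.DataFrame) -> pd.Series:
    """Image counts per modelling category (conservation: sums to len(df))."""
    return detections["category"].value_counts()


# --------------------------------------------------------------------------
# Event grouping


def group_events(detections: pd.DataFrame, gap_seconds: int = 60) -> pd.DataFrame:
    """Aggregate images into independent events.

    Within a site, images stream by individual identity when known; images of
    unidentified cats stream by coat category. A new event starts whenever the
    gap between consecutive images strictly exceeds ``gap_seconds``. Distinct
    known individuals never merge into one event.

    Returns a table with columns site_id, individual_id, category,
    start_time, end_time, n_images.
    """
    if gap_seconds <= 0:
        raise ValueError("gap_seconds must be positive")
    if detections.empty:
        return pd.DataFrame(
            columns=["site_id", "individual_id", "category", "start_time", "end_time", "n_images"]
        )
    df = detections.copy()
    known = df["individual_id"] != _UNKNOWN_ID
    # unknown-ID images stream by coat category so an event has one category
    df["_stream"] = np.where(known, "id:" + df["individual_id"], "cat:" + df["category"])
    df = df.sort_values(["site_id", "_stream", "timestamp"], kind="mergesort")

    dup = df.duplicated(subset=["site_id", "_stream", "timestamp"])
    if dup.any():
        warnings.warn(
            f"{int(dup.sum())} duplicate timestamps within a detection stream; keeping first",
            stacklevel=2,
        )
        df = df[~dup]

    same_stream = (df["site_id"] == df["site_id"].shift()) & (df["_stream"] == df["_stream"].shift())
    gap = df["timestamp"].diff().dt.total_seconds()
    new_event = ~same_stream | (gap > gap_seconds)
    df["_event"] = new_event.cumsum()

    events = (
        df.groupby("_event", sort=True)
        .agg(
            site_id=("site_id", "first"),
            individual_id=("individual_id", "first"),
            category=("category", "first"),
            start_time=("timestamp", "min"),
            end_time=("timestamp", "max"),
            n_images=("timestamp", "size"),
        )
        .reset_index(drop=True)
    )
    return events


def daily_records(events: pd.DataFrame, deployments: pd.DataFrame | None = None) -> pd.DataFrame:
    """One presence flag per (site, calendar date, category) with >= 1 event.

    The date is the local calendar date of the event start. If a deployment
    table is given, events outside their site's window raise a validation
    error.
    """
    if events.empty:
        return pd.DataFrame(columns=["site_id", "date", "category"])
    df = events.copy()
    df["date"] = df["start_time"].dt.normalize()
    if deployments is not None:
        merged = df.merge(
            deployments[["site_id", "start_date", "end_date"]], on="site_id", how="left"
        )
        outside = (merged["date"] < merged["start_date"]) | (merged["date"] > merged["end_date"])
        if outside.any():
            raise SchemaError(
                f"{int(outside.sum())} events fall outside their site's deployment window"
            )
    return df[["site_id", "date", "category"]].drop_duplicates().reset_index(drop=True)


# --------------------------------------------------------------------------
# Site retention


@dataclass(frozen=True)
class RetentionConfig:
    """Rule for discarding short cat-free deployments as potential false
    negatives."""

    threshold_days: int = 83
    percentile: float = 95.0

    def __post_init__(self) -> None:
        if self.threshold_days < 0:
            raise ValueError("threshold_days must be >= 0")
        if not 0 < self.percentile <= 100:
            raise ValueError("percentile must lie in (0, 100]")


def first_detection_latency(deployment, events: pd.DataFrame) -> int | None:
    """Whole days from deployment start to the first cat event, or None."""
    site_events = events[events["site_id"] == str(deployment["site_id"])]
    if site_events.empty:
        return None
    start = pd.Timestamp(deployment["start_date"]).normalize()
    first = site_events["start_time"].min().normalize()
    if first < start:
        raise SchemaError(
            f"site {deployment['site_id']}: event on {first.date()} precedes "
            f"deployment start {start.date()}"
        )
    return int((first - start).days)


def derive_retention_threshold(latencies: Iterable[float], percentile: float = 95.0) -> int:
    """Empirical percentile of first-detection latencies, ceiled to whole days.

    The ceiling is conservative: it discards more short cat-free deployments,
    retaining fewer potential false absences.
    """
    arr = np.asarray([x for x in latencies if x is not None and np.isfinite(x)], dtype=float)
    if arr.size == 0:
        raise ValueError("no finite latencies to derive a threshold from")
    return int(math.ceil(np.percentile(arr, percentile)))


def filter_sites(
    deployments: pd.DataFrame, events: pd.DataFrame, config: RetentionConfig
) -> set[str]:
    """Sites retained: any cat event, or operating long enough for a credible
    absence. A site with a detection is never discarded."""
    with_cats = set(events["site_id"].astype(str)) if not events.empty else set()
    long_enough = set(
        deployments.loc[deployments["operating_days"] >= config.threshold_days, "site_id"]
    )
    retained = with_cats | long_enough
    dropped = set(deployments["site_id"]) - retained
    if dropped:
        logger.info(
            "discarded %d cat-free sites operating < %d days", len(dropped), config.threshold_days
        )
    return retained


# --------------------------------------------------------------------------
# Black-cat abundance and modal coat type


@dataclass(frozen=True)
class BlackCountEstimate:
    """Ratio estimate of unmarked solid-black individuals.

    images_per_cat = identifiable images / identified individuals;
    estimated_black = black images / images_per_cat.
    """

    images_identifiable: int
    individuals_identified: int
    black_images: int
    images_per_cat: float = field(init=False)
    estimated_black: float = field(init=False)

    def __post_init__(self) -> None:
        if self.individuals_identified <= 0 or self.images_identifiable <= 0:
            raise ValueError("identifiable image and individual counts must be positive")
        object.__setattr__(
            self, "images_per_cat", self.images_identifiable / self.individuals_identified
        )
        object.__setattr__(self, "estimated_black", self.black_images / self.images_per_cat)

    @property
    def estimated_black_rounded(self) -> int:
        return int(round(self.estimated_black))


def estimate_black(
    images_identifiable: int, individuals_identified: int, black_images: int
) -> BlackCountEstimate:
    """Apply the images-per-cat ratio estimator for unmarked black cats."""
    return BlackCountEstimate(images_identifiable, individuals_identified, black_images)


def black_estimate_from_detections(detections: pd.DataFrame) -> BlackCountEstimate:
    """Compute the black-cat estimate from a detection table.

    Identifiable images are all images that are neither solid black nor of
    unknown coat (quality exclusions); identified individuals are the distinct
    known IDs among them.
    """
    known_coat = (detections["pattern"] != "unknown") & (detections["colour"] != "unknown")
    non_black = detections["category"] != ModelCategory.SOLID_BLACK.value
    identifiable = detections[known_coat & non_black]
    ids = identifiable.loc[identifiable["individual_id"] != _UNKNOWN_ID, "individual_id"]
    black_images = int((detections["category"] == ModelCategory.SOLID_BLACK.value).sum())
    return estimate_black(len(identifiable), ids.nunique(), black_images)


def site_black_individuals(black_images: int, images_per_cat: float) -> int:
    """Per-site black individual tally: the global images-per-cat ratio applied
    locally, floored at one cat whenever black images exist."""
    if black_images <= 0:
        return 0
    return max(1, int(round(black_images / images_per_cat)))


def modal_coat(
    individuals: Mapping[ModelCategory, int], event_counts: Mapping[ModelCategory, int]
) -> tuple[ModelCategory, bool]:
    """Modal coat type of a site: most individuals, ties broken by most
    events, residual ties by fixed prevalence order (flagged)."""
    active = [
        c
        for c in MODEL_CATEGORIES
        if individuals.get(c, 0) > 0 or event_counts.get(c, 0) > 0
    ]
    if not active:
        raise ValueError("site has no non-excluded coat category (should have been filtered)")
    max_ind = max(individuals.get(c, 0) for c in active)
    leaders = [c for c in active if individuals.get(c, 0) == max_ind]
    if len(leaders) == 1:
        return leaders[0], False
    max_ev = max(event_counts.get(c, 0) for c in leaders)
    leaders = [c for c in leaders if event_counts.get(c, 0) == max_ev]
    # MODEL_CATEGORIES is already in the deterministic tie-break order
    return leaders[0], True


def site_summaries(
    events: pd.DataFrame,
    detections: pd.DataFrame,
    images_per_cat: float | None = None,
) -> pd.DataFrame:
    """Per-site tallies and modal category.

    Individuals per category are distinct known IDs among the site's events;
    solid-black individuals use the ratio rule (``site_black_individuals``)
    with the survey-wide images-per-cat ratio (computed from the detections
    when not supplied).

    Returns one row per site with ``n_ind_<cat>``, ``n_ev_<cat>``,
    ``modal_category`` and ``tie_broken`` columns.
    """
    if images_per_cat is None:
        images_per_cat = black_estimate_from_detections(detections).images_per_cat

    cats = [c.value for c in MODEL_CATEGORIES]
    rows = []
    black = ModelCategory.SOLID_BLACK.value
    ev_by_site = dict(tuple(events.groupby("site_id")))
    det_by_site = dict(tuple(detections.groupby("site_id")))
    for site_id in sorted(set(events["site_id"]).union(detections["site_id"])):
        sev = ev_by_site.get(site_id, events.iloc[0:0])
        sdet = det_by_site.get(site_id, detections.iloc[0:0])
        ind: dict[ModelCategory, int] = {}
        evc: dict[ModelCategory, int] = {}
        for cat in MODEL_CATEGORIES:
            cev = sev[sev["category"] == cat.value]
            evc[cat] = len(cev)
            if cat.value == black:
                n_black_imgs = int((sdet["category"] == black).sum())
                ind[cat] = site_black_individuals(n_black_imgs, images_per_cat)
            else:
                ids = cev.loc[cev["individual_id"] != _UNKNOWN_ID, "individual_id"]
                ind[cat] = int(ids.nunique())
        row: dict = {"site_id": site_id}
        row.update({f"n_ind_{c}": ind[cat] for c, cat in zip(cats, MODEL_CATEGORIES)})
        row.update({f"n_ev_{c}": evc[cat] for c, cat in zip(cats, MODEL_CATEGORIES)})
        try:
            modal, tied = modal_coat(ind, evc)
        except ValueError:
            modal, tied = ModelCategory.EXCLUDED, False
        row["modal_category"] = modal.value
        row["tie_broken"] = tied
        rows.append(row)
    return pd.DataFrame(rows)
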