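"""Published summary counts from the Tasmanian state-wide feral cat
camera-trap survey (651 retained sites, 234,200 operating days).

These printed tallies are inputs to the package's bookkeeping checks and to
the black-cat ratio estimator; they are not produced by this package. The
mackerel rows aggregate their broken/spotted/striped/ticked subcategories.
Individuals could not be counted for unmarked solid black cats, nor for
unclassifiable (unknown-coat) images.
"""

from __future__ import annotations

import pandas as pd

#: survey-wide totals
TOTAL_SITES = 651
TOTAL_OPERATING_DAYS = 234_200
RETENTION_THRESHOLD_DAYS = 83

#: temporal-model subset: camera-nights under a bright or dark moon
FULL_MOON_NIGHTS = 89_847
NEW_MOON_NIGHTS = 90_759
MOON_SUBSET_NIGHTS_PRINTED = 180_060  # as printed; cf. the sum of the two counts
CAPTURE_NIGHTS_IN_SUBSET = 7_433

#: mean activity index (percent of operating nights with a capture)
PDE_FULL_PERCENT = 3.4
PDE_FULL_SE = 0.18
PDE_NEW_PERCENT = 4.0
PDE_NEW_SE = 0.23

_SUMMARY_ROWS = [
    # coat_type, subcategory_of, images, daily_events, pct_images, individuals, images_white, sites
    ("solid_black", None, 9706, 8276, 40.32, None, 150, 478),
    ("blotched_brown", None, 3636, 3009, 15.10, 194, 38, 281),
    ("mackerel_brown", None, 7413, 6011, 30.79, 349, 41, 455),
    ("broken_brown", "mackerel_brown", 4266, 3545, 17.72, 204, 33, 349),
    ("spotted_brown", "mackerel_brown", 2878, 2264, 11.95, 129, 8, 225),
    ("striped_brown", "mackerel_brown", 224, 167, 0.93, 11, 0, 19),
    ("ticked_brown", "mackerel_brown", 45, 35, 0.19, 5, 0, 12),
    ("blotched_orange", None, 297, 250, 1.23, 20, 14, 46),
    ("mackerel_orange", None, 761, 492, 3.16, 45, 8, 87),
    ("broken_orange", "mackerel_orange", 457, 252, 1.90, 29, 8, 62),
    ("spotted_orange", "mackerel_orange", 288, 229, 1.20, 12, 0, 22),
    ("striped_orange", "mackerel_orange", 7, 6, 0.03, 3, 0, 3),
    ("ticked_orange", "mackerel_orange", 9, 5, 0.04, 1, 0, 1),
    ("tortoiseshell", None, 691, 508, 2.87, 55, 14, 92),
    ("tuxedo", None, 183, 160, 0.76, 11, 183, 12),
    ("unknown", None, 1388, 1014, 5.77, None, 0, 464),
]

PRINTED_TOTAL_IMAGES = 24_075
PRINTED_TOTAL_DAILY_EVENTS = 19_837
PRINTED_TOTAL_INDIVIDUALS = 674
PRINTED_TOTAL_IMAGES_WHITE = 456


def survey_summary() -> pd.DataFrame:
    """The published per-coat-type survey summary as a tidy DataFrame.

    ``subcategory_of`` is non-null for the mackerel subtypes, which are
    already included in their parent rows; filter it out for grand totals.
    """
    return pd.DataFrame(
        _SUMMARY_ROWS,
        columns=[
            "coat_type",
            "subcategory_of",
            "images",
            "daily_events",
            "pct_images",
            "individuals",
            "images_white",
            "sites",
        ],
    )


def top_level_summary() -> pd.DataFrame:
    """Summary rows excluding mackerel subcategories (no double counting)."""
    df = survey_summary()
    return df[df["subcategory_of"].isna()].reset_index(drop=True)
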