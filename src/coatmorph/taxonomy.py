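"""Coat phenotype vocabulary and the mapping to modelling categories.

Feral cat coats are recorded per image as a (pattern, colour, white) triple:
a pelage pattern, a colour gene expression, and a flag for white patches
(controlled by a separate locus, so it may co-occur with any pattern/colour).
For statistical modelling the raw vocabulary is collapsed into five
categories of assumed ecological similarity — solid black, blotched brown,
mackerel brown, orange, and tortoiseshell — with mostly-white (tuxedo) cats
and unclassifiable images excluded.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from pathlib import Path

logger = logging.getLogger(__name__)


class CoatPattern(str, enum.Enum):
    """Pelage pattern as labelled from a camera-trap image."""

    SOLID = "solid"
    BLOTCHED = "blotched"
    BROKEN = "broken"
    SPOTTED = "spotted"
    STRIPED = "striped"
    TICKED = "ticked"
    TORTOISESHELL = "tortoiseshell"
    TUXEDO = "tuxedo"
    UNKNOWN = "unknown"


class CoatColour(str, enum.Enum):
    """Coat colour; tabby patterns can be brown or orange, tortoiseshell is a
    mosaic ('mixed'), solid cats are black."""

    BLACK = "black"
    BROWN = "brown"
    ORANGE = "orange"
    MIXED = "mixed"
    UNKNOWN = "unknown"


class ModelCategory(str, enum.Enum):
    """The five analysis coat classes, plus the excluded bucket."""

    SOLID_BLACK = "solid_black"
    BLOTCHED_BROWN = "blotched_brown"
    MACKEREL_BROWN = "mackerel_brown"
    ORANGE = "orange"
    TORTOISESHELL = "tortoiseshell"
    EXCLUDED = "excluded"


#: Categories that enter any statistical model, in the fixed tie-break order
#: (descending survey-wide prevalence).
MODEL_CATEGORIES: tuple[ModelCategory, ...] = (
    ModelCategory.SOLID_BLACK,
    ModelCategory.MACKEREL_BROWN,
    ModelCategory.BLOTCHED_BROWN,
    ModelCategory.ORANGE,
    ModelCategory.TORTOISESHELL,
)

#: Tabby patterns; each may be brown or orange.
TABBY_PATTERNS = frozenset(
    {
        CoatPattern.BLOTCHED,
        CoatPattern.BROKEN,
        CoatPattern.SPOTTED,
        CoatPattern.STRIPED,
        CoatPattern.TICKED,
    }
)

#: The "mackerel" group: tabby patterns pooled with blotched excluded.
MACKEREL_PATTERNS = frozenset(
    {CoatPattern.BROKEN, CoatPattern.SPOTTED, CoatPattern.STRIPED, CoatPattern.TICKED}
)


class CoatValidationError(ValueError):
    """An internally inconsistent (pattern, colour, white) triple."""


@dataclass(frozen=True)
class CoatRecord:
    """One image's coat labels.

    ``white`` flags any white patch, sock or point colouration; it is
    independent of pattern and colour except that tuxedo (a mostly-white cat)
    implies ``white=True``.
    """

    pattern: CoatPattern
    colour: CoatColour
    white: bool = False

    def __post_init__(self) -> None:
        validate_coat(self.pattern, self.colour, self.white)


def _legal_colours(pattern: CoatPattern) -> frozenset[CoatColour]:
    if pattern in TABBY_PATTERNS:
        return frozenset({CoatColour.BROWN, CoatColour.ORANGE, CoatColour.UNKNOWN})
    if pattern is CoatPattern.SOLID:
        return frozenset({CoatColour.BLACK, CoatColour.UNKNOWN})
    if pattern is CoatPattern.TORTOISESHELL:
        return frozenset({CoatColour.MIXED, CoatColour.UNKNOWN})
    if pattern is CoatPattern.TUXEDO:
        return frozenset({CoatColour.BLACK, CoatColour.UNKNOWN})
    # unknown pattern: colour unconstrained (nothing to validate against)
    return frozenset(CoatColour)


def validate_coat(pattern: CoatPattern, colour: CoatColour, white: bool) -> None:
    """Reject illegal label combinations rather than coercing them.

    Raises
    ------
    CoatValidationError
        If the pattern/colour pair is impossible (e.g. solid + orange) or a
        tuxedo record carries ``white=False``.
    """
    pattern = CoatPattern(pattern)
    colour = CoatColour(colour)
    if colour not in _legal_colours(pattern):
        raise CoatValidationError(
            f"illegal coat labels: pattern={pattern.value!r} cannot pair with "
            f"colour={colour.value!r}"
        )
    if pattern is CoatPattern.TUXEDO and not white:
        raise CoatValidationError(
            "illegal coat labels: pattern='tuxedo' requires white=True "
            "(tuxedo is defined by majority-white coverage)"
        )


def legal_raw_types() -> list[tuple[CoatPattern, CoatColour]]:
    """All fully-determined (pattern, colour) coat types (no unknown field).

    Five tabby patterns x two colours, plus solid black, tortoiseshell and
    tuxedo: 13 types in total.
    """
    types: list[tuple[CoatPattern, CoatColour]] = []
    for pattern in CoatPattern:
        if pattern is CoatPattern.UNKNOWN:
            continue
        for colour in sorted(_legal_colours(pattern), key=lambda c: c.value):
            if colour is not CoatColour.UNKNOWN:
                types.append((pattern, colour))
    return types


def legal_triples() -> list[tuple[CoatPattern, CoatColour, bool]]:
    """All legal (pattern, colour, white) triples including unknown states."""
    triples = []
    for pattern in CoatPattern:
        for colour in _legal_colours(pattern):
            for white in (False, True):
                if pattern is CoatPattern.TUXEDO and not white:
                    continue
                triples.append((pattern, colour, white))
    return triples


def to_model_category(coat: CoatRecord) -> ModelCategory:
    """Map a validated coat record onto one of the five modelling categories.

    The mapping is total and deterministic: any unknown field or a tuxedo
    pattern maps to ``EXCLUDED``; orange tabbies of any pattern pool into
    ``ORANGE``; brown broken/spotted/striped/ticked tabbies pool into
    ``MACKEREL_BROWN``. The white flag never changes the category (tuxedo is
    the only white-defined pattern and is excluded outright).
    """
    pattern, colour = coat.pattern, coat.colour
    if pattern is CoatPattern.UNKNOWN or colour is CoatColour.UNKNOWN:
        return ModelCategory.EXCLUDED
    if pattern is CoatPattern.TUXEDO:
        return ModelCategory.EXCLUDED
    if pattern is CoatPattern.TORTOISESHELL:
        return ModelCategory.TORTOISESHELL
    if pattern is CoatPattern.SOLID:
        return ModelCategory.SOLID_BLACK
    # tabby patterns from here on
    if colour is CoatColour.ORANGE:
        return ModelCategory.ORANGE
    if pattern is CoatPattern.BLOTCHED:
        return ModelCategory.BLOTCHED_BROWN
    return ModelCategory.MACKEREL_BROWN


# --------------------------------------------------------------------------
# Ingest helpers

#: Raw colour labels recoded at ingest; grey cats sit on a gradient to brown
#: and are folded into brown.
COLOUR_RECODES = {"grey": "brown", "gray": "brown"}

DETECTION_COLUMNS = ("site_id", "timestamp", "pattern", "colour", "white", "individual_id")


def normalise_colour(raw: str) -> str:
    """Lower-case a raw colour label and apply ingest recodes (grey -> brown)."""
    label = str(raw).strip().lower()
    if label in COLOUR_RECODES:
        logger.info("recoding colour %r -> %r at ingest", label, COLOUR_RECODES[label])
        return COLOUR_RECODES[label]
    return label


def coat_from_labels(pattern: str, colour: str, white) -> CoatRecord:
    """Build a validated CoatRecord from raw string/flag labels."""
    try:
        pat = CoatPattern(str(pattern).strip().lower())
    except ValueError as exc:
        raise CoatValidationError(f"unrecognised pattern label {pattern!r}") from exc
    try:
        col = CoatColour(normalise_colour(colour))
    except ValueError as exc:
        raise CoatValidationError(f"unrecognised colour label {colour!r}") from exc
    return CoatRecord(pat, col, bool(int(white)))


def taxonomy_table() -> dict[str, list[str]]:
    """Legal label values, for machine-readable ingest validation."""
    return {
        "pattern": [p.value for p in CoatPattern],
        "colour": [c.value for c in CoatColour] + sorted(COLOUR_RECODES),
        "white": ["0", "1"],
        "model_category": [c.value for c in ModelCategory],
    }


def write_taxonomy_file(path: str | Path) -> None:
    """Write the legal vocabulary as a key-value text file (one key per line)."""
    lines = [f"{key} = {', '.join(values)}" for key, values in taxonomy_table().items()]
    Path(path).write_text("\n".join(lines) + "\n")
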