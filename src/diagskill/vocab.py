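"""Aspect vocabularies for the eight tongue-diagnosis viewpoints.

A tongue image is diagnosed on eight categorical aspects (size, colour and
moisture of the tongue body; tooth marks; cracks; thickness, colour and
moisture of the tongue coating).  Each aspect has a closed answer
vocabulary of 4-6 categories.  ``not_applicable`` (and, for size,
``unevaluable``) are genuine selectable answers — a rater can judge that a
finding cannot be assessed — and are therefore vocabulary members, distinct
from a missing response (which is simply an absent record).

Category labels are canonical snake_case tokens; :data:`DISPLAY_TO_TOKEN`
maps the human-readable display strings found in published tables
("Red–deep red", "Light red") onto tokens so that keys typed from such
tables join cleanly with machine-generated data.
"""

from __future__ import annotations

import re

from .errors import VocabularyError

#: Ordered vocabularies, one per aspect.  Order matters for the "adjacent"
#: confusion kernel, which treats the substantive categories as ordinal.
ASPECTS: dict[str, tuple[str, ...]] = {
    "body_size": ("normal", "swelling", "thin", "not_applicable", "unevaluable"),
    "body_color": ("pale", "light_red", "red_to_deep_red", "purple", "not_applicable"),
    "body_moisture": ("normal", "dry", "wet", "not_applicable"),
    "tooth_marks": ("none", "mild", "severe", "not_applicable"),
    "cracks": ("none", "mild", "severe", "not_applicable"),
    "coating_thickness": (
        "none",
        "normal",
        "moderate",
        "moderate_or_higher_with_peeling",
        "thick",
        "not_applicable",
    ),
    "coating_color": (
        "white",
        "yellowish_white_to_light_brown",
        "yellow",
        "dark_brown_to_black",
        "not_applicable",
    ),
    "coating_moisture": ("normal", "dry", "wet", "not_applicable"),
}

ASPECT_NAMES: tuple[str, ...] = tuple(ASPECTS)

#: Categories that mean "cannot be assessed"; excluded from the default
#: latent-truth prior in simulations but always selectable by raters.
NON_FINDING: tuple[str, ...] = ("not_applicable", "unevaluable")

_DISPLAY_RAW = {
    "normal": "normal",
    "swelling": "swelling",
    "thin": "thin",
    "not applicable": "not_applicable",
    "unevaluable": "unevaluable",
    "unevaluable due to insufficient tongue protruding out of the mouth": "unevaluable",
    "pale": "pale",
    "light red": "light_red",
    "red-deep red": "red_to_deep_red",
    "red to deep red": "red_to_deep_red",
    "purple": "purple",
    "dry": "dry",
    "wet": "wet",
    "none": "none",
    "mild": "mild",
    "severe": "severe",
    "moderate": "moderate",
    "moderate or higher with peeling": "moderate_or_higher_with_peeling",
    "thick": "thick",
    "white": "white",
    "yellowish white-light brown": "yellowish_white_to_light_brown",
    "yellowish white to light brown": "yellowish_white_to_light_brown",
    "yellow": "yellow",
    "dark brown-black": "dark_brown_to_black",
    "dark brown to black": "dark_brown_to_black",
}


def _normalise(display: str) -> str:
    # unify unicode dashes and whitespace before lookup
    s = re.sub(r"[‐-―−]", "-", display.strip().lower())
    return re.sub(r"\s+", " ", s)


DISPLAY_TO_TOKEN: dict[str, str] = {k: v for k, v in _DISPLAY_RAW.items()}


def vocabulary(aspect: str) -> tuple[str, ...]:
    """Return the ordered category vocabulary of *aspect*."""
    try:
        return ASPECTS[aspect]
    except KeyError:
        raise VocabularyError(
            f"unknown aspect {aspect!r}; expected one of {ASPECT_NAMES}"
        ) from None


def substantive_categories(aspect: str) -> tuple[str, ...]:
    """Categories of *aspect* that describe an actual finding."""
    return tuple(c for c in vocabulary(aspect) if c not in NON_FINDING)


def to_token(display: str, aspect: str | None = None) -> str:
    """Convert a display string (e.g. ``"Red–deep red"``) to its token.

    Strings that already are canonical tokens pass through unchanged.  If
    *aspect* is given the result is additionally checked for membership in
    that aspect's vocabulary.
    """
    key = _normalise(display)
    token = DISPLAY_TO_TOKEN.get(key, DISPLAY_TO_TOKEN.get(key.replace("_", " "), display))
    if aspect is not None and token not in vocabulary(aspect):
        raise VocabularyError(
            f"{display!r} (token {token!r}) is not in the {aspect} vocabulary"
        )
    return token
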