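"""Instrument definitions and scoring rules.

Three instruments are supported:

* **PRHISM** — 13 principles, each rated on a 0–4 Likert scale, any of
  which may be marked not applicable (NA).  The principle ratings are
  converted to a 0–100 *PRHISM score* over the applicable items only, and
  the score is banded into four quality categories (poor, mediocre, good,
  excellent).  A single 0–4 *overall quality* judgment is recorded
  alongside the principles; it never enters the 13-item score and exists
  solely for agreement analyses.
* **DISCERN** — 15 quality items plus 1 overall judgment, each rated 1–5.
  The classic total is the sum of all 16 responses (16–80).  The
  *modified DISCERN score* drops the overall item and rescales the 15
  items to 0–100 over the applicable ones, making it directly comparable
  with the PRHISM score.
* **Expert assessment** — accuracy and potential-harm judgments on a 1–5
  scale.  The source tool codes 1 = accurate / not harmful; ratings are
  reversed (``value -> 6 - value``) so that 5 = accurate / nonharmful,
  matching the orientation of the other two instruments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

__all__ = [
    "N_PRHISM_ITEMS",
    "N_DISCERN_ITEMS",
    "QualityBand",
    "PrhismRating",
    "DiscernRating",
    "ExpertAssessment",
    "ScoredRating",
    "prhism_score",
    "prhism_category",
    "discern_total",
    "modified_discern_score",
    "recode_expert",
]

N_PRHISM_ITEMS = 13
N_DISCERN_ITEMS = 15  # quality items; the overall judgment is the 16th response


class NoApplicableItemsError(ValueError):
    """Raised when every item of a rating is marked not applicable."""


class QualityBand(str, Enum):
    """Four-level quality classification of a 0–100 score.

    Bands follow the published integer ranges: 0–25 poor, 26–50 mediocre,
    51–75 good, 76–100 excellent.  ``code`` gives the conventional ordinal
    coding 1 = poor … 4 = excellent used in agreement analyses.
    """

    POOR = "poor"
    MEDIOCRE = "mediocre"
    GOOD = "good"
    EXCELLENT = "excellent"

    @property
    def code(self) -> int:
        return {"poor": 1, "mediocre": 2, "good": 3, "excellent": 4}[self.value]


def _check_items(values: Sequence[Optional[int]], n: int, lo: int, hi: int,
                 what: str) -> None:
    if len(values) != n:
        raise ValueError(f"expected exactly {n} {what}, got {len(values)}")
    for v in values:
        if v is None:
            continue
        if not isinstance(v, (int,)) or isinstance(v, bool) or not lo <= v <= hi:
            raise ValueError(
                f"{what} values must be integers in [{lo}, {hi}] or None (NA); got {v!r}"
            )


def _check_scalar(v: int, lo: int, hi: int, what: str) -> None:
    if not isinstance(v, int) or isinstance(v, bool) or not lo <= v <= hi:
        raise ValueError(f"{what} must be an integer in [{lo}, {hi}]; got {v!r}")


@dataclass(frozen=True)
class PrhismRating:
    """One rater's PRHISM assessment of one video.

    ``principle_scores`` holds the 13 principle responses (0–4, ``None``
    for not applicable); ``overall`` is the global 0–4 quality judgment,
    which is never NA and never contributes to the score.
    """

    principle_scores: tuple
    overall: int

    def __post_init__(self):
        object.__setattr__(self, "principle_scores", tuple(self.principle_scores))
        _check_items(self.principle_scores, N_PRHISM_ITEMS, 0, 4, "PRHISM principle")
        _check_scalar(self.overall, 0, 4, "PRHISM overall")


@dataclass(frozen=True)
class DiscernRating:
    """One rater's DISCERN assessment: 15 items (1–5 or NA) plus overall (1–5)."""

    item_scores: tuple
    overall: int

    def __post_init__(self):
        object.__setattr__(self, "item_scores", tuple(self.item_scores))
        _check_items(self.item_scores, N_DISCERN_ITEMS, 1, 5, "DISCERN item")
        _check_scalar(self.overall, 1, 5, "DISCERN overall")


@dataclass(frozen=True)
class ExpertAssessment:
    """Expert accuracy/harm judgment, oriented so 5 = accurate / nonharmful."""

    accuracy: int
    harm: int
    reason_text: Optional[str] = field(default=None, compare=False)

    def __post_init__(self):
        _check_scalar(self.accuracy, 1, 5, "accuracy")
        _check_scalar(self.harm, 1, 5, "harm")


@dataclass(frozen=True)
class ScoredRating:
    """A 0–100 instrument score with its applicability count and, for
    PRHISM, the quality band."""

    score: float
    n_applicable: int
    category: Optional[QualityBand] = None

    def __post_init__(self):
        if not 0.0 <= self.score <= 100.0:
            raise ValueError(f"score must lie in [0, 100]; got {self.score}")
        if self.n_applicable < 1:
            raise ValueError("n_applicable must be >= 1")
        if self.category is not None and self.category != prhism_category(self.score):
            raise ValueError(
                f"category {self.category} inconsistent with score {self.score}"
            )


def prhism_score(rating: PrhismRating) -> ScoredRating:
    """Convert a PRHISM rating to the 0–100 PRHISM score.

    The score is the sum of the applicable (non-NA) principle responses
    as a percentage of the maximum attainable over those items:
    ``100 * sum / (4 * n_applicable)``.  The overall-quality judgment is
    excluded.  Raises :class:`NoApplicableItemsError` if all 13
    principles are NA.
    """
    applicable = [v for v in rating.principle_scores if v is not None]
    if not applicable:
        raise NoApplicableItemsError(
            "all 13 PRHISM principles are marked not applicable; "
            "no score can be computed"
        )
    n = len(applicable)
    score = 100.0 * sum(applicable) / (4.0 * n)
    return ScoredRating(score=score, n_applicable=n, category=prhism_category(score))


def prhism_category(score: float) -> QualityBand:
    """Band a 0–100 score into poor / mediocre / good / excellent.

    The published bands are integer ranges (0–25, 26–50, 51–75, 76–100);
    fractional scores are rounded half-up to the nearest integer first,
    so 75.5 -> 76 -> excellent while 75.4 -> 75 -> good.
    """
    if not 0.0 <= score <= 100.0:
        raise ValueError(f"score must lie in [0, 100]; got {score}")
    rounded = math.floor(score + 0.5)
    if rounded <= 25:
        return QualityBand.POOR
    if rounded <= 50:
        return QualityBand.MEDIOCRE
    if rounded <= 75:
        return QualityBand.GOOD
    return QualityBand.EXCELLENT


def discern_total(rating: DiscernRating) -> int:
    """Classic DISCERN total: sum of the 15 items plus the overall (16–80).

    Only defined when every item is applicable; with NA items present the
    caller should use :func:`modified_discern_score`, which rescales over
    the applicable items.
    """
    if any(v is None for v in rating.item_scores):
        raise ValueError(
            "DISCERN total is undefined with NA items; "
            "use modified_discern_score, which rescales over applicable items"
        )
    total = sum(rating.item_scores) + rating.overall
    assert 16 <= total <= 80
    return total


def modified_discern_score(rating: DiscernRating) -> ScoredRating:
    """Modified DISCERN score on a 0–100 scale.

    The overall-quality item is dropped and the remaining 15 items are
    rescaled over the applicable ones: ``100 * sum / (5 * n_applicable)``.
    Because items floor at 1, the minimum attainable score is 20.  This
    mirrors the PRHISM conversion so the two scores are comparable.
    """
    applicable = [v for v in rating.item_scores if v is not None]
    if not applicable:
        raise NoApplicableItemsError(
            "all 15 DISCERN items are marked not applicable; "
            "no score can be computed"
        )
    n = len(applicable)
    score = 100.0 * sum(applicable) / (5.0 * n)
    return ScoredRating(score=score, n_applicable=n)


def recode_expert(raw_accuracy: int, raw_harm: int,
                  reason_text: Optional[str] = None) -> ExpertAssessment:
    """Reverse-code expert ratings so that 5 = accurate / nonharmful.

    The source tool rates accurate information as 1 and inaccurate as 5
    (likewise harm); each value is mapped to ``6 - value``.  The mapping
    is an involution: applying it twice returns the original coding.
    """
    _check_scalar(raw_accuracy, 1, 5, "raw accuracy")
    _check_scalar(raw_harm, 1, 5, "raw harm")
    return ExpertAssessment(
        accuracy=6 - raw_accuracy, harm=6 - raw_harm, reason_text=reason_text
    )
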