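"""Relationship Assessment Scale (RAS) scoring.

The RAS is a 7-item relationship-satisfaction questionnaire answered on a
7-point Likert scale.  Items 4 ("How often do you wish you hadn't gotten
into this relationship?") and 7 ("How many problems are there in your
relationship?") are phrased negatively and are reverse-scored with the
instrument's standard key, ``x -> 8 - x``.  The satisfaction score is the
mean of the seven keyed items, so it lives on the same 1..7 scale as the
responses.

The reverse-scored item set is an argument throughout, because published
analyses do not always state their scoring key.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ValidationError

N_ITEMS = 7
LIKERT_MIN = 1
LIKERT_MAX = 7

#: 1-based indices of the negatively phrased items.
REVERSE_SCORED_ITEMS: tuple[int, ...] = (4, 7)


@dataclass(frozen=True)
class RASResponse:
    """One participant's seven Likert responses (each an integer in 1..7)."""

    items: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.items) != N_ITEMS:
            raise ValidationError(
                f"RAS response needs exactly {N_ITEMS} items, got {len(self.items)}"
            )
        for i, x in enumerate(self.items, start=1):
            if not isinstance(x, (int,)) or isinstance(x, bool):
                raise ValidationError(f"RAS item {i} must be an integer, got {x!r}")
            if not LIKERT_MIN <= x <= LIKERT_MAX:
                raise ValidationError(
                    f"RAS item {i} = {x} outside the {LIKERT_MIN}..{LIKERT_MAX} scale"
                )


def score_ras(
    response: RASResponse,
    reverse_items: tuple[int, ...] = REVERSE_SCORED_ITEMS,
) -> float:
    """Satisfaction score: mean of the keyed items, in [1, 7]."""
    keyed = [
        (LIKERT_MAX + 1 - x) if i in reverse_items else x
        for i, x in enumerate(response.items, start=1)
    ]
    return sum(keyed) / N_ITEMS


def satisfaction_difference(score_a: float, score_b: float) -> float:
    """Absolute difference of two satisfaction scores; symmetric, >= 0."""
    for name, s in (("score_a", score_a), ("score_b", score_b)):
        if not LIKERT_MIN <= s <= LIKERT_MAX:
            raise ValidationError(f"{name} = {s} outside the [1, 7] score range")
    return abs(score_a - score_b)
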