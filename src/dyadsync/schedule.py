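"""Block paradigm of the co-viewing experiment.

Each session alternates a 60 s fixation block with a 114 s emotive video,
seven times, for a total of 1218 s (20 min 18 s).  The seven videos are a
fixed set of emotion-eliciting clips; each dyad sees them in one of three
predefined orders (sequences A, B and C).
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ValidationError

FIXATION_DURATION_S = 60.0
VIDEO_DURATION_S = 114.0
N_VIDEOS = 7
TOTAL_DURATION_S = N_VIDEOS * (FIXATION_DURATION_S + VIDEO_DURATION_S)  # 1218 s

#: Video orders of the three stimulus sequences.  "neutral" is the calm
#: ocean clip used as the baseline condition.
SEQUENCES: dict[str, tuple[str, ...]] = {
    "A": ("love", "disgust", "pride", "fear", "happiness", "sadness", "neutral"),
    "B": ("sadness", "love", "neutral", "pride", "disgust", "fear", "happiness"),
    "C": ("neutral", "sadness", "disgust", "happiness", "fear", "pride", "love"),
}

#: Emotion-category membership used by the condition-level aggregation.
CONDITION_CATEGORY: dict[str, str] = {
    "happiness": "positive",
    "love": "positive",
    "pride": "positive",
    "sadness": "negative",
    "fear": "negative",
    "disgust": "negative",
    "neutral": "baseline",
}

VIDEO_CONDITIONS = tuple(CONDITION_CATEGORY)


@dataclass(frozen=True)
class Block:
    """One paradigm block: condition label, onset and duration in seconds."""

    condition: str
    onset_s: float
    duration_s: float


@dataclass(frozen=True)
class EventSchedule:
    """Ordered fixation/video blocks of one session."""

    sequence_label: str
    blocks: tuple[Block, ...]

    @property
    def video_blocks(self) -> tuple[Block, ...]:
        return tuple(b for b in self.blocks if b.condition != "fixation")

    @property
    def total_duration_s(self) -> float:
        last = self.blocks[-1]
        return last.onset_s + last.duration_s

    @property
    def video_onsets_s(self) -> tuple[float, ...]:
        return tuple(b.onset_s for b in self.video_blocks)


def make_schedule(sequence_label: str) -> EventSchedule:
    """Build the event schedule for sequence ``A``, ``B`` or ``C``.

    Video k (1-based) starts at ``60 + 174*(k-1)`` seconds; every fixation
    block lasts 60 s and every video 114 s, so the schedule always totals
    1218 s.
    """
    try:
        order = SEQUENCES[sequence_label]
    except KeyError:
        raise ValidationError(
            f"unknown sequence label {sequence_label!r}; expected one of "
            f"{sorted(SEQUENCES)}"
        ) from None
    blocks: list[Block] = []
    t = 0.0
    for condition in order:
        blocks.append(Block("fixation", t, FIXATION_DURATION_S))
        t += FIXATION_DURATION_S
        blocks.append(Block(condition, t, VIDEO_DURATION_S))
        t += VIDEO_DURATION_S
    return EventSchedule(sequence_label, tuple(blocks))
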