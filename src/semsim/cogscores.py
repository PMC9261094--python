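"""Cognitive summary scores from raw task counts.

Stroop interference follows the Golden method: the predicted colour-word
score is the harmonic composition W*C/(W+C) of the word-reading (W) and
colour-naming (C) counts, and the interference score IG is the actual
colour-word count minus that prediction. The modified DSST total is the mean
of the oral and written correct counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

__all__ = [
    "StroopRecord",
    "CognitiveScores",
    "predicted_colour_word",
    "golden_interference",
    "dsst_total",
]


@dataclass(frozen=True)
class StroopRecord:
    word_score: float          # W: words read correctly
    colour_score: float        # C: colour hues named correctly
    colour_word_score: float   # CW: correct in the incongruent condition
    total_correct: Optional[float] = None
    total_time: Optional[float] = None        # seconds
    incongruent_time: Optional[float] = None  # seconds

    def __post_init__(self):
        for name in ("word_score", "colour_score", "colour_word_score"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class CognitiveScores:
    IG: float
    DSST_total: float
    fluency_count: Optional[int] = None


def predicted_colour_word(word_score: float, colour_score: float) -> float:
    """Predicted colour-word score W*C/(W+C); never exceeds min(W, C)."""
    if word_score < 0 or colour_score < 0:
        raise ValueError("Stroop counts must be >= 0")
    total = word_score + colour_score
    if total == 0:
        raise ValueError("W + C must be positive to predict a colour-word score")
    return word_score * colour_score / total


def golden_interference(record: StroopRecord) -> float:
    """IG = CW - W*C/(W+C). Symmetric in W and C; +1 per extra CW item."""
    return record.colour_word_score - predicted_colour_word(
        record.word_score, record.colour_score
    )


def dsst_total(oral: float, written: float) -> float:
    """Mean of the oral and written DSST correct counts."""
    if oral < 0 or written < 0:
        raise ValueError("DSST counts must be >= 0")
    return (oral + written) / 2.0
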