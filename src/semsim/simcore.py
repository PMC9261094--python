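"""Average Similarity of Words (ASW) metrics.

ASW-F is the mean pairwise cosine similarity of all eligible word vectors in
the full frame (one complete 1-minute description). ASW-10 slides a 10-word
window across the eligible sequence with step 1 and averages the within-window
mean similarity over all window positions. Eligible words are those present in
the embedding vocabulary and, by default, not stop words.

Both metrics admit two pairing rules: ``all_pairs`` (every unordered pair in
the frame; the default, matching "mean similarity over the frame") and
``adjacent`` (successive pairs only). Undefined values (fewer than two
eligible words) propagate as ``None`` / NaN, never as 0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .embeddings import EmbeddingTable
from .textprep import TokenizedTranscript, word_count

__all__ = [
    "SimConfig",
    "SimilarityProfile",
    "SubjectLinguistics",
    "eligible_sequence",
    "asw_full",
    "asw_window",
    "profile_transcript",
    "aggregate_subject",
    "profiles_to_frame",
]

logger = logging.getLogger(__name__)

PAIR_MODES = ("all_pairs", "adjacent")


@dataclass(frozen=True)
class SimConfig:
    """Similarity-scoring settings, recorded in every output row."""

    window: int = 10
    pair_mode: str = "all_pairs"
    include_stops: bool = False
    stoplist_id: str = "stopwords_en_v1"

    def __post_init__(self):
        if self.window < 2:
            raise ValueError(f"window must be >= 2, got {self.window}")
        if self.pair_mode not in PAIR_MODES:
            raise ValueError(f"pair_mode must be one of {PAIR_MODES}")


@dataclass
class SimilarityProfile:
    subject_id: str
    picture_id: str
    timepoint: str
    NW: int
    n_eligible: int
    ASW_F: Optional[float]
    ASW_10: Optional[float]
    pair_mode: str = "all_pairs"
    window: int = 10


@dataclass
class SubjectLinguistics:
    """Per-subject arithmetic means across that subject's picture descriptions."""

    subject_id: str
    timepoint: str
    NW_mean: Optional[float]
    ASW_F_mean: Optional[float]
    ASW_10_mean: Optional[float]
    n_pictures: int


def eligible_sequence(
    transcript: TokenizedTranscript,
    table: EmbeddingTable,
    include_stops: bool = False,
) -> np.ndarray:
    """Vectors of in-vocabulary (and, unless ``include_stops``, non-stop)
    tokens, in order of occurrence. Shape (n_eligible, dimension)."""
    vecs = []
    for tok in transcript.tokens:
        if not tok.in_vocab:
            continue
        if tok.is_stop and not include_stops:
            continue
        vec = table.get(tok.surface)
        assert vec is not None  # in_vocab flag guarantees presence
        vecs.append(vec)
    if not vecs:
        return np.empty((0, table.dimension))
    return np.vstack(vecs)


def _unit_rows(seq: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(seq, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("zero-norm vector in similarity sequence")
    return seq / norms


def _mean_upper(sim: np.ndarray) -> float:
    n = sim.shape[0]
    iu = np.triu_indices(n, k=1)
    return float(np.mean(sim[iu]))


def asw_full(seq: Sequence[Sequence[float]], pair_mode: str = "all_pairs") -> Optional[float]:
    """Mean cosine similarity over the full frame.

    ``all_pairs``: mean over all C(n,2) unordered pairs. ``adjacent``: mean
    over the n-1 successive pairs. Returns ``None`` when n < 2.
    """
    if pair_mode not in PAIR_MODES:
        raise ValueError(f"pair_mode must be one of {PAIR_MODES}")
    seq = np.asarray(seq, dtype=float)
    n = seq.shape[0]
    if n < 2:
        return None
    unit = _unit_rows(seq)
    if pair_mode == "adjacent":
        return float(np.mean(np.sum(unit[:-1] * unit[1:], axis=1)))
    return _mean_upper(unit @ unit.T)


def asw_window(
    seq: Sequence[Sequence[float]],
    window: int = 10,
    pair_mode: str = "all_pairs",
) -> Optional[float]:
    """Moving-window ASW: mean of :func:`asw_full` over every full window of
    ``window`` consecutive eligible tokens (step 1). For n <= window the whole
    sequence is the single frame, so the value equals ``asw_full(seq)``.
    Returns ``None`` when n < 2.
    """
    if window < 2:
        raise ValueError(f"window must be >= 2, got {window}")
    seq = np.asarray(seq, dtype=float)
    n = seq.shape[0]
    if n < 2:
        return None
    if n <= window:
        return asw_full(seq, pair_mode=pair_mode)
    unit = _unit_rows(seq)
    sim = unit @ unit.T
    n_windows = n - window + 1
    if pair_mode == "adjacent":
        adj = np.sum(unit[:-1] * unit[1:], axis=1)
        vals = [float(np.mean(adj[s: s + window - 1])) for s in range(n_windows)]
    else:
        vals = [
            _mean_upper(sim[s: s + window, s: s + window]) for s in range(n_windows)
        ]
    return float(np.mean(vals))


def profile_transcript(
    transcript: TokenizedTranscript,
    table: EmbeddingTable,
    config: SimConfig = SimConfig(),
) -> SimilarityProfile:
    """Bundle NW, ASW-F and ASW-10 for one transcript."""
    seq = eligible_sequence(transcript, table, include_stops=config.include_stops)
    n_eligible = seq.shape[0]
    logger.debug(
        "profile %s/%s/%s: NW=%d n_eligible=%d",
        transcript.subject_id, transcript.picture_id, transcript.timepoint,
        word_count(transcript), n_eligible,
    )
    return SimilarityProfile(
        subject_id=transcript.subject_id,
        picture_id=transcript.picture_id,
        timepoint=transcript.timepoint,
        NW=word_count(transcript),
        n_eligible=n_eligible,
        ASW_F=asw_full(seq, pair_mode=config.pair_mode),
        ASW_10=asw_window(seq, window=config.window, pair_mode=config.pair_mode),
        pair_mode=config.pair_mode,
        window=config.window,
    )


def _mean_defined(values: List[Optional[float]], what: str, subject_id: str) -> Optional[float]:
    defined = [v for v in values if v is not None and not (isinstance(v, float) and math.isnan(v))]
    if len(defined) < len(values):
        logger.warning(
            "subject %s: %d of %d %s values undefined; excluded from the mean",
            subject_id, len(values) - len(defined), len(values), what,
        )
    if not defined:
        return None
    return float(np.mean(defined))


def aggregate_subject(profiles: Sequence[SimilarityProfile]) -> SubjectLinguistics:
    """Arithmetic means of NW/ASW-F/ASW-10 across one subject's pictures.

    All profiles must share subject and timepoint. Undefined per-picture
    values are excluded from the mean with a warning; if none are defined the
    aggregate is undefined.
    """
    if not profiles:
        raise ValueError("no profiles to aggregate")
    subject_ids = {p.subject_id for p in profiles}
    timepoints = {p.timepoint for p in profiles}
    if len(subject_ids) != 1 or len(timepoints) != 1:
        raise ValueError(
            f"profiles span subjects {subject_ids} / timepoints {timepoints}; "
            "aggregate one subject x timepoint at a time"
        )
    sid = profiles[0].subject_id
    return SubjectLinguistics(
        subject_id=sid,
        timepoint=profiles[0].timepoint,
        NW_mean=float(np.mean([p.NW for p in profiles])),
        ASW_F_mean=_mean_defined([p.ASW_F for p in profiles], "ASW_F", sid),
        ASW_10_mean=_mean_defined([p.ASW_10 for p in profiles], "ASW_10", sid),
        n_pictures=len(profiles),
    )


def profiles_to_frame(
    profiles: Sequence[SimilarityProfile],
    stoplist_id: str = "stopwords_en_v1",
    embedding_label: str = "",
) -> pd.DataFrame:
    """Tabular form matching the ``similarity_profiles.csv`` schema."""
    return pd.DataFrame(
        {
            "subject": [p.subject_id for p in profiles],
            "picture": [p.picture_id for p in profiles],
            "timepoint": [p.timepoint for p in profiles],
            "NW": [p.NW for p in profiles],
            "n_eligible": [p.n_eligible for p in profiles],
            "ASW_F": [np.nan if p.ASW_F is None else p.ASW_F for p in profiles],
            "ASW_10": [np.nan if p.ASW_10 is None else p.ASW_10 for p in profiles],
            "pair_mode": [p.pair_mode for p in profiles],
            "window": [p.window for p in profiles],
            "stoplist_id": stoplist_id,
            "embedding_label": embedding_label,
        }
    )
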