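"""Transcript preprocessing: tokenization, stop-word marking, vocabulary check.

The preprocessing contract mirrors the tool used to score the descriptions:
punctuation is removed, stop words are *marked* (flagged, so downstream
similarity can exclude them), and words absent from the embedding table are
flagged out-of-vocabulary with a logged warning. NW, the number of words, is
the count of all non-punctuation tokens — stop words and OOV words included —
which is what makes a one-minute description land near 70 words.
"""

from __future__ import annotations

import logging
import re
import unicodedata
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Tuple

from .embeddings import EmbeddingTable, normalize_token

__all__ = [
    "Token",
    "TokenizedTranscript",
    "tokenize",
    "annotate",
    "word_count",
    "default_stoplist",
    "load_stoplist",
    "read_plain_transcript",
    "read_chat_transcript",
    "parse_transcript_filename",
]

logger = logging.getLogger(__name__)

# word-internal apostrophes survive; every other punctuation char is stripped.
_APOSTROPHES = "'’ʼ"
_HYPHEN_SPLIT = re.compile(r"[-‐‑‒–—/]+")


@dataclass(frozen=True)
class Token:
    surface: str
    is_stop: bool = False
    in_vocab: bool = True


@dataclass
class TokenizedTranscript:
    """Ordered annotated tokens for one subject x picture x timepoint."""

    subject_id: str
    picture_id: str
    timepoint: str
    tokens: List[Token] = field(default_factory=list)
    oov_report: List[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.tokens)


def _is_punct(ch: str) -> bool:
    return unicodedata.category(ch).startswith("P") or unicodedata.category(ch).startswith("S")


def _clean_word(word: str) -> str:
    word = word.replace("’", "'").replace("ʼ", "'")
    # strip leading/trailing punctuation; keep internal apostrophes and digits
    start, end = 0, len(word)
    while start < end and _is_punct(word[start]):
        start += 1
    while end > start and _is_punct(word[end - 1]):
        end -= 1
    return word[start:end]


def tokenize(raw_text: str) -> List[str]:
    """Whitespace tokenization with punctuation removal.

    Hyphens and slashes split words; leading/trailing punctuation is stripped;
    word-internal apostrophes are preserved (``it's`` stays one token); empty
    results are dropped. Idempotent on its own (re-joined) output.
    """
    out: List[str] = []
    for chunk in raw_text.split():
        for piece in _HYPHEN_SPLIT.split(chunk):
            cleaned = _clean_word(piece)
            if cleaned:
                out.append(cleaned)
    return out


def default_stoplist(case: str = "lower") -> frozenset:
    """The packaged English stop-list, normalized with ``case``."""
    text = resources.files("semsim.data").joinpath("stopwords_en.txt").read_text("utf-8")
    return _parse_stoplist(text, case)


def load_stoplist(path: str | Path, case: str = "lower") -> frozenset:
    """Read a one-token-per-line stop-list file ('#' starts a comment)."""
    return _parse_stoplist(Path(path).read_text("utf-8"), case)


def _parse_stoplist(text: str, case: str) -> frozenset:
    words = set()
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            words.add(normalize_token(line, case))
    return frozenset(words)


def annotate(
    tokens: Sequence[str],
    stoplist: Iterable[str],
    table: EmbeddingTable,
    subject_id: str = "",
    picture_id: str = "",
    timepoint: str = "",
) -> TokenizedTranscript:
    """Flag each token as stop-word and in/out of vocabulary.

    Token order and count are preserved. Every unique OOV surface form is
    recorded in ``oov_report`` and warned to the log, mirroring the scoring
    tool's "missing words" warning.
    """
    stopset = set(stoplist)
    annotated: List[Token] = []
    oov: List[str] = []
    seen_oov = set()
    for surface in tokens:
        norm = normalize_token(surface, table.case)
        in_vocab = norm in table.vectors
        annotated.append(Token(surface=surface, is_stop=norm in stopset, in_vocab=in_vocab))
        if not in_vocab and surface not in seen_oov:
            seen_oov.add(surface)
            oov.append(surface)
            logger.warning(
                "OOV word %r (subject=%s picture=%s timepoint=%s)",
                surface, subject_id, picture_id, timepoint,
            )
    return TokenizedTranscript(
        subject_id=subject_id,
        picture_id=picture_id,
        timepoint=timepoint,
        tokens=annotated,
        oov_report=oov,
    )


def word_count(transcript: TokenizedTranscript) -> int:
    """NW: all tokens after punctuation removal, stop words and OOV included."""
    return len(transcript.tokens)


_FILENAME_RE = re.compile(r"^(?P<subject>.+)_(?P<timepoint>[^_]+)_(?P<picture>[^_.]+)\.(txt|cha)$")


def parse_transcript_filename(name: str) -> Tuple[str, str, str]:
    """Split ``<subject>_<timepoint>_<picture>.txt`` into its three fields."""
    m = _FILENAME_RE.match(Path(name).name)
    if not m:
        raise ValueError(
            f"transcript filename {name!r} does not match "
            "'<subject>_<timepoint>_<picture>.txt'"
        )
    return m.group("subject"), m.group("timepoint"), m.group("picture")


def read_plain_transcript(path: str | Path) -> str:
    """Plain-text reader; assumes pre-cleaned, participant-only text."""
    return Path(path).read_text(encoding="utf-8")


_CHAT_PAREN = re.compile(r"\((.*?)\)")  # shortened forms: (be)cause -> because
_CHAT_BRACKET = re.compile(r"\[[^\]]*\]")  # event/error codes
_CHAT_ANGLE = re.compile(r"[<>]")  # retracing scope markers


def read_chat_transcript(path: str | Path, participant: str = "PAR") -> str:
    """Extract main-tier utterances of one participant from a CHAT (.cha) file.

    Keeps ``*PAR:`` lines (with continuation lines starting with a tab),
    expands shortened forms, drops bracketed codes, fillers (``&``-prefixed),
    unintelligible ``xxx``/``yyy`` markers and terminators. Dependent tiers
    (``%``) and other speakers are ignored.
    """
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    marker = f"*{participant}:"
    utterances: List[str] = []
    current: Optional[str] = None
    for line in lines:
        if line.startswith(marker):
            if current is not None:
                utterances.append(current)
            current = line[len(marker):].strip()
        elif current is not None and line.startswith("\t"):
            current += " " + line.strip()
        else:
            if current is not None:
                utterances.append(current)
                current = None
    if current is not None:
        utterances.append(current)

    cleaned: List[str] = []
    for utt in utterances:
        utt = utt.split("\x15")[0]  # strip time-alignment payload
        utt = _CHAT_BRACKET.sub(" ", utt)
        utt = _CHAT_PAREN.sub(r"\1", utt)
        utt = _CHAT_ANGLE.sub(" ", utt)
        words = [
            w for w in utt.split()
            if not w.startswith("&") and not w.startswith("+")
            and w not in {"xxx", "yyy", "www"}
        ]
        if words:
            cleaned.append(" ".join(words))
    return "\n".join(cleaned)
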