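"""Word-embedding tables in GloVe text format.

A table maps a normalized token to a fixed-dimension real vector. Lookup of a
token that is absent from the vocabulary returns ``None`` (a distinguishable
"missing" value), never a default vector. Cosine similarity between two
vectors is the workhorse primitive of all downstream similarity metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Optional

import numpy as np

__all__ = [
    "EmbeddingError",
    "EmbeddingTable",
    "load_embedding_table",
    "write_embedding_table",
    "cosine_similarity",
    "normalize_token",
]


class EmbeddingError(ValueError):
    """Raised for malformed embedding files or invalid vector operations."""


def normalize_token(token: str, case: str = "lower") -> str:
    """Normalize a surface token for table lookup.

    ``case`` is ``"lower"`` (default; maximizes coverage for spoken-language
    transcripts) or ``"preserve"``.
    """
    if case == "lower":
        return token.lower()
    if case == "preserve":
        return token
    raise ValueError(f"unknown case rule: {case!r} (expected 'lower' or 'preserve')")


@dataclass
class EmbeddingTable:
    """Token -> vector map with a fixed dimension.

    Parameters
    ----------
    dimension
        Length of every stored vector.
    vectors
        Mapping from normalized token to a 1-D float array of that length.
    source_label
        Free-text provenance (e.g. file name or "synthetic K=20 d=50").
    case
        Normalization rule applied to tokens at load time and at lookup.
    """

    dimension: int
    vectors: Dict[str, np.ndarray] = field(default_factory=dict)
    source_label: str = ""
    case: str = "lower"

    @property
    def vocabulary(self) -> set:
        return set(self.vectors)

    def __len__(self) -> int:
        return len(self.vectors)

    def __contains__(self, token: str) -> bool:
        return normalize_token(token, self.case) in self.vectors

    def get(self, token: str) -> Optional[np.ndarray]:
        """Vector for ``token`` under this table's normalization, or ``None``."""
        return self.vectors.get(normalize_token(token, self.case))


def vector_for(table: EmbeddingTable, token: str) -> Optional[np.ndarray]:
    """Functional alias for :meth:`EmbeddingTable.get`."""
    return table.get(token)


def load_embedding_table(
    path: str | Path,
    expected_dimension: Optional[int] = None,
    case: str = "lower",
    source_label: Optional[str] = None,
) -> EmbeddingTable:
    """Read a GloVe-format text file: ``token v1 v2 ... vD`` per line, no header.

    Raises
    ------
    EmbeddingError
        On inconsistent row lengths (citing the offending line number),
        duplicate tokens, zero vectors, or unparsable numbers.
    """
    path = Path(path)
    vectors: Dict[str, np.ndarray] = {}
    dimension: Optional[int] = None
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            token = normalize_token(parts[0], case)
            try:
                vec = np.array([float(x) for x in parts[1:]], dtype=float)
            except ValueError as exc:
                raise EmbeddingError(f"{path}: line {lineno}: unparsable number ({exc})")
            if dimension is None:
                dimension = vec.size
                if expected_dimension is not None and dimension != expected_dimension:
                    raise EmbeddingError(
                        f"{path}: line {lineno}: dimension {dimension} != expected "
                        f"{expected_dimension}"
                    )
                if dimension == 0:
                    raise EmbeddingError(f"{path}: line {lineno}: no vector components")
            elif vec.size != dimension:
                raise EmbeddingError(
                    f"{path}: line {lineno}: row has {vec.size} components, "
                    f"expected {dimension}"
                )
            if token in vectors:
                raise EmbeddingError(f"{path}: line {lineno}: duplicate token {token!r}")
            if not np.any(vec):
                raise EmbeddingError(f"{path}: line {lineno}: zero vector for {token!r}")
            vectors[token] = vec
    if dimension is None:
        raise EmbeddingError(f"{path}: empty embedding file")
    return EmbeddingTable(
        dimension=dimension,
        vectors=vectors,
        source_label=source_label if source_label is not None else path.name,
        case=case,
    )


def write_embedding_table(table: EmbeddingTable, path: str | Path) -> None:
    """Write ``table`` in GloVe text format (single-space separated, UTF-8)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for token, vec in table.vectors.items():
            fh.write(token + " " + " ".join(repr(float(v)) for v in vec) + "\n")


def cosine_similarity(u: Iterable[float], v: Iterable[float]) -> float:
    """Cosine of the angle between ``u`` and ``v``: dot(u,v) / (|u||v|).

    Symmetric and invariant to positive rescaling; always in [-1, 1] up to
    floating-point rounding. Zero-norm inputs are a domain error.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise EmbeddingError(f"shape mismatch: {u.shape} vs {v.shape}")
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise EmbeddingError("cosine similarity undefined for zero-norm vector")
    return float(np.dot(u, v) / (nu * nv))
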