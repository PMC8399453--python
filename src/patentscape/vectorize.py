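"""Top-M keyword vectors and the angular cosine similarity coefficient.

Each patent is summarized by its M most frequent cleaned lemmas (default
M = 5; frequency ties broken by first occurrence in the text, then
lexicographically).  All distinct selected words across the corpus span a
d-dimensional Euclidean keyword space in which each patent is a
nonnegative frequency vector v_i.  Dissimilarity between patents i and j
is the normalized angle

    c_ij = (2/pi) * arccos( v_i . v_j / (|v_i| |v_j|) )

so c = 0 for identical keyword lists (including a patent against itself)
and c = 1 when the two lists share no word.  Because frequencies are
nonnegative, the cosine is >= 0 and c always lies in [0, 1].
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .preprocess import TokenStream

__all__ = [
    "KeywordRanking",
    "PatentVector",
    "VocabularySpace",
    "SimilarityMatrix",
    "rank_words",
    "select_top_m",
    "build_space",
    "similarity",
    "similarity_matrix",
    "similarity_density",
    "vectors_to_frame",
]

logger = logging.getLogger(__name__)

DEFAULT_M = 5


@dataclass
class KeywordRanking:
    """Distinct words of one token stream, ordered by
    (frequency desc, first occurrence asc, word asc)."""

    entries: list[tuple[str, int, int]]  # (word, frequency, first_position)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class PatentVector:
    """A patent's top-M keyword list with raw frequencies."""

    patent_id: str
    words: list[tuple[str, int]]

    def __len__(self) -> int:
        return len(self.words)

    @property
    def as_dict(self) -> dict[str, int]:
        return dict(self.words)


@dataclass
class VocabularySpace:
    """Bijection from the corpus's selected keywords onto axes 0..d-1."""

    index: dict[str, int]

    @property
    def dimension(self) -> int:
        return len(self.index)


@dataclass
class SimilarityMatrix:
    """Symmetric N x N store of c_ij; the diagonal is 0 by definition."""

    ids: list[str]
    values: np.ndarray

    def pair(self, i: str, j: str) -> float:
        pos = {p: k for k, p in enumerate(self.ids)}
        return float(self.values[pos[i], pos[j]])

    def off_diagonal(self) -> np.ndarray:
        """Upper-triangle values (each unordered pair once)."""
        n = len(self.ids)
        iu = np.triu_indices(n, k=1)
        return self.values[iu]


def rank_words(stream: TokenStream | Sequence[str]) -> KeywordRanking:
    """Rank the distinct words of a stream by frequency, breaking ties by
    earliest occurrence, then alphabetically."""
    tokens = list(stream.tokens if isinstance(stream, TokenStream) else stream)
    freq: dict[str, int] = {}
    first: dict[str, int] = {}
    for pos, tok in enumerate(tokens):
        freq[tok] = freq.get(tok, 0) + 1
        if tok not in first:
            first[tok] = pos
    entries = sorted(
        ((w, freq[w], first[w]) for w in freq),
        key=lambda e: (-e[1], e[2], e[0]),
    )
    return KeywordRanking(entries=entries)


def select_top_m(ranking: KeywordRanking, m: int = DEFAULT_M, patent_id: str = "") -> PatentVector:
    """Keep the first min(M, len) ranked words with their frequencies."""
    if m < 1:
        raise ValueError(f"M must be >= 1, got {m}")
    return PatentVector(patent_id=patent_id, words=[(w, f) for w, f, _ in ranking.entries[:m]])


def build_vectors(
    streams: Mapping[str, TokenStream],
    m: int = DEFAULT_M,
) -> dict[str, PatentVector]:
    """Rank and select top-M keywords for every non-empty stream.

    Patents with empty streams cannot be normalized and are excluded
    (their ids are logged).
    """
    vectors: dict[str, PatentVector] = {}
    excluded = []
    for pid, stream in streams.items():
        vec = select_top_m(rank_words(stream), m, patent_id=pid)
        if len(vec) == 0:
            excluded.append(pid)
        else:
            vectors[pid] = vec
    if excluded:
        logger.info("excluded %d patents with empty keyword lists: %s", len(excluded), excluded)
    return vectors


def build_space(vectors: Iterable[PatentVector]) -> VocabularySpace:
    """Span the keyword space: one axis per distinct selected word,
    ordered lexicographically for determinism."""
    words: set[str] = set()
    for vec in vectors:
        words.update(w for w, _ in vec.words)
    if not words:
        raise ValueError("cannot build a vocabulary space from empty vectors")
    return VocabularySpace(index={w: i for i, w in enumerate(sorted(words))})


def similarity(v_i: PatentVector, v_j: PatentVector, space: VocabularySpace | None = None) -> float:
    """Angular cosine similarity coefficient c_ij in [0, 1].

    Only shared words contribute to the dot product, so the computation
    runs over the two sparse keyword lists; the ambient space fixes the
    geometry but not the value.
    """
    if len(v_i) == 0 or len(v_j) == 0:
        raise ValueError("similarity undefined for an empty keyword vector")
    di, dj = v_i.as_dict, v_j.as_dict
    dot = sum(f * dj[w] for w, f in di.items() if w in dj)
    if dot == 0:
        return 1.0  # no shared word: orthogonal by construction
    n2_i = sum(f * f for f in di.values())
    n2_j = sum(f * f for f in dj.values())
    # integer frequencies make proportionality detectable exactly
    # (Cauchy-Schwarz equality), so coinciding lists give c = 0 with no
    # rounding residue from the two norms
    if dot * dot == n2_i * n2_j:
        return 0.0
    cos = dot / math.sqrt(n2_i * n2_j)
    cos = min(1.0, max(-1.0, cos))  # absorb rounding before arccos
    return (2.0 / math.pi) * math.acos(cos)


def similarity_matrix(
    vectors: Mapping[str, PatentVector] | Sequence[PatentVector],
    space: VocabularySpace | None = None,
) -> SimilarityMatrix:
    """All pairwise coefficients, each unordered pair computed once so
    symmetry is exact; the diagonal (self-comparison) is 0."""
    if isinstance(vectors, Mapping):
        vecs = list(vectors.values())
    else:
        vecs = list(vectors)
    if len(vecs) < 2:
        raise ValueError("need at least 2 non-empty patent vectors")
    ids = [v.patent_id for v in vecs]
    n = len(vecs)
    values = np.zeros((n, n), dtype=float)
    for a in range(n):
        for b in range(a + 1, n):
            c = similarity(vecs[a], vecs[b], space)
            values[a, b] = values[b, a] = c
    return SimilarityMatrix(ids=ids, values=values)


def similarity_density(
    matrix: SimilarityMatrix, bins: int | Sequence[float] = 40
) -> tuple[np.ndarray, np.ndarray]:
    """Probability density rho(c) of the off-diagonal coefficients over
    [0, 1]; returns (bin_edges, density) normalized to unit integral."""
    vals = matrix.off_diagonal()
    if vals.size == 0:
        raise ValueError("similarity matrix has no off-diagonal pairs")
    density, edges = np.histogram(vals, bins=bins, range=(0.0, 1.0), density=True)
    return edges, density


def vectors_to_frame(vectors: Mapping[str, PatentVector]) -> pd.DataFrame:
    """Long-form export: (patent_id, rank, word, frequency)."""
    rows = [
        {"patent_id": pid, "rank": r + 1, "word": w, "frequency": f}
        for pid, vec in vectors.items()
        for r, (w, f) in enumerate(vec.words)
    ]
    return pd.DataFrame(rows, columns=["patent_id", "rank", "word", "frequency"])
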