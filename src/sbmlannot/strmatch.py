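"""Character-count string matching for species names.

A name is mapped into a 36-dimensional count vector (one coordinate per
letter a-z, then per numeral 0-9). The species match score ``cScore``
between a query name and a reference term is the maximum, over the term's
synonyms, of the cosine between the two count vectors. The encoding is
deliberately lossy — anagrams coincide — but is cheap, length-tolerant,
and works well for short chemical names where alignment-style scoring
(Needleman-Wunsch and friends) is ill-suited.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .refdb import ReferenceDatabase, SpeciesTerm

__all__ = [
    "ALPHABET",
    "N_DIMS",
    "QueryString",
    "normalize_string",
    "vectorize",
    "cosine",
    "cscore",
    "SynonymIndex",
]

ALPHABET = "abcdefghijklmnopqrstuvwxyz0123456789"
N_DIMS = len(ALPHABET)
_COORD = {ch: i for i, ch in enumerate(ALPHABET)}
_NON_ALNUM = re.compile(r"[^a-z0-9]+")


@dataclass(frozen=True)
class QueryString:
    source: str
    normalized: str


def normalize_string(s: str) -> QueryString:
    """Lowercase and keep only [a-z0-9]; everything else (whitespace,
    punctuation, Greek letters, any non-ASCII) is dropped, not transliterated."""
    return QueryString(source=s, normalized=_NON_ALNUM.sub("", s.lower()))


def vectorize(q: QueryString | str) -> np.ndarray:
    """36-dim count vector of a normalized string (a..z then 0..9)."""
    if isinstance(q, str):
        q = normalize_string(q)
    v = np.zeros(N_DIMS, dtype=np.int64)
    for ch in q.normalized:
        v[_COORD[ch]] += 1
    return v


def cosine(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine of two count vectors, in [0, 1]; 0 if either vector is zero."""
    nu = math.sqrt(float(u @ u))
    nv = math.sqrt(float(v @ v))
    if nu == 0.0 or nv == 0.0:
        return 0.0
    c = float(u @ v) / (nu * nv)
    # sqrt/division rounding can land an exact match an ulp off 1
    if c >= 1.0 - 1e-12:
        return 1.0
    return max(0.0, c)


def cscore(q: QueryString | str, term: "SpeciesTerm") -> float:
    """Species match score: max cosine over the term's synonyms."""
    qv = vectorize(q)
    return max(cosine(qv, vectorize(normalize_string(s))) for s in term.synonyms)


class SynonymIndex:
    """Precomputed synonym vectors for scoring a query against a whole database.

    Results are identical to calling :func:`cscore` per term; the index only
    batches the cosines through one matrix product.
    """

    def __init__(self, db: "ReferenceDatabase") -> None:
        self.term_ids: list[str] = sorted(db.species)
        rows: list[np.ndarray] = []
        owner: list[int] = []
        for ti, term_id in enumerate(self.term_ids):
            for syn in db.species[term_id].synonyms:
                rows.append(vectorize(normalize_string(syn)))
                owner.append(ti)
        self._matrix = (
            np.vstack(rows).astype(np.float64) if rows else np.zeros((0, N_DIMS))
        )
        self._owner = np.asarray(owner, dtype=np.intp)
        norms = np.linalg.norm(self._matrix, axis=1)
        norms[norms == 0.0] = 1.0  # zero synonym vectors score 0 regardless
        self._inv_norms = 1.0 / norms

    def score_all(self, q: QueryString | str) -> dict[str, float]:
        """cScore of the query against every term; keys are term ids."""
        qv = vectorize(q).astype(np.float64)
        qn = np.linalg.norm(qv)
        if qn == 0.0 or self._matrix.shape[0] == 0:
            return {t: 0.0 for t in self.term_ids}
        cos = np.clip((self._matrix @ qv) * self._inv_norms / qn, 0.0, None)
        cos[cos >= 1.0 - 1e-12] = 1.0  # snap exact matches hit by rounding
        best = np.zeros(len(self.term_ids))
        np.maximum.at(best, self._owner, cos)
        return dict(zip(self.term_ids, best.tolist()))
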