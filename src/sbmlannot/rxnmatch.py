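"""Reaction matching in the simplified-formula vector space.

A reaction is a binary vector over the distinct simplified formulas of the
reference database: coordinate i is 1 when at least one participant has
that simplified formula. Direction and stoichiometry are ignored —
reactants and products are pooled. The raw similarity between a query
reaction Rq and a reference reaction Rr is the dot product Rq·Rr (the
number of shared simplified formulas); the match score normalizes it:

    rScore(Rq, Rr) = (Rq·Rr) / D

where D is the smallest self-dot-product (participant-formula count) among
the reference reactions that achieve the maximal dot product M_q with the
query. D never changes the ranking of reference reactions, only the scale
of the scores against the user's cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Mapping

if TYPE_CHECKING:  # pragma: no cover
    from .predict import PredictionSet, QueryReaction
    from .refdb import ReactionTerm, ReferenceDatabase

__all__ = [
    "ReactionVector",
    "NormalizerContext",
    "reference_reaction_vector",
    "query_reaction_vector",
    "compute_normalizer",
    "rscore",
    "score_all_reactions",
]


@dataclass(frozen=True)
class ReactionVector:
    """Binary vector represented by its support (set of coordinates equal to 1)."""

    support: frozenset[int]

    def dot(self, other: "ReactionVector") -> int:
        return len(self.support & other.support)

    def __len__(self) -> int:
        return len(self.support)


@dataclass(frozen=True)
class NormalizerContext:
    """M_q, the argmax set L_q, and the normalization constant D for one query."""

    M_q: int
    L_q: frozenset[str]
    D: int


def reference_reaction_vector(term: "ReactionTerm", db: "ReferenceDatabase") -> ReactionVector:
    """Vector of a reference reaction: union of its participants' formulas."""
    try:
        support = frozenset(db.formula_index[f] for f in term.formula_set)
    except KeyError as exc:  # pragma: no cover - guarded by db invariants
        raise ValueError(f"reaction {term.reaction_id}: formula {exc} not indexed") from exc
    return ReactionVector(support=support)


def query_reaction_vector(rxn: "QueryReaction",
                          species_preds: Mapping[str, "PredictionSet"],
                          db: "ReferenceDatabase") -> ReactionVector:
    """Vector of a query reaction built from predicted species annotations.

    Every candidate term surviving the species-level selection contributes
    all of its simplified formulas; a species with multiple candidate terms
    or multiple formulas therefore sets several coordinates. Participants
    with empty predictions contribute nothing.
    """
    support: set[int] = set()
    for sp_id in rxn.participant_ids:
        pred = species_preds.get(sp_id)
        if pred is None:
            continue
        for cand in pred.candidates:
            if cand.annotation_id in db.species:
                support |= db.coords_of_term(cand.annotation_id)
    return ReactionVector(support=frozenset(support))


def compute_normalizer(qvec: ReactionVector, db: "ReferenceDatabase") -> NormalizerContext:
    """Scan all reference reactions for M_q, L_q and D.

    With an empty query vector every dot product is 0, so M_q = 0, L_q is
    the whole table and D is set to 0 (all scores 0 by convention).
    """
    if not db.reactions:
        raise ValueError("reference database has no reactions")
    dots = {
        rid: qvec.dot(reference_reaction_vector(term, db))
        for rid, term in db.reactions.items()
    }
    M_q = max(dots.values())
    L_q = frozenset(rid for rid, d in dots.items() if d == M_q)
    if M_q == 0:
        return NormalizerContext(M_q=0, L_q=L_q, D=0)
    D = min(len(reference_reaction_vector(db.reactions[rid], db)) for rid in L_q)
    return NormalizerContext(M_q=M_q, L_q=L_q, D=D)


def rscore(qvec: ReactionVector, rvec: ReactionVector, ctx: NormalizerContext) -> float:
    """Normalized reaction match score (Rq·Rr)/D, in [0, 1]; 0 when D = 0."""
    if ctx.D == 0:
        return 0.0
    return qvec.dot(rvec) / ctx.D


def score_all_reactions(qvec: ReactionVector,
                        db: "ReferenceDatabase") -> tuple[dict[str, float], NormalizerContext]:
    """rScore of one query vector against every reference reaction."""
    ctx = compute_normalizer(qvec, db)
    scores = {
        rid: rscore(qvec, reference_reaction_vector(term, db), ctx)
        for rid, term in db.reactions.items()
    }
    return scores, ctx
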