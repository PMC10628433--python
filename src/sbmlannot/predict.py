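"""End-to-end annotation prediction.

For each query element: an element filter decides whether there is enough
information to predict at all (short species names such as "S1" carry no
signal); a match score function scores the element against every reference
element (cScore for species, rScore for reactions); a match score
selection criterion (MSSC) turns the scored list into the prediction set:

* ``top``   — annotations of the reference element(s) tied at the maximal
              score, provided that score is at or above the cutoff;
* ``above`` — annotations of all reference elements scoring at or above
              the cutoff.

Reactions are scored after species: the query reaction vector is assembled
from the candidate terms its participant species received.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from . import rxnmatch
from .refdb import ReferenceDatabase
from .strmatch import SynonymIndex, normalize_string

__all__ = [
    "QuerySpecies",
    "QueryReaction",
    "Candidate",
    "PredictionSet",
    "PredictionParams",
    "EVALUATION_PRESET",
    "filter_species",
    "filter_reaction",
    "select_candidates",
    "predict_species_annotations",
    "predict_reaction_annotations",
    "write_report",
]


@dataclass(frozen=True)
class QuerySpecies:
    """A model species to annotate; the query string is the display name
    when present and nonempty (after trimming), else the element id."""

    element_id: str
    display_name: str | None = None
    annotations: frozenset[str] = frozenset()

    @property
    def query_string(self) -> str:
        if self.display_name is not None and self.display_name.strip():
            return self.display_name
        return self.element_id


@dataclass(frozen=True)
class QueryReaction:
    """A model reaction to annotate: its reactant+product species ids."""

    element_id: str
    participant_ids: frozenset[str]
    annotations: frozenset[str] = frozenset()


@dataclass(frozen=True)
class Candidate:
    annotation_id: str
    score: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score must be in [0, 1], got {self.score}")


@dataclass(frozen=True)
class PredictionSet:
    """Candidates selected for one element under a given MSSC and cutoff.

    Candidates are kept in lexicographic annotation-id order so output is
    reproducible. ``source`` distinguishes string/participant evidence from
    reaction-driven revisions made by the refinement pass.
    """

    element_id: str
    candidates: tuple[Candidate, ...] = ()
    mssc: str = "top"
    cutoff: float = 0.0
    source: str = "match-score"

    @property
    def annotation_ids(self) -> frozenset[str]:
        return frozenset(c.annotation_id for c in self.candidates)

    @property
    def top_score(self) -> float:
        return max((c.score for c in self.candidates), default=0.0)

    def __bool__(self) -> bool:
        return bool(self.candidates)


@dataclass(frozen=True)
class PredictionParams:
    """MSSC, cutoff, and element-filter settings for one prediction run."""

    mssc: str = "top"
    cutoff: float = 0.0
    min_len: int = 3
    min_participants: int = 0

    def __post_init__(self) -> None:
        if self.mssc not in ("top", "above"):
            raise ValueError(f"mssc must be 'top' or 'above', got {self.mssc!r}")
        if not 0.0 <= self.cutoff <= 1.0:
            raise ValueError(f"cutoff must be in [0, 1], got {self.cutoff}")


#: Filter configuration used for corpus evaluation: species names of at
#: least three characters, reactions with at least three participants.
EVALUATION_PRESET = PredictionParams(min_len=3, min_participants=3)


def filter_species(q: QuerySpecies, min_len: int) -> bool:
    """Pass iff the normalized query string has at least ``min_len`` characters."""
    return len(normalize_string(q.query_string).normalized) >= min_len


def filter_reaction(r: QueryReaction, min_participants: int) -> bool:
    """Pass iff the reaction has at least ``min_participants`` participants."""
    return len(r.participant_ids) >= min_participants


def select_candidates(scored: Iterable[Candidate], mssc: str, cutoff: float) -> tuple[Candidate, ...]:
    """Apply an MSSC to a scored candidate list.

    The cutoff comparison is inclusive (score >= cutoff). Selection is
    deterministic and independent of input order; ties are returned in
    lexicographic annotation-id order.
    """
    if mssc not in ("top", "above"):
        raise ValueError(f"mssc must be 'top' or 'above', got {mssc!r}")
    cands = list(scored)
    if not cands:
        return ()
    if mssc == "top":
        best = max(c.score for c in cands)
        if best < cutoff:
            return ()
        chosen = [c for c in cands if c.score == best]
    else:
        chosen = [c for c in cands if c.score >= cutoff]
    return tuple(sorted(chosen, key=lambda c: c.annotation_id))


def predict_species_annotations(model, db: ReferenceDatabase,
                                params: PredictionParams = PredictionParams(),
                                index: SynonymIndex | None = None,
                                ) -> dict[str, PredictionSet]:
    """Predict annotations for every species of a model.

    ``model`` is any object with a ``species`` iterable of
    :class:`QuerySpecies`. Filtered-out species get an empty prediction set.
    """
    if index is None:
        index = SynonymIndex(db)
    out: dict[str, PredictionSet] = {}
    for sp in model.species:
        if not filter_species(sp, params.min_len):
            out[sp.element_id] = PredictionSet(sp.element_id, (), params.mssc, params.cutoff)
            continue
        scores = index.score_all(sp.query_string)
        scored = [Candidate(t, s) for t, s in scores.items()]
        chosen = _drop_zero_evidence(select_candidates(scored, params.mssc, params.cutoff))
        out[sp.element_id] = PredictionSet(sp.element_id, chosen, params.mssc, params.cutoff)
    return out


def _drop_zero_evidence(chosen: tuple[Candidate, ...]) -> tuple[Candidate, ...]:
    """A selection whose best score is 0 carries no evidence at all; such
    elements get an empty prediction set rather than an arbitrary tie."""
    if chosen and max(c.score for c in chosen) == 0.0:
        return ()
    return chosen


def predict_reaction_annotations(model, db: ReferenceDatabase,
                                 species_preds: Mapping[str, PredictionSet],
                                 params: PredictionParams = PredictionParams(),
                                 ) -> dict[str, PredictionSet]:
    """Predict annotations for every reaction, given species predictions."""
    out: dict[str, PredictionSet] = {}
    for rxn in model.reactions:
        if not filter_reaction(rxn, params.min_participants) or not db.reactions:
            out[rxn.element_id] = PredictionSet(rxn.element_id, (), params.mssc, params.cutoff)
            continue
        qvec = rxnmatch.query_reaction_vector(rxn, species_preds, db)
        scores, _ctx = rxnmatch.score_all_reactions(qvec, db)
        scored = [Candidate(rid, s) for rid, s in scores.items()]
        chosen = _drop_zero_evidence(select_candidates(scored, params.mssc, params.cutoff))
        out[rxn.element_id] = PredictionSet(rxn.element_id, chosen, params.mssc, params.cutoff)
    return out


def write_report(species_preds: Mapping[str, PredictionSet],
                 reaction_preds: Mapping[str, PredictionSet],
                 path: str | Path,
                 existing: Mapping[str, frozenset[str]] | None = None) -> pd.DataFrame:
    """Write the recommendation report TSV and return it as a DataFrame.

    Columns: element_id, element_type, annotation_id, match_score (6
    decimals), selected_by, existing_annotation.
    """
    existing = existing or {}
    rows = []
    for etype, preds in (("species", species_preds), ("reaction", reaction_preds)):
        for el_id in sorted(preds):
            for cand in preds[el_id].candidates:
                rows.append({
                    "element_id": el_id,
                    "element_type": etype,
                    "annotation_id": cand.annotation_id,
                    "match_score": f"{cand.score:.6f}",
                    "selected_by": preds[el_id].mssc,
                    "existing_annotation": "yes" if existing.get(el_id) else "no",
                })
    df = pd.DataFrame(rows, columns=["element_id", "element_type", "annotation_id",
                                     "match_score", "selected_by", "existing_annotation"])
    df.to_csv(path, sep="\t", index=False)
    return df


def reselect(pred: PredictionSet, scored: Iterable[Candidate],
             params: PredictionParams) -> PredictionSet:
    """Re-apply selection to a fresh scored list, keeping element identity."""
    chosen = _drop_zero_evidence(select_candidates(scored, params.mssc, params.cutoff))
    return replace(pred, candidates=chosen, mssc=params.mssc, cutoff=params.cutoff)
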