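"""Iterative cross-optimization of species and reaction predictions.

Once a query reaction has a mapped reference reaction (its top-scoring
candidate), the participants of the two reactions can be paired. A pair is
"matched" when the query species' current predicted annotations contain
the paired reference participant; an unmatched pair is evidence that the
species' string-derived annotation is wrong, and proposes replacing it
with the paired reference term. Accepted proposals feed back into the
reaction scores of every reaction touching the revised species, and the
loop repeats until a fixed point (or an iteration cap) is reached.

Pairing fixes exact annotation matches first and then pairs the remaining
participants greedily by descending name similarity (cScore), with
deterministic lexicographic tie-breaks. Conflicting proposals for one
species are resolved by choosing the term that maximizes the summed top
rScore over all reactions containing that species.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from . import rxnmatch
from .predict import (Candidate, PredictionParams, PredictionSet, QueryReaction,
                      reselect)
from .refdb import ReactionTerm, ReferenceDatabase
from .strmatch import cscore

logger = logging.getLogger(__name__)

__all__ = ["Pairing", "RefinementState", "pair_participants", "revise_species",
           "iterate_refinement"]


@dataclass(frozen=True)
class Pairing:
    """Participant pairing of one query reaction against its mapped reaction."""

    reaction_id: str           # query reaction element id
    mapped_id: str             # reference reaction id
    pairs: tuple[tuple[str, str, bool], ...]  # (species element_id, term_id, matched)

    @property
    def n_matched(self) -> int:
        return sum(1 for _, _, m in self.pairs if m)

    @property
    def unmatched(self) -> tuple[tuple[str, str], ...]:
        return tuple((s, t) for s, t, m in self.pairs if not m)


@dataclass
class RefinementState:
    """Predictions after refinement, with an audit log of revisions."""

    species_preds: dict[str, PredictionSet]
    reaction_preds: dict[str, PredictionSet]
    iteration: int = 0
    changed: bool = False
    audit: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["iteration", "reaction_element_id", "mapped_reaction_id",
                 "species_element_id", "old_annotations", "new_annotation",
                 "score_before", "score_after"]))


def pair_participants(rxn: QueryReaction, mapped: ReactionTerm,
                      species_preds: Mapping[str, PredictionSet],
                      db: ReferenceDatabase,
                      names: Mapping[str, str] | None = None) -> Pairing:
    """Pair the participants of a query reaction with those of its mapped
    reference reaction.

    Exact annotation matches are paired first; remaining participants are
    paired greedily by descending cScore between the query species' name
    and the reference participant's synonyms. Each side is used at most
    once; tie-breaks are lexicographic on (element_id, term_id).
    """
    names = names or {}
    q_free = sorted(rxn.participant_ids)
    r_free = sorted(mapped.participants)
    pairs: list[tuple[str, str, bool]] = []

    # 1) exact matches: current prediction contains the reference term
    for sp_id in list(q_free):
        pred = species_preds.get(sp_id)
        if pred is None:
            continue
        hit = sorted(pred.annotation_ids & set(r_free))
        if hit:
            pairs.append((sp_id, hit[0], True))
            q_free.remove(sp_id)
            r_free.remove(hit[0])

    # 2) greedy name-similarity pairing of the remainder
    if q_free and r_free:
        scored = sorted(
            ((cscore(names.get(sp_id, sp_id), db.species[t]), sp_id, t)
             for sp_id in q_free for t in r_free if t in db.species),
            key=lambda x: (-x[0], x[1], x[2]),
        )
        used_q: set[str] = set()
        used_r: set[str] = set()
        for _score, sp_id, t in scored:
            if sp_id in used_q or t in used_r:
                continue
            pairs.append((sp_id, t, False))
            used_q.add(sp_id)
            used_r.add(t)

    pairs.sort(key=lambda p: (p[0], p[1]))
    return Pairing(reaction_id=rxn.element_id, mapped_id=mapped.reaction_id,
                   pairs=tuple(pairs))


def revise_species(pairing: Pairing,
                   species_preds: Mapping[str, PredictionSet]) -> dict[str, set[str]]:
    """Proposals from one pairing: species element id -> proposed term ids.

    Each unmatched pair proposes adopting the paired reference term;
    matched pairs propose nothing.
    """
    proposals: dict[str, set[str]] = {}
    for sp_id, term_id in pairing.unmatched:
        proposals.setdefault(sp_id, set()).add(term_id)
    return proposals


def _reaction_scores(model, db: ReferenceDatabase,
                     species_preds: Mapping[str, PredictionSet],
                     element_ids: set[str] | None = None) -> dict[str, dict[str, float]]:
    out: dict[str, dict[str, float]] = {}
    for rxn in model.reactions:
        if element_ids is not None and rxn.element_id not in element_ids:
            continue
        qvec = rxnmatch.query_reaction_vector(rxn, species_preds, db)
        scores, _ = rxnmatch.score_all_reactions(qvec, db)
        out[rxn.element_id] = scores
    return out


def _summed_top_rscore(model, db: ReferenceDatabase,
                       species_preds: Mapping[str, PredictionSet],
                       touching: set[str]) -> float:
    total = 0.0
    for rid, scores in _reaction_scores(model, db, species_preds, touching).items():
        total += max(scores.values(), default=0.0)
    return total


def iterate_refinement(model, db: ReferenceDatabase,
                       species_preds: Mapping[str, PredictionSet],
                       reaction_preds: Mapping[str, PredictionSet],
                       params: PredictionParams = PredictionParams(),
                       max_iter: int = 3) -> RefinementState:
    """Run the species/reaction cross-optimization loop.

    Stops when an iteration accepts no proposal, or after ``max_iter``
    iterations. ``max_iter=0`` returns the inputs unchanged.
    """
    sp = dict(species_preds)
    rx = dict(reaction_preds)
    state = RefinementState(species_preds=sp, reaction_preds=rx)
    audit_rows: list[dict] = []
    names = {s.element_id: s.query_string for s in model.species}
    rxns_by_species: dict[str, set[str]] = {}
    rxn_by_id: dict[str, QueryReaction] = {}
    for rxn in model.reactions:
        rxn_by_id[rxn.element_id] = rxn
        for sp_id in rxn.participant_ids:
            rxns_by_species.setdefault(sp_id, set()).add(rxn.element_id)

    for iteration in range(1, max_iter + 1):
        state.iteration = iteration
        # (a) pair every reaction with a nonempty prediction against its
        #     top-scoring mapped reaction(s); ties all contribute
        proposals: dict[str, set[str]] = {}
        proposer: dict[tuple[str, str], tuple[str, str, float]] = {}
        for rid in sorted(rx):
            pred = rx[rid]
            if not pred:
                continue
            top = pred.top_score
            mapped_ids = sorted(c.annotation_id for c in pred.candidates
                                if c.score == top and c.annotation_id in db.reactions)
            for mid in mapped_ids:
                pairing = pair_participants(rxn_by_id[rid], db.reactions[mid], sp, db, names)
                for sp_id, terms in revise_species(pairing, sp).items():
                    for t in terms:
                        proposals.setdefault(sp_id, set()).add(t)
                        proposer.setdefault((sp_id, t), (rid, mid, top))

        # (b) drop proposals that would not change anything
        for sp_id in list(proposals):
            current = sp.get(sp_id)
            cur_ids = current.annotation_ids if current else frozenset()
            proposals[sp_id] -= cur_ids
            if not proposals[sp_id]:
                del proposals[sp_id]

        if not proposals:
            state.changed = state.changed or False
            break

        # (c) conflict resolution: per species, pick the term maximizing the
        #     summed top rScore over reactions containing it
        accepted: dict[str, str] = {}
        for sp_id in sorted(proposals):
            terms = sorted(proposals[sp_id])
            if len(terms) == 1:
                accepted[sp_id] = terms[0]
                continue
            touching = rxns_by_species.get(sp_id, set())
            best_term, best_val = None, -1.0
            for t in terms:
                trial = dict(sp)
                trial[sp_id] = PredictionSet(sp_id, (Candidate(t, 1.0),),
                                             params.mssc, params.cutoff,
                                             source="revised-by-reaction")
                val = _summed_top_rscore(model, db, trial, touching)
                if val > best_val:  # strict: earlier (lexicographic) term wins ties
                    best_term, best_val = t, val
            accepted[sp_id] = best_term

        # (d) apply accepted proposals
        touched_rxns: set[str] = set()
        for sp_id, term in accepted.items():
            rid, mid, top = proposer[(sp_id, term)]
            old = sp.get(sp_id)
            old_ids = sorted(old.annotation_ids) if old else []
            score_before = rx[rid].top_score if rx.get(rid) else 0.0
            sp[sp_id] = PredictionSet(sp_id, (Candidate(term, top),),
                                      params.mssc, params.cutoff,
                                      source="revised-by-reaction")
            touched_rxns |= rxns_by_species.get(sp_id, set())
            audit_rows.append({
                "iteration": iteration, "reaction_element_id": rid,
                "mapped_reaction_id": mid, "species_element_id": sp_id,
                "old_annotations": "|".join(old_ids), "new_annotation": term,
                "score_before": score_before, "score_after": None,
            })

        # (e)+(f) re-score and re-select every reaction touching a revision
        new_scores = _reaction_scores(model, db, sp, touched_rxns)
        for rid, scores in new_scores.items():
            scored = [Candidate(r, s) for r, s in scores.items()]
            rx[rid] = reselect(rx[rid], scored, params)
        for row in audit_rows:
            if row["score_after"] is None and row["reaction_element_id"] in new_scores:
                row["score_after"] = rx[row["reaction_element_id"]].top_score
        state.changed = True
        logger.info("refinement iteration %d: revised %d species", iteration, len(accepted))

    state.audit = pd.DataFrame(audit_rows, columns=state.audit.columns)
    return state
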