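"""Binary reaction vectors, the normalizer D, and rScore."""

import random

import pytest

from sbmlannot import synthgen
from sbmlannot.predict import Candidate, PredictionSet, QueryReaction
from sbmlannot.rxnmatch import (NormalizerContext, compute_normalizer,
                                query_reaction_vector, reference_reaction_vector,
                                rscore, score_all_reactions)
from sbmlannot.refdb import ReferenceDatabase, SpeciesTerm, ReactionTerm


def brute_normalizer(qvec, db):
    """Oracle: plain loops straight from the definitions of M_q, L_q, D."""
    dots = {}
    for rid, term in db.reactions.items():
        support = set()
        for p in term.participants:
            for f in db.species[p].formulas:
                support.add(db.formula_index[f])
        dots[rid] = len(set(qvec.support) & support)
    M_q = max(dots.values())
    L_q = {rid for rid, d in dots.items() if d == M_q}
    if M_q == 0:
        return M_q, L_q, 0
    D = min(
        len({db.formula_index[f] for p in db.reactions[rid].participants
             for f in db.species[p].formulas})
        for rid in L_q
    )
    return M_q, L_q, D


def preds_for(db, terms_by_species):
    return {
        sp: PredictionSet(sp, tuple(Candidate(t, 1.0) for t in ts))
        for sp, ts in terms_by_species.items()
    }


def test_worked_example_numbers(fixture_db):
    """ATP→ADP query vs the five-participant hydrolysis reference:
    dot 2, M_q 2, D 5, rScore 0.4."""
    rxn = QueryReaction("R_hydro", frozenset({"M_atp", "M_adp"}))
    sp = preds_for(fixture_db, {"M_atp": ["CHEBI:30616"], "M_adp": ["CHEBI:456216"]})
    qvec = query_reaction_vector(rxn, sp, fixture_db)
    rvec = reference_reaction_vector(fixture_db.reactions["RHEA:13065"], fixture_db)
    assert len(qvec) == 2 and len(rvec) == 5
    assert qvec.dot(rvec) == 2
    ctx = compute_normalizer(qvec, fixture_db)
    assert ctx.M_q == 2
    assert ctx.D == 5
    assert rscore(qvec, rvec, ctx) == pytest.approx(0.4)


def test_multi_candidate_and_shared_formula_support(fixture_db):
    # two candidate terms with distinct formulas both set coordinates
    rxn = QueryReaction("R", frozenset({"s1"}))
    sp = preds_for(fixture_db, {"s1": ["CHEBI:30616", "CHEBI:456216"]})
    assert len(query_reaction_vector(rxn, sp, fixture_db)) == 2
    # NAD+ and NADH share one simplified formula: support collapses
    sp = preds_for(fixture_db, {"s1": ["CHEBI:15846", "CHEBI:16908"]})
    assert len(query_reaction_vector(rxn, sp, fixture_db)) == 1
    # unpredicted participants contribute nothing
    rxn2 = QueryReaction("R2", frozenset({"s1", "s2"}))
    sp = {"s1": PredictionSet("s1"), "s2": PredictionSet("s2")}
    assert len(query_reaction_vector(rxn2, sp, fixture_db)) == 0


def test_empty_query_vector_scores_zero_everywhere(fixture_db):
    rxn = QueryReaction("R", frozenset({"s1"}))
    qvec = query_reaction_vector(rxn, {"s1": PredictionSet("s1")}, fixture_db)
    ctx = compute_normalizer(qvec, fixture_db)
    assert ctx.M_q == 0 and ctx.D == 0
    assert set(ctx.L_q) == set(fixture_db.reactions)
    scores, _ = score_all_reactions(qvec, fixture_db)
    assert all(s == 0.0 for s in scores.values())


def test_empty_reaction_table_is_an_error():
    db = ReferenceDatabase(
        species={"CHEBI:1": SpeciesTerm("CHEBI:1", ("a",), frozenset({"C"}))},
        reactions={})
    rxn_vec = reference_reaction_vector(
        ReactionTerm("RHEA:1", frozenset({"CHEBI:1"}), frozenset({"C"})),
        ReferenceDatabase(
            species={"CHEBI:1": SpeciesTerm("CHEBI:1", ("a",), frozenset({"C"}))},
            reactions={"RHEA:1": ReactionTerm("RHEA:1", frozenset({"CHEBI:1"}),
                                              frozenset({"C"}))}))
    with pytest.raises(ValueError):
        compute_normalizer(rxn_vec, db)


@pytest.mark.parametrize("seed", [3, 17])
def test_normalizer_matches_brute_force_on_random_databases(seed):
    cfg = synthgen.SynthConfig(n_species_terms=40, n_reactions=50,
                               participants_per_reaction=(2, 8), seed=seed)
    db = synthgen.generate_reference_db(cfg)
    rng = random.Random(seed + 1)
    term_ids = sorted(db.species)
    for _ in range(30):
        # random query: a handful of species terms with exact candidates
        chosen = rng.sample(term_ids, rng.randint(0, 6))
        rxn = QueryReaction("Rq", frozenset(f"s{i}" for i in range(len(chosen))) or frozenset({"s0"}))
        sp = preds_for(db, {f"s{i}": [t] for i, t in enumerate(chosen)})
        sp.setdefault("s0", PredictionSet("s0"))
        qvec = query_reaction_vector(rxn, sp, db)
        ctx = compute_normalizer(qvec, db)
        M_q, L_q, D = brute_normalizer(qvec, db)
        assert (ctx.M_q, set(ctx.L_q), ctx.D) == (M_q, L_q, D)
        # score properties: bounds and rank preservation vs raw dot product
        scores, _ = score_all_reactions(qvec, db)
        dots = {rid: qvec.dot(reference_reaction_vector(db.reactions[rid], db))
                for rid in db.reactions}
        assert all(0.0 <= s <= 1.0 for s in scores.values())
        by_score = sorted(db.reactions, key=lambda r: (-scores[r], r))
        by_dot = sorted(db.reactions, key=lambda r: (-dots[r], r))
        assert by_score == by_dot


def test_every_reference_reaction_self_matches_at_score_one(synth_corpus):
    db, _model, _truth = synth_corpus
    for rid, term in db.reactions.items():
        rxn = QueryReaction("q", frozenset(term.participants))
        sp = preds_for(db, {p: [p] for p in term.participants})
        qvec = query_reaction_vector(rxn, sp, db)
        scores, ctx = score_all_reactions(qvec, db)
        assert scores[rid] == pytest.approx(1.0)
        assert scores[rid] == max(scores.values())
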