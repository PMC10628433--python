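"""Element filters, MSSC selection, and end-to-end prediction."""

import itertools
import random

import pytest

from sbmlannot.predict import (Candidate, PredictionParams, QueryReaction,
                               QuerySpecies, filter_reaction, filter_species,
                               predict_reaction_annotations,
                               predict_species_annotations, select_candidates)
from sbmlannot.sbmlio import ModelView


def brute_select(scored, mssc, cutoff):
    """Oracle: direct restatement of the two selection criteria."""
    kept = {c.annotation_id for c in scored if c.score >= cutoff}
    if mssc == "above":
        return kept
    if not scored:
        return set()
    best = max(c.score for c in scored)
    return {c.annotation_id for c in scored if c.score == best} & kept


def test_species_filter_rejects_uninformative_names():
    assert not filter_species(QuerySpecies("S1", "S1"), min_len=3)
    assert filter_species(QuerySpecies("x", "atp"), min_len=3)
    assert not filter_species(QuerySpecies("x", ""), min_len=2)  # falls back to id "x"
    assert not filter_species(QuerySpecies("x", "a-!-"), min_len=2)  # normalized is "a"


def test_reaction_filter_counts_participants():
    r2 = QueryReaction("r", frozenset({"a", "b"}))
    r3 = QueryReaction("r", frozenset({"a", "b", "c"}))
    assert not filter_reaction(r2, 3)
    assert filter_reaction(r3, 3)
    assert filter_reaction(r2, 0)


def test_select_candidates_examples():
    scored = [Candidate("A", 0.9), Candidate("B", 0.9), Candidate("C", 0.5)]
    top = select_candidates(scored, "top", 0.8)
    assert [c.annotation_id for c in top] == ["A", "B"]  # tie inclusion, sorted
    above = select_candidates(scored, "above", 0.4)
    assert [c.annotation_id for c in above] == ["A", "B", "C"]
    assert select_candidates([Candidate("A", 0.9)], "top", 0.95) == ()
    # inclusive comparison: an exact match survives cutoff 1.0
    assert select_candidates([Candidate("A", 1.0)], "top", 1.0) != ()


def test_select_candidates_matches_brute_force_enumeration():
    levels = [0.0, 0.3, 0.5, 0.5, 0.8, 1.0]
    rng = random.Random(99)
    for n in range(7):
        for _ in range(40):
            scored = [Candidate(f"id{i}", rng.choice(levels)) for i in range(n)]
            for mssc in ("top", "above"):
                for cutoff in (0.0, 0.3, 0.5, 0.79, 1.0):
                    got = {c.annotation_id
                           for c in select_candidates(scored, mssc, cutoff)}
                    assert got == brute_select(scored, mssc, cutoff)
                    # top is always a subset of above at equal cutoff
                    above = {c.annotation_id
                             for c in select_candidates(scored, "above", cutoff)}
                    top = {c.annotation_id
                           for c in select_candidates(scored, "top", cutoff)}
                    assert top <= above


def test_selection_is_order_independent():
    scored = [Candidate("B", 0.7), Candidate("A", 0.7), Candidate("C", 0.2)]
    for perm in itertools.permutations(scored):
        assert select_candidates(list(perm), "top", 0.0) == \
            select_candidates(scored, "top", 0.0)


def test_species_prediction_on_fixture(fixture_db, fixture_model, default_params):
    preds = predict_species_annotations(fixture_model, fixture_db, default_params)
    assert preds["M_atp"].annotation_ids == {"CHEBI:30616"}
    assert preds["M_atp"].top_score == 1.0


def test_uninformative_model_yields_empty_sets(fixture_db, default_params):
    model = ModelView("m", species=[QuerySpecies(f"S{i}", f"S{i}") for i in range(5)])
    preds = predict_species_annotations(model, fixture_db, default_params)
    assert all(not p for p in preds.values())
    empty = ModelView("empty")
    assert predict_species_annotations(empty, fixture_db, default_params) == {}


def test_reaction_prediction_cutoff_gates_worked_example(fixture_db, fixture_model):
    """The hydrolysis analogue scores 0.4: included at cutoff 0.3 under
    'above', excluded at 0.5."""
    sp = predict_species_annotations(fixture_model, fixture_db, PredictionParams())
    lo = predict_reaction_annotations(fixture_model, fixture_db, sp,
                                      PredictionParams(mssc="above", cutoff=0.3))
    assert "RHEA:13065" in lo["R_hydro"].annotation_ids
    hi = predict_reaction_annotations(fixture_model, fixture_db, sp,
                                      PredictionParams(mssc="above", cutoff=0.5))
    assert "RHEA:13065" not in hi["R_hydro"].annotation_ids


def test_reaction_with_unpredicted_participants_is_empty(fixture_db):
    model = ModelView("m",
                      species=[QuerySpecies("S1", "S1"), QuerySpecies("S2", "S2")],
                      reactions=[QueryReaction("r", frozenset({"S1", "S2"}))])
    sp = predict_species_annotations(model, fixture_db, PredictionParams())
    rx = predict_reaction_annotations(model, fixture_db, sp, PredictionParams())
    assert not rx["r"]


def test_prediction_sets_shrink_as_cutoff_rises(fixture_db, fixture_model):
    """Per-element monotonicity: candidates at a higher cutoff are a subset
    of candidates at any lower cutoff (both MSSCs)."""
    for mssc in ("top", "above"):
        prev_sp = prev_rx = None
        for cutoff in [0.0, 0.25, 0.5, 0.75, 1.0]:
            params = PredictionParams(mssc=mssc, cutoff=cutoff)
            sp = predict_species_annotations(fixture_model, fixture_db, params)
            rx = predict_reaction_annotations(fixture_model, fixture_db, sp, params)
            if prev_sp is not None:
                for el in sp:
                    assert sp[el].annotation_ids <= prev_sp[el].annotation_ids
                for el in rx:
                    assert rx[el].annotation_ids <= prev_rx[el].annotation_ids
            prev_sp, prev_rx = sp, rx


def test_prediction_is_deterministic(fixture_db, fixture_model, default_params):
    runs = [predict_species_annotations(fixture_model, fixture_db, default_params)
            for _ in range(2)]
    assert runs[0] == runs[1]


def test_display_name_preference_and_fallback():
    assert QuerySpecies("sid", "Glucose").query_string == "Glucose"
    assert QuerySpecies("sid", None).query_string == "sid"
    assert QuerySpecies("sid", "   ").query_string == "sid"


@pytest.mark.parametrize("bad", [dict(cutoff=-0.1), dict(cutoff=1.5), dict(mssc="best")])
def test_invalid_params_rejected(bad):
    with pytest.raises(ValueError):
        PredictionParams(**bad)
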