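"""SBML reading, annotation writing, and round trips."""

import pytest

from sbmlannot import synthgen
from sbmlannot.predict import QueryReaction, QuerySpecies
from sbmlannot.sbmlio import (AnnotationRecord, AnnotationWriteError, ModelView,
                              SBMLReadError, model_to_sbml, parse_resource_uri,
                              read_model, resource_uri, write_annotations)


@pytest.fixture()
def small_model():
    species = [
        QuerySpecies("M_atp", "ATP", annotations=frozenset({"CHEBI:30616"})),
        QuerySpecies("M_adp", "ADP"),
        QuerySpecies("M_pi", None),  # no display name: falls back to id
    ]
    reactions = [
        QueryReaction("R1", frozenset({"M_atp", "M_adp"}),
                      annotations=frozenset({"RHEA:13065"})),
        QueryReaction("R2", frozenset({"M_adp", "M_pi"})),
    ]
    return ModelView("toy", species=species, reactions=reactions)


@pytest.mark.parametrize("uri,expected", [
    ("https://identifiers.org/CHEBI:17634", "CHEBI:17634"),
    ("http://identifiers.org/chebi/CHEBI:17634", "CHEBI:17634"),
    ("https://identifiers.org/rhea/13065", "RHEA:13065"),
    ("https://identifiers.org/RHEA:13065", "RHEA:13065"),
    ("https://identifiers.org/kegg.reaction/R00086", "KEGG:R00086"),
    ("https://identifiers.org/ec-code/2.7.1.1", "EC:2.7.1.1"),
    ("urn:miriam:chebi:CHEBI%3A17634", "CHEBI:17634"),
    ("urn:miriam:obo.chebi:CHEBI%3A17634", "CHEBI:17634"),
    ("urn:miriam:kegg.reaction:R00086", "KEGG:R00086"),
    ("https://identifiers.org/uniprot/P12345", None),  # foreign namespace
])
def test_parse_resource_uri_dialects(uri, expected):
    assert parse_resource_uri(uri) == expected


def test_uri_round_trip_for_all_reference_ids(fixture_db):
    ids = list(fixture_db.species) + list(fixture_db.reactions)
    for aid in ids:
        assert parse_resource_uri(resource_uri(aid)) == aid


def test_model_round_trips_through_sbml(tmp_path, small_model):
    path = tmp_path / "toy.xml"
    model_to_sbml(small_model, path)
    back = read_model(path)
    assert back.model_id == "toy"
    assert [s.element_id for s in back.species] == ["M_atp", "M_adp", "M_pi"]
    by_id = back.species_by_id
    assert by_id["M_atp"].display_name == "ATP"
    assert by_id["M_atp"].annotations == {"CHEBI:30616"}
    assert by_id["M_pi"].display_name is None
    assert by_id["M_pi"].query_string == "M_pi"
    rxns = {r.element_id: r for r in back.reactions}
    assert rxns["R1"].participant_ids == {"M_atp", "M_adp"}
    assert rxns["R1"].annotations == {"RHEA:13065"}


def test_read_model_errors(tmp_path):
    with pytest.raises(SBMLReadError):
        read_model(tmp_path / "nope.xml")
    bad = tmp_path / "bad.xml"
    bad.write_text("<sbml><model>")
    with pytest.raises(SBMLReadError):
        read_model(bad)


def test_modelview_integrity_checks():
    with pytest.raises(ValueError, match="unique"):
        ModelView("m", species=[QuerySpecies("a"), QuerySpecies("a")])
    with pytest.raises(ValueError, match="unknown participant"):
        ModelView("m", species=[QuerySpecies("a")],
                  reactions=[QueryReaction("r", frozenset({"ghost"}))])


def test_write_annotations_append_and_reread(tmp_path, small_model):
    src = tmp_path / "in.xml"
    out = tmp_path / "out.xml"
    model_to_sbml(small_model, src)
    records = [
        AnnotationRecord("M_adp", ("CHEBI:456216", "CHEBI:16761")),
        AnnotationRecord("R2", ("RHEA:11352",)),
    ]
    write_annotations(src, records, out, mode="append")
    back = read_model(out)
    assert back.species_by_id["M_adp"].annotations == {"CHEBI:456216", "CHEBI:16761"}
    # untouched elements preserved exactly
    assert back.species_by_id["M_atp"].annotations == {"CHEBI:30616"}
    rxns = {r.element_id: r for r in back.reactions}
    assert rxns["R2"].annotations == {"RHEA:11352"}
    assert rxns["R1"].annotations == {"RHEA:13065"}
    assert rxns["R1"].participant_ids == {"M_atp", "M_adp"}


def test_write_annotations_replace_supersedes_same_namespace(tmp_path, small_model):
    src, out = tmp_path / "in.xml", tmp_path / "out.xml"
    model_to_sbml(small_model, src)
    write_annotations(src, [AnnotationRecord("M_atp", ("CHEBI:15422",))],
                      out, mode="replace")
    back = read_model(out)
    assert back.species_by_id["M_atp"].annotations == {"CHEBI:15422"}


def test_append_keeps_existing_annotation(tmp_path, small_model):
    src, out = tmp_path / "in.xml", tmp_path / "out.xml"
    model_to_sbml(small_model, src)
    write_annotations(src, [AnnotationRecord("M_atp", ("CHEBI:15422",))],
                      out, mode="append")
    back = read_model(out)
    assert back.species_by_id["M_atp"].annotations == {"CHEBI:30616", "CHEBI:15422"}


def test_empty_record_list_is_identity(tmp_path, small_model):
    src, out = tmp_path / "in.xml", tmp_path / "out.xml"
    model_to_sbml(small_model, src)
    write_annotations(src, [], out)
    a, b = read_model(src), read_model(out)
    assert a.species == b.species and a.reactions == b.reactions


def test_unknown_element_fails_before_writing(tmp_path, small_model):
    src, out = tmp_path / "in.xml", tmp_path / "out.xml"
    model_to_sbml(small_model, src)
    with pytest.raises(AnnotationWriteError, match="ghost"):
        write_annotations(src, [AnnotationRecord("ghost", ("CHEBI:1",))], out)
    assert not out.exists()
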