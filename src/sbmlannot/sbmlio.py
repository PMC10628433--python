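"""SBML input/output for annotation recommendation.

Reads the slice of an SBML Level 2/3 document that annotation prediction
needs — species ids and display names, reaction reactant/product lists,
and existing MIRIAM-style controlled-vocabulary annotations — and writes
recommended annotations back as RDF CV terms carrying identifiers.org
resource URIs. No math, units, rules or layout are interpreted; the rest
of the document is preserved untouched on write.

Modifier species are read but not counted as reaction participants
(participants are reactants or products).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from lxml import etree

from .predict import QueryReaction, QuerySpecies

__all__ = [
    "ModelView",
    "AnnotationRecord",
    "SBMLReadError",
    "AnnotationWriteError",
    "read_model",
    "write_annotations",
    "model_to_sbml",
    "parse_resource_uri",
    "resource_uri",
]

RDF_NS = "http://www.w3.org/1999/02/22-rdf-syntax-ns#"
BQBIOL_NS = "http://biomodels.net/biology-qualifiers/"
SBML_L3V2_NS = "http://www.sbml.org/sbml/level3/version2/core"


class SBMLReadError(ValueError):
    """Raised when an SBML file cannot be parsed."""


class AnnotationWriteError(ValueError):
    """Raised when annotation records reference unknown model elements."""


@dataclass
class ModelView:
    """The annotation-relevant surface of one SBML model."""

    model_id: str
    species: list[QuerySpecies] = field(default_factory=list)
    reactions: list[QueryReaction] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.element_id for s in self.species] + [r.element_id for r in self.reactions]
        if len(ids) != len(set(ids)):
            raise ValueError("element ids must be unique within a model")
        sp_ids = {s.element_id for s in self.species}
        for rxn in self.reactions:
            missing = rxn.participant_ids - sp_ids
            if missing:
                raise ValueError(
                    f"reaction {rxn.element_id}: unknown participant species {sorted(missing)}"
                )

    @property
    def species_by_id(self) -> dict[str, QuerySpecies]:
        return {s.element_id: s for s in self.species}


@dataclass(frozen=True)
class AnnotationRecord:
    """Annotations to write for one element under one biology qualifier."""

    element_id: str
    annotation_ids: tuple[str, ...]
    qualifier: str = "is"


# --- identifiers.org URI handling -------------------------------------------

# Modern id-style, path-style, and legacy urn:miriam dialects.
_URI_PATTERNS: list[tuple[re.Pattern[str], str]] = [
    (re.compile(r"identifiers\.org/(?:chebi/)?CHEBI(?::|%3A)(\d+)$", re.I), "CHEBI:{0}"),
    (re.compile(r"identifiers\.org/(?:rhea/|RHEA:)(\d+)$", re.I), "RHEA:{0}"),
    (re.compile(r"identifiers\.org/kegg\.reaction[/:]([A-Za-z0-9]+)$", re.I), "KEGG:{0}"),
    (re.compile(r"identifiers\.org/ec-code[/:]([\d.\-]+)$", re.I), "EC:{0}"),
    (re.compile(r"urn:miriam:(?:obo\.)?chebi:CHEBI(?:%3A|:)(\d+)$", re.I), "CHEBI:{0}"),
    (re.compile(r"urn:miriam:rhea:(\d+)$", re.I), "RHEA:{0}"),
    (re.compile(r"urn:miriam:kegg\.reaction:([A-Za-z0-9]+)$", re.I), "KEGG:{0}"),
    (re.compile(r"urn:miriam:ec-code:([\d.\-]+)$", re.I), "EC:{0}"),
]


def parse_resource_uri(uri: str) -> str | None:
    """Extract a canonical annotation id (CHEBI:/RHEA:/KEGG:/EC:) from a
    resource URI in any supported identifiers.org dialect; None if the
    namespace is not recognized."""
    uri = uri.strip()
    for pat, fmt in _URI_PATTERNS:
        m = pat.search(uri)
        if m:
            return fmt.format(m.group(1))
    return None


def resource_uri(annotation_id: str) -> str:
    """Modern identifiers.org URI for a canonical annotation id."""
    prefix, _, local = annotation_id.partition(":")
    if not local:
        raise ValueError(f"not a prefixed annotation id: {annotation_id!r}")
    if prefix == "CHEBI":
        return f"https://identifiers.org/CHEBI:{local}"
    if prefix == "RHEA":
        return f"https://identifiers.org/rhea/{local}"
    if prefix == "KEGG":
        return f"https://identifiers.org/kegg.reaction/{local}"
    if prefix == "EC":
        return f"https://identifiers.org/ec-code/{local}"
    raise ValueError(f"unsupported annotation namespace: {annotation_id!r}")


# --- reading -----------------------------------------------------------------

def _local(el: etree._Element) -> str:
    return etree.QName(el).localname


def _element_annotations(el: etree._Element) -> frozenset[str]:
    ids: set[str] = set()
    for ann in el:
        if _local(ann) != "annotation":
            continue
        for li in ann.iter(f"{{{RDF_NS}}}li"):
            uri = li.get(f"{{{RDF_NS}}}resource")
            if uri:
                parsed = parse_resource_uri(uri)
                if parsed:
                    ids.add(parsed)
    return frozenset(ids)


def read_model(path: str | Path) -> ModelView:
    """Read species, reactions and existing annotations from an SBML file."""
    try:
        tree = etree.parse(str(path))
    except (OSError, etree.XMLSyntaxError) as exc:
        raise SBMLReadError(f"cannot parse SBML file {path}: {exc}") from exc
    root = tree.getroot()
    model_el = next((el for el in root.iter() if _local(el) == "model"), None)
    if model_el is None:
        raise SBMLReadError(f"{path}: no <model> element found")

    species: list[QuerySpecies] = []
    for sp in model_el.iter():
        if _local(sp) != "species":
            continue
        sid = sp.get("id")
        if not sid:
            continue
        species.append(QuerySpecies(
            element_id=sid,
            display_name=sp.get("name"),
            annotations=_element_annotations(sp),
        ))

    reactions: list[QueryReaction] = []
    for rx in model_el.iter():
        if _local(rx) != "reaction":
            continue
        rid = rx.get("id")
        if not rid:
            continue
        participants: set[str] = set()
        for lst in rx:
            if _local(lst) in ("listOfReactants", "listOfProducts"):
                for ref in lst:
                    if _local(ref) == "speciesReference" and ref.get("species"):
                        participants.add(ref.get("species"))
        reactions.append(QueryReaction(
            element_id=rid,
            participant_ids=frozenset(participants),
            annotations=_element_annotations(rx),
        ))

    return ModelView(model_id=model_el.get("id") or "", species=species, reactions=reactions)


# --- writing -----------------------------------------------------------------

_SPECIES_NAMESPACES = ("CHEBI",)
_REACTION_NAMESPACES = ("RHEA", "KEGG", "EC")


def _find_elements_by_id(model_el: etree._Element) -> dict[str, etree._Element]:
    out: dict[str, etree._Element] = {}
    for el in model_el.iter():
        if _local(el) in ("species", "reaction") and el.get("id"):
            out[el.get("id")] = el
    return out


def _ensure_metaid(el: etree._Element) -> str:
    metaid = el.get("metaid")
    if not metaid:
        metaid = f"metaid_{el.get('id')}"
        el.set("metaid", metaid)
    return metaid


def _rdf_description(el: etree._Element, metaid: str) -> etree._Element:
    """Find or create <annotation><rdf:RDF><rdf:Description rdf:about="#metaid">."""
    ann = next((c for c in el if _local(c) == "annotation"), None)
    if ann is None:
        ann = etree.SubElement(el, f"{{{etree.QName(el).namespace}}}annotation"
                               if etree.QName(el).namespace else "annotation")
        el.insert(0, ann)
    rdf = next(iter(ann.iter(f"{{{RDF_NS}}}RDF")), None)
    if rdf is None:
        rdf = etree.SubElement(ann, f"{{{RDF_NS}}}RDF",
                               nsmap={"rdf": RDF_NS, "bqbiol": BQBIOL_NS})
    desc = None
    for d in rdf.iter(f"{{{RDF_NS}}}Description"):
        if d.get(f"{{{RDF_NS}}}about") in (f"#{metaid}", metaid):
            desc = d
            break
    if desc is None:
        desc = etree.SubElement(rdf, f"{{{RDF_NS}}}Description")
        desc.set(f"{{{RDF_NS}}}about", f"#{metaid}")
    return desc


def _strip_namespaced_resources(el: etree._Element, namespaces: Sequence[str]) -> None:
    """Remove rdf:li entries whose resource parses into one of the given
    annotation namespaces; other annotations are left untouched."""
    for ann in list(el):
        if _local(ann) != "annotation":
            continue
        for li in list(ann.iter(f"{{{RDF_NS}}}li")):
            uri = li.get(f"{{{RDF_NS}}}resource") or ""
            parsed = parse_resource_uri(uri)
            if parsed and parsed.split(":", 1)[0] in namespaces:
                li.getparent().remove(li)


def write_annotations(path_in: str | Path, records: Iterable[AnnotationRecord],
                      path_out: str | Path, mode: str = "append") -> None:
    """Add controlled-vocabulary annotations to an SBML file.

    ``append`` adds the new resource URIs alongside whatever is present;
    ``replace`` first removes existing annotations in the same namespace
    family (ChEBI for species, Rhea/KEGG/EC for reactions). All records
    are validated against the model before anything is written.
    """
    if mode not in ("append", "replace"):
        raise ValueError(f"mode must be 'append' or 'replace', got {mode!r}")
    records = list(records)
    tree = etree.parse(str(path_in))
    model_el = next((el for el in tree.getroot().iter() if _local(el) == "model"), None)
    if model_el is None:
        raise SBMLReadError(f"{path_in}: no <model> element found")
    by_id = _find_elements_by_id(model_el)
    unknown = sorted({r.element_id for r in records} - by_id.keys())
    if unknown:
        raise AnnotationWriteError(f"unknown element id(s): {', '.join(unknown)}")

    for rec in records:
        if not rec.annotation_ids:
            continue
        el = by_id[rec.element_id]
        if mode == "replace":
            fams = _SPECIES_NAMESPACES if _local(el) == "species" else _REACTION_NAMESPACES
            _strip_namespaced_resources(el, fams)
        metaid = _ensure_metaid(el)
        desc = _rdf_description(el, metaid)
        qual = etree.QName(BQBIOL_NS, rec.qualifier)
        qual_el = next(iter(desc.iter(qual.text)), None)
        if qual_el is None:
            qual_el = etree.SubElement(desc, qual.text)
        bag = next(iter(qual_el.iter(f"{{{RDF_NS}}}Bag")), None)
        if bag is None:
            bag = etree.SubElement(qual_el, f"{{{RDF_NS}}}Bag")
        present = {li.get(f"{{{RDF_NS}}}resource") for li in bag.iter(f"{{{RDF_NS}}}li")}
        for aid in rec.annotation_ids:
            uri = resource_uri(aid)
            if uri not in present:
                li = etree.SubElement(bag, f"{{{RDF_NS}}}li")
                li.set(f"{{{RDF_NS}}}resource", uri)

    tree.write(str(path_out), xml_declaration=True, encoding="UTF-8", pretty_print=True)


# --- minimal model writer (used by the synthetic generator and tests) --------

def model_to_sbml(model: ModelView, path: str | Path | None = None) -> str:
    """Serialize a ModelView as a minimal SBML Level 3 Version 2 document.

    Every species is placed in a single compartment; reaction participants
    are split arbitrarily into reactants and products (participant matching
    ignores direction). Existing annotations on the view are emitted as
    bqbiol:is CV terms.
    """
    nsmap = {None: SBML_L3V2_NS, "rdf": RDF_NS, "bqbiol": BQBIOL_NS}
    sbml = etree.Element(f"{{{SBML_L3V2_NS}}}sbml", nsmap=nsmap)
    sbml.set("level", "3")
    sbml.set("version", "2")
    model_el = etree.SubElement(sbml, f"{{{SBML_L3V2_NS}}}model")
    if model.model_id:
        model_el.set("id", model.model_id)
    comps = etree.SubElement(model_el, f"{{{SBML_L3V2_NS}}}listOfCompartments")
    comp = etree.SubElement(comps, f"{{{SBML_L3V2_NS}}}compartment")
    comp.set("id", "c")
    comp.set("constant", "true")

    def _annotate(el: etree._Element, ids: frozenset[str]) -> None:
        if not ids:
            return
        metaid = _ensure_metaid(el)
        desc = _rdf_description(el, metaid)
        qual_el = etree.SubElement(desc, f"{{{BQBIOL_NS}}}is")
        bag = etree.SubElement(qual_el, f"{{{RDF_NS}}}Bag")
        for aid in sorted(ids):
            li = etree.SubElement(bag, f"{{{RDF_NS}}}li")
            li.set(f"{{{RDF_NS}}}resource", resource_uri(aid))

    sp_list = etree.SubElement(model_el, f"{{{SBML_L3V2_NS}}}listOfSpecies")
    for sp in model.species:
        el = etree.SubElement(sp_list, f"{{{SBML_L3V2_NS}}}species")
        el.set("id", sp.element_id)
        if sp.display_name is not None:
            el.set("name", sp.display_name)
        el.set("compartment", "c")
        el.set("hasOnlySubstanceUnits", "false")
        el.set("boundaryCondition", "false")
        el.set("constant", "false")
        _annotate(el, sp.annotations)

    if model.reactions:
        rx_list = etree.SubElement(model_el, f"{{{SBML_L3V2_NS}}}listOfReactions")
        for rxn in model.reactions:
            el = etree.SubElement(rx_list, f"{{{SBML_L3V2_NS}}}reaction")
            el.set("id", rxn.element_id)
            el.set("reversible", "false")
            parts = sorted(rxn.participant_ids)
            half = max(1, len(parts) // 2)
            for tag, chunk in (("listOfReactants", parts[:half]),
                               ("listOfProducts", parts[half:])):
                if not chunk:
                    continue
                lst = etree.SubElement(el, f"{{{SBML_L3V2_NS}}}{tag}")
                for sid in chunk:
                    ref = etree.SubElement(lst, f"{{{SBML_L3V2_NS}}}speciesReference")
                    ref.set("species", sid)
                    ref.set("stoichiometry", "1")
                    ref.set("constant", "true")
            _annotate(el, rxn.annotations)

    xml = etree.tostring(sbml, xml_declaration=True, encoding="UTF-8", pretty_print=True)
    if path is not None:
        Path(path).write_bytes(xml)
    return xml.decode("utf-8")
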