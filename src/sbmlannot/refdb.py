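"""Reference databases of annotated species and reactions.

A species reference term (ChEBI-style) carries a list of synonyms and one
or more chemical formulas; a reaction reference term (Rhea-style) is a set
of participant species terms. Reaction matching works in a vector space
whose dimensions are *simplified* formulas: all hydrogen is dropped, except
that pure-hydrogen species (H, H2, ... "Hn") keep the single symbol ``H``.
Dropping hydrogen makes protonation/deprotonation variants of the same
metabolite land on the same coordinate.

Only species terms with at least one parsable formula are admitted, since
the reaction space is built from formulas.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ChemicalFormula",
    "FormulaParseError",
    "ReferenceLoadError",
    "SpeciesTerm",
    "ReactionTerm",
    "ReferenceDatabase",
    "CrossRefMap",
    "parse_formula",
    "simplify_formula",
    "load_reference_db",
    "load_crossref_map",
    "write_reference_db",
]


class FormulaParseError(ValueError):
    """Raised when a chemical formula string cannot be tokenized."""


class ReferenceLoadError(ValueError):
    """Raised when a reference table violates referential integrity."""


# Element symbol: capital letter optionally followed by one lowercase letter.
_TOKEN_RE = re.compile(r"([A-Z][a-z]?)(\d*)")
# Trailing net-charge token: a sign, optionally preceded by one magnitude
# digit ("+", "-", "2-", "3−"); tolerated and discarded. Note "C2H3O2-" is
# inherently ambiguous in this notation (O2 + charge 1-, or O + charge 2-);
# it parses as charge "2-", so charge-free spellings are preferred in tables.
_CHARGE_RE = re.compile(r"\d?[+\-−]$")


@dataclass(frozen=True)
class ChemicalFormula:
    """A parsed chemical formula: element symbol -> positive count."""

    elements: Mapping[str, int]
    raw: str

    def __post_init__(self) -> None:
        for sym, n in self.elements.items():
            if n < 1:
                raise ValueError(f"count for {sym!r} must be >= 1, got {n}")


def parse_formula(raw: str) -> ChemicalFormula:
    """Parse a molecular formula such as ``"C6H12O6"`` or ``"PO43-"``.

    Repeated element symbols are summed; a trailing charge token is
    stripped. Parenthesized groups and isotope notation are rejected.
    """
    if not raw or not raw.strip():
        raise FormulaParseError("empty formula")
    s = raw.strip()
    s = _CHARGE_RE.sub("", s)
    if not s:
        raise FormulaParseError(f"formula {raw!r} contains only a charge token")
    elements: dict[str, int] = {}
    pos = 0
    while pos < len(s):
        m = _TOKEN_RE.match(s, pos)
        if m is None or m.end() == pos:
            raise FormulaParseError(
                f"malformed formula {raw!r}: unexpected character {s[pos]!r} at position {pos}"
            )
        sym, digits = m.groups()
        count = int(digits) if digits else 1
        if count < 1:
            raise FormulaParseError(f"malformed formula {raw!r}: zero count at position {pos}")
        elements[sym] = elements.get(sym, 0) + count
        pos = m.end()
    return ChemicalFormula(elements=elements, raw=raw)


def simplify_formula(f: ChemicalFormula) -> str:
    """Canonical simplified formula: hydrogen removed, "Hn" maps to "H".

    Remaining elements are serialized in alphabetical order with the count
    suffix omitted when it is 1 (e.g. C6H12O6 -> "C6O6", H2O -> "O",
    H2 -> "H"). The result is a stable dictionary key: equal element
    multisets always yield equal strings.
    """
    if not f.elements:
        raise ValueError("formula has no elements")
    rest = {sym: n for sym, n in f.elements.items() if sym != "H"}
    if not rest:
        return "H"
    return "".join(
        sym + (str(n) if n > 1 else "") for sym, n in sorted(rest.items())
    )


@dataclass(frozen=True)
class SpeciesTerm:
    """A reference species term: id, synonyms, simplified formulas."""

    term_id: str
    synonyms: tuple[str, ...]
    formulas: frozenset[str]

    def __post_init__(self) -> None:
        if not self.synonyms:
            raise ValueError(f"{self.term_id}: synonyms must be nonempty")
        if not self.formulas:
            raise ValueError(f"{self.term_id}: at least one formula required")


@dataclass(frozen=True)
class ReactionTerm:
    """A reference reaction: id, participant term ids and their formula set."""

    reaction_id: str
    participants: frozenset[str]
    formula_set: frozenset[str]

    def __post_init__(self) -> None:
        if not self.participants:
            raise ValueError(f"{self.reaction_id}: participants must be nonempty")


@dataclass
class ReferenceDatabase:
    """Indexed species + reaction reference tables.

    ``formula_index`` maps every distinct simplified formula appearing in
    the database to a dense coordinate 0..K-1; it is the dimension basis of
    the binary reaction vectors.
    """

    species: dict[str, SpeciesTerm]
    reactions: dict[str, ReactionTerm]
    formula_index: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.formula_index:
            self.formula_index = self._build_formula_index()
        self._formula_by_coord = {i: f for f, i in self.formula_index.items()}

    def _build_formula_index(self) -> dict[str, int]:
        formulas: set[str] = set()
        for term in self.species.values():
            formulas |= term.formulas
        for rxn in self.reactions.values():
            formulas |= rxn.formula_set
        return {f: i for i, f in enumerate(sorted(formulas))}

    def formula_at(self, coord: int) -> str:
        return self._formula_by_coord[coord]

    def coords_of_term(self, term_id: str) -> frozenset[int]:
        """Coordinates of all simplified formulas of one species term."""
        return frozenset(self.formula_index[f] for f in self.species[term_id].formulas)


def _build_reaction(reaction_id: str, participants: Iterable[str],
                    species: Mapping[str, SpeciesTerm]) -> ReactionTerm:
    parts = frozenset(participants)
    missing = sorted(p for p in parts if p not in species)
    if missing:
        raise ReferenceLoadError(
            f"reaction {reaction_id}: unknown participant term(s): {', '.join(missing)}"
        )
    fset = frozenset(f for p in parts for f in species[p].formulas)
    return ReactionTerm(reaction_id=reaction_id, participants=parts, formula_set=fset)


def load_reference_db(species_path: str | Path,
                      reactions_path: str | Path | None = None) -> ReferenceDatabase:
    """Load species and (optionally) reaction reference tables.

    Species table: TSV with columns ``term_id``, ``name``, ``synonyms``
    (pipe-separated), ``formula`` (semicolon-separated). Reaction table:
    TSV with columns ``reaction_id``, ``participants`` (pipe-separated
    term ids). Species terms without any parsable formula are dropped with
    a warning; a reaction referencing an unknown term is a load error.
    """
    sp_df = pd.read_csv(species_path, sep="\t", dtype=str).fillna("")
    required = {"term_id", "name", "synonyms", "formula"}
    if not required.issubset(sp_df.columns):
        raise ReferenceLoadError(
            f"species table missing columns: {sorted(required - set(sp_df.columns))}"
        )
    species: dict[str, SpeciesTerm] = {}
    for row in sp_df.itertuples(index=False):
        term_id = row.term_id.strip()
        if not term_id:
            continue
        if term_id in species:
            raise ReferenceLoadError(f"duplicate term_id {term_id}")
        synonyms = [s for s in ([row.name.strip()] + row.synonyms.split("|")) if s.strip()]
        # preserve order, drop duplicates
        seen: dict[str, None] = {}
        for s in synonyms:
            seen.setdefault(s.strip(), None)
        formulas: set[str] = set()
        for raw in row.formula.split(";"):
            raw = raw.strip()
            if not raw:
                continue
            try:
                formulas.add(simplify_formula(parse_formula(raw)))
            except FormulaParseError as exc:
                logger.warning("term %s: skipping unparsable formula %r (%s)", term_id, raw, exc)
        if not formulas:
            logger.warning("term %s dropped: no parsable chemical formula", term_id)
            continue
        species[term_id] = SpeciesTerm(
            term_id=term_id, synonyms=tuple(seen), formulas=frozenset(formulas)
        )

    reactions: dict[str, ReactionTerm] = {}
    if reactions_path is not None:
        rx_df = pd.read_csv(reactions_path, sep="\t", dtype=str).fillna("")
        if not {"reaction_id", "participants"}.issubset(rx_df.columns):
            raise ReferenceLoadError("reaction table must have columns reaction_id, participants")
        for row in rx_df.itertuples(index=False):
            rid = row.reaction_id.strip()
            if not rid:
                continue
            if rid in reactions:
                raise ReferenceLoadError(f"duplicate reaction_id {rid}")
            parts = [p.strip() for p in row.participants.split("|") if p.strip()]
            reactions[rid] = _build_reaction(rid, parts, species)

    return ReferenceDatabase(species=species, reactions=reactions)


def write_reference_db(db: ReferenceDatabase, species_path: str | Path,
                       reactions_path: str | Path) -> None:
    """Serialize a database back to the TSV dialect read by load_reference_db.

    Simplified formulas are written as-is (they re-parse and re-simplify to
    themselves), so a written database round-trips.
    """
    sp_rows = [
        {
            "term_id": t.term_id,
            "name": t.synonyms[0],
            "synonyms": "|".join(t.synonyms),
            "formula": ";".join(sorted(t.formulas)),
        }
        for t in db.species.values()
    ]
    pd.DataFrame(sp_rows, columns=["term_id", "name", "synonyms", "formula"]).to_csv(
        species_path, sep="\t", index=False
    )
    rx_rows = [
        {"reaction_id": r.reaction_id, "participants": "|".join(sorted(r.participants))}
        for r in db.reactions.values()
    ]
    pd.DataFrame(rx_rows, columns=["reaction_id", "participants"]).to_csv(
        reactions_path, sep="\t", index=False
    )


@dataclass
class CrossRefMap:
    """Foreign reaction identifiers (KEGG reaction ids, EC numbers) -> reaction ids."""

    mapping: dict[str, frozenset[str]] = field(default_factory=dict)

    def lookup(self, foreign_id: str) -> frozenset[str]:
        return self.mapping.get(foreign_id, frozenset())

    def __len__(self) -> int:
        return len(self.mapping)


def load_crossref_map(path: str | Path,
                      db: ReferenceDatabase | None = None) -> CrossRefMap:
    """Load a two-column TSV ``foreign_id`` / ``reaction_ids`` (pipe-separated).

    Duplicate foreign ids union their targets. Targets absent from ``db``
    (when given) are retained with a warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if not {"foreign_id", "reaction_ids"}.issubset(df.columns):
        raise ReferenceLoadError("crossref table must have columns foreign_id, reaction_ids")
    mapping: dict[str, set[str]] = {}
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        fid = row.foreign_id.strip()
        targets = {t.strip() for t in row.reaction_ids.split("|") if t.strip()}
        if not fid or not targets:
            raise ReferenceLoadError(f"crossref line {lineno}: malformed row")
        mapping.setdefault(fid, set()).update(targets)
    if db is not None:
        for fid, targets in mapping.items():
            unknown = targets - db.reactions.keys()
            if unknown:
                logger.warning("crossref %s: unresolvable target(s) %s", fid, sorted(unknown))
    return CrossRefMap({fid: frozenset(t) for fid, t in mapping.items()})
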