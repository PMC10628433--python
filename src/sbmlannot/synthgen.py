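"""Synthetic reference databases, models and ground truth.

Everything here exists so that the whole prediction pipeline is testable
without downloading ChEBI or Rhea: a generator for reference tables and
matching SBML models whose display names are (optionally noisy) variants
of reference synonyms, and a hand-built fixture reproducing the canonical
ATP-hydrolysis worked example and the acetate-kinase refinement scenario.

All randomness flows through one explicitly seeded ``random.Random``
(integer draws only), so generated corpora are bit-identical across
platforms for a fixed seed.
"""

from __future__ import annotations

import random
import string
from dataclasses import dataclass
from importlib import resources

from .predict import QueryReaction, QuerySpecies
from .refdb import (ReactionTerm, ReferenceDatabase, SpeciesTerm,
                    load_crossref_map, load_reference_db)
from .sbmlio import ModelView
from .strmatch import normalize_string

__all__ = ["SynthConfig", "ConfigError", "GroundTruth", "generate_reference_db",
           "generate_model", "paper_fixture", "fixture_crossref",
           "fig2_initial_species_predictions"]

GroundTruth = dict[str, dict[str, frozenset[str]]]

_NAME_CHARS = string.ascii_lowercase
_ELEMENTS = ("C", "N", "O", "P", "S")  # H added separately


class ConfigError(ValueError):
    """Raised when a synthetic-data configuration is not constructible."""


@dataclass(frozen=True)
class SynthConfig:
    """Knobs of the synthetic corpus.

    Defaults give a small but nondegenerate corpus: 50 species terms with
    1-3 synonyms each, 20 reactions of 2-6 participants, clean names
    (noise 0) and complete participant lists (dropout 0).
    """

    n_species_terms: int = 50
    synonyms_per_term: tuple[int, int] = (1, 3)
    name_length: tuple[int, int] = (4, 10)
    n_formula_elements: tuple[int, int] = (1, 4)
    n_reactions: int = 20
    participants_per_reaction: tuple[int, int] = (2, 6)
    name_noise_rate: float = 0.0
    participant_dropout_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for lo, hi in (self.synonyms_per_term, self.name_length,
                       self.n_formula_elements, self.participants_per_reaction):
            if lo < 1 or hi < lo:
                raise ConfigError(f"range ({lo}, {hi}) is empty or invalid")
        for rate in (self.name_noise_rate, self.participant_dropout_rate):
            if not 0.0 <= rate <= 1.0:
                raise ConfigError(f"rate {rate} outside [0, 1]")
        if self.n_species_terms < 1 or self.n_reactions < 0:
            raise ConfigError("need at least one species term")
        if self.participants_per_reaction[0] > self.n_species_terms:
            raise ConfigError("reactions need more participants than terms exist")


def _signature(s: str) -> str:
    """Character-multiset signature of a normalized string; two strings with
    equal signatures are indistinguishable to the count-vector encoding."""
    return "".join(sorted(normalize_string(s).normalized))


def _random_formula(rng: random.Random, cfg: SynthConfig) -> str:
    # ~1 in 12 terms is pure hydrogen so the Hn -> "H" rule is exercised
    if rng.randrange(12) == 0:
        return f"H{rng.randint(1, 4)}"
    k = rng.randint(*cfg.n_formula_elements)
    syms = rng.sample(_ELEMENTS, min(k, len(_ELEMENTS)))
    parts = [f"{sym}{rng.randint(1, 20)}" for sym in sorted(syms)]
    if rng.randrange(2):
        parts.append(f"H{rng.randint(1, 20)}")
    return "".join(parts)


def _perturb(name: str, rate: float, rng: random.Random) -> str:
    """Per-character substitution/deletion noise at the given rate."""
    out: list[str] = []
    for ch in name:
        if rng.random() < rate:
            if rng.randrange(2):
                out.append(rng.choice(_NAME_CHARS))
            # else: deletion
        else:
            out.append(ch)
    return "".join(out)


def generate_reference_db(cfg: SynthConfig) -> ReferenceDatabase:
    """Generate a reference database of species terms and reactions.

    Synonym sets are rejection-sampled so that no two terms share a
    character multiset: with clean names, the true term is always the
    unique cosine-1 match.
    """
    rng = random.Random(cfg.seed)
    taken_signatures: set[str] = set()
    species: dict[str, SpeciesTerm] = {}
    for i in range(cfg.n_species_terms):
        term_id = f"CHEBI:{900000 + i}"
        synonyms: list[str] = []
        n_syn = rng.randint(*cfg.synonyms_per_term)
        attempts = 0
        while len(synonyms) < n_syn:
            attempts += 1
            if attempts > 10000:
                raise ConfigError("cannot construct collision-free synonyms; "
                                  "increase name_length or reduce n_species_terms")
            if not synonyms:
                cand = "".join(rng.choice(_NAME_CHARS)
                               for _ in range(rng.randint(*cfg.name_length)))
            else:
                base = synonyms[0]
                variant = rng.randrange(3)
                if variant == 0:
                    cand = base + rng.choice(_NAME_CHARS)
                elif variant == 1:
                    cand = base + "s"
                else:
                    pos = rng.randrange(len(base) + 1)
                    cand = base[:pos] + str(rng.randrange(10)) + base[pos:]
            sig = _signature(cand)
            if sig and sig not in taken_signatures:
                taken_signatures.add(sig)
                synonyms.append(cand)
        formulas = frozenset({simplify(_random_formula(rng, cfg))})
        species[term_id] = SpeciesTerm(term_id=term_id, synonyms=tuple(synonyms),
                                       formulas=formulas)

    term_ids = sorted(species)
    reactions: dict[str, ReactionTerm] = {}
    seen_sets: set[frozenset[str]] = set()
    attempts = 0
    while len(reactions) < cfg.n_reactions:
        attempts += 1
        if attempts > 10000:
            raise ConfigError("cannot construct the requested number of distinct reactions")
        k = rng.randint(*cfg.participants_per_reaction)
        parts = frozenset(rng.sample(term_ids, min(k, len(term_ids))))
        if parts in seen_sets:
            continue
        seen_sets.add(parts)
        rid = f"RHEA:{800000 + len(reactions)}"
        fset = frozenset(f for p in parts for f in species[p].formulas)
        reactions[rid] = ReactionTerm(reaction_id=rid, participants=parts, formula_set=fset)

    return ReferenceDatabase(species=species, reactions=reactions)


def simplify(raw: str) -> str:
    """Parse-and-simplify convenience used by the generator."""
    from .refdb import parse_formula, simplify_formula
    return simplify_formula(parse_formula(raw))


def generate_model(db: ReferenceDatabase, cfg: SynthConfig) -> tuple[ModelView, GroundTruth]:
    """Build a model whose elements derive from reference entries.

    Each of (up to) ``cfg.n_reactions`` reference reactions becomes a
    model reaction over species drawn from its participants; display names
    are synonyms perturbed at ``name_noise_rate`` and participants are
    dropped at ``participant_dropout_rate`` (at least one is kept).
    Elements carry their source ids as annotations, which double as the
    returned ground truth.
    """
    rng = random.Random(cfg.seed + 1)
    rids = sorted(db.reactions)[: cfg.n_reactions]
    used_terms: list[str] = sorted({p for rid in rids for p in db.reactions[rid].participants})

    sp_el_of_term: dict[str, str] = {}
    species: list[QuerySpecies] = []
    sp_truth: dict[str, frozenset[str]] = {}
    for i, term_id in enumerate(used_terms):
        el_id = f"M_sp{i}"
        syn = rng.choice(db.species[term_id].synonyms)
        name = _perturb(syn, cfg.name_noise_rate, rng)
        species.append(QuerySpecies(element_id=el_id, display_name=name,
                                    annotations=frozenset({term_id})))
        sp_el_of_term[term_id] = el_id
        sp_truth[el_id] = frozenset({term_id})

    reactions: list[QueryReaction] = []
    rx_truth: dict[str, frozenset[str]] = {}
    for j, rid in enumerate(rids):
        el_id = f"R_rx{j}"
        parts = sorted(db.reactions[rid].participants)
        kept = [p for p in parts if rng.random() >= cfg.participant_dropout_rate]
        if not kept:
            kept = [rng.choice(parts)]
        reactions.append(QueryReaction(
            element_id=el_id,
            participant_ids=frozenset(sp_el_of_term[p] for p in kept),
            annotations=frozenset({rid}),
        ))
        rx_truth[el_id] = frozenset({rid})

    model = ModelView(model_id=f"synthetic_seed{cfg.seed}",
                      species=species, reactions=reactions)
    return model, {"species": sp_truth, "reactions": rx_truth}


# --- hand-built fixture ------------------------------------------------------

def _data_path(name: str):
    return resources.files("sbmlannot").joinpath("data", name)


def paper_fixture() -> tuple[ReferenceDatabase, ModelView]:
    """The packaged worked-example fixture.

    The reference database (ATP, ADP, water, phosphate, proton, acetate,
    ... ~two dozen terms and six reactions) is loaded from the packaged
    TSV tables. The model contains:

    * ``R_hydro``: an ATP -> ADP reaction, a stripped-down description of
      ATP hydrolysis. Its query vector shares exactly 2 simplified
      formulas with the 5-participant hydrolysis reference RHEA:13065,
      and every reference reaction containing both ATP and ADP has 5 or
      more participant formulas, so M_q = 2, D = 5 and
      rScore(query, RHEA:13065) = 2/5 = 0.4.
    * ``R_ACKr``: an acetate-kinase reaction with four participants, the
      refinement scenario (see :func:`fig2_initial_species_predictions`).
    """
    with resources.as_file(_data_path("species.tsv")) as sp, \
         resources.as_file(_data_path("reactions.tsv")) as rx:
        db = load_reference_db(sp, rx)

    species = [
        QuerySpecies("M_atp", "ATP"),
        QuerySpecies("M_adp", "ADP"),
        QuerySpecies("M_ac_c", "acetate"),
        QuerySpecies("M_atp_c", "atp"),
        QuerySpecies("M_adp_c", "ADP"),
        QuerySpecies("M_actp_c", "acetyl phosphate"),
    ]
    reactions = [
        QueryReaction("R_hydro", frozenset({"M_atp", "M_adp"})),
        QueryReaction("R_ACKr", frozenset({"M_ac_c", "M_atp_c", "M_adp_c", "M_actp_c"})),
    ]
    model = ModelView(model_id="worked_example", species=species, reactions=reactions)
    return db, model


def fixture_crossref():
    """Cross-reference map (KEGG/EC -> Rhea) companion to the fixture."""
    with resources.as_file(_data_path("crossref.tsv")) as path:
        return load_crossref_map(path)


def fig2_initial_species_predictions(db: ReferenceDatabase):
    """Species predictions for the refinement scenario.

    Three of the four acetate-kinase participants carry their correct
    annotation; ``M_atp_c`` starts out wrongly annotated as dATP (a
    plausible string-level confusion: "atp" vs "dATP"). Pairing against
    the mapped reference reaction RHEA:11352 yields three matched pairs
    and one unmatched pair, and refinement replaces the dATP annotation
    with ATP (CHEBI:30616), strictly increasing the reaction's rScore.
    """
    from .predict import Candidate, PredictionSet

    def single(el_id: str, term: str, score: float) -> PredictionSet:
        return PredictionSet(el_id, (Candidate(term, score),))

    return {
        "M_ac_c": single("M_ac_c", "CHEBI:30089", 1.0),
        "M_atp_c": single("M_atp_c", "CHEBI:61404", 0.87),
        "M_adp_c": single("M_adp_c", "CHEBI:456216", 1.0),
        "M_actp_c": single("M_actp_c", "CHEBI:22191", 1.0),
        "M_atp": single("M_atp", "CHEBI:30616", 1.0),
        "M_adp": single("M_adp", "CHEBI:456216", 1.0),
    }
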