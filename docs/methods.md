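# Methods

This note records the model, the numerical and design choices behind
`sbmlannot`, and what the synthetic test corpus does and does not show.

## Matching model

The recommender treats annotation as nearest-neighbour search under a
type-specific match score in [0, 1].

**Species.** Names are normalized (lowercased; every character outside
[a-z0-9] dropped — whitespace, punctuation, Greek and all other
non-ASCII are removed, not transliterated, because the vector space has
exactly 36 dimensions) and encoded as character-count vectors. cScore is
the maximal cosine against a reference term's synonyms. The cosine of a
zero vector is defined as 0; the paper-style formula is undefined there,
and such queries are normally rejected by the length filter anyway. The
encoding cannot distinguish anagrams; this is accepted as the price of
robustness for short chemical names.

**Reactions.** Reference participants are reduced to simplified formulas
(hydrogen removed; a formula containing only hydrogen becomes "H").
This identifies protonation/deprotonation variants and shrinks the
coordinate space. The canonical serialization orders element symbols
alphabetically and omits the count suffix 1 ("C6O6", "O"): any fixed
deterministic form works, and alphabetical order makes equal element
multisets collide by construction. Binary reaction vectors ignore
direction and stoichiometry; the query vector takes the union of all
formulas of all candidate terms surviving species-level selection for
each participant, so one species can set several coordinates.

The normalizer D is the smallest self-dot-product among the reference
reactions tied at the maximal dot product with the query. Consequences
worth noting: D ≥ M_q always, so scores stay in [0, 1]; D rescales but
never reranks; a reference reaction used as its own query always scores
exactly 1 (it sits in L_q, and every other member of L_q has a support
superset). When the query vector is empty or disjoint from every
reference reaction, M_q = 0; we define D = 0 and all scores 0, and an
all-zero selection is reported as an empty prediction set rather than an
arbitrary full-database tie.

**Selection.** The cutoff comparison is inclusive (score ≥ cutoff): the
documented default cutoff of 0 then recommends whenever any evidence
exists, and cutoff 1.0 still admits exact matches. Ties under `top` are
all returned, in lexicographic annotation-id order for reproducible
output. Default filters are min_len = 3 for species and
min_participants = 0 (`predict.EVALUATION_PRESET` bundles the stricter
3/3 configuration used for corpus evaluation). When a display name is
present and nonempty after trimming it is always preferred over the
element id; there is no fallback to the id for uninformative display
names.

## Refinement

Refinement cross-optimizes species and reaction predictions. Per
iteration: every reaction with a nonempty prediction is paired against
its top-scoring mapped reference reaction(s) (score ties all
contribute); pairing fixes exact annotation matches first and pairs the
remainder greedily by descending cScore between the query species' name
and the reference participant's synonyms, breaking ties on
(element_id, term_id); each unmatched pair proposes adopting the paired
reference term. Where different reactions propose different terms for
one species, the accepted term is the one maximizing the summed top
rScore over all reactions containing that species, ties again
lexicographic. Accepted revisions replace the species' candidate set
with the single proposed term (scored at the proposing reaction's top
rScore and flagged `revised-by-reaction` so users can tell
reaction-derived from string-derived evidence), after which every
touched reaction is re-scored and re-selected. The loop stops at a fixed
point or after max_iter = 3 iterations — each pass is one
species→reaction→species round, and fixtures reach a fixed point in 1–2
passes. An accepted revision can never lower the proposing reaction's
score, since the revised coordinate is by construction present in the
mapped reference. The pairing heuristic, conflict rule and iteration cap
are this package's own concrete choices for a procedure whose published
description leaves them open; they are isolated in `refine` so they can
be swapped.

## Reference data and formats

Species tables are TSV (term_id, name, synonyms pipe-separated, formula
semicolon-separated); reaction tables map reaction_id to pipe-separated
participant term ids; a cross-reference TSV maps KEGG reaction ids and
EC numbers to reaction ids. Terms without a parsable formula are dropped
with a warning (the reaction space is built from formulas); a reaction
referencing an unknown term is a hard load error. Formula parsing
accepts element-symbol/count tokens plus one trailing charge token (a
sign optionally preceded by a single magnitude digit: "+", "2-"); the
charge is discarded, since hydrogen removal is precisely what absorbs
protonation differences. The digit-before-sign notation is inherently
ambiguous ("C2H3O2-" could be …O2 with charge 1- or …O with charge 2-;
it parses as charge "2-"), so charge-free spellings are preferred in
tables. Parenthesized groups and isotope notation are rejected rather
than guessed. Multiple formulas per term are allowed and all retained.
Conversion from official ChEBI/Rhea dumps is a matter of emitting these
TSVs; no live download is required or attempted, and ChEBI is-a
hierarchy information is not used.

SBML I/O is implemented over `lxml` and deliberately reads only ids,
display names, reactant/product lists and RDF CV-term annotations
(modifiers are not participants; math, units, rules and layout are
untouched and preserved on write). Written URIs use the modern
identifiers.org form; the reader additionally accepts the path-style and
legacy `urn:miriam` dialects. The default write mode is append —
silently destroying curator annotations would be unsafe — with
`replace` opt-in, which supersedes only the same namespace family
(ChEBI for species; Rhea/KEGG/EC for reactions). The qualifier defaults
to `bqbiol:is` and is configurable per record.

## Metrics

accuracy = min(1, |P ∩ E|) is a per-element indicator (did at least one
correct annotation make the set?); its corpus mean is the probability of
that event among nonempty predictions. exactness = 1/|P| penalizes
large recommendation lists. Both are undefined on empty sets, which is
why `nonempty` is a separate metric; recall/precision are not computed
(correlated numerators; precision undefined on empty sets). Corpus
averages pool elements across models rather than weighting per model.
Elements whose existing annotations cannot be resolved against the
reference database (or mapped through the cross-reference table, for
KEGG/EC reaction annotations) are excluded from evaluation rather than
counted as failures.

## Synthetic corpus

The generator emulates the structure the matcher relies on — terms with
synonym variants (suffix, pluralization, digit insertion), formulas over
a small element alphabet including hydrogen (about one term in twelve is
pure hydrogen so the "Hn → H" rule is exercised), reactions as random
participant subsets, and models whose display names are synonyms
perturbed by per-character substitution/deletion noise, with optional
participant dropout. Default condition: 50 terms, 1–3 synonyms of 4–10
characters, 20 reactions of 2–6 participants, noise 0, dropout 0.
Synonyms are rejection-sampled so no two terms share a character
multiset, making noiseless recovery exact by construction. All
randomness flows through one seeded `random.Random` using integer draws
only, so corpora are identical across platforms.

What the synthetic corpus does *not* emulate: real ChEBI synonym
statistics (shared synonyms between terms, multilingual or
punctuation-heavy names), Rhea reaction-size distributions, models whose
names are abbreviations or ids, and annotation errors in curated models.
Passing the recovery and monotonicity tests therefore demonstrates
correctness of the machinery, not field performance on BioModels/BiGG
scale corpora, which would require the full reference databases.

## Numerical choices

Cosines are computed in float64; scores within 1e-12 of 1 are snapped to
exactly 1.0 so that exact synonym matches survive a cutoff of 1.0, and
tiny negative rounding is clamped to 0. rScore is an exact ratio of
small integers. Synonym vectors are precomputed per database
(`strmatch.SynonymIndex`); results are bit-identical to the uncached
per-term computation, which the tests assert. Dot products use sparse
support-set intersection, equivalent to dense arithmetic on 0/1 vectors.

## Problem sizes

The test suite and the acceptance script run on the packaged fixture
(23 species terms, 6 reactions) and generated corpora of 25–50 terms and
10–50 reactions — small enough to cross-check every kernel against
brute-force oracles while exercising ties, formula collisions
(NAD+/NADH; water/hydroxide) and empty-prediction paths.
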