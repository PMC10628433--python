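# sbmlannot

Annotation recommendation for SBML models.

Most published biochemical models carry few or no machine-readable
annotations: their species and reactions are not linked to reference
ontologies such as ChEBI (small molecules) or Rhea (biochemical
reactions), which makes the models hard to search, compare, merge and
reuse. Annotating by hand is slow — a name like "glucose" matches around
a thousand ChEBI entries. `sbmlannot` is a recommender for this task: it
scores every unannotated species and reaction of an SBML model against a
reference database and proposes ranked candidate annotations for a
curator to review.

## Method

**Species (cScore).** A name is encoded as a count vector in a
36-dimensional space, one coordinate per letter a–z and numeral 0–9
("ATP" → 1 at a, t, p). The match score between a query species S_q with
name vector N_q and a reference term S_r with synonym vectors {N_jr} is
the maximal cosine

    cScore(S_q, S_r) = max_j (N_q · N_jr) / (‖N_q‖ ‖N_jr‖) ∈ [0, 1].

The encoding is deliberately lossy (anagrams coincide) but is robust to
short names, reorderings and length differences where alignment-style
scores are not.

**Reactions (rScore).** Participants are mapped to *simplified* chemical
formulas — all hydrogen removed, pure-hydrogen species kept as "H" — so
protonation variants coincide. A reaction becomes a binary vector R over
the space of simplified formulas (coordinate 1 iff some participant has
that formula; direction and stoichiometry are ignored). With M_q the
largest dot product of the query R_q against any reference reaction,
L_q the set of reference reactions achieving it, and
D = min { R_rj · R_rj : R_rj ∈ L_q },

    rScore(R_q, R_r) = (R_q · R_r) / D ∈ [0, 1].

D rescales but never reranks. Reaction prediction consumes the species
predictions: each participant contributes the formulas of its surviving
candidate terms to R_q.

**Selection.** An element filter rejects uninformative queries (species
names shorter than 3 characters; optionally reactions with few
participants). A match score selection criterion turns scores into the
prediction set: **top** keeps the candidates tied at the maximal score if
that score reaches the cutoff; **above** keeps everything at or above the
cutoff. An optional refinement pass pairs the participants of each
reaction with those of its best-matching ("mapped") reference reaction
and revises species annotations that disagree with their paired
reference participant, then re-scores the affected reactions, iterating
to a fixed point.

**Metrics.** Per element with prediction set P and expected set E:
nonempty = [P ≠ ∅]; accuracy = min(1, |P ∩ E|) and exactness = 1/|P|,
both defined only when P is nonempty; all averaged over a corpus.

## Worked example

The packaged reference fixture contains ~two dozen ChEBI-style terms and
six Rhea-style reactions, including the ATP-hydrolysis analogue
RHEA:13065 with participants ATP, H2O, ADP, H+ and phosphate. Build the
example model and ask for recommendations:

```sh
python -c "
from sbmlannot import synthgen
from sbmlannot.sbmlio import model_to_sbml
db, model = synthgen.paper_fixture()
model_to_sbml(model, 'example_model.xml')"
recommend-annotation example_model.xml --cutoff 0.35 --report rec.tsv --quiet
```

prints

```
Model file: example_model.xml
Number of species in model: 6
Number of species with recommended annotations: 6
Number of reactions in model: 2
Number of reactions with recommended annotations: 2
Recommendation report: rec.tsv
```

and the report contains, among others,

```
element_id  element_type  annotation_id  match_score  selected_by  existing_annotation
M_atp       species       CHEBI:30616    1.000000     top          no
R_hydro     reaction      RHEA:13065     0.400000     top          no
R_ACKr      reaction      RHEA:11352     0.800000     top          no
```

Reading the numbers: "ATP" matches the ATP term's synonym exactly
(cosine 1). The ATP→ADP query reaction shares 2 simplified formulas with
RHEA:13065; the smallest best-matching reference reaction has 5
participant formulas, so rScore = 2/5 = 0.4 — at a cutoff above 0.4 this
reaction would receive no recommendation. Applying the report writes the
annotations into the model as RDF CV terms (bqbiol:is, identifiers.org
URIs):

```sh
update-annotation example_model.xml rec.tsv --outfile annotated.xml
```

`recommend-species` and `recommend-reactions` restrict to one element
type; `--mssc above`, `--min-len`, `--min-participants`, `--optimize`
and `--mode replace` expose the remaining knobs.

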