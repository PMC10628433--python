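"""Prediction-quality metrics and corpus-level aggregation.

Per element, with prediction set P and expected (ground-truth) set E:

* ``nonempty``  — 1 if P is not empty, else 0;
* ``accuracy``  — min(1, |P ∩ E|): did at least one correct annotation
  make it into the prediction set? Defined only when P is nonempty;
* ``exactness`` — 1/|P|, the specificity of the recommendation. Defined
  only when P is nonempty.

Recall/precision are deliberately not used: they share a numerator (so
they are correlated), and precision is undefined on the empty prediction
sets this recommender intentionally produces. Corpus summaries average
each metric over its own denominator (all elements for nonempty, the
nonempty ones for accuracy/exactness), pooling elements across models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .predict import (PredictionParams, PredictionSet,
                      predict_reaction_annotations, predict_species_annotations)
from .refdb import CrossRefMap, ReferenceDatabase
from .sbmlio import ModelView
from .strmatch import SynonymIndex

logger = logging.getLogger(__name__)

__all__ = ["ElementEvaluation", "RepositorySummary", "evaluate_element",
           "summarize", "sweep", "strip_annotations"]


@dataclass(frozen=True)
class ElementEvaluation:
    nonempty: int
    accuracy: float | None
    exactness: float | None


@dataclass(frozen=True)
class RepositorySummary:
    n_elements: int
    n_nonempty: int
    mean_nonempty: float | None
    mean_accuracy: float | None
    mean_exactness: float | None


def evaluate_element(P: frozenset[str] | set[str], E: frozenset[str] | set[str]) -> ElementEvaluation:
    """Evaluate one prediction set against its expected set."""
    if not E:
        raise ValueError("expected set must be nonempty; filter such elements upstream")
    if not P:
        return ElementEvaluation(nonempty=0, accuracy=None, exactness=None)
    return ElementEvaluation(
        nonempty=1,
        accuracy=float(min(1, len(set(P) & set(E)))),
        exactness=1.0 / len(P),
    )


def summarize(evals: Sequence[ElementEvaluation]) -> RepositorySummary:
    """Pooled means; accuracy/exactness averaged over nonempty elements only."""
    n = len(evals)
    nonempty = [e for e in evals if e.nonempty]
    k = len(nonempty)
    return RepositorySummary(
        n_elements=n,
        n_nonempty=k,
        mean_nonempty=(k / n) if n else None,
        mean_accuracy=(sum(e.accuracy for e in nonempty) / k) if k else None,
        mean_exactness=(sum(e.exactness for e in nonempty) / k) if k else None,
    )


def _evaluate_preds(preds: Mapping[str, PredictionSet],
                    truth: Mapping[str, frozenset[str]]) -> list[ElementEvaluation]:
    return [
        evaluate_element(preds[el].annotation_ids, truth[el])
        for el in sorted(truth)
        if el in preds and truth[el]
    ]


def sweep(models: Sequence[ModelView] | ModelView, db: ReferenceDatabase,
          ground_truth: Mapping[str, Mapping[str, frozenset[str]]],
          cutoffs: Iterable[float],
          filters: Iterable[tuple[int, int]] = ((3, 0),),
          mssc: str = "top") -> pd.DataFrame:
    """Repository summaries over a grid of cutoffs and element filters.

    ``ground_truth`` has keys "species" and "reactions", each mapping
    element id -> expected annotation ids. ``filters`` is an iterable of
    (min_len, min_participants). Returns one row per
    (cutoff, filter, element type), pooling elements across models.
    """
    if isinstance(models, ModelView):
        models = [models]
    sp_truth = ground_truth.get("species", {})
    rx_truth = ground_truth.get("reactions", {})
    index = SynonymIndex(db)
    rows = []
    for min_len, min_participants in filters:
        for cutoff in cutoffs:
            params = PredictionParams(mssc=mssc, cutoff=cutoff, min_len=min_len,
                                      min_participants=min_participants)
            sp_evals: list[ElementEvaluation] = []
            rx_evals: list[ElementEvaluation] = []
            for model in models:
                sp_preds = predict_species_annotations(model, db, params, index=index)
                rx_preds = predict_reaction_annotations(model, db, sp_preds, params)
                sp_evals.extend(_evaluate_preds(sp_preds, sp_truth))
                rx_evals.extend(_evaluate_preds(rx_preds, rx_truth))
            for etype, evals in (("species", sp_evals), ("reaction", rx_evals)):
                s = summarize(evals)
                rows.append({
                    "cutoff": cutoff,
                    "filter_setting": f"min_len={min_len},min_participants={min_participants}",
                    "mssc": mssc, "element_type": etype,
                    "n_elements": s.n_elements, "n_nonempty": s.n_nonempty,
                    "mean_nonempty": s.mean_nonempty,
                    "mean_accuracy": s.mean_accuracy,
                    "mean_exactness": s.mean_exactness,
                })
    return pd.DataFrame(rows, columns=["cutoff", "filter_setting", "mssc", "element_type",
                                       "n_elements", "n_nonempty", "mean_nonempty",
                                       "mean_accuracy", "mean_exactness"])


def strip_annotations(model: ModelView, db: ReferenceDatabase | None = None,
                      crossref: CrossRefMap | None = None,
                      ) -> tuple[ModelView, dict[str, dict[str, frozenset[str]]]]:
    """Split a model into (annotation-free view, extracted ground truth).

    Species ground truth keeps ChEBI ids; reaction ground truth keeps Rhea
    ids directly and maps KEGG/EC ids through the cross-reference map when
    one is supplied. Elements whose annotations cannot be resolved (e.g.
    an EC number absent from the map, or a term missing from ``db``) are
    excluded from the ground truth with a warning — they are unscorable,
    not wrong.
    """
    sp_truth: dict[str, frozenset[str]] = {}
    for sp in model.species:
        ids = {a for a in sp.annotations if a.startswith("CHEBI:")}
        if db is not None:
            ids &= db.species.keys()
        if ids:
            sp_truth[sp.element_id] = frozenset(ids)
        elif sp.annotations:
            logger.warning("species %s: no resolvable annotation; excluded", sp.element_id)

    rx_truth: dict[str, frozenset[str]] = {}
    for rxn in model.reactions:
        ids: set[str] = set()
        for a in rxn.annotations:
            if a.startswith("RHEA:"):
                ids.add(a)
            elif crossref is not None:
                ids |= crossref.lookup(a)
        if db is not None:
            ids &= db.reactions.keys()
        if ids:
            rx_truth[rxn.element_id] = frozenset(ids)
        elif rxn.annotations:
            logger.warning("reaction %s: no resolvable annotation; excluded", rxn.element_id)

    stripped = ModelView(
        model_id=model.model_id,
        species=[replace(s, annotations=frozenset()) for s in model.species],
        reactions=[replace(r, annotations=frozenset()) for r in model.reactions],
    )
    return stripped, {"species": sp_truth, "reactions": rx_truth}
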