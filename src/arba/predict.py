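"""Model application and comparison of predicted vs. reference pathway labels.

A model fires on an entry when some clause's antecedent is a subset of the
entry's attribute items; the prediction's strength is taken from the best
(smallest-distance) firing clause, reported as score = 2 - distance so that
higher is better and any firing clause scores positively.

Predicted labels are compared to reference annotations hierarchically:
*identical* when the canonical strings match, *similar* when one label is a
more general/specific version of the other (level-list prefix, or same
levels with a step on only one side), *distinct* otherwise.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .ingest import Item, PathwayLabel, TransactionDB, parse_pathway_label
from .models import PredictionModel

__all__ = [
    "Prediction",
    "apply_models",
    "compare_labels",
    "compare_prediction_sets",
    "read_predictions_tsv",
    "write_predictions_tsv",
]


@dataclass(frozen=True)
class Prediction:
    """A predicted (protein, pathway) association with its clause score."""

    entry_id: str
    pathway: Item
    best_distance: float
    n_firing_clauses: int

    @property
    def score(self) -> float:
        """2 - best clause distance; in (0, 2] for any firing clause."""
        return 2.0 - self.best_distance


def apply_models(
    models: Sequence[PredictionModel], db: TransactionDB
) -> list[Prediction]:
    """Apply every model to every transaction (attribute items only).

    At most one prediction per (entry, pathway); ``best_distance`` is the
    minimum distance over firing clauses.  Transactions may lack pathway
    items entirely (application mode).
    """
    predictions: list[Prediction] = []
    for t in db.transactions:
        attrs = t.attributes
        for model in models:
            firing = [c for c in model.clauses if c.antecedent <= attrs]
            if firing:
                predictions.append(
                    Prediction(
                        t.entry_id,
                        model.consequent,
                        min(c.distance for c in firing),
                        len(firing),
                    )
                )
    return predictions


def compare_labels(p: PathwayLabel, r: PathwayLabel) -> str:
    """Classify two pathway labels as 'identical', 'similar' or 'distinct'.

    Identical: equal canonical strings.  Similar: one level list is a
    strict prefix of the other (ignoring steps), or the level lists are
    equal and exactly one label carries a step.  Distinct otherwise.
    """
    if p.render() == r.render():
        return "identical"
    lp, lr = p.levels, r.levels
    if lp == lr:
        has_p, has_r = p.step_index is not None, r.step_index is not None
        return "similar" if has_p != has_r else "distinct"
    shorter, longer = (lp, lr) if len(lp) < len(lr) else (lr, lp)
    if len(shorter) < len(longer) and longer[: len(shorter)] == shorter:
        return "similar"
    return "distinct"


def _label_of(pathway: Item | str) -> PathwayLabel:
    text = pathway.value if isinstance(pathway, Item) else pathway
    return parse_pathway_label(text)


def compare_prediction_sets(
    ours: Iterable[Prediction],
    theirs: Mapping[str, Iterable[Item | str]],
) -> dict[str, int]:
    """Classify our predictions against another system's annotations.

    Each prediction is compared to all of the other system's annotations
    for the same entry: counted as identical if any identical match exists,
    else similar if any similar match, else distinct.  Predictions for
    entries absent from ``theirs`` count as novel.
    """
    counts = {"identical": 0, "similar": 0, "distinct": 0, "novel": 0}
    theirs_parsed: dict[str, list[PathwayLabel]] = {
        entry: [_label_of(a) for a in annots] for entry, annots in theirs.items()
    }
    for pred in ours:
        if pred.entry_id not in theirs_parsed or not theirs_parsed[pred.entry_id]:
            counts["novel"] += 1
            continue
        ours_label = _label_of(pred.pathway)
        outcomes = {compare_labels(ours_label, lab) for lab in theirs_parsed[pred.entry_id]}
        if "identical" in outcomes:
            counts["identical"] += 1
        elif "similar" in outcomes:
            counts["similar"] += 1
        else:
            counts["distinct"] += 1
    return counts


def read_predictions_tsv(path: str | Path) -> list[Prediction]:
    predictions = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            predictions.append(
                Prediction(
                    row["accession"],
                    Item.from_canonical(row["pathway"]),
                    float(row["best_distance"]),
                    int(row["n_firing_clauses"]),
                )
            )
    return predictions


def write_predictions_tsv(predictions: Iterable[Prediction], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["accession", "pathway", "best_distance", "score", "n_firing_clauses"])
        for p in predictions:
            w.writerow(
                [p.entry_id, p.pathway.canonical, repr(p.best_distance), repr(p.score), p.n_firing_clauses]
            )
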