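"""Pair-level evaluation: confusion counting, P/R/F1/AUC, cross-validation.

Evaluation is at the (protein, pathway) pair level over a *reference set*
of pathways — those annotated in at least ``ref_min_count`` entries of the
full learning database.  For every protein and every reference pathway the
pair is a TP/FP/FN/TN according to whether the pathway was predicted and
whether it was annotated.  Robustness is estimated with a k-fold
cross-validation repeated for several runs with different random splits:
per run, fold-level confusion counts are averaged; across runs the report
gives the mean and a deviation of half the absolute run difference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import rankdata

from .ingest import Item, TransactionDB, reference_pathways
from .metrics import score_rules
from .mining import derive_rules, mine_frequent_antecedents
from .models import aggregate
from .predict import Prediction, apply_models
from .skyrule import select_representatives

__all__ = [
    "ConfusionMatrix",
    "EvaluationReport",
    "confusion_matrix",
    "precision",
    "recall",
    "f1",
    "auc",
    "truncate3",
    "cross_validate",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Pair-level counts; totals cover every (protein, reference-pathway) pair."""

    TP: int
    FP: int
    FN: int
    TN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.FN, self.TN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


def confusion_matrix(
    predictions: Iterable[Prediction] | Iterable[tuple[str, Item]],
    annotations: Mapping[str, Iterable[Item]],
    proteins: Sequence[str],
    reference: frozenset[Item] | set[Item],
) -> ConfusionMatrix:
    """Count TP/FP/FN/TN over all (protein, reference pathway) pairs.

    ``annotations`` maps each protein to its annotated pathway items
    (restricted internally to the reference set); predictions outside the
    reference set are ignored.
    """
    if not reference:
        raise ValueError("reference pathway set must be non-empty")
    reference = frozenset(reference)
    predicted: set[tuple[str, Item]] = set()
    for p in predictions:
        entry, pathway = (p.entry_id, p.pathway) if isinstance(p, Prediction) else p
        if pathway in reference:
            predicted.add((entry, pathway))
    tp = fp = fn = tn = 0
    for protein in proteins:
        annotated = frozenset(annotations.get(protein, ())) & reference
        for pathway in reference:
            is_pred = (protein, pathway) in predicted
            is_ann = pathway in annotated
            if is_pred and is_ann:
                tp += 1
            elif is_pred:
                fp += 1
            elif is_ann:
                fn += 1
            else:
                tn += 1
    return ConfusionMatrix(tp, fp, fn, tn)


def precision(cm) -> float:
    """TP/(TP+FP); 1.0 when no positive predictions were made (no errors)."""
    denom = cm.TP + cm.FP
    return cm.TP / denom if denom else 1.0


def recall(cm) -> float:
    """TP/(TP+FN); 1.0 when there are no annotated pairs to recover."""
    denom = cm.TP + cm.FN
    return cm.TP / denom if denom else 1.0


def f1(cm) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    p, r = precision(cm), recall(cm)
    return 2 * p * r / (p + r) if p + r else 0.0


def truncate3(x: float) -> float:
    """Truncate (not round) to three decimals, as in reported metric tables."""
    return math.floor(x * 1000) / 1000


def auc(scored_pairs: Sequence[tuple[float, bool]]) -> float:
    """Rank-based (Mann-Whitney) AUC with tie correction.

    Equals the trapezoidal area under the ROC curve; ties contribute half a
    concordant pair.  Raises on single-class input.
    """
    scores = np.asarray([s for s, _ in scored_pairs], dtype=float)
    labels = np.asarray([bool(l) for _, l in scored_pairs])
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: need at least one positive and one negative")
    ranks = rankdata(scores)
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------


def _mean(values: Sequence[float]) -> float:
    return float(sum(values) / len(values))


def _half_range(values: Sequence[float]) -> float:
    return (max(values) - min(values)) / 2.0


@dataclass
class EvaluationReport:
    """Per-fold, per-run and global cross-validation results.

    Fold-level confusion counts are integers; run-level cells are fold
    averages (possibly fractional); global cells are run means with a
    deviation of half the absolute difference between the runs.
    """

    params: dict
    n_reference_pathways: int
    fold_matrices: list[list[ConfusionMatrix]]
    fold_aucs: list[list[float | None]]
    run_matrices: list[dict[str, float]] = field(default_factory=list)
    run_metrics: list[dict[str, float | None]] = field(default_factory=list)
    global_matrix: dict[str, dict[str, float]] = field(default_factory=dict)
    global_metrics: dict[str, dict[str, float | None]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "params": self.params,
            "n_reference_pathways": self.n_reference_pathways,
            "folds": [
                [
                    {"TP": m.TP, "FP": m.FP, "FN": m.FN, "TN": m.TN, "auc": a}
                    for m, a in zip(run_ms, run_as)
                ]
                for run_ms, run_as in zip(self.fold_matrices, self.fold_aucs)
            ],
            "runs": [
                {"matrix": m, "metrics": met}
                for m, met in zip(self.run_matrices, self.run_metrics)
            ],
            "global": {"matrix": self.global_matrix, "metrics": self.global_metrics},
        }


@dataclass(frozen=True)
class _MatrixLike:
    TP: float
    FP: float
    FN: float
    TN: float


def cross_validate(
    db: TransactionDB,
    k: int = 5,
    runs: int = 2,
    seed: int = 0,
    min_support_abs: int = 20,
    min_conf: float = 1.0,
    max_antecedent: int = 4,
    ref_min_count: int = 20,
) -> EvaluationReport:
    """k-fold cross-validation of the full mine/select/aggregate/apply pipeline.

    Per run the transactions are randomly partitioned into k folds (sizes
    differing by at most one); each fold is predicted by models learned on
    the other k-1 folds and scored against the reference pathway set
    computed once on the full database.  Pairs with no firing clause score
    0 for the AUC.
    """
    if k < 2:
        raise ValueError("need at least 2 folds")
    if runs < 1:
        raise ValueError("need at least 1 run")
    if db.N < k:
        raise ValueError("database smaller than the number of folds")

    reference = reference_pathways(db, ref_min_count)
    if not reference:
        raise ValueError("reference pathway set is empty; lower ref_min_count")

    fold_matrices: list[list[ConfusionMatrix]] = []
    fold_aucs: list[list[float | None]] = []
    for run in range(runs):
        rng = np.random.default_rng((int(seed) * 1_000_003 + run) % (2**31))
        order = rng.permutation(db.N)
        folds = np.array_split(order, k)
        run_ms: list[ConfusionMatrix] = []
        run_as: list[float | None] = []
        for fold in folds:
            held = frozenset(int(i) for i in fold)
            train = TransactionDB(
                tuple(t for i, t in enumerate(db.transactions) if i not in held)
            )
            test = [db.transactions[i] for i in sorted(held)]
            frequent = mine_frequent_antecedents(train, min_support_abs, max_antecedent)
            rules = derive_rules(train, frequent, min_conf)
            score_rules(rules, train.N)
            models = aggregate(select_representatives(rules))
            test_db = TransactionDB(tuple(test))
            predictions = apply_models(models, test_db)
            annotations = {t.entry_id: t.targets & reference for t in test}
            proteins = [t.entry_id for t in test]
            run_ms.append(confusion_matrix(predictions, annotations, proteins, reference))
            # AUC over all held-out pairs; non-predicted pairs score 0
            pred_scores = {(p.entry_id, p.pathway): p.score for p in predictions}
            pairs = [
                (pred_scores.get((protein, pw), 0.0), pw in annotations[protein])
                for protein in proteins
                for pw in reference
            ]
            labels = {lab for _, lab in pairs}
            run_as.append(auc(pairs) if len(labels) == 2 else None)
        fold_matrices.append(run_ms)
        fold_aucs.append(run_as)

    report = EvaluationReport(
        params={
            "k": k,
            "runs": runs,
            "seed": int(seed),
            "min_support_abs": min_support_abs,
            "min_conf": min_conf,
            "max_antecedent": max_antecedent,
            "ref_min_count": ref_min_count,
        },
        n_reference_pathways=len(reference),
        fold_matrices=fold_matrices,
        fold_aucs=fold_aucs,
    )
    for run_ms, run_as in zip(fold_matrices, fold_aucs):
        avg = {
            name: _mean([getattr(m, name) for m in run_ms]) for name in ("TP", "FP", "FN", "TN")
        }
        report.run_matrices.append(avg)
        mat = _MatrixLike(**avg)
        aucs = [a for a in run_as if a is not None]
        report.run_metrics.append(
            {
                "precision": precision(mat),
                "recall": recall(mat),
                "f1": f1(mat),
                "auc": _mean(aucs) if aucs else None,
            }
        )
    for name in ("TP", "FP", "FN", "TN"):
        vals = [m[name] for m in report.run_matrices]
        report.global_matrix[name] = {"mean": _mean(vals), "deviation": _half_range(vals)}
    for name in ("precision", "recall", "f1", "auc"):
        vals = [m[name] for m in report.run_metrics if m[name] is not None]
        report.global_metrics[name] = (
            {"mean": _mean(vals), "deviation": _half_range(vals)} if vals else {"mean": None, "deviation": None}
        )
    return report
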