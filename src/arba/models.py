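"""Per-pathway prediction models: disjunctions of representative antecedents.

Representative rules sharing a consequent are aggregated into a single
model ``A OR B OR ... => pathway``: the model fires on a protein if any
clause's antecedent is contained in the protein's attribute items.  Models
are serialized to JSON (lossless, full float precision) and to a
human-readable block format::

    [PREDICT] PATHWAY:...
    [IF] [IPR:..., TAXON:...] support–confidence–lift_norm–p_norm → distance
    OR [IPR:...] ...
    [END]
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .ingest import Item, ParseError
from .metrics import MetricVector
from .mining import AssociationRule
from .skyrule import comparable

__all__ = [
    "Clause",
    "PredictionModel",
    "ModelValidationError",
    "aggregate",
    "render_human",
    "parse_human",
    "write_models",
    "read_models",
]


@dataclass(frozen=True)
class Clause:
    """One disjunct of a model: an antecedent with its quality metrics."""

    antecedent: frozenset[Item]
    metrics: MetricVector
    distance: float

    def __post_init__(self) -> None:
        if not self.antecedent:
            raise ValueError("clause antecedent must be non-empty")

    @property
    def sort_key(self) -> tuple[float, tuple[str, ...]]:
        return (self.distance, tuple(sorted(i.canonical for i in self.antecedent)))


@dataclass(frozen=True)
class PredictionModel:
    """One pathway consequent with clauses ordered by ascending distance."""

    consequent: Item
    clauses: tuple[Clause, ...]

    def __post_init__(self) -> None:
        if not self.clauses:
            raise ValueError("model must have at least one clause")


def aggregate(representatives: Sequence[AssociationRule]) -> list[PredictionModel]:
    """Group pairwise-incomparable representatives into per-pathway models.

    Each representative becomes one clause; clauses are ordered by
    ascending distance (ties on antecedent strings), models by consequent.
    A comparable pair in the input is a contract violation.
    """
    reps = list(representatives)
    for i, r1 in enumerate(reps):
        for r2 in reps[i + 1 :]:
            if comparable(r1, r2):
                raise ValueError(
                    f"representatives must be pairwise incomparable: {r1.key} vs {r2.key}"
                )
    by_consequent: dict[Item, list[AssociationRule]] = {}
    for r in reps:
        if r.metrics is None or r.distance is None:
            raise ValueError("representatives must carry normalized metrics")
        by_consequent.setdefault(r.consequent, []).append(r)
    models = []
    for consequent in sorted(by_consequent, key=lambda i: i.canonical):
        clauses = sorted(
            (Clause(r.antecedent, r.metrics, r.distance) for r in by_consequent[consequent]),
            key=lambda c: c.sort_key,
        )
        models.append(PredictionModel(consequent, tuple(clauses)))
    return models


# ---------------------------------------------------------------------------
# Human-readable rendering
# ---------------------------------------------------------------------------

_DASH = "–"  # en dash between metric components


def _render_clause(clause: Clause, first: bool) -> str:
    items = ", ".join(sorted(i.canonical for i in clause.antecedent))
    metrics = _DASH.join(repr(float(m)) for m in clause.metrics)
    prefix = "[IF]" if first else "OR"
    return f"{prefix} [{items}] {metrics} → {repr(float(clause.distance))}"


def render_human(model: PredictionModel) -> str:
    """Render one model as a [PREDICT]/[IF]/OR/[END] block."""
    lines = [f"[PREDICT] {model.consequent.canonical}"]
    lines.extend(_render_clause(c, i == 0) for i, c in enumerate(model.clauses))
    lines.append("[END]")
    return "\n".join(lines)


_CLAUSE_RE = re.compile(
    r"^(?:\[IF\]|OR)\s+\[(?P<items>[^\]]*)\]\s+(?P<metrics>\S+)\s+(?:→|->)\s+(?P<distance>\S+)\s*$"
)
# split metric components on en dash, or on hyphen not part of an exponent
_METRIC_SPLIT_RE = re.compile(r"–|(?<![eE])-")


def parse_human(text: str) -> list[PredictionModel]:
    """Parse the block format back into models (accepts en dash or hyphen)."""
    models: list[PredictionModel] = []
    consequent: Item | None = None
    clauses: list[Clause] = []
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("[PREDICT]"):
            if consequent is not None:
                raise ParseError(f"line {lineno}: nested [PREDICT] block")
            consequent = Item.from_canonical(line[len("[PREDICT]") :].strip())
            clauses = []
        elif line == "[END]":
            if consequent is None:
                raise ParseError(f"line {lineno}: [END] outside a block")
            models.append(PredictionModel(consequent, tuple(clauses)))
            consequent = None
        else:
            m = _CLAUSE_RE.match(line)
            if not m or consequent is None:
                raise ParseError(f"line {lineno}: cannot parse clause: {line!r}")
            items = frozenset(
                Item.from_canonical(tok.strip()) for tok in m.group("items").split(",") if tok.strip()
            )
            parts = _METRIC_SPLIT_RE.split(m.group("metrics"))
            if len(parts) != 4:
                raise ParseError(f"line {lineno}: expected 4 metric components")
            clauses.append(
                Clause(items, MetricVector(*(float(p) for p in parts)), float(m.group("distance")))
            )
    if consequent is not None:
        raise ParseError("unterminated [PREDICT] block")
    return models


# ---------------------------------------------------------------------------
# JSON serialization
# ---------------------------------------------------------------------------


class ModelValidationError(ValueError):
    """Model JSON failed validation; ``pointer`` locates the offending element."""

    def __init__(self, pointer: str, message: str):
        self.pointer = pointer
        super().__init__(f"{pointer}: {message}")


def _check(cond: bool, pointer: str, message: str) -> None:
    if not cond:
        raise ModelValidationError(pointer, message)


def _clause_to_json(c: Clause) -> dict:
    return {
        "antecedent": sorted(i.canonical for i in c.antecedent),
        "support": c.metrics.m_support,
        "confidence": c.metrics.m_confidence,
        "lift_norm": c.metrics.m_lift,
        "p_norm": c.metrics.m_p,
        "distance": c.distance,
    }


def write_models(
    models: Iterable[PredictionModel], path: str | Path, meta: dict | None = None
) -> None:
    """Write models to JSON; float round-tripping is lossless."""
    doc = {
        "models": [
            {
                "consequent": m.consequent.canonical,
                "clauses": [_clause_to_json(c) for c in m.clauses],
            }
            for m in models
        ],
        "meta": dict(meta or {}),
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


_CLAUSE_NUM_FIELDS = ("support", "confidence", "lift_norm", "p_norm", "distance")


def read_models(path: str | Path) -> list[PredictionModel]:
    """Read and validate a models JSON file.

    Structural violations raise :class:`ModelValidationError` with a JSON
    pointer to the offending element.
    """
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    _check(isinstance(doc, dict), "", "document must be an object")
    _check("models" in doc, "", "missing 'models' key")
    _check(isinstance(doc["models"], list), "/models", "'models' must be an array")
    models: list[PredictionModel] = []
    for i, mobj in enumerate(doc["models"]):
        mp = f"/models/{i}"
        _check(isinstance(mobj, dict), mp, "model must be an object")
        _check(isinstance(mobj.get("consequent"), str), f"{mp}/consequent", "missing or non-string consequent")
        _check(isinstance(mobj.get("clauses"), list) and mobj["clauses"], f"{mp}/clauses", "model needs a non-empty clause array")
        clauses = []
        for j, cobj in enumerate(mobj["clauses"]):
            cp = f"{mp}/clauses/{j}"
            _check(isinstance(cobj, dict), cp, "clause must be an object")
            ant = cobj.get("antecedent")
            _check(isinstance(ant, list) and ant and all(isinstance(s, str) for s in ant), f"{cp}/antecedent", "antecedent must be a non-empty string array")
            for name in _CLAUSE_NUM_FIELDS:
                _check(
                    isinstance(cobj.get(name), (int, float)) and not isinstance(cobj.get(name), bool),
                    f"{cp}/{name}",
                    f"missing or non-numeric '{name}'",
                )
            clauses.append(
                Clause(
                    frozenset(Item.from_canonical(s) for s in ant),
                    MetricVector(
                        float(cobj["support"]),
                        float(cobj["confidence"]),
                        float(cobj["lift_norm"]),
                        float(cobj["p_norm"]),
                    ),
                    float(cobj["distance"]),
                )
            )
        models.append(PredictionModel(Item.from_canonical(mobj["consequent"]), tuple(clauses)))
    return models
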