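"""Shared fixtures and helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from arba.ingest import Item, Transaction, TransactionDB
from arba.mining import AssociationRule
from arba.metrics import MetricVector


def make_rule(
    antecedent: set[str],
    consequent: str,
    metrics: tuple[float, float, float, float] | None = None,
    distance: float | None = None,
    support_abs: int = 20,
    N: int = 100,
    confidence: float = 1.0,
    lift: float = 1.0,
    p_value: float = 0.0,
) -> AssociationRule:
    """Construct a rule directly, for selection/aggregation tests."""
    rule = AssociationRule(
        antecedent=frozenset(Item.from_canonical(a) for a in antecedent),
        consequent=Item.from_canonical(consequent),
        support_abs=support_abs,
        support_rel=support_abs / N,
        confidence=confidence,
        lift=lift,
        p_value=p_value,
    )
    if metrics is not None:
        rule.metrics = MetricVector(*metrics)
    if distance is not None:
        rule.distance = distance
    return rule


def random_db(
    rng: np.random.Generator,
    n_txns: int,
    n_attrs: int = 8,
    n_pathways: int = 3,
    attr_rate: float = 0.35,
    pathway_rate: float = 0.5,
) -> TransactionDB:
    """A random transaction database over small attribute/pathway universes."""
    attrs = [Item("IPR", f"IPR{100000 + i}") for i in range(n_attrs)]
    pathways = [Item("PATHWAY", f"Pathway {chr(65 + i)}") for i in range(n_pathways)]
    txns = []
    for t in range(n_txns):
        items = {a for a in attrs if rng.random() < attr_rate}
        items |= {p for p in pathways if rng.random() < pathway_rate}
        txns.append(Transaction(f"T{t:04d}", frozenset(items)))
    return TransactionDB(tuple(txns))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20160708)
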