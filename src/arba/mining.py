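"""Class-association rule mining: frequent antecedents => single pathways.

This is a level-wise Apriori restricted to the class-association setting:
candidate itemsets are built only from attribute items (``TAXON:``/``IPR:``)
and every rule's consequent is a single ``PATHWAY:`` item.  Rule support is
*antecedent-based*: supp(rule) = supp(X), the number of transactions in
which the rule applies, rather than the classical supp(X u Y).  With the
default thresholds (absolute support 20, confidence 100%) only rules that
are always correct where applicable survive.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

from .ingest import Item, TransactionDB
from .metrics import ContingencyTable2x2, MetricVector, g_test_p_value

__all__ = [
    "FrequentItemset",
    "AssociationRule",
    "itemset_support",
    "mine_frequent_antecedents",
    "derive_rules",
    "write_rules_tsv",
]

_CONF_EPS = 1e-12  # guard against float round-off at exact thresholds


@dataclass(frozen=True)
class FrequentItemset:
    """An attribute itemset with absolute support >= the mining threshold."""

    items: frozenset[Item]
    support_abs: int


@dataclass
class AssociationRule:
    """A mined rule X => Y with raw and (optionally) normalized metrics.

    ``support_abs``/``support_rel`` follow the antecedent-based definition
    supp(X); ``metrics`` and ``distance`` are filled by
    :func:`arba.metrics.score_rules`.
    """

    antecedent: frozenset[Item]
    consequent: Item
    support_abs: int
    support_rel: float
    confidence: float
    lift: float
    p_value: float
    metrics: MetricVector | None = None
    distance: float | None = None

    @property
    def key(self) -> tuple[str, tuple[str, ...]]:
        """Identity: (consequent, sorted antecedent), all canonical strings."""
        return (self.consequent.canonical, tuple(sorted(i.canonical for i in self.antecedent)))


def itemset_support(db: TransactionDB, items: Iterable[Item]) -> int:
    """Number of transactions containing every item; the empty set gives N."""
    items = frozenset(items)
    return sum(1 for t in db.transactions if items <= t.items)


def _sort_key(items: frozenset[Item]) -> tuple[str, ...]:
    return tuple(sorted(i.canonical for i in items))


def mine_frequent_antecedents(
    db: TransactionDB,
    min_support_abs: int = 20,
    max_size: int = 4,
) -> list[FrequentItemset]:
    """All frequent attribute itemsets of size 1..max_size (level-wise Apriori).

    Candidates of size k are joined from frequent (k-1)-itemsets sharing a
    (k-2)-prefix and pruned by the antimonotonicity of support; output is
    deterministic — sorted by size, then lexicographically on canonical
    item strings.
    """
    if db.N == 0:
        raise ValueError("cannot mine an empty transaction database")
    if min_support_abs < 1:
        raise ValueError("min_support_abs must be >= 1")
    if max_size < 1:
        raise ValueError("max_size must be >= 1")

    attr_sets = [t.attributes for t in db.transactions]
    counts: Counter[Item] = Counter()
    for attrs in attr_sets:
        counts.update(attrs)

    result: list[FrequentItemset] = []
    current: dict[frozenset[Item], int] = {
        frozenset({i}): n for i, n in counts.items() if n >= min_support_abs
    }
    size = 1
    while current:
        result.extend(
            FrequentItemset(items, n)
            for items, n in sorted(current.items(), key=lambda kv: _sort_key(kv[0]))
        )
        if size == max_size:
            break
        # join step: frequent k-sets sharing a (k-1)-prefix in sorted order
        frequent_keys = set(current)
        sorted_sets = sorted((tuple(sorted(s, key=lambda i: i.canonical)) for s in current),)
        candidates: set[frozenset[Item]] = set()
        for a, b in combinations(sorted_sets, 2):
            if a[:-1] == b[:-1]:
                cand = frozenset(a) | frozenset(b)
                if all(
                    frozenset(sub) in frequent_keys
                    for sub in combinations(sorted(cand, key=lambda i: i.canonical), size)
                ):
                    candidates.add(cand)
        nxt: dict[frozenset[Item], int] = {}
        for cand in candidates:
            n = sum(1 for attrs in attr_sets if cand <= attrs)
            if n >= min_support_abs:
                nxt[cand] = n
        current = nxt
        size += 1
    return result


def derive_rules(
    db: TransactionDB,
    frequent: Sequence[FrequentItemset],
    min_conf: float = 1.0,
) -> list[AssociationRule]:
    """Emit X => Y rules for every frequent antecedent and co-occurring pathway.

    A rule is kept iff conf = supp(X u Y)/supp(X) >= min_conf.  Lift and the
    G-test p-value are computed from the 2x2 contingency table of X and Y.
    """
    if not 0.0 < min_conf <= 1.0:
        raise ValueError("min_conf must be in (0, 1]")
    N = db.N
    target_counts: Counter[Item] = Counter()
    for t in db.transactions:
        target_counts.update(t.targets)

    rules: list[AssociationRule] = []
    for fi in frequent:
        co: Counter[Item] = Counter()
        for t in db.transactions:
            if fi.items <= t.items:
                co.update(t.targets)
        for y, n_xy in co.items():
            conf = n_xy / fi.support_abs
            if conf + _CONF_EPS < min_conf:
                continue
            n_y = target_counts[y]
            table = ContingencyTable2x2.from_supports(n_xy, fi.support_abs, n_y, N)
            rules.append(
                AssociationRule(
                    antecedent=fi.items,
                    consequent=y,
                    support_abs=fi.support_abs,
                    support_rel=fi.support_abs / N,
                    confidence=conf,
                    lift=conf / (n_y / N),
                    p_value=g_test_p_value(table),
                )
            )
    rules.sort(key=lambda r: r.key)
    return rules


def write_rules_tsv(rules: Iterable[AssociationRule], path: str | Path) -> None:
    """Dump mined rules as TSV (one row per rule, canonical item strings)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(
            ["consequent", "antecedent", "support_abs", "support_rel", "confidence", "lift", "p_value"]
        )
        for r in rules:
            w.writerow(
                [
                    r.consequent.canonical,
                    ";".join(sorted(i.canonical for i in r.antecedent)),
                    r.support_abs,
                    repr(r.support_rel),
                    repr(r.confidence),
                    repr(r.lift),
                    repr(r.p_value),
                ]
            )
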