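"""Rule-quality metrics and the distance-to-ideal scoring used for selection.

Four interestingness measures are attached to every class-association rule
X => Y over a transaction database of size N:

* support   — supp(X)/N, the fraction of transactions where the rule applies
  (antecedent-based support);
* confidence — supp(X u Y)/supp(X), the rule's correctness rate;
* lift      — confidence divided by the consequent's baseline rate
  supp(Y)/N; 1 means the two sides are independent;
* p-value   — upper tail of the chi-square(1) distribution at the
  G-statistic (log-likelihood ratio test of independence on the 2x2
  contingency table of X and Y).

For selection the four measures are normalized into the unit hypercube as
(support, confidence, lift/N, 1 - p) and each rule is ranked by its
Euclidean distance to the ideal corner (1, 1, 1, 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

from scipy.special import xlogy
from scipy.stats import chi2

from .ingest import Item, TransactionDB

__all__ = [
    "MetricVector",
    "ContingencyTable2x2",
    "confidence",
    "lift",
    "g_test_p_value",
    "normalize",
    "ideal_distance",
    "score_rules",
]


class MetricVector(NamedTuple):
    """Normalized rule metrics, each component in [0, 1]; 1 is ideal."""

    m_support: float
    m_confidence: float
    m_lift: float
    m_p: float


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Joint occurrence counts of an antecedent X and a consequent Y.

    ``a``: X and Y, ``b``: X without Y, ``c``: Y without X, ``d``: neither.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @classmethod
    def from_supports(cls, n_xy: int, n_x: int, n_y: int, n: int) -> "ContingencyTable2x2":
        return cls(n_xy, n_x - n_xy, n_y - n_xy, n - n_x - n_y + n_xy)


def _support(db: TransactionDB, items: frozenset[Item] | set[Item]) -> int:
    items = frozenset(items)
    return sum(1 for t in db.transactions if items <= t.items)


def confidence(db: TransactionDB, X: frozenset[Item], Y: Item) -> float:
    """supp(X u Y) / supp(X); undefined (error) when supp(X) = 0."""
    n_x = _support(db, X)
    if n_x == 0:
        raise ValueError("confidence undefined: antecedent has zero support")
    return _support(db, frozenset(X) | {Y}) / n_x


def lift(db: TransactionDB, X: frozenset[Item], Y: Item) -> float:
    """conf(X => Y) / conf(empty => Y), the posterior/prior confidence ratio."""
    n_y = _support(db, {Y})
    if n_y == 0:
        raise ValueError("lift undefined: consequent has zero support")
    return confidence(db, X, Y) / (n_y / db.N)


def g_test_p_value(table: ContingencyTable2x2) -> float:
    """P-value of the G-test of independence on a 2x2 table.

    G = 2 * sum over cells of O * ln(O/E) with E the independence
    expectation (zero observed cells contribute nothing); under
    independence G is chi-square distributed with one degree of freedom.
    A zero row or column margin yields p = 1 (no evidence of association).
    """
    n = table.n
    if n <= 0:
        raise ValueError("empty contingency table")
    row1, row2 = table.a + table.b, table.c + table.d
    col1, col2 = table.a + table.c, table.b + table.d
    if 0 in (row1, row2, col1, col2):
        return 1.0
    g = 0.0
    for obs, rm, cm in (
        (table.a, row1, col1),
        (table.b, row1, col2),
        (table.c, row2, col1),
        (table.d, row2, col2),
    ):
        g += xlogy(obs, obs * n / (rm * cm))
    g = max(2.0 * g, 0.0)
    return float(chi2.sf(g, df=1))


def _clamp01(x: float) -> float:
    return min(1.0, max(0.0, x))


def normalize(rule, N: int) -> MetricVector:
    """Map a rule's raw metrics into the unit hypercube.

    Support and confidence are already ratios; lift is divided by N (its
    maximum over the database — for a confidence-1 rule this equals
    1/supp_abs(Y)); the p-value is flipped to 1 - p so that 1 is ideal.
    """
    return MetricVector(
        _clamp01(rule.support_rel),
        _clamp01(rule.confidence),
        _clamp01(rule.lift / N),
        _clamp01(1.0 - rule.p_value),
    )


def ideal_distance(m: MetricVector) -> float:
    """Euclidean distance from the normalized metrics to the ideal (1,1,1,1)."""
    return math.sqrt(sum((1.0 - mk) ** 2 for mk in m))


def score_rules(rules, N: int) -> None:
    """Fill in the normalized metric vector and distance of each rule in place."""
    for rule in rules:
        rule.metrics = normalize(rule, N)
        rule.distance = ideal_distance(rule.metrics)
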