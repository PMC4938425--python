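"""Skyline selection of representative rules via comparability and dominance.

Two rules are *comparable* when they predict the same pathway and their
antecedents overlap — they encode redundant knowledge, so only one of them
should survive.  Among comparable rules, dominance is the usual Pareto
order on the four normalized quality metrics.  Selection is iterative:
repeatedly pick the remaining rule closest to the ideal metric point (such
a rule is undominated within the candidate set) and discard every rule
comparable to it.  The survivors are pairwise incomparable representative
rules.
"""

from __future__ import annotations

import math
from typing import Sequence

from .mining import AssociationRule

__all__ = ["comparable", "dominates", "select_representatives", "selection_key"]


def comparable(r1: AssociationRule, r2: AssociationRule) -> bool:
    """True iff the consequents are equal and the antecedents intersect."""
    return r1.consequent == r2.consequent and bool(r1.antecedent & r2.antecedent)


def dominates(r1: AssociationRule, r2: AssociationRule) -> bool:
    """Pareto dominance on metric vectors: all >= with at least one strict."""
    m1, m2 = r1.metrics, r2.metrics
    if m1 is None or m2 is None:
        raise ValueError("rules must have normalized metrics before dominance checks")
    return all(a >= b for a, b in zip(m1, m2)) and any(a > b for a, b in zip(m1, m2))


def selection_key(rule: AssociationRule) -> tuple[float, str, tuple[str, ...]]:
    """Selection order: ascending distance, then lexicographic rule identity."""
    return (rule.distance, *rule.key)


def select_representatives(rules: Sequence[AssociationRule]) -> list[AssociationRule]:
    """Iteratively select undominated, pairwise-incomparable representatives.

    While candidates remain, the rule with minimal distance to the ideal
    point becomes a representative (ties broken lexicographically on the
    consequent and sorted antecedent for determinism) and every candidate
    comparable to it is removed.
    """
    seen = set()
    for r in rules:
        if r.distance is None or not math.isfinite(r.distance):
            raise ValueError("rules must have finite distances before selection")
        if r.key in seen:
            raise ValueError(f"duplicate rule in candidate set: {r.key}")
        seen.add(r.key)

    remaining = sorted(rules, key=selection_key)
    representatives: list[AssociationRule] = []
    while remaining:
        rep = remaining[0]
        representatives.append(rep)
        remaining = [r for r in remaining[1:] if not comparable(rep, r)]
    return representatives
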