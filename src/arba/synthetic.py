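"""Synthetic fixture generation with planted rule structure.

The generator emulates the statistical shape of an annotated prokaryotic
protein collection: every entry gets a taxonomic lineage sampled from a
small synthetic taxonomy tree; a configurable set of *planted rules* makes
a block of carrier entries share an attribute antecedent and (up to a
contamination fraction) a pathway annotation, so that mining at perfect
confidence recovers exactly the uncontaminated planted rules; remaining
entries carry only noise items from vocabularies disjoint from the planted
antecedents, so recovery assertions are exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
import numpy as np

from .ingest import (
    Item,
    PathwayAnnotation,
    ProteinEntry,
    parse_pathway_label,
)

__all__ = ["PlantedRule", "SyntheticSpec", "generate", "generate_worked_example", "default_planted"]


@dataclass(frozen=True)
class PlantedRule:
    """An antecedent -> pathway regularity planted into the fixture.

    ``contamination`` is the fraction of carrier entries *not* annotated
    with the pathway; at 0 the mined rule has confidence exactly 1.
    """

    antecedent: frozenset[Item]
    pathway: Item
    carrier_count: int
    contamination: float = 0.0

    def __post_init__(self) -> None:
        if self.carrier_count < 1:
            raise ValueError("carrier_count must be >= 1")
        if not 0.0 <= self.contamination < 1.0:
            raise ValueError("contamination must be in [0, 1)")
        if not self.antecedent:
            raise ValueError("planted antecedent must be non-empty")
        if any(i.is_target for i in self.antecedent):
            raise ValueError("planted antecedent must hold attribute items only")
        if not self.pathway.is_target:
            raise ValueError("planted pathway must be a PATHWAY item")

    @property
    def n_annotated(self) -> int:
        return math.ceil((1.0 - self.contamination) * self.carrier_count)


def default_planted() -> list[PlantedRule]:
    """Four noiseless planted rules of varying antecedent shape."""
    return [
        PlantedRule(
            frozenset({Item("IPR", "IPR900001")}),
            Item("PATHWAY", "Planted metabolism; alpha biosynthesis"),
            30,
        ),
        PlantedRule(
            frozenset({Item("IPR", "IPR900002"), Item("IPR", "IPR900003")}),
            Item("PATHWAY", "Planted metabolism; beta degradation; beta from gamma: step 1/2"),
            30,
        ),
        PlantedRule(
            frozenset({Item("IPR", "IPR900004"), Item("TAXON", "Plantedclade")}),
            Item("PATHWAY", "Planted metabolism; gamma salvage"),
            30,
        ),
        PlantedRule(
            frozenset({Item("IPR", "IPR900005")}),
            Item("PATHWAY", "Cofactor biosynthesis; delta biosynthesis"),
            30,
        ),
    ]


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic dataset."""

    n_entries: int = 200
    planted: list[PlantedRule] = field(default_factory=default_planted)
    n_noise_taxa: int = 10
    n_noise_ipr: int = 20
    noise_item_rate: float = 0.1
    multi_pathway_rate: float = 0.1
    lineage_depth: int = 6
    seed: int = 0

    @classmethod
    def from_dict(cls, data: dict) -> "SyntheticSpec":
        data = dict(data)
        planted = [
            PlantedRule(
                antecedent=frozenset(Item.from_canonical(s) for s in p["antecedent"]),
                pathway=Item.from_canonical(
                    p["pathway"] if p["pathway"].startswith("PATHWAY:") else "PATHWAY:" + p["pathway"]
                ),
                carrier_count=int(p["carrier_count"]),
                contamination=float(p.get("contamination", 0.0)),
            )
            for p in data.pop("planted", [])
        ]
        spec = cls(**data)
        if planted:
            spec.planted = planted
        return spec


def _validate(spec: SyntheticSpec) -> None:
    if spec.n_entries < 1:
        raise ValueError("n_entries must be >= 1")
    if sum(p.carrier_count for p in spec.planted) > spec.n_entries:
        raise ValueError("carrier counts exceed n_entries")
    for rate in (spec.noise_item_rate, spec.multi_pathway_rate):
        if not 0.0 <= rate <= 1.0:
            raise ValueError("rates must be in [0, 1]")
    if spec.lineage_depth < 0:
        raise ValueError("lineage_depth must be >= 0")
    ants = [p.antecedent for p in spec.planted]
    for i, a in enumerate(ants):
        for j, b in enumerate(ants):
            if i != j and a <= b:
                raise ValueError("planted antecedents must not be subsets of one another")
    planted_items = set().union(*ants) if ants else set()
    noise_names = {f"NoiseTaxon{i:02d}" for i in range(spec.n_noise_taxa)} | {
        f"IPR8{i:05d}" for i in range(spec.n_noise_ipr)
    }
    if {i.value for i in planted_items} & noise_names:
        raise ValueError("planted antecedent items collide with the noise vocabulary")
    if any(i.value.startswith("SynTaxon") for i in planted_items):
        raise ValueError("planted taxa collide with the synthetic taxonomy tree")


def _sample_lineage(rng: np.random.Generator, depth: int) -> tuple[str, ...]:
    """A root-to-node path in a binary synthetic taxonomy of the given depth."""
    if depth == 0:
        return ()
    lineage = ["SynTaxon1x0"]
    index = 0
    for level in range(2, depth + 1):
        index = index * 2 + int(rng.integers(0, 2))
        lineage.append(f"SynTaxon{level}x{index}")
    return tuple(lineage)


def generate(spec: SyntheticSpec) -> list[ProteinEntry]:
    """Generate ``spec.n_entries`` protein entries, deterministic in the seed.

    Each planted rule gets exactly ``carrier_count`` carrier entries bearing
    its full antecedent, of which ``ceil((1-contamination)*carrier_count)``
    are annotated with its pathway (experimental evidence); contaminated
    carriers are annotated with a decoy secondary pathway instead so that
    they survive learning-mode evidence filtering.  All other entries carry
    lineage plus independent noise items and never a full planted
    antecedent.
    """
    _validate(spec)
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(spec.n_entries)

    carrier_of: dict[int, PlantedRule] = {}
    annotated: set[int] = set()
    offset = 0
    for rule in spec.planted:
        block = [int(i) for i in order[offset : offset + rule.carrier_count]]
        offset += rule.carrier_count
        for idx in block:
            carrier_of[idx] = rule
        annotated.update(block[: rule.n_annotated])

    noise_taxa = [f"NoiseTaxon{i:02d}" for i in range(spec.n_noise_taxa)]
    noise_ipr = [f"IPR8{i:05d}" for i in range(spec.n_noise_ipr)]
    extra_pathways = [
        parse_pathway_label(f"Secondary metabolism; auxiliary pathway {i + 1}") for i in range(3)
    ]

    entries: list[ProteinEntry] = []
    for idx in range(spec.n_entries):
        lineage = list(_sample_lineage(rng, spec.lineage_depth))
        rule = carrier_of.get(idx)
        if rule is not None:
            interpro = frozenset(i.value for i in rule.antecedent if i.namespace == "IPR")
            lineage.extend(sorted(i.value for i in rule.antecedent if i.namespace == "TAXON"))
            pathways: list[PathwayAnnotation] = []
            if idx in annotated:
                pathways.append(
                    PathwayAnnotation(
                        parse_pathway_label(rule.pathway.value), frozenset({"ECO:0000269"})
                    )
                )
                if rng.random() < spec.multi_pathway_rate:
                    extra = extra_pathways[int(rng.integers(0, len(extra_pathways)))]
                    pathways.append(PathwayAnnotation(extra, frozenset({"ECO:0000250"})))
            else:
                # contaminated carriers get a decoy pathway instead, so they
                # survive learning-mode evidence filtering and depress the
                # planted rule's confidence to 1 - contamination
                extra = extra_pathways[int(rng.integers(0, len(extra_pathways)))]
                pathways.append(PathwayAnnotation(extra, frozenset({"ECO:0000250"})))
        else:
            interpro = frozenset(i for i in noise_ipr if rng.random() < spec.noise_item_rate)
            lineage.extend(t for t in noise_taxa if rng.random() < spec.noise_item_rate)
            pathways = []
        entries.append(
            ProteinEntry(f"SYN{idx:05d}", tuple(lineage), interpro, tuple(pathways))
        )
    return entries


def generate_worked_example() -> list[ProteinEntry]:
    """Two hand-checked fixture entries with known itemsets.

    A methanogenesis CO-dehydrogenase subunit from Methanosarcina (one
    pathway, seven signatures) and an E. coli acetylornithine/succinyl-
    diaminopimelate aminotransferase (two pathway annotations with steps).
    """
    eco = frozenset({"ECO:0000269"})
    q8trz4 = ProteinEntry(
        "Q8TRZ4",
        (
            "Archaea",
            "Euryarchaeota",
            "Methanomicrobia",
            "Methanosarcinales",
            "Methanosarcinaceae",
            "Methanosarcina",
        ),
        frozenset(
            {
                "IPR017896",
                "IPR017900",
                "IPR004460",
                "IPR004137",
                "IPR009051",
                "IPR011254",
                "IPR016099",
            }
        ),
        (
            PathwayAnnotation(
                parse_pathway_label("One-carbon metabolism; methanogenesis from acetate"), eco
            ),
        ),
    )
    p18335 = ProteinEntry(
        "P18335",
        (
            "Bacteria",
            "Proteobacteria",
            "Gammaproteobacteria",
            "Enterobacteriales",
            "Enterobacteriaceae",
            "Escherichia",
        ),
        frozenset(
            {"IPR017652", "IPR004636", "IPR005814", "IPR015424", "IPR015421", "IPR015422"}
        ),
        (
            PathwayAnnotation(
                parse_pathway_label(
                    "Amino-acid biosynthesis; L-arginine biosynthesis; "
                    "N(2)-acetyl-L-ornithine from L-glutamate: step 4/4"
                ),
                eco,
            ),
            PathwayAnnotation(
                parse_pathway_label(
                    "Amino-acid biosynthesis; L-lysine biosynthesis via DAP pathway; "
                    "LL-2, 6-diaminopimelate from (S)-tetrahydrodipicolinate "
                    "(succinylase route): step 2/3"
                ),
                eco,
            ),
        ),
    )
    return [q8trz4, p18335]
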