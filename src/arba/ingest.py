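"""Entry ingestion: pathway labels, evidence filtering, and transaction building.

A protein entry carries an accession, an ordered taxonomic lineage (most
general taxon first), a set of InterPro signature identifiers and zero or
more pathway annotations, each supported by ECO evidence codes.  For rule
mining every entry is flattened into a *transaction*: a set of namespaced
items where ``TAXON:`` and ``IPR:`` items are attributes and ``PATHWAY:``
items are the prediction targets.

Two input dialects are supported: a simple TSV format (the primary dialect)
and a subset of the UniProtKB flat text format (``AC``, ``OC``,
``DR InterPro`` and ``CC -!- PATHWAY`` lines), read through Biopython's
SwissProt parser.
"""

from __future__ import annotations

import csv
import re
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "MANUAL_ASSERTION_CODES",
    "PathwayLabel",
    "PathwayAnnotation",
    "ProteinEntry",
    "Item",
    "Transaction",
    "TransactionDB",
    "ParseError",
    "parse_pathway_label",
    "filter_by_evidence",
    "build_transactions",
    "reference_pathways",
    "read_entries_tsv",
    "write_entries_tsv",
    "read_entries_flatfile",
]

#: ECO codes accepted as manual assertion evidence for pathway annotations.
#: Experimental, non-traceable author statement, curator inference, sequence
#: similarity, sequence model and combinatorial evidence.
MANUAL_ASSERTION_CODES: frozenset[str] = frozenset(
    {
        "ECO:0000269",
        "ECO:0000303",
        "ECO:0000305",
        "ECO:0000250",
        "ECO:0000255",
        "ECO:0000244",
    }
)

_ECO_RE = re.compile(r"^ECO:[0-9]{7}$")
_IPR_RE = re.compile(r"^IPR[0-9]{6}$")
_STEP_RE = re.compile(r"^(?P<head>.*?):\s*step\s+(?P<i>[0-9]+)/(?P<n>[0-9]+)\s*$")


class ParseError(ValueError):
    """Raised when an input text cannot be parsed into a domain object."""


def _normalize_ws(text: str) -> str:
    """Trim ends and collapse internal whitespace runs to single spaces."""
    return re.sub(r"\s+", " ", text.strip())


# ---------------------------------------------------------------------------
# Pathway labels
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PathwayLabel:
    """Hierarchical pathway name: up to three levels plus an optional step.

    Levels run from super-pathway down to sub-pathway.  When the protein's
    position within the pathway is known, the label ends with
    ``: step i/n`` on its most specific level.
    """

    levels: tuple[str, ...]
    step_index: int | None = None
    step_total: int | None = None

    def __post_init__(self) -> None:
        if not 1 <= len(self.levels) <= 3:
            raise ParseError(f"pathway label must have 1-3 levels, got {len(self.levels)}")
        if any(not lv for lv in self.levels):
            raise ParseError("pathway label has an empty level")
        if (self.step_index is None) != (self.step_total is None):
            raise ParseError("step_index and step_total must be given together")
        if self.step_index is not None:
            assert self.step_total is not None
            if not 1 <= self.step_index <= self.step_total:
                raise ParseError(
                    f"invalid step {self.step_index}/{self.step_total}"
                )

    def render(self) -> str:
        """Canonical string form, e.g. ``A; B; C: step 1/5``."""
        text = "; ".join(self.levels)
        if self.step_index is not None:
            text += f": step {self.step_index}/{self.step_total}"
        return text

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()


def parse_pathway_label(text: str) -> PathwayLabel:
    """Parse a pathway string into its hierarchy levels and optional step.

    ``"Amino-acid biosynthesis; L-tryptophan biosynthesis; L-tryptophan from
    chorismate: step 1/5"`` yields three levels with step 1 of 5.  Raises
    :class:`ParseError` for empty text, more than three levels or a
    malformed step suffix.
    """
    if text is None or not text.strip():
        raise ParseError("empty pathway label")
    segments = [_normalize_ws(seg) for seg in text.split(";")]
    if any(not seg for seg in segments):
        raise ParseError(f"pathway label has an empty level: {text!r}")
    if len(segments) > 3:
        raise ParseError(f"pathway label has more than 3 levels: {text!r}")
    step_index = step_total = None
    last = segments[-1]
    m = _STEP_RE.match(last)
    if m:
        segments[-1] = _normalize_ws(m.group("head"))
        if not segments[-1]:
            raise ParseError(f"pathway label has an empty level: {text!r}")
        step_index, step_total = int(m.group("i")), int(m.group("n"))
        if not 1 <= step_index <= step_total:
            raise ParseError(f"malformed step suffix in {text!r}")
    elif re.search(r":\s*step\b", last):
        raise ParseError(f"malformed step suffix in {text!r}")
    return PathwayLabel(tuple(segments), step_index, step_total)


# ---------------------------------------------------------------------------
# Entries
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PathwayAnnotation:
    """A pathway label together with its supporting ECO evidence codes.

    The evidence set may be empty only for unannotated application-mode
    input (entries to be predicted, not learned from).
    """

    label: PathwayLabel
    evidence: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        bad = [e for e in self.evidence if not _ECO_RE.match(e)]
        if bad:
            raise ParseError(f"invalid ECO code(s): {bad}")


@dataclass(frozen=True)
class ProteinEntry:
    """One annotated protein: accession, lineage, signatures, pathways."""

    accession: str
    lineage: tuple[str, ...] = ()
    interpro_ids: frozenset[str] = frozenset()
    pathways: tuple[PathwayAnnotation, ...] = ()

    def __post_init__(self) -> None:
        if not self.accession:
            raise ParseError("entry accession must be non-empty")
        bad = [i for i in self.interpro_ids if not _IPR_RE.match(i)]
        if bad:
            raise ParseError(f"invalid InterPro id(s) for {self.accession}: {bad}")


def filter_by_evidence(
    entries: Iterable[ProteinEntry],
    allowed: frozenset[str] | set[str] = MANUAL_ASSERTION_CODES,
) -> list[ProteinEntry]:
    """Keep only manually asserted pathway annotations (learning mode).

    Each pathway annotation survives iff its evidence set intersects
    ``allowed``; entries left without any pathway annotation are dropped
    entirely, since they contribute nothing to learning.
    """
    allowed = frozenset(allowed)
    kept: list[ProteinEntry] = []
    for entry in entries:
        pws = tuple(p for p in entry.pathways if p.evidence & allowed)
        if pws:
            if len(pws) == len(entry.pathways):
                kept.append(entry)
            else:
                kept.append(
                    ProteinEntry(entry.accession, entry.lineage, entry.interpro_ids, pws)
                )
    return kept


# ---------------------------------------------------------------------------
# Items and transactions
# ---------------------------------------------------------------------------

_NAMESPACES = ("PATHWAY", "TAXON", "IPR")


@dataclass(frozen=True, order=True)
class Item:
    """A namespaced item; equality and ordering are on the canonical form."""

    namespace: str
    value: str

    def __post_init__(self) -> None:
        if self.namespace not in _NAMESPACES:
            raise ParseError(f"unknown item namespace: {self.namespace!r}")
        if not self.value:
            raise ParseError("item value must be non-empty")

    @property
    def canonical(self) -> str:
        return f"{self.namespace}:{self.value}"

    @classmethod
    def from_canonical(cls, text: str) -> "Item":
        ns, sep, value = text.partition(":")
        if not sep:
            raise ParseError(f"item missing namespace separator: {text!r}")
        return cls(ns, value)

    @property
    def is_target(self) -> bool:
        return self.namespace == "PATHWAY"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.canonical


@dataclass(frozen=True)
class Transaction:
    """The itemset derived from one protein entry."""

    entry_id: str
    items: frozenset[Item]

    @property
    def attributes(self) -> frozenset[Item]:
        return frozenset(i for i in self.items if not i.is_target)

    @property
    def targets(self) -> frozenset[Item]:
        return frozenset(i for i in self.items if i.is_target)


@dataclass(frozen=True)
class TransactionDB:
    """An ordered collection of transactions; ``N`` is its size."""

    transactions: tuple[Transaction, ...]

    @property
    def N(self) -> int:
        return len(self.transactions)


def build_transactions(entries: Sequence[ProteinEntry]) -> TransactionDB:
    """Flatten entries into namespaced itemsets, one transaction per entry.

    Every lineage node becomes a ``TAXON:`` item, every signature an
    ``IPR:`` item and every pathway annotation a ``PATHWAY:`` item carrying
    the full canonical pathway string including any step suffix.
    """
    dup = [acc for acc, n in Counter(e.accession for e in entries).items() if n > 1]
    if dup:
        raise ParseError(f"duplicate accession(s): {sorted(dup)}")
    txns = []
    for e in entries:
        items = {Item("TAXON", _normalize_ws(t)) for t in e.lineage if t.strip()}
        items |= {Item("IPR", i) for i in e.interpro_ids}
        items |= {Item("PATHWAY", p.label.render()) for p in e.pathways}
        txns.append(Transaction(e.accession, frozenset(items)))
    return TransactionDB(tuple(txns))


def reference_pathways(db: TransactionDB, min_count: int = 20) -> frozenset[Item]:
    """Pathway items present in at least ``min_count`` transactions.

    This set defines the evaluation universe: only pathways with a minimal
    amount of annotation support are scored during cross-validation.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    counts: Counter[Item] = Counter()
    for t in db.transactions:
        counts.update(t.targets)
    return frozenset(i for i, n in counts.items() if n >= min_count)


# ---------------------------------------------------------------------------
# TSV dialect
# ---------------------------------------------------------------------------

_TSV_COLUMNS = ("accession", "lineage", "interpro", "pathways")
_PW_RECORD_RE = re.compile(r"^(?P<label>.*?)(?:\{(?P<eco>[^{}]*)\})?\s*$")


def _format_pathway_record(p: PathwayAnnotation) -> str:
    text = p.label.render()
    if p.evidence:
        text += "{" + ";".join(sorted(p.evidence)) + "}"
    return text


def _parse_pathway_record(text: str) -> PathwayAnnotation:
    m = _PW_RECORD_RE.match(text.strip())
    assert m is not None
    label = parse_pathway_label(m.group("label"))
    eco = m.group("eco")
    evidence = frozenset(e.strip() for e in eco.split(";") if e.strip()) if eco else frozenset()
    return PathwayAnnotation(label, evidence)


def write_entries_tsv(entries: Iterable[ProteinEntry], path: str | Path) -> None:
    """Write entries in the TSV dialect (header row, tab separated)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_TSV_COLUMNS)
        for e in entries:
            w.writerow(
                [
                    e.accession,
                    ";".join(e.lineage),
                    ";".join(sorted(e.interpro_ids)),
                    "|".join(_format_pathway_record(p) for p in e.pathways),
                ]
            )


def read_entries_tsv(path: str | Path) -> list[ProteinEntry]:
    """Read entries from the TSV dialect written by :func:`write_entries_tsv`."""
    entries: list[ProteinEntry] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(_TSV_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise ParseError(f"entries TSV missing column(s): {sorted(missing)}")
        for row in reader:
            lineage = tuple(
                _normalize_ws(t) for t in (row["lineage"] or "").split(";") if t.strip()
            )
            ipr = frozenset(i.strip() for i in (row["interpro"] or "").split(";") if i.strip())
            pathways = tuple(
                _parse_pathway_record(rec)
                for rec in (row["pathways"] or "").split("|")
                if rec.strip()
            )
            entries.append(ProteinEntry(row["accession"].strip(), lineage, ipr, pathways))
    return entries


# ---------------------------------------------------------------------------
# UniProtKB flat-file subset
# ---------------------------------------------------------------------------

_ECO_TOKEN_RE = re.compile(r"ECO:[0-9]{7}")


def _split_pathway_comment(comment: str) -> list[tuple[str, frozenset[str]]]:
    """Split one CC PATHWAY comment into (label text, evidence) records.

    A block may hold several records separated on ``. PATHWAY:`` boundaries;
    each record may end with an evidence group ``{ECO:...|source, ...}``
    whose source cross-references (after ``|``) are ignored.
    """
    body = comment
    if body.startswith("PATHWAY:"):
        body = body[len("PATHWAY:") :]
    records = re.split(r"\.\s+PATHWAY:\s*", body)
    out = []
    for rec in records:
        rec = rec.strip()
        if not rec:
            continue
        evidence: frozenset[str] = frozenset()
        m = re.search(r"\{([^{}]*)\}\.?\s*$", rec)
        if m:
            evidence = frozenset(_ECO_TOKEN_RE.findall(m.group(1)))
            rec = rec[: m.start()].strip()
        rec = rec.rstrip(".").strip()
        if rec:
            out.append((rec, evidence))
    return out


def read_entries_flatfile(path: str | Path) -> list[ProteinEntry]:
    """Read a subset of the UniProtKB flat text format.

    Only the ``AC`` (first accession), ``OC`` (taxonomic lineage),
    ``DR InterPro`` and ``CC -!- PATHWAY`` content is used; everything else
    in the record is ignored.
    """
    from Bio import SwissProt

    entries: list[ProteinEntry] = []
    with open(path, encoding="utf-8") as fh:
        for rec in SwissProt.parse(fh):
            if not rec.accessions:
                raise ParseError("flat-file record without an AC line")
            lineage = tuple(_normalize_ws(t) for t in rec.organism_classification)
            ipr = frozenset(
                xref[1] for xref in rec.cross_references if xref and xref[0] == "InterPro"
            )
            pathways = []
            for comment in rec.comments:
                if not comment.startswith("PATHWAY"):
                    continue
                for text, evidence in _split_pathway_comment(comment):
                    pathways.append(PathwayAnnotation(parse_pathway_label(text), evidence))
            entries.append(
                ProteinEntry(rec.accessions[0], lineage, ipr, tuple(pathways))
            )
    return entries
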