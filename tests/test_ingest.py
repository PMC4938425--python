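"""Ingestion: pathway label parsing, evidence filtering, transaction building."""

from __future__ import annotations

import pytest
from hypothesis import given, settings, strategies as st

from arba.ingest import (
    MANUAL_ASSERTION_CODES,
    Item,
    ParseError,
    PathwayAnnotation,
    PathwayLabel,
    ProteinEntry,
    build_transactions,
    filter_by_evidence,
    parse_pathway_label,
    read_entries_flatfile,
    read_entries_tsv,
    reference_pathways,
    write_entries_tsv,
)
from arba.synthetic import SyntheticSpec, generate, generate_worked_example


class TestParsePathwayLabel:
    @pytest.mark.parametrize(
        "text,levels,step",
        [
            (
                "Amino-acid biosynthesis; L-tryptophan biosynthesis; "
                "L-tryptophan from chorismate: step 1/5",
                (
                    "Amino-acid biosynthesis",
                    "L-tryptophan biosynthesis",
                    "L-tryptophan from chorismate",
                ),
                (1, 5),
            ),
            (
                "One-carbon metabolism; methanogenesis from acetate",
                ("One-carbon metabolism", "methanogenesis from acetate"),
                None,
            ),
            ("X", ("X",), None),
        ],
    )
    def test_examples(self, text, levels, step):
        label = parse_pathway_label(text)
        assert label.levels == levels
        if step is None:
            assert label.step_index is None and label.step_total is None
        else:
            assert (label.step_index, label.step_total) == step

    @pytest.mark.parametrize(
        "bad",
        ["", "   ", "a; b; c; d", "A: step 0/5", "A: step 6/5", "A; ; B", "A: step x/y"],
    )
    def test_errors_name_offending_text(self, bad):
        with pytest.raises(ParseError):
            parse_pathway_label(bad)

    def test_whitespace_normalization(self):
        label = parse_pathway_label("  Amino-acid   biosynthesis ;  L-lysine  biosynthesis ")
        assert label.levels == ("Amino-acid biosynthesis", "L-lysine biosynthesis")

    @settings(deadline=None, max_examples=80, derandomize=True)
    @given(
        levels=st.lists(
            st.text(
                alphabet=st.characters(whitelist_categories=("Lu", "Ll", "Nd"), whitelist_characters=" -()"),
                min_size=1,
                max_size=20,
            ).map(lambda s: " ".join(s.split())).filter(bool),
            min_size=1,
            max_size=3,
        ),
        step=st.one_of(st.none(), st.tuples(st.integers(1, 9), st.integers(1, 9))),
    )
    def test_canonical_round_trip(self, levels, step):
        """render(parse(s)) is canonical: parsing its own rendering is a fixed point."""
        if step is not None and step[0] > step[1]:
            step = (step[1], step[0])
        label = PathwayLabel(tuple(levels), *(step or (None, None)))
        rendered = label.render()
        reparsed = parse_pathway_label(rendered)
        assert reparsed.render() == rendered


def _entry(acc, pathways):
    return ProteinEntry(acc, ("Bacteria",), frozenset({"IPR000001"}), tuple(pathways))


def _ann(text, *eco):
    return PathwayAnnotation(parse_pathway_label(text), frozenset(eco))


class TestEvidenceFilter:
    def test_manual_assertion_retained(self):
        e = _entry("A1", [_ann("P one", "ECO:0000269")])
        assert filter_by_evidence([e]) == [e]

    def test_non_manual_entry_removed(self):
        e = _entry("A1", [_ann("P one", "ECO:0000501")])
        assert filter_by_evidence([e]) == []

    def test_per_annotation_filtering(self):
        e = _entry("A1", [_ann("P one", "ECO:0000250"), _ann("P two", "ECO:0000501")])
        (kept,) = filter_by_evidence([e])
        assert [p.label.render() for p in kept.pathways] == ["P one"]

    def test_six_manual_codes(self):
        assert len(MANUAL_ASSERTION_CODES) == 6
        for code in MANUAL_ASSERTION_CODES:
            assert filter_by_evidence([_entry("A1", [_ann("P", code)])])

    def test_count_preserved_minus_dropped(self, rng):
        entries = generate(SyntheticSpec(seed=1))
        kept = filter_by_evidence(entries)
        db = build_transactions(kept)
        assert db.N == len(kept) <= len(entries)


class TestBuildTransactions:
    def test_worked_example_itemsets(self):
        db = build_transactions(generate_worked_example())
        by_id = {t.entry_id: t for t in db.transactions}
        q = by_id["Q8TRZ4"]
        assert len(q.items) == 14  # 6 taxa + 7 signatures + 1 pathway
        assert Item("PATHWAY", "One-carbon metabolism; methanogenesis from acetate") in q.items
        assert Item("TAXON", "Methanosarcina") in q.items
        assert Item("IPR", "IPR016099") in q.items
        p = by_id["P18335"]
        assert len(p.targets) == 2
        assert len(p.items) == 14  # 6 taxa + 6 signatures + 2 pathways

    def test_entry_without_signatures(self):
        e = ProteinEntry("A1", ("Bacteria",), frozenset(), (_ann("P one", "ECO:0000269"),))
        db = build_transactions([e])
        assert {i.namespace for i in db.transactions[0].items} == {"TAXON", "PATHWAY"}

    def test_duplicate_accession_rejected(self):
        e = _entry("A1", [_ann("P", "ECO:0000269")])
        with pytest.raises(ParseError, match="A1"):
            build_transactions([e, e])

    def test_item_canonical_round_trip(self):
        db = build_transactions(generate_worked_example())
        for t in db.transactions:
            for item in t.items:
                assert Item.from_canonical(item.canonical) == item


class TestReferencePathways:
    def _db_with_counts(self, counts):
        entries = []
        n = 0
        for pathway, count in counts.items():
            for _ in range(count):
                entries.append(_entry(f"E{n}", [_ann(pathway, "ECO:0000269")]))
                n += 1
        return build_transactions(entries)

    def test_at_least_boundary(self):
        db = self._db_with_counts({"P twenty": 20, "P nineteen": 19})
        ref = reference_pathways(db, 20)
        assert ref == {Item("PATHWAY", "P twenty")}

    def test_matches_brute_force_on_synthetic_db(self):
        entries = filter_by_evidence(generate(SyntheticSpec(n_entries=200, seed=42)))
        db = build_transactions(entries)
        for min_count in (1, 5, 20, 40):
            expected = set()
            for t in db.transactions:
                for item in t.targets:
                    if sum(1 for u in db.transactions if item in u.items) >= min_count:
                        expected.add(item)
            assert reference_pathways(db, min_count) == expected

    def test_monotone_in_min_count(self):
        entries = filter_by_evidence(generate(SyntheticSpec(seed=7)))
        db = build_transactions(entries)
        sets = [reference_pathways(db, m) for m in (1, 10, 20, 30, 50)]
        for bigger, smaller in zip(sets, sets[1:]):
            assert smaller <= bigger

    def test_min_count_must_be_positive(self):
        db = self._db_with_counts({"P": 1})
        with pytest.raises(ValueError):
            reference_pathways(db, 0)


class TestTsvDialect:
    def test_round_trip(self, tmp_path):
        entries = generate_worked_example() + [
            ProteinEntry("NOATTR", (), frozenset(), (_ann("P one", "ECO:0000269"),)),
            ProteinEntry("UNANN", ("Bacteria",), frozenset({"IPR000100"}), ()),
        ]
        path = tmp_path / "entries.tsv"
        write_entries_tsv(entries, path)
        assert read_entries_tsv(path) == entries

    def test_evidence_braces_optional(self, tmp_path):
        path = tmp_path / "entries.tsv"
        path.write_text(
            "accession\tlineage\tinterpro\tpathways\n"
            "A1\tBacteria;Escherichia\tIPR000001\tSome pathway; some sub\n",
            encoding="utf-8",
        )
        (entry,) = read_entries_tsv(path)
        assert entry.pathways[0].evidence == frozenset()
        assert entry.pathways[0].label.levels == ("Some pathway", "some sub")

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("accession\tlineage\nA1\tBacteria\n", encoding="utf-8")
        with pytest.raises(ParseError, match="interpro"):
            read_entries_tsv(path)


FLATFILE = """\
ID   TEST1_METAC             Reviewed;         100 AA.
AC   Q8TRZ4; Q9XYZ1;
OC   Archaea; Euryarchaeota; Methanomicrobia; Methanosarcinales;
OC   Methanosarcinaceae; Methanosarcina.
DR   InterPro; IPR017896; 4Fe4S_Fe-S-bd.
DR   InterPro; IPR004460; CdhD.
DR   Pfam; PF03599; CdhD.
CC   -!- FUNCTION: Part of the ACDS complex.
CC   -!- PATHWAY: One-carbon metabolism; methanogenesis from acetate.
CC       {ECO:0000269|PubMed:11823864, ECO:0000305}.
SQ   SEQUENCE   10 AA;  1000 MW;  0000000000ABCDEF CRC64;
     MKLVINLAAA
//
ID   TEST2_ECOLI             Reviewed;         100 AA.
AC   P18335;
OC   Bacteria; Proteobacteria; Gammaproteobacteria; Enterobacteriales;
OC   Enterobacteriaceae; Escherichia.
DR   InterPro; IPR017652; Ac/SucOrn_transaminase_bac.
CC   -!- PATHWAY: Amino-acid biosynthesis; L-arginine biosynthesis;
CC       N(2)-acetyl-L-ornithine from L-glutamate: step 4/4. PATHWAY:
CC       Amino-acid biosynthesis; L-lysine biosynthesis via DAP pathway;
CC       LL-2, 6-diaminopimelate from (S)-tetrahydrodipicolinate
CC       (succinylase route): step 2/3. {ECO:0000250}.
SQ   SEQUENCE   10 AA;  1000 MW;  0000000000ABCDEF CRC64;
     MKLVINLAAA
//
"""


class TestFlatFileSubset:
    def test_parses_ac_oc_dr_cc(self, tmp_path):
        path = tmp_path / "test.dat"
        path.write_text(FLATFILE, encoding="utf-8")
        first, second = read_entries_flatfile(path)
        assert first.accession == "Q8TRZ4"
        assert first.lineage[0] == "Archaea" and first.lineage[-1] == "Methanosarcina"
        assert first.interpro_ids == {"IPR017896", "IPR004460"}
        (pw,) = first.pathways
        assert pw.label.render() == "One-carbon metabolism; methanogenesis from acetate"
        assert pw.evidence == {"ECO:0000269", "ECO:0000305"}

    def test_multi_record_pathway_block(self, tmp_path):
        path = tmp_path / "test.dat"
        path.write_text(FLATFILE, encoding="utf-8")
        _, second = read_entries_flatfile(path)
        labels = [p.label.render() for p in second.pathways]
        assert labels == [
            "Amino-acid biosynthesis; L-arginine biosynthesis; "
            "N(2)-acetyl-L-ornithine from L-glutamate: step 4/4",
            "Amino-acid biosynthesis; L-lysine biosynthesis via DAP pathway; "
            "LL-2, 6-diaminopimelate from (S)-tetrahydrodipicolinate "
            "(succinylase route): step 2/3",
        ]
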