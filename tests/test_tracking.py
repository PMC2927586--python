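"""Funnel arithmetic, expression consistency and PO analytics."""

import pytest

from promoterforge.fixtures import funnel_records, load_funnel_fixture, load_table1_fixture, po_vocabulary
from promoterforge.tracking import (
    CONSISTENT_MULTI,
    FUNNEL_STAGES,
    INCONSISTENT,
    NO_EXPRESSION,
    SINGLE_EXPRESSING_OF_MANY,
    SINGLE_LINE_EXPRESSING,
    AnnotationStore,
    POAnnotation,
    PipelineRecord,
    TransgenicLine,
    classify_consistency,
    records_from_counts,
    stage_counts,
    success_rate,
    summarize_po,
)


def _line(line_id, gene="g1", dip="d1", codes=(), stage="rosette"):
    obs = {stage: set(codes)} if codes else {}
    return TransgenicLine(line_id=line_id, gene_id=gene, dip_event=dip, observations=obs)


class TestFunnel:
    def test_records_from_counts_monotone(self):
        records = funnel_records()
        counts = stage_counts(records)
        assert counts == load_funnel_fixture()
        ordered = [counts[s] for s in FUNNEL_STAGES]
        assert ordered == sorted(ordered, reverse=True)

    def test_success_rates_on_study_funnel(self):
        records = funnel_records()
        assert success_rate(records, "primer_designed", "entry_clone") == 74.8
        assert success_rate(records, "dipped", "transgenic_positive") == 75.4
        assert success_rate(records, "entry_clone", "expression_clone") == 94.2
        assert success_rate(records, "expression_clone", "agro_clone") == 79.9

    def test_success_rate_identity_and_zero_denominator(self):
        records = funnel_records()
        assert success_rate(records, "dipped", "dipped") == 100.0
        none_reached = [PipelineRecord("g", furthest_stage="primer_designed")]
        with pytest.raises(ZeroDivisionError):
            success_rate(none_reached, "gfp_positive", "gfp_positive")

    def test_half_up_rounding(self):
        # 15/40 = 37.5 exactly at the rounding boundary -> 37.5; 1/3 -> 33.3
        records = records_from_counts(
            {"primer_designed": 40, "entry_clone": 15}
        )
        assert success_rate(records, "primer_designed", "entry_clone") == 37.5
        records = records_from_counts({"primer_designed": 3, "entry_clone": 1})
        assert success_rate(records, "primer_designed", "entry_clone") == 33.3

    def test_counts_must_be_nested(self):
        with pytest.raises(ValueError):
            records_from_counts({"primer_designed": 5, "entry_clone": 7})


class TestConsistency:
    def test_two_agreeing_lines_dominate_a_silent_one(self):
        lines = [
            _line("l1", dip="d1", codes={"PO:0000036"}),
            _line("l2", dip="d1", codes={"PO:0000036"}),
            _line("l3", dip="d2"),
        ]
        result = classify_consistency(lines)
        assert result.category == CONSISTENT_MULTI
        assert not result.independent_dip_consistent  # same dip event

    def test_independent_dips_raise_confidence(self):
        lines = [
            _line("l1", dip="d1", codes={"PO:0000036"}),
            _line("l2", dip="d2", codes={"PO:0000036"}),
        ]
        assert classify_consistency(lines) == (CONSISTENT_MULTI, True)

    def test_disagreeing_patterns_are_inconsistent(self):
        lines = [
            _line("l1", codes={"PO:0000036"}),
            _line("l2", codes={"PO:0009005"}),
        ]
        assert classify_consistency(lines).category == INCONSISTENT

    def test_single_line_and_single_expressing(self):
        assert classify_consistency([_line("l1", codes={"PO:0009005"})]).category == SINGLE_LINE_EXPRESSING
        lines = [_line("l1", codes={"PO:0009005"}), _line("l2")]
        assert classify_consistency(lines).category == SINGLE_EXPRESSING_OF_MANY
        assert classify_consistency([_line("l1"), _line("l2")]).category == NO_EXPRESSION

    def test_pattern_is_union_over_stages(self):
        l1 = TransgenicLine("l1", "g1", "d1", observations={
            "plate_day10": {"PO:0009005"}, "flowering": {"PO:0000036"}})
        l2 = TransgenicLine("l2", "g1", "d2", observations={
            "rosette": {"PO:0009005", "PO:0000036"}})
        assert classify_consistency([l1, l2]) == (CONSISTENT_MULTI, True)

    def test_relaxed_mode_accepts_overlap(self):
        lines = [
            _line("l1", codes={"PO:0000036", "PO:0009005"}),
            _line("l2", codes={"PO:0009005"}),
        ]
        assert classify_consistency(lines).category == INCONSISTENT
        assert classify_consistency(lines, relaxed=True).category == CONSISTENT_MULTI

    def test_categories_partition(self):
        """Every gene with >=1 line lands in exactly one category."""
        cases = {
            "a": [_line("a1", gene="a", codes={"PO:0009005"})],
            "b": [_line("b1", gene="b"), _line("b2", gene="b")],
            "c": [_line("c1", gene="c", codes={"PO:0009005"}),
                  _line("c2", gene="c", dip="d2", codes={"PO:0009005"})],
        }
        cats = [classify_consistency(v).category for v in cases.values()]
        assert len(cats) == len(cases)


class TestPOAnalytics:
    def test_table1_fixture_shape(self):
        summary = load_table1_fixture()
        assert summary.n_distinct_codes == 81
        assert summary.most_frequent == ("PO:0000036", 38)
        by_code = {r.po_code: r for r in summary.rows}
        assert by_code["PO:0005660"].po_name == "hydathode"
        assert by_code["PO:0005660"].n_promoters == 35
        assert by_code["PO:0009005"] == ("PO:0009005", "root", 37)
        assert by_code["PO:0009073"] == ("PO:0009073", "stigma", 1)

    def test_summarize_counts_distinct_genes_once(self):
        vocab = po_vocabulary()
        anns = [
            POAnnotation("i1", "l1", "g1", frozenset({"PO:0009005"}), "rosette"),
            POAnnotation("i2", "l1", "g1", frozenset({"PO:0009005"}), "flowering"),
            POAnnotation("i3", "l2", "g2", frozenset({"PO:0009005", "PO:0000036"}), "rosette"),
        ]
        summary = summarize_po(anns, vocab)
        assert summary.n_distinct_codes == 2
        rows = {r.po_code: r.n_promoters for r in summary.rows}
        assert rows == {"PO:0009005": 2, "PO:0000036": 1}
        # order invariance and idempotence
        assert summarize_po(reversed(anns), vocab) == summary
        # most-frequent ties break to the lexicographically smallest code
        anns.append(POAnnotation("i4", "l3", "g3", frozenset({"PO:0000036"}), "rosette"))
        assert summarize_po(anns, vocab).most_frequent == ("PO:0000036", 2)

    def test_empty_summary(self):
        summary = summarize_po([])
        assert summary.n_distinct_codes == 0 and summary.most_frequent is None

    def test_invalid_po_code_rejected_at_load(self):
        with pytest.raises(ValueError, match="invalid PO code"):
            POAnnotation("i1", "l1", "g1", frozenset({"PO:1"}), "rosette")
        with pytest.raises(ValueError, match="not in vocabulary"):
            summarize_po(
                [POAnnotation("i1", "l1", "g1", frozenset({"PO:9999999"}), "rosette")],
                po_vocabulary(),
            )


class TestStore:
    @pytest.fixture()
    def store(self):
        store = AnnotationStore()
        store.load_vocabulary(load_table1_fixture().rows)
        store.add_annotations([
            POAnnotation("i1", "l1", "g1", frozenset({"PO:0005660"}), "rosette"),
            POAnnotation("i2", "l2", "g2", frozenset({"PO:0009005"}), "flowering"),
        ])
        return store

    def test_query_by_tissue_substring(self, store):
        result = store.query("tissue", "hydathode")
        assert result.summary_rows == [("PO:0005660", "hydathode", 35)]
        assert [a.gene_id for a in result.annotations] == ["g1"]

    def test_query_by_code_and_gene(self, store):
        assert store.query("po_code", "PO:0009005").annotations[0].image_id == "i2"
        assert store.query("po_code", "PO:0009073").annotations == []
        assert [a.image_id for a in store.query("gene_id", "g1").annotations] == ["i1"]

    def test_unknown_query_key(self, store):
        with pytest.raises(ValueError, match="unknown query key"):
            store.query("locus", "g1")

    def test_annotation_round_trip(self, store, tmp_path):
        path = tmp_path / "annotations.tsv"
        store.export_annotations(str(path))
        fresh = AnnotationStore()
        fresh.load_vocabulary(load_table1_fixture().rows)
        fresh.import_annotations(str(path))
        assert fresh.query("gene_id", "g2").annotations == store.query("gene_id", "g2").annotations
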