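"""Indication filter scope, benchmark overlap arithmetic, output files."""

import random

import pytest

from labelminer._util import pct_half_up
from labelminer.aggregate import (
    NER_INDICATION_SECTION,
    NLP_INDICATION,
    NLP_PRECONDITION,
    DrugADRPair,
    DrugRecord,
    IndicationRecord,
    collect_indications,
    compute_overlap,
    filter_adr_pairs,
    render_pairs_tsv,
    write_outputs,
)
from labelminer.frequency import FrequencyRecord
from labelminer.lexicon import Concept, build_lexicon
from labelminer.ner import Mention
from labelminer.relations import ExtractedRelation

from conftest import make_doc


def registry_two_labels():
    d = DrugRecord("CIDm1", "CIDs1", ["Drugone"], ["L1", "L2"])
    return {"L1": d, "L2": d}


def mention(label, cid, section="adverse_reactions", start=0, end=5, suppressed=False):
    m = Mention(label, section, 0, start, end, "x" * (end - start), cid)
    if suppressed:
        m.suppress("hedged_sentence")
    return m


def table_freq(label, cid, lo=0.1, hi=0.1):
    return FrequencyRecord(cid, "drug", lo, hi, f"{int(lo*100)}%", "table", label, "table:0")


LEX = build_lexicon(
    [
        Concept("C1", "alpha syndrome", ["alpha syndrome"], ["sign_or_symptom"], "10000001"),
        Concept("C2", "beta syndrome", ["beta syndrome"], ["sign_or_symptom"], "10000002"),
    ],
    ["sign_or_symptom"],
)


class TestCollectIndications:
    def test_nlp_relation_becomes_record(self):
        rel = ExtractedRelation("indication", "CIDm1", "C1", "r", "L1", "indications", 0)
        (rec,) = collect_indications([rel], [], registry_two_labels())
        assert rec == IndicationRecord("CIDm1", "C1", NLP_INDICATION, "L1")

    def test_precondition_relation_method(self):
        rel = ExtractedRelation("precondition", None, "C1", "r", "L2", "adverse_reactions", 3)
        (rec,) = collect_indications([rel], [], registry_two_labels())
        assert rec.method == NLP_PRECONDITION

    def test_combination_relations_ignored(self):
        rel = ExtractedRelation("combination", "CIDm2", None, "r", "L1", "indications", 0)
        assert collect_indications([rel], [], registry_two_labels()) == []

    def test_indications_section_mention_becomes_record(self):
        m = mention("L1", "C2", section="indications")
        (rec,) = collect_indications([], [m], registry_two_labels())
        assert rec.method == NER_INDICATION_SECTION

    def test_suppressed_mention_excluded(self):
        m = mention("L1", "C2", section="indications", suppressed=True)
        assert collect_indications([], [m], registry_two_labels()) == []

    def test_empty_corpus(self):
        assert collect_indications([], [], registry_two_labels()) == []

    def test_orphan_label_is_error(self):
        m = mention("L9", "C1", section="indications")
        with pytest.raises(KeyError, match="L9"):
            collect_indications([], [m], registry_two_labels())

    def test_deduplicated_per_drug_concept_method_label(self):
        ms = [mention("L1", "C1", section="indications", start=i * 10, end=i * 10 + 5)
              for i in range(3)]
        assert len(collect_indications([], ms, registry_two_labels())) == 1


class TestFilterScope:
    """The three scope scenarios of the indication-based ADR filter."""

    def test_same_label_ner_indication_discards_free_text(self):
        reg = registry_two_labels()
        ind = [IndicationRecord("CIDm1", "C1", NER_INDICATION_SECTION, "L1")]
        m = mention("L1", "C1")
        pairs = filter_adr_pairs([m], [], ind, reg, LEX)
        assert pairs == []
        assert m.suppressed and m.suppression_reason == "indication_filter"

    def test_sibling_label_ner_indication_keeps_free_text(self):
        reg = registry_two_labels()
        ind = [IndicationRecord("CIDm1", "C1", NER_INDICATION_SECTION, "L2")]
        m = mention("L1", "C1")
        pairs = filter_adr_pairs([m], [], ind, reg, LEX)
        assert [(p.flat_id, p.concept_id) for p in pairs] == [("CIDm1", "C1")]
        assert not m.suppressed

    def test_nlp_indication_discards_across_labels(self):
        reg = registry_two_labels()
        for method in (NLP_INDICATION, NLP_PRECONDITION):
            ind = [IndicationRecord("CIDm1", "C1", method, "L2")]
            m = mention("L1", "C1")
            assert filter_adr_pairs([m], [], ind, reg, LEX) == []

    def test_table_evidence_exempt_from_filter(self):
        reg = registry_two_labels()
        ind = [
            IndicationRecord("CIDm1", "C1", NER_INDICATION_SECTION, "L1"),
            IndicationRecord("CIDm1", "C1", NLP_INDICATION, "L1"),
        ]
        fr = table_freq("L1", "C1")
        pairs = filter_adr_pairs([], [fr], ind, reg, LEX)
        assert [(p.flat_id, p.concept_id) for p in pairs] == [("CIDm1", "C1")]
        assert pairs[0].frequency_records == [fr]

    def test_text_frequency_dropped_with_filtered_mention(self):
        reg = registry_two_labels()
        ind = [IndicationRecord("CIDm1", "C1", NER_INDICATION_SECTION, "L1")]
        m = mention("L1", "C1")
        text_fr = FrequencyRecord("C1", "drug", 0.12, 0.12, "12%", "text", "L1", "sentence:0")
        assert filter_adr_pairs([m], [text_fr], ind, reg, LEX) == []

    def test_filter_monotonicity_under_added_indications(self):
        rng = random.Random(5)
        reg = registry_two_labels()
        concepts = [f"C{i}" for i in range(1, 3)]
        for _ in range(20):
            ms = [
                mention(rng.choice(["L1", "L2"]), rng.choice(concepts),
                        start=i * 10, end=i * 10 + 5)
                for i in range(rng.randint(1, 4))
            ]
            frs = [table_freq("L1", rng.choice(concepts))] if rng.random() < 0.5 else []
            inds = [
                IndicationRecord("CIDm1", rng.choice(concepts),
                                 rng.choice([NLP_INDICATION, NER_INDICATION_SECTION]),
                                 rng.choice(["L1", "L2"]))
                for _ in range(rng.randint(0, 2))
            ]
            import copy

            base = len(filter_adr_pairs(copy.deepcopy(ms), frs, inds, reg, LEX))
            extra = inds + [
                IndicationRecord("CIDm1", rng.choice(concepts),
                                 rng.choice([NLP_INDICATION, NER_INDICATION_SECTION]),
                                 rng.choice(["L1", "L2"]))
            ]
            more = len(filter_adr_pairs(copy.deepcopy(ms), frs, extra, reg, LEX))
            assert more <= base

    def test_pair_merges_evidence_across_labels(self):
        reg = registry_two_labels()
        ms = [mention("L1", "C1"), mention("L2", "C1", start=30, end=35)]
        fr = table_freq("L2", "C1")
        (pair,) = filter_adr_pairs(ms, [fr], [], reg, LEX)
        assert {lab for lab, _ in pair.provenance} == {"L1", "L2"}
        assert pair.meddra_code == "10000001"
        assert pair.term == "alpha syndrome"


class TestComputeOverlap:
    def test_identical_sets(self):
        pairs = {("d1", "c1"), ("d2", "c2")}
        stats = compute_overlap(pairs, set(pairs))
        assert stats.pct_rel_a == stats.pct_rel_b == 100
        assert stats.only_a == stats.only_b == 0
        assert stats.intersection == 2

    def test_disjoint_over_common_identifiers(self):
        a = {("d1", "c1"), ("d2", "c2")}
        b = {("d1", "c2"), ("d2", "c1")}
        stats = compute_overlap(a, b)
        assert stats.intersection == 0
        assert stats.pct_rel_a == 0 and stats.pct_rel_b == 0

    def test_restriction_to_common_drugs_and_concepts(self):
        a = {("d1", "c1"), ("d1", "c2"), ("d2", "c1"), ("d3", "c9")}
        b = {("d1", "c1"), ("d2", "c2"), ("d2", "c5"), ("d4", "c2")}
        stats = compute_overlap(a, b)
        assert (stats.common_drugs, stats.common_concepts) == (2, 2)
        assert (stats.only_a, stats.intersection, stats.only_b) == (2, 1, 1)
        assert stats.pct_rel_a == 33 and stats.pct_rel_b == 50
        assert stats.matched == 3 and stats.total_a == 4

    def test_overlap_identities_and_symmetry(self):
        rng = random.Random(9)
        for _ in range(20):
            a = {(f"d{rng.randint(0,5)}", f"c{rng.randint(0,5)}") for _ in range(rng.randint(0, 15))}
            b = {(f"d{rng.randint(0,5)}", f"c{rng.randint(0,5)}") for _ in range(rng.randint(0, 15))}
            ab = compute_overlap(a, b)
            ba = compute_overlap(b, a)
            assert ab.only_a + ab.intersection == ab.matched
            assert ab.only_a == ba.only_b and ab.only_b == ba.only_a
            assert ab.pct_rel_a == ba.pct_rel_b and ab.pct_rel_b == ba.pct_rel_a

    def test_empty_identifier_intersection_gives_blank_percentages(self):
        stats = compute_overlap({("d1", "c1")}, {("d2", "c2")})
        assert stats.intersection == 0
        assert stats.pct_rel_a is None and stats.pct_rel_b is None

    @pytest.mark.parametrize(
        "intersection,only,expected",
        [
            (1010, 655, 61),   # indications by NLP, relative to extracted
            (499, 434, 53),    # preconditions, relative to extracted
            (1685, 2111, 44),  # indications by NER, relative to extracted
            (1010, 1328, 43),  # indications by NLP, relative to reference
            (499, 1020, 33),   # preconditions, relative to reference
            (1685, 1034, 62),  # indications by NER, relative to reference
        ],
    )
    def test_benchmark_percentages_from_printed_counts(self, intersection, only, expected):
        assert pct_half_up(intersection, intersection + only) == expected


class TestWriteOutputs:
    def setup_corpus(self):
        reg = registry_two_labels()
        doc = make_doc(
            "L1",
            [
                ("h", "ADVERSE REACTIONS"),
                ("p", "alpha syndrome occurred. beta syndrome has not been observed."),
            ],
        )
        m1 = Mention("L1", "adverse_reactions", 0, 18, 32, "alpha syndrome", "C1")
        text = doc.text
        s = text.index("beta syndrome")
        m2 = Mention("L1", "adverse_reactions", 1, s, s + 13, "beta syndrome", "C2")
        m2.suppress("hedged_sentence")
        pairs = filter_adr_pairs([m1, m2], [table_freq("L1", "C1")], [], reg, LEX)
        return reg, doc, [m1, m2], pairs

    def test_outputs_are_byte_identical_across_runs(self, tmp_path):
        reg, doc, mentions, pairs = self.setup_corpus()
        for d in ("run1", "run2"):
            write_outputs(pairs, [], {"L1": doc}, mentions, tmp_path / d, LEX)
        for name in ["pairs.tsv", "indications.tsv", "html/L1.html"]:
            assert (tmp_path / "run1" / name).read_bytes() == (
                tmp_path / "run2" / name
            ).read_bytes()

    def test_suppressed_mention_in_html_not_in_pairs(self, tmp_path):
        reg, doc, mentions, pairs = self.setup_corpus()
        write_outputs(pairs, [], {"L1": doc}, mentions, tmp_path, LEX)
        html = (tmp_path / "html" / "L1.html").read_text()
        assert 'data-reason="hedged_sentence"' in html
        assert 'data-concept="C2"' in html
        pairs_tsv = (tmp_path / "pairs.tsv").read_text()
        assert "C2" not in pairs_tsv
        assert "C1" in pairs_tsv

    def test_empty_corpus_writes_header_only_tsvs(self, tmp_path):
        write_outputs([], [], {}, [], tmp_path, LEX)
        assert (tmp_path / "pairs.tsv").read_text().count("\n") == 1
        assert (tmp_path / "indications.tsv").read_text().count("\n") == 1
        assert not (tmp_path / "html").exists()

    def test_dangling_concept_reference_is_error(self, tmp_path):
        pair = DrugADRPair("CIDm1", "C999", None, "ghost")
        with pytest.raises(ValueError, match="dangling"):
            write_outputs([pair], [], {}, [], tmp_path, LEX)
        assert not (tmp_path / "pairs.tsv").exists()

    def test_pairs_tsv_row_per_frequency_record(self):
        reg = registry_two_labels()
        pairs = filter_adr_pairs(
            [mention("L1", "C1"), mention("L1", "C2", start=20, end=25)],
            [table_freq("L1", "C1"), table_freq("L1", "C2", 0.05, 0.05)],
            [],
            reg,
            LEX,
        )
        tsv = render_pairs_tsv(pairs)
        lines = tsv.strip().split("\n")
        assert len(lines) == 3  # header + one frequency row per concept
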