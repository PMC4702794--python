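"""Entity masking and dependency-triple rule matching."""

import itertools
import random

import pytest

from labelminer.ner import Mention
from labelminer.relations import (
    DEFAULT_RULES_TEXT,
    DependencyTriple,
    MaskedSentence,
    collapse_prepositions,
    extract_relations,
    lemma,
    load_rules,
    mask_entities,
    parse_rules,
    unmask,
)

RULES = load_rules()


def worked_triples():
    """The seven dependency triples for
    'DRUG may be used for the treatment of INDICATION'."""
    return [
        DependencyTriple("nsubjpass", ("used", 4), ("DRUG", 1)),
        DependencyTriple("aux", ("used", 4), ("may", 2)),
        DependencyTriple("auxpass", ("used", 4), ("be", 3)),
        DependencyTriple("root", ("ROOT", 0), ("used", 4)),
        DependencyTriple("det", ("treatment", 7), ("the", 6)),
        DependencyTriple("prep_for", ("used", 4), ("treatment", 7)),
        DependencyTriple("prep_of", ("treatment", 7), ("INDICATION", 9)),
    ]


def worked_masked():
    return MaskedSentence.from_tokens(
        ["DRUG", "may", "be", "used", "for", "the", "treatment", "of", "INDICATION"],
        {"DRUG": "drug", "INDICATION": "condition"},
    )


def precondition_triples():
    """'In patients with COND1, COND2 may occur' (collapsed dialect)."""
    return [
        DependencyTriple("root", ("ROOT", 0), ("occur", 8)),
        DependencyTriple("prep_in", ("occur", 8), ("patients", 2)),
        DependencyTriple("prep_with", ("patients", 2), ("COND1", 4)),
        DependencyTriple("nsubj", ("occur", 8), ("COND2", 6)),
        DependencyTriple("aux", ("occur", 8), ("may", 7)),
    ]


def precondition_masked():
    return MaskedSentence.from_tokens(
        ["In", "patients", "with", "COND1", ",", "COND2", "may", "occur", "."],
        {"COND1": "condition", "COND2": "condition"},
    )


# --- independent oracle ------------------------------------------------------

def oracle_extract(triples, masked, rules, label_drug=None):
    """Brute force: enumerate all injective assignments of a rule's slot
    names to token indices and keep those satisfying every template."""

    def slot_ok(slot, word, index):
        if slot.kind == "free":
            return True
        if slot.kind == "lex":
            return lemma(word) in slot.lemmas
        cls = masked.entity_class_at(index)
        if cls == slot.entity_class:
            return True
        return (
            slot.entity_class == "drug"
            and label_drug is not None
            and word.casefold() == label_drug.casefold()
        )

    results = set()
    indices = range(0, len(masked.tokens) + 1)
    for rule in rules:
        names = []
        for t in rule.pattern:
            for slot in (t.governor, t.dependent):
                if slot.name not in names:
                    names.append(slot.name)
        for combo in itertools.permutations(indices, len(names)):
            binding = dict(zip(names, combo))
            if all(
                any(
                    template.relation_matches(tr.relation)
                    and tr.governor[1] == binding[template.governor.name]
                    and tr.dependent[1] == binding[template.dependent.name]
                    and slot_ok(template.governor, *tr.governor)
                    and slot_ok(template.dependent, *tr.dependent)
                    for tr in triples
                )
                for template in rule.pattern
            ):
                args = []
                for var in rule.produce_args:
                    idx = binding[var]
                    args.append(masked.tokens[idx - 1] if 1 <= idx <= len(masked.tokens) else "")
                results.add((rule.production, tuple(args)))
    return results


class TestWorkedExample:
    def test_exactly_one_indication_relation(self):
        rels = extract_relations(worked_triples(), worked_masked(), RULES)
        assert len(rels) == 1
        (rel,) = rels
        assert rel.rel_type == "indication"
        assert rel.drug == "DRUG"
        assert rel.concept_id == "INDICATION"

    def test_triple_and_rule_order_invariance(self):
        base = extract_relations(worked_triples(), worked_masked(), RULES)
        rng = random.Random(3)
        for _ in range(10):
            triples = worked_triples()
            rules = list(RULES)
            rng.shuffle(triples)
            rng.shuffle(rules)
            got = extract_relations(triples, worked_masked(), rules)
            assert {r.key for r in got} == {r.key for r in base}

    def test_modern_dialect_collapses_to_same_relation(self):
        modern = [
            DependencyTriple("nsubj:pass", ("used", 4), ("DRUG", 1)),
            DependencyTriple("nmod", ("used", 4), ("treatment", 7)),
            DependencyTriple("case", ("treatment", 7), ("for", 5)),
            DependencyTriple("nmod", ("treatment", 7), ("INDICATION", 9)),
            DependencyTriple("case", ("INDICATION", 9), ("of", 8)),
        ]
        rels = extract_relations(collapse_prepositions(modern), worked_masked(), RULES)
        assert [(r.rel_type, r.drug, r.concept_id) for r in rels] == [
            ("indication", "DRUG", "INDICATION")
        ]


class TestPrecondition:
    def test_only_the_with_argument_is_a_precondition(self):
        rels = extract_relations(precondition_triples(), precondition_masked(), RULES)
        assert [(r.rel_type, r.concept_id) for r in rels] == [("precondition", "COND1")]


class TestEdgeCases:
    def test_empty_triples_yield_nothing(self):
        assert extract_relations([], worked_masked(), RULES) == []

    def test_out_of_range_index_is_error(self):
        bad = [DependencyTriple("prep_of", ("treatment", 7), ("X", 99))]
        with pytest.raises(ValueError, match="99"):
            extract_relations(bad, worked_masked(), RULES)


class TestOracleEquivalence:
    def test_matches_brute_force_on_random_triple_sets(self):
        rng = random.Random(23)
        vocab = ["used", "treatment", "patients", "combination", "history",
                 "receiving", "may", "occur", "the", "of"]
        for _ in range(40):
            n_tokens = rng.randint(4, 9)
            tokens = [rng.choice(vocab) for _ in range(n_tokens)]
            classes = {}
            for pos in rng.sample(range(n_tokens), k=min(2, n_tokens)):
                cls = rng.choice(["drug", "condition"])
                tokens[pos] = f"{cls.upper()}{pos}"
                classes[tokens[pos]] = cls
            masked = MaskedSentence.from_tokens(tokens, classes)
            relations = ["nsubjpass", "prep_for", "prep_of", "prep_in",
                         "prep_with", "dobj", "vmod", "nsubj"]
            triples = [
                DependencyTriple(
                    rng.choice(relations),
                    (tokens[g - 1], g),
                    (tokens[d - 1], d),
                )
                for g, d in (
                    rng.sample(range(1, n_tokens + 1), 2)
                    for _ in range(rng.randint(2, 6))
                )
            ]
            got = {
                (r.rel_type, r.rule_name)
                for r in extract_relations(triples, masked, RULES)
            }
            want = {
                (production, )
                for production, _args in oracle_extract(triples, masked, RULES)
            }
            assert {g[0] for g in got} == {w[0] for w in want}


class TestMasking:
    def mention(self, start, end, cls="condition", cid="C1"):
        return Mention("L1", "indications", 0, start, end, "", cid, entity_class=cls)

    def test_multiword_mention_collapses_to_one_token(self):
        text = "X is used for the treatment of congestive heart failure"
        m = self.mention(text.index("congestive"), len(text))
        m.surface = "congestive heart failure"
        masked = mask_entities(text, [m])
        plain = mask_entities(text, [])
        assert len(masked.tokens) == len(plain.tokens) - 2
        assert sum(t in masked.entity_map for t in masked.tokens) == 1

    def test_no_mentions_plain_tokenization(self):
        masked = mask_entities("Nothing to mask here.", [])
        assert masked.entity_map == {}
        assert masked.tokens == ["Nothing", "to", "mask", "here", "."]

    def test_two_mentions_distinct_placeholders_and_lossless_unmask(self):
        text = "headache preceded nausea"
        m1 = self.mention(0, 8, cid="C1")
        m2 = self.mention(18, 24, cid="C2")
        masked = mask_entities(text, [m1, m2])
        placeholders = [t for t in masked.tokens if t in masked.entity_map]
        assert len(placeholders) == 2 and len(set(placeholders)) == 2
        assert unmask(masked) == text

    def test_overlapping_mentions_rejected(self):
        text = "blood pressure decreased"
        with pytest.raises(ValueError, match="overlap"):
            mask_entities(text, [self.mention(0, 14), self.mention(6, 24)])

    def test_suppressed_mentions_still_masked(self):
        text = "agranulocytosis has not been observed"
        m = self.mention(0, 15)
        m.suppress("hedged_sentence")
        masked = mask_entities(text, [m])
        assert any(t in masked.entity_map for t in masked.tokens)


class TestRuleLoading:
    def test_default_rules_cover_required_constructions(self):
        names = [r.name for r in RULES]
        assert len(names) >= 5
        assert len(set(names)) == len(names)
        productions = {r.production for r in RULES}
        assert productions == {"indication", "precondition", "combination"}

    def test_unbound_production_variable_is_load_error(self):
        bad = (
            "rule broken\n"
            "var COND : condition\n"
            "pattern prep_of history COND\n"
            "produce indication GHOST COND\n"
        )
        with pytest.raises(ValueError, match="broken"):
            parse_rules(bad)

    def test_user_file_appends_one_rule(self, tmp_path):
        extra = (
            DEFAULT_RULES_TEXT
            + "\nrule indication_for_use_in\n"
            "var COND : condition\n"
            "pattern prep_in ?V use\n"
            "pattern prep_for ?V COND\n"
            "produce indication COND\n"
        )
        path = tmp_path / "rules.txt"
        path.write_text(extra)
        assert len(load_rules(path)) == len(RULES) + 1

    def test_duplicate_rule_names_rejected(self):
        text = DEFAULT_RULES_TEXT + "\n" + DEFAULT_RULES_TEXT
        with pytest.raises(ValueError, match="duplicate"):
            parse_rules(text)
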