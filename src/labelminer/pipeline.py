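"""End-to-end orchestration: documents in, filtered pair set out."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .aggregate import (
    DrugADRPair,
    IndicationRecord,
    Registry,
    collect_indications,
    filter_adr_pairs,
)
from .config import ADVERSE_REACTIONS, MinerConfig
from .frequency import (
    REJECT,
    FrequencyRecord,
    classify_table,
    parse_frequency_table,
    parse_frequency_text,
)
from .label_ingest import IngestedLabel, StyledDocument, ingest
from .lexicon import Lexicon
from .ner import Mention, filter_hedged_sentences, find_mentions
from .relations import (
    DependencyTriple,
    ExtractedRelation,
    RelationRule,
    extract_relations,
    load_rules,
    mask_entities,
)


@dataclass
class LabelResult:
    label: IngestedLabel
    mentions: list[Mention] = field(default_factory=list)  # condition mentions
    drug_mentions: list[Mention] = field(default_factory=list)
    relations: list[ExtractedRelation] = field(default_factory=list)
    frequency_records: list[FrequencyRecord] = field(default_factory=list)
    rejected_tables: list[int] = field(default_factory=list)


@dataclass
class CorpusResult:
    labels: dict[str, LabelResult]
    indications: list[IndicationRecord]
    pairs: list[DrugADRPair]

    @property
    def mentions(self) -> list[Mention]:
        return [m for r in self.labels.values() for m in r.mentions]

    @property
    def all_mentions(self) -> list[Mention]:
        return [
            m
            for r in self.labels.values()
            for m in (*r.mentions, *r.drug_mentions)
        ]

    @property
    def relations(self) -> list[ExtractedRelation]:
        return [rel for r in self.labels.values() for rel in r.relations]

    @property
    def frequency_records(self) -> list[FrequencyRecord]:
        return [fr for r in self.labels.values() for fr in r.frequency_records]


def process_label(
    doc: StyledDocument,
    lexicon: Lexicon,
    drug_lexicon: Lexicon | None = None,
    triples: Mapping[int, Sequence[DependencyTriple]] | None = None,
    rules: Sequence[RelationRule] | None = None,
    config: MinerConfig = MinerConfig(),
    drug_name: str | None = None,
) -> LabelResult:
    """Run every per-label stage on one styled document.

    Stages: segment -> NER (conditions + drugs) -> hedge suppression ->
    entity masking + rule-based relation extraction (for sentences with
    dependency triples) -> table and free-text frequency extraction.
    """
    label = ingest(doc, config)
    result = LabelResult(label)
    if rules is None:
        rules = load_rules()

    sentences = {s.index: s for _, s in label.sentences()}
    for section in label.mined_sections():
        result.mentions.extend(find_mentions(section, lexicon, doc.label_id))
        if drug_lexicon is not None:
            result.drug_mentions.extend(
                find_mentions(section, drug_lexicon, doc.label_id, entity_class="drug")
            )
    filter_hedged_sentences(result.mentions, sentences, config)

    # relation extraction over pre-parsed sentences
    if triples:
        by_sentence: dict[int, list[Mention]] = {}
        for m in (*result.mentions, *result.drug_mentions):
            by_sentence.setdefault(m.sentence_index, []).append(m)
        section_of = {
            s.index: sec.kind for sec, s in label.sentences()
        }
        for sent_idx, sent_triples in triples.items():
            sent = sentences.get(sent_idx)
            if sent is None:
                continue
            masked = mask_entities(
                sent.text,
                by_sentence.get(sent_idx, []),
                sentence_offset=sent.char_start,
                label_id=doc.label_id,
                section_kind=section_of.get(sent_idx, ""),
                sentence_index=sent_idx,
            )
            result.relations.extend(
                extract_relations(sent_triples, masked, rules, label_drug=drug_name)
            )

    # frequencies: tables, then free text in the ADR section
    drug_names = [drug_name] if drug_name else []
    for section in label.mined_sections():
        for table in section.tables:
            roles = classify_table(table, drug_names, config)
            if roles == REJECT:
                result.rejected_tables.append(table.index)
                continue
            result.frequency_records.extend(
                parse_frequency_table(table, roles, lexicon, config, doc.label_id)
            )
        if section.kind != ADVERSE_REACTIONS:
            continue
        active = [m for m in result.mentions if not m.suppressed]
        for para in section.paragraphs:
            for sent in para.sentences:
                result.frequency_records.extend(
                    parse_frequency_text(sent, active, config, doc.label_id)
                )
    return result


def process_corpus(
    documents: Mapping[str, StyledDocument],
    registry: Registry,
    lexicon: Lexicon,
    drug_lexicon: Lexicon | None = None,
    triples: Mapping[str, Mapping[int, Sequence[DependencyTriple]]] | None = None,
    rules: Sequence[RelationRule] | None = None,
    config: MinerConfig = MinerConfig(),
) -> CorpusResult:
    """Process every label, pool indications, and apply the ADR filter."""
    if rules is None:
        rules = load_rules()
    labels: dict[str, LabelResult] = {}
    for label_id in sorted(documents):
        doc = documents[label_id]
        drug = registry.get(label_id)
        labels[label_id] = process_label(
            doc,
            lexicon,
            drug_lexicon=drug_lexicon,
            triples=(triples or {}).get(label_id),
            rules=rules,
            config=config,
            drug_name=drug.names[0] if drug and drug.names else None,
        )
    result = CorpusResult(labels, [], [])
    result.indications = collect_indications(
        result.relations, result.mentions, registry
    )
    result.pairs = filter_adr_pairs(
        result.mentions,
        result.frequency_records,
        result.indications,
        registry,
        lexicon,
    )
    return result
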