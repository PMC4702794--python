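"""Corpus-level aggregation: indication filter, benchmark overlap, outputs.

Per-label extractions are pooled per drug (flat compound id; stereoisomers
and salt forms merge).  Indications detected by NLP or by NER in the
indications section then filter the ADR candidates: a concept supported only
by free text in the ADR section is discarded when the same drug has an NLP
indication/precondition for it on *any* label, or an NER indication on the
*same* label (NER indications are noisier, so their filter scope is narrower).
Concepts supported by an ADR frequency table keep their table evidence
regardless — a tabulated frequency is strong evidence the term is a real ADR.

The benchmark compares the final (drug, concept) pair sets against an
external reference on exactly matching identifiers, restricted to the drugs
and concepts both sides know about.
"""

from __future__ import annotations

import html as html_mod
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from ._util import pct_half_up
from .config import ADVERSE_REACTIONS, INDICATIONS, MinerConfig
from .frequency import FrequencyRecord
from .label_ingest import StyledDocument
from .lexicon import Lexicon
from .ner import INDICATION_FILTER, Mention
from .relations import ExtractedRelation

NLP_INDICATION = "nlp_indication"
NLP_PRECONDITION = "nlp_precondition"
NER_INDICATION_SECTION = "ner_indication_section"


@dataclass
class DrugRecord:
    flat_id: str
    stereo_id: str | None = None
    names: list[str] = field(default_factory=list)
    label_ids: list[str] = field(default_factory=list)


Registry = dict[str, DrugRecord]  # label_id -> drug


@dataclass(frozen=True)
class IndicationRecord:
    flat_id: str
    concept_id: str
    method: str  # nlp_indication | nlp_precondition | ner_indication_section
    label_id: str


@dataclass
class DrugADRPair:
    flat_id: str
    concept_id: str
    meddra_code: str | None
    term: str
    stereo_id: str | None = None
    frequency_records: list[FrequencyRecord] = field(default_factory=list)
    provenance: list[tuple[str, str]] = field(default_factory=list)  # (label, locator)


@dataclass
class OverlapStats:
    common_drugs: int
    common_concepts: int
    only_a: int
    intersection: int
    only_b: int
    pct_rel_a: float | None
    pct_rel_b: float | None
    matched: int  # restricted |A|
    total_a: int  # unrestricted |A|


def collect_indications(
    relations: Iterable[ExtractedRelation],
    mentions: Iterable[Mention],
    registry: Registry,
) -> list[IndicationRecord]:
    """Pool per-label indication evidence into per-drug records.

    NLP relations map to their method; every unsuppressed condition mention
    in an indications section yields an NER record.  Deduplicated per
    (drug, concept, method, label).
    """
    relations = list(relations)
    mentions = list(mentions)
    orphans = sorted(
        {r.label_id for r in relations if r.label_id not in registry}
        | {m.label_id for m in mentions if m.label_id not in registry}
    )
    if orphans:
        raise KeyError(f"labels missing from drug registry: {orphans}")
    records: set[IndicationRecord] = set()
    for rel in relations:
        if rel.rel_type == "indication":
            method = NLP_INDICATION
        elif rel.rel_type == "precondition":
            method = NLP_PRECONDITION
        else:
            continue  # combinations are drug-drug, not indications
        if rel.concept_id is None:
            continue
        records.add(
            IndicationRecord(
                registry[rel.label_id].flat_id, rel.concept_id, method, rel.label_id
            )
        )
    for m in mentions:
        if (
            m.section_kind == INDICATIONS
            and m.entity_class == "condition"
            and not m.suppressed
        ):
            records.add(
                IndicationRecord(
                    registry[m.label_id].flat_id,
                    m.concept_id,
                    NER_INDICATION_SECTION,
                    m.label_id,
                )
            )
    return sorted(records, key=lambda r: (r.flat_id, r.concept_id, r.method, r.label_id))


def filter_adr_pairs(
    mentions: Iterable[Mention],
    frequency_records: Iterable[FrequencyRecord],
    indications: Iterable[IndicationRecord],
    registry: Registry,
    lexicon: Lexicon,
) -> list[DrugADRPair]:
    """Build the final drug–ADR pair set under the indication filter.

    Free-text evidence for (drug d, concept c) on label L is discarded iff
    (i) an NLP indication/precondition record for (d, c) exists on any
    label, or (ii) an NER indication-section record for c exists on L
    itself.  Table-derived frequency evidence is exempt.  Discarded mentions
    are flagged (reason ``indication_filter``), never deleted.
    """
    indications = list(indications)
    nlp_any = {
        (r.flat_id, r.concept_id)
        for r in indications
        if r.method in (NLP_INDICATION, NLP_PRECONDITION)
    }
    ner_same = {
        (r.label_id, r.concept_id)
        for r in indications
        if r.method == NER_INDICATION_SECTION
    }

    freq_by_source: dict[str, list[FrequencyRecord]] = {"table": [], "text": []}
    for fr in frequency_records:
        freq_by_source.setdefault(fr.source, []).append(fr)

    # free-text support: unsuppressed condition mentions in ADR sections
    surviving_text: dict[tuple[str, str], list[Mention]] = {}
    for m in mentions:
        if (
            m.section_kind != ADVERSE_REACTIONS
            or m.entity_class != "condition"
            or m.suppressed
        ):
            continue
        drug = registry[m.label_id].flat_id
        if (drug, m.concept_id) in nlp_any or (m.label_id, m.concept_id) in ner_same:
            m.suppress(INDICATION_FILTER)
            continue
        surviving_text.setdefault((drug, m.concept_id), []).append(m)

    pairs: dict[tuple[str, str], DrugADRPair] = {}

    def pair_for(drug: str, concept_id: str, label_id: str) -> DrugADRPair:
        key = (drug, concept_id)
        if key not in pairs:
            concept = lexicon.concepts.get(concept_id)
            pairs[key] = DrugADRPair(
                flat_id=drug,
                concept_id=concept_id,
                meddra_code=concept.meddra_code if concept else None,
                term=concept.preferred_name if concept else concept_id,
                stereo_id=registry[label_id].stereo_id,
            )
        return pairs[key]

    for (drug, cid), ms in surviving_text.items():
        pair = pair_for(drug, cid, ms[0].label_id)
        for m in ms:
            pair.provenance.append((m.label_id, f"char:{m.char_start}-{m.char_end}"))
        # free-text frequency records ride on surviving free-text evidence
        for fr in freq_by_source.get("text", ()):
            if fr.concept_id == cid and registry[fr.label_id].flat_id == drug:
                pair.frequency_records.append(fr)

    # table evidence: exempt from the indication filter
    for fr in freq_by_source.get("table", ()):
        drug = registry[fr.label_id].flat_id
        pair = pair_for(drug, fr.concept_id, fr.label_id)
        pair.frequency_records.append(fr)
        pair.provenance.append((fr.label_id, fr.locator))

    for pair in pairs.values():
        pair.frequency_records.sort(
            key=lambda fr: (fr.label_id, fr.locator, fr.arm, fr.display)
        )
        pair.provenance = sorted(set(pair.provenance))
    return sorted(pairs.values(), key=lambda p: (p.flat_id, p.concept_id))


def compute_overlap(
    pairs_a: Iterable[tuple[str, str]],
    pairs_b: Iterable[tuple[str, str]],
    config: MinerConfig = MinerConfig(),
) -> OverlapStats:
    """Contingency of two (drug, concept) pair sets on shared identifiers.

    Both sets are restricted to drugs and concepts occurring in both before
    counting; percentages are half-up rounded and undefined (None) when a
    restricted set is empty.  ``matched``/``total_a`` support the
    matched-fraction report (how much of A could be compared at all).
    """
    set_a = set(pairs_a)
    set_b = set(pairs_b)
    drugs_a = {d for d, _ in set_a}
    drugs_b = {d for d, _ in set_b}
    concepts_a = {c for _, c in set_a}
    concepts_b = {c for _, c in set_b}
    common_drugs = drugs_a & drugs_b
    common_concepts = concepts_a & concepts_b
    ra = {p for p in set_a if p[0] in common_drugs and p[1] in common_concepts}
    rb = {p for p in set_b if p[0] in common_drugs and p[1] in common_concepts}
    inter = len(ra & rb)
    only_a = len(ra - rb)
    only_b = len(rb - ra)
    digits = config.overlap_pct_digits
    return OverlapStats(
        common_drugs=len(common_drugs),
        common_concepts=len(common_concepts),
        only_a=only_a,
        intersection=inter,
        only_b=only_b,
        pct_rel_a=pct_half_up(inter, inter + only_a, digits),
        pct_rel_b=pct_half_up(inter, inter + only_b, digits),
        matched=len(ra),
        total_a=len(set_a),
    )


# ---------------------------------------------------------------------------
# Output files

_TSV_PAIR_HEADER = [
    "flat_id", "stereo_id", "concept_id", "meddra_code", "term",
    "arm", "freq_display", "freq_lower", "freq_upper", "source", "label_id",
]
_TSV_IND_HEADER = ["flat_id", "concept_id", "method", "label_id"]


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        return f"{value:g}"
    return str(value)


def _tsv(rows: Iterable[Sequence], header: Sequence[str]) -> str:
    lines = ["\t".join(header)]
    for row in rows:
        lines.append("\t".join(_fmt(v) for v in row))
    return "\n".join(lines) + "\n"


def render_pairs_tsv(pairs: Sequence[DrugADRPair]) -> str:
    rows = []
    for p in sorted(pairs, key=lambda p: (p.flat_id, p.concept_id)):
        if p.frequency_records:
            for fr in p.frequency_records:
                rows.append(
                    (p.flat_id, p.stereo_id, p.concept_id, p.meddra_code, p.term,
                     fr.arm, fr.display, fr.freq_lower, fr.freq_upper, fr.source,
                     fr.label_id)
                )
        else:
            label = p.provenance[0][0] if p.provenance else ""
            rows.append(
                (p.flat_id, p.stereo_id, p.concept_id, p.meddra_code, p.term,
                 "", "", None, None, "", label)
            )
    rows.sort(key=lambda r: tuple(_fmt(v) for v in r))
    return _tsv(rows, _TSV_PAIR_HEADER)


def render_indications_tsv(indications: Sequence[IndicationRecord]) -> str:
    rows = sorted(
        (r.flat_id, r.concept_id, r.method, r.label_id) for r in indications
    )
    return _tsv(rows, _TSV_IND_HEADER)


def render_label_html(
    doc: StyledDocument, mentions: Sequence[Mention]
) -> str:
    """Label text with every mention wrapped in an annotated span.

    Suppressed mentions stay visible (distinct class + reason attribute):
    provenance must survive filtering so extractions can be traced.
    """
    text = doc.text
    ordered = sorted(
        (m for m in mentions if m.label_id == doc.label_id),
        key=lambda m: m.char_start,
    )
    parts: list[str] = []
    cursor = 0
    for m in ordered:
        if m.char_start < cursor:
            continue  # overlap safety; upstream guarantees disjoint spans
        parts.append(html_mod.escape(text[cursor : m.char_start]))
        cls = "mention suppressed" if m.suppressed else "mention"
        reason = f' data-reason="{html_mod.escape(m.suppression_reason)}"' if m.suppression_reason else ""
        parts.append(
            f'<span class="{cls}" data-concept="{html_mod.escape(m.concept_id)}"'
            f' data-class="{m.entity_class}"{reason}>'
            f"{html_mod.escape(text[m.char_start : m.char_end])}</span>"
        )
        cursor = m.char_end
    parts.append(html_mod.escape(text[cursor:]))
    body = "".join(parts)
    return (
        "<!DOCTYPE html>\n<html><head><meta charset=\"utf-8\">"
        f"<title>{html_mod.escape(doc.label_id)}</title>"
        "<style>.mention{background:#ffe28a}.mention.suppressed{background:#e0e0e0;"
        "text-decoration:line-through}</style></head>\n"
        f"<body><pre>{body}</pre></body></html>\n"
    )


def write_outputs(
    pairs: Sequence[DrugADRPair],
    indications: Sequence[IndicationRecord],
    documents: Mapping[str, StyledDocument],
    mentions: Sequence[Mention],
    out_dir: str | Path,
    lexicon: Lexicon,
) -> list[Path]:
    """Write pairs TSV, indications TSV and per-label highlighted HTML.

    Referential integrity is checked before anything is written; outputs are
    deterministically ordered, so reruns are byte-identical.
    """
    dangling: list[str] = []
    for p in pairs:
        if p.concept_id not in lexicon.concepts:
            dangling.append(f"pair concept {p.concept_id}")
    for r in indications:
        if r.label_id not in documents:
            dangling.append(f"indication label {r.label_id}")
    for m in mentions:
        if m.label_id not in documents:
            dangling.append(f"mention label {m.label_id}")
    if dangling:
        raise ValueError(f"dangling references: {sorted(set(dangling))}")

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    pairs_path = out / "pairs.tsv"
    pairs_path.write_text(render_pairs_tsv(pairs), encoding="utf-8")
    written.append(pairs_path)

    ind_path = out / "indications.tsv"
    ind_path.write_text(render_indications_tsv(indications), encoding="utf-8")
    written.append(ind_path)

    if any(mentions):
        html_dir = out / "html"
        html_dir.mkdir(exist_ok=True)
        by_label: dict[str, list[Mention]] = {}
        for m in mentions:
            by_label.setdefault(m.label_id, []).append(m)
        for label_id in sorted(by_label):
            doc = documents[label_id]
            path = html_dir / f"{label_id}.html"
            path.write_text(render_label_html(doc, by_label[label_id]), encoding="utf-8")
            written.append(path)
    return written
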