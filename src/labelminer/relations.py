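"""Rule-based relation extraction over dependency triples.

Recognized entities are first collapsed to single placeholder tokens
(masking), which both simplifies parsing of multi-word medical terms and
gives the rules typed anchors.  An external dependency parser (out of scope
here; consumed as input) turns each masked sentence into a list of triples
(relation, governor, dependent), in the collapsed-preposition dialect where
e.g. "treatment of X" yields ``prep_of(treatment, X)``.  A small declarative
rule language then classifies entity roles:

    rule indication_treatment_of
    var DRUG : drug
    var COND : condition
    pattern nsubjpass ?V DRUG
    pattern prep_for ?V treatment|management|relief
    pattern prep_of treatment|management|relief COND
    produce indication DRUG COND

Slots are entity-typed variables (declared with ``var``), free variables
(``?name``) or lexical literals (lower-case, matched on casefolded lemmas
with ``|`` alternation; a literal repeated within one rule must bind the
same token).  A rule fires for every injective assignment of its slots to
token indices that satisfies all pattern lines simultaneously; firings that
produce the same (type, drug, concept) are deduplicated, so rule and triple
order never matter.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from ._util import word_tokens
from .ner import Mention

ROOT_INDEX = 0

RELATION_TYPES = ("indication", "precondition", "combination")

# Minimal lemma table for the lexical vocabulary the shipped rules use.
LEMMA_TABLE = {
    "used": "use", "uses": "use", "using": "use", "use": "use",
    "indicated": "indicate", "indicate": "indicate", "indicates": "indicate",
    "treatment": "treatment", "treatments": "treatment",
    "management": "management", "relief": "relief",
    "patients": "patient", "patient": "patient",
    "receiving": "receive", "received": "receive", "receives": "receive",
    "receive": "receive",
    "histories": "history", "history": "history",
    "combination": "combination", "combinations": "combination",
}


def lemma(word: str) -> str:
    w = word.casefold()
    return LEMMA_TABLE.get(w, w)


@dataclass(frozen=True)
class DependencyTriple:
    relation: str
    governor: tuple[str, int]  # (word, 1-based token index; 0 = ROOT)
    dependent: tuple[str, int]

    def __post_init__(self) -> None:
        if not self.relation:
            raise ValueError("relation label must be non-empty")
        if self.governor[1] < 0 or self.dependent[1] < 0:
            raise ValueError(f"negative token index in triple {self}")


@dataclass
class MaskedSentence:
    """A sentence with entity spans collapsed to placeholder tokens."""

    tokens: list[str]
    entity_map: dict[str, tuple[Mention | None, str]]  # placeholder -> (mention, class)
    original_text: str = ""
    label_id: str = ""
    section_kind: str = ""
    sentence_index: int = -1

    def entity_class_at(self, index: int) -> str | None:
        """Entity class of the token at a 1-based index, if it is a placeholder."""
        if not 1 <= index <= len(self.tokens):
            return None
        entry = self.entity_map.get(self.tokens[index - 1])
        return entry[1] if entry else None

    def mention_at(self, index: int) -> Mention | None:
        entry = self.entity_map.get(self.tokens[index - 1])
        return entry[0] if entry else None

    @classmethod
    def from_tokens(
        cls, tokens: Sequence[str], entity_classes: dict[str, str]
    ) -> "MaskedSentence":
        """Build directly from pre-masked tokens (fixture/worked-example path)."""
        return cls(
            tokens=list(tokens),
            entity_map={tok: (None, c) for tok, c in entity_classes.items()},
            original_text=" ".join(tokens),
        )


# ---------------------------------------------------------------------------
# Masking

_TOKEN_RE = __import__("re").compile(r"\w+|[^\w\s]")


def mask_entities(
    sentence_text: str,
    mentions: Sequence[Mention],
    sentence_offset: int = 0,
    **provenance,
) -> MaskedSentence:
    """Replace each mention span by a unique placeholder token.

    *mentions* carry absolute offsets; *sentence_offset* is the sentence's
    own absolute start.  Mentions must be non-overlapping and lie within the
    sentence.  Suppressed mentions are masked too — masking precedes any
    filtering.  Unmasking (``original_text``) is lossless by construction.
    """
    ordered = sorted(mentions, key=lambda m: m.char_start)
    prev_end = -1
    for m in ordered:
        rel_start = m.char_start - sentence_offset
        rel_end = m.char_end - sentence_offset
        if rel_start < prev_end:
            raise ValueError(f"overlapping mentions at offset {m.char_start}")
        if rel_start < 0 or rel_end > len(sentence_text):
            raise ValueError("mention outside sentence bounds")
        prev_end = rel_end

    tokens: list[str] = []
    entity_map: dict[str, tuple[Mention | None, str]] = {}
    cursor = 0
    counters = {"drug": 0, "condition": 0}
    for m in ordered:
        rel_start = m.char_start - sentence_offset
        rel_end = m.char_end - sentence_offset
        tokens.extend(t.group(0) for t in _TOKEN_RE.finditer(sentence_text[cursor:rel_start]))
        counters[m.entity_class] = counters.get(m.entity_class, 0) + 1
        placeholder = f"{m.entity_class.upper()}{counters[m.entity_class]:03d}"
        tokens.append(placeholder)
        entity_map[placeholder] = (m, m.entity_class)
        cursor = rel_end
    tokens.extend(t.group(0) for t in _TOKEN_RE.finditer(sentence_text[cursor:]))
    return MaskedSentence(
        tokens=tokens,
        entity_map=entity_map,
        original_text=sentence_text,
        **provenance,
    )


def unmask(masked: MaskedSentence) -> str:
    return masked.original_text


# ---------------------------------------------------------------------------
# Rules

@dataclass(frozen=True)
class Slot:
    kind: str  # "entity" | "free" | "lex"
    name: str  # variable name, or the literal text for lex slots
    entity_class: str | None = None
    lemmas: frozenset[str] | None = None  # for lex slots


@dataclass(frozen=True)
class TripleTemplate:
    relations: frozenset[str]  # {"*"} = wildcard
    governor: Slot
    dependent: Slot

    def relation_matches(self, label: str) -> bool:
        return "*" in self.relations or label in self.relations


@dataclass(frozen=True)
class RelationRule:
    name: str
    pattern: tuple[TripleTemplate, ...]
    production: str  # relation type
    produce_args: tuple[str, ...]  # variable names, in production order

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError(f"rule {self.name}: empty pattern")
        bound = set()
        for t in self.pattern:
            for slot in (t.governor, t.dependent):
                bound.add(slot.name)
        for var in self.produce_args:
            if var not in bound:
                raise ValueError(
                    f"rule {self.name}: production variable {var!r} not bound by pattern"
                )
        if self.production not in RELATION_TYPES:
            raise ValueError(f"rule {self.name}: unknown relation type {self.production!r}")


@dataclass(frozen=True)
class ExtractedRelation:
    rel_type: str
    drug: str | None  # drug surface/concept for indication & combination
    concept_id: str | None  # condition concept (None for combination)
    rule_name: str = ""
    label_id: str = ""
    section_kind: str = ""
    sentence_index: int = -1

    @property
    def key(self) -> tuple[str, str | None, str | None]:
        return (self.rel_type, self.drug, self.concept_id)


DEFAULT_RULES_TEXT = """\
# Default relation rules.  Coverage: the worked indication constructions
# ("used/indicated for the treatment|management|relief of X", "indicated
# for X"), pre-existing-condition constructions ("in patients with X",
# "patients receiving X", "history of X") and drug combinations
# ("in combination with DRUG").

rule indication_treatment_of
var DRUG : drug
var COND : condition
pattern nsubjpass ?V DRUG
pattern prep_for ?V treatment|management|relief
pattern prep_of treatment|management|relief COND
produce indication DRUG COND

rule indication_indicated_for
var DRUG : drug
var COND : condition
pattern nsubjpass ?V DRUG
pattern prep_for ?V COND
produce indication DRUG COND

rule precondition_in_patients_with
var COND : condition
pattern prep_in ?V patient
pattern prep_with patient COND
produce precondition COND

rule precondition_history_of
var COND : condition
pattern prep_of history COND
produce precondition COND

rule precondition_patients_receiving
var COND : condition
pattern vmod|partmod|acl patient receive
pattern dobj receive COND
produce precondition COND

rule combination_with
var DRUG : drug
pattern prep_in ?V combination
pattern prep_with combination DRUG
produce combination DRUG
"""


def _parse_slot(token: str, var_classes: dict[str, str]) -> Slot:
    if token.startswith("?"):
        return Slot("free", token)
    if token in var_classes:
        return Slot("entity", token, entity_class=var_classes[token])
    lemmas = frozenset(lemma(alt) for alt in token.split("|"))
    return Slot("lex", token, lemmas=lemmas)


def parse_rules(text: str) -> list[RelationRule]:
    rules: list[RelationRule] = []
    name: str | None = None
    var_classes: dict[str, str] = {}
    pattern: list[TripleTemplate] = []
    production: tuple[str, tuple[str, ...]] | None = None

    def flush() -> None:
        nonlocal name, var_classes, pattern, production
        if name is None:
            return
        if production is None:
            raise ValueError(f"rule {name}: missing produce line")
        rule = RelationRule(name, tuple(pattern), production[0], production[1])
        if any(r.name == rule.name for r in rules):
            raise ValueError(f"duplicate rule name: {rule.name}")
        rules.append(rule)
        name, var_classes, pattern, production = None, {}, [], None

    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        keyword = parts[0]
        if keyword == "rule":
            flush()
            name = parts[1]
        elif keyword == "var":
            # "var NAME : class"
            body = " ".join(parts[1:])
            var_name, _, cls = (p.strip() for p in body.partition(":"))
            var_classes[var_name] = cls
        elif keyword == "pattern":
            if len(parts) != 4:
                raise ValueError(f"rule {name}: malformed pattern line {line!r}")
            relations = frozenset(parts[1].split("|"))
            pattern.append(
                TripleTemplate(
                    relations,
                    _parse_slot(parts[2], var_classes),
                    _parse_slot(parts[3], var_classes),
                )
            )
        elif keyword == "produce":
            production = (parts[1], tuple(parts[2:]))
        else:
            raise ValueError(f"unrecognized rule line: {line!r}")
    flush()
    return rules


def load_rules(source: str | Path | io.TextIOBase | None = None) -> list[RelationRule]:
    """Load rules from a file path / stream, or the shipped defaults."""
    if source is None:
        return parse_rules(DEFAULT_RULES_TEXT)
    if isinstance(source, io.TextIOBase):
        return parse_rules(source.read())
    return parse_rules(Path(source).read_text(encoding="utf-8"))


# ---------------------------------------------------------------------------
# Matching

def _slot_matches(
    slot: Slot,
    word: str,
    index: int,
    masked: MaskedSentence,
    label_drug: str | None,
) -> bool:
    if slot.kind == "free":
        return True
    if slot.kind == "lex":
        return lemma(word) in slot.lemmas  # type: ignore[operator]
    # entity-typed variable
    cls = masked.entity_class_at(index)
    if cls == slot.entity_class:
        return True
    if (
        slot.entity_class == "drug"
        and label_drug is not None
        and word.casefold() == label_drug.casefold()
    ):
        return True
    return False


def _match_rule(
    rule: RelationRule,
    triples: Sequence[DependencyTriple],
    masked: MaskedSentence,
    label_drug: str | None,
) -> list[dict[str, int]]:
    """All injective slot-name -> token-index assignments satisfying the rule."""
    results: list[dict[str, int]] = []

    def backtrack(t_idx: int, binding: dict[str, int]) -> None:
        if t_idx == len(rule.pattern):
            results.append(dict(binding))
            return
        template = rule.pattern[t_idx]
        for triple in triples:
            if not template.relation_matches(triple.relation):
                continue
            trial = dict(binding)
            ok = True
            for slot, (word, index) in (
                (template.governor, triple.governor),
                (template.dependent, triple.dependent),
            ):
                if not _slot_matches(slot, word, index, masked, label_drug):
                    ok = False
                    break
                bound = trial.get(slot.name)
                if bound is not None:
                    if bound != index:
                        ok = False
                        break
                else:
                    if index in trial.values():  # injectivity
                        ok = False
                        break
                    trial[slot.name] = index
            if ok:
                backtrack(t_idx + 1, trial)

    backtrack(0, {})
    return results


def _resolve_entity(
    masked: MaskedSentence, index: int, label_drug: str | None
) -> tuple[str | None, str | None]:
    """(drug surface/id, condition concept id) contribution of a bound token."""
    mention = masked.mention_at(index)
    cls = masked.entity_class_at(index)
    word = masked.tokens[index - 1] if 1 <= index <= len(masked.tokens) else ""
    if cls == "condition":
        return None, mention.concept_id if mention else word
    if cls == "drug":
        return (mention.concept_id if mention else word), None
    # label's own product name matched literally
    return word, None


def extract_relations(
    triples: Sequence[DependencyTriple],
    masked: MaskedSentence,
    rules: Sequence[RelationRule],
    label_drug: str | None = None,
) -> list[ExtractedRelation]:
    """Apply every rule; one relation per firing, deduplicated.

    Independent of triple order and rule order.  Token indices in triples
    must be consistent with the masked sentence (0 is reserved for ROOT).
    """
    n = len(masked.tokens)
    for triple in triples:
        for word, index in (triple.governor, triple.dependent):
            if index > n:
                raise ValueError(
                    f"triple {triple.relation}({triple.governor}, {triple.dependent}) "
                    f"references token {index} but sentence has {n} tokens"
                )
    seen: set[tuple[str, str | None, str | None]] = set()
    out: list[ExtractedRelation] = []
    for rule in sorted(rules, key=lambda r: r.name):
        for binding in _match_rule(rule, triples, masked, label_drug):
            drug_ref: str | None = None
            concept: str | None = None
            for var in rule.produce_args:
                d, c = _resolve_entity(masked, binding[var], label_drug)
                drug_ref = drug_ref or d
                concept = concept or c
            rel = ExtractedRelation(
                rel_type=rule.production,
                drug=drug_ref,
                concept_id=concept,
                rule_name=rule.name,
                label_id=masked.label_id,
                section_kind=masked.section_kind,
                sentence_index=masked.sentence_index,
            )
            if rel.key not in seen:
                seen.add(rel.key)
                out.append(rel)
    return out


# ---------------------------------------------------------------------------
# Dialect normalization (modern case/nmod parses -> collapsed labels)

def collapse_prepositions(triples: Iterable[DependencyTriple]) -> list[DependencyTriple]:
    """Map the two-edge (nmod + case) dialect onto collapsed prep_* labels.

    ``nmod(g, d)`` with ``case(d, p)`` becomes ``prep_p(g, d)``; the case
    edge is dropped.  Triples already in collapsed form pass through, as do
    all other relations.
    """
    triples = list(triples)
    case_of: dict[int, str] = {}
    for t in triples:
        if t.relation == "case":
            case_of[t.governor[1]] = t.dependent[0].casefold()
    out: list[DependencyTriple] = []
    for t in triples:
        if t.relation == "case" and t.governor[1] in case_of:
            continue
        base = t.relation.split(":")[0]
        if base in ("nmod", "obl") and t.dependent[1] in case_of:
            out.append(
                DependencyTriple(
                    f"prep_{case_of[t.dependent[1]]}", t.governor, t.dependent
                )
            )
        elif t.relation in ("nsubj:pass", "nsubjpass"):
            out.append(DependencyTriple("nsubjpass", t.governor, t.dependent))
        elif t.relation in ("aux:pass", "auxpass"):
            out.append(DependencyTriple("auxpass", t.governor, t.dependent))
        else:
            out.append(t)
    return out
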