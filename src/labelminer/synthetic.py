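"""Synthetic lexicons and label corpora with exhaustive ground truth.

Real concept vocabularies (UMLS/MedDRA) and label corpora are licensed, so
every stage of the miner is exercised against generated stand-ins instead.
The generator's central trick is vocabulary disjointness: lexicon words,
filler words and drug names are built from three disjoint consonant pools,
so a concept name can never occur in filler text by accident.  On such a
corpus any false positive indicates a real engine defect, which makes
precision = recall = 1 a legitimate acceptance property.

Generated labels contain heading-styled indications/ADR/terminator sections,
sentences instantiated from the constructions the default relation rules
cover, hedged sentences, both free-text frequency patterns, drug/placebo
frequency tables, decoy (rejectable) tables, and concepts planted both as
indications and as ADR text to exercise the indication filter — each with
exact character spans and the final pair set they should survive into.

All generation is a pure function of (seed, parameters).
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from ._util import normalize_surface
from .aggregate import (
    NER_INDICATION_SECTION,
    NLP_INDICATION,
    NLP_PRECONDITION,
    DrugRecord,
    Registry,
)
from .label_ingest import Span, StyledDocument
from .lexicon import Concept, Lexicon, build_lexicon
from .relations import DependencyTriple

logger = logging.getLogger(__name__)

_VOWELS = "aeiou"
_LEX_CONSONANTS = "bdglmnr"
_FILLER_CONSONANTS = "pstfkv"
_DRUG_CONSONANTS = "zcwhj"

ADR_SEMTYPE = "sign_or_symptom"
OFFLIST_SEMTYPE = "laboratory_procedure"


def _word(rng: random.Random, consonants: str, n_syllables: int) -> str:
    return "".join(
        rng.choice(consonants) + rng.choice(_VOWELS) for _ in range(n_syllables)
    )


def _unique_words(rng: random.Random, consonants: str, n: int) -> list[str]:
    out: list[str] = []
    seen: set[str] = set()
    while len(out) < n:
        w = _word(rng, consonants, rng.randint(2, 3))
        if w not in seen:
            seen.add(w)
            out.append(w)
    return out


# ---------------------------------------------------------------------------
# Lexicon generation

@dataclass
class SyntheticLexicon:
    lexicon: Lexicon
    concept_records: list[Concept]  # includes off-whitelist concepts
    semantic_whitelist: tuple[str, ...]
    excluded_concepts: list[str]
    blocked_names: list[str]
    synonym_groups: list[tuple[str, str]]
    withheld: list[tuple[str, str]]  # (concept_id, permutation-only surface)
    filler_words: list[str]


def generate_lexicon(
    seed: int,
    n_concepts: int = 30,
    n_names_per_concept: int = 2,
    n_synonym_groups: int = 4,
    withheld_fraction: float = 0.4,
) -> SyntheticLexicon:
    """Deterministic concept dictionary with planted structure.

    Plants: shared modifier words across concepts (longest-match pressure),
    one off-whitelist concept (dropped by the semantic filter), one excluded
    concept, one blocked name, synonym word groups, and withheld
    permutation-only surfaces that only dictionary expansion can recover.
    """
    if min(n_concepts, n_names_per_concept, n_synonym_groups) < 1:
        raise ValueError("all generator parameters must be >= 1")
    rng = random.Random(seed)
    heads = _unique_words(rng, _LEX_CONSONANTS, n_concepts + 2)
    modifiers = _unique_words(rng, _LEX_CONSONANTS, max(6, n_synonym_groups + 2))
    while set(modifiers) & set(heads):
        modifiers = _unique_words(rng, _LEX_CONSONANTS, max(6, n_synonym_groups + 2))
    synonyms = _unique_words(rng, _LEX_CONSONANTS, n_synonym_groups)
    while set(synonyms) & (set(heads) | set(modifiers)):
        synonyms = _unique_words(rng, _LEX_CONSONANTS, n_synonym_groups)
    groups = [(modifiers[i], synonyms[i]) for i in range(n_synonym_groups)]

    concepts: list[Concept] = []
    withheld: list[tuple[str, str]] = []
    for i in range(n_concepts):
        cid = f"C{i:04d}"
        head = heads[i]
        names: list[str] = []
        if i % 3 == 0:
            names.append(head)  # single-word preferred name
        else:
            names.append(f"{head} {modifiers[i % len(modifiers)]}")
        for j in range(1, n_names_per_concept):
            extra = f"{modifiers[(i + j) % len(modifiers)]} {head}"
            if extra not in names:
                names.append(extra)
        # longest-match pressure: extend the previous concept's single-word name
        if i % 5 == 4 and (i - 1) % 3 == 0:
            longer = f"{heads[i - 1]} {modifiers[(i + 3) % len(modifiers)]} {head}"
            names.append(longer)
        concepts.append(
            Concept(
                concept_id=cid,
                preferred_name=names[0],
                names=list(names),
                semantic_types=[ADR_SEMTYPE],
                meddra_code=f"10{i:06d}",
                level="PT",
            )
        )
        # withhold permutation-only surfaces from multi-word names
        for name in names:
            words = name.split()
            if len(words) < 2:
                continue
            if rng.random() >= withheld_fraction:
                continue
            permuted = list(reversed(words))
            # sometimes substitute a synonym-group word as well
            for gi, (word, syn) in enumerate(groups):
                if word in permuted and rng.random() < 0.5:
                    permuted[permuted.index(word)] = syn
                    break
            surface = " ".join(permuted)
            if surface != name and all(surface not in c.names for c in concepts):
                withheld.append((cid, surface))

    # one off-whitelist concept: must be dropped by the semantic filter
    concepts.append(
        Concept(
            concept_id=f"C{n_concepts:04d}",
            preferred_name=heads[n_concepts],
            names=[heads[n_concepts]],
            semantic_types=[OFFLIST_SEMTYPE],
            meddra_code=None,
            level="unknown",
        )
    )
    excluded = [concepts[min(1, n_concepts - 1)].concept_id]
    blocked = [concepts[0].names[-1]] if len(concepts[0].names) > 1 else []

    lex = build_lexicon(
        concepts,
        semantic_whitelist=[ADR_SEMTYPE],
        excluded_concepts=excluded,
        blocked_names=blocked,
        synonym_groups=groups,
    )
    withheld = [
        (cid, s)
        for cid, s in withheld
        if cid not in excluded and lex.lookup(normalize_surface(s)) is None
    ]
    filler = _unique_words(rng, _FILLER_CONSONANTS, 40)
    return SyntheticLexicon(
        lexicon=lex,
        concept_records=concepts,
        semantic_whitelist=(ADR_SEMTYPE,),
        excluded_concepts=excluded,
        blocked_names=blocked,
        synonym_groups=groups,
        withheld=withheld,
        filler_words=filler,
    )


def safe_plant_names(lexicon: Lexicon) -> dict[str, str]:
    """concept_id -> a name safe to plant in text.

    A name is safe when its token sequence is not a proper prefix of any
    other dictionary key (so longest-match cannot reattribute it) and it
    belongs unambiguously to one concept.
    """
    keys = {k: cid for k, cid in lexicon.name_index.items()}
    token_keys = {tuple(k.split()): k for k in keys}
    out: dict[str, str] = {}
    for toks, key in sorted(token_keys.items()):
        prefix_of_other = any(
            other[: len(toks)] == toks and other != toks for other in token_keys
        )
        if prefix_of_other:
            continue
        cid = keys[key]
        out.setdefault(cid, key)
    return out


# ---------------------------------------------------------------------------
# Corpus generation

@dataclass
class GroundTruth:
    """Exactly what the pipeline should recover from a generated corpus."""

    mentions: set[tuple[str, str, int, int]] = field(default_factory=set)
    hedged_sentences: set[tuple[str, int]] = field(default_factory=set)
    relations: set[tuple[str, str, str]] = field(default_factory=set)  # (label, type, value)
    freq_records: set[tuple[str, str, str, float, float, str]] = field(default_factory=set)
    reject_tables: set[tuple[str, int]] = field(default_factory=set)
    planted_withheld: set[tuple[str, str]] = field(default_factory=set)  # (cid, surface)
    expected_indications: set[tuple[str, str, str, str]] = field(default_factory=set)
    expected_pairs: set[tuple[str, str]] = field(default_factory=set)
    # raw evidence sets, kept so tests can re-derive expected_pairs independently
    free_text_evidence: set[tuple[str, str, str]] = field(default_factory=set)  # (flat, label, cid)
    table_evidence: set[tuple[str, str, str]] = field(default_factory=set)
    # guaranteed filter-scope scenario instances: (flat, concept, kind)
    scenarios: dict[str, tuple[str, str]] = field(default_factory=dict)


@dataclass
class SyntheticCorpus:
    documents: dict[str, StyledDocument]
    triples: dict[str, dict[int, list[DependencyTriple]]]  # label -> sentence -> triples
    registry: Registry
    drug_lexicon: Lexicon
    lexicon: Lexicon
    truth: GroundTruth


class _LabelBuilder:
    def __init__(self, label_id: str) -> None:
        self.label_id = label_id
        self.spans: list[Span] = []
        self.pos = 0
        self.sentence_index = -1  # next sentence gets index + 1
        self.table_index = -1

    def add_raw(self, text: str, style: str) -> int:
        start = self.pos
        self.spans.append(Span(text, style))
        self.pos += len(text)
        return start

    def add_heading(self, text: str, style: str = "H1") -> None:
        self.add_raw(text + "\n", style)

    def add_sentence(self, parts: Sequence, style: str = "P") -> tuple[int, list]:
        """One sentence paragraph.  *parts* mixes strings and
        ("mention", cid, surface, entity_class) tuples; returns
        (sentence_index, [(cid, abs_start, abs_end, class), ...])."""
        self.sentence_index += 1
        text_parts: list[str] = []
        mention_offsets: list[tuple[str, int, int, str]] = []
        cursor = 0
        for part in parts:
            if isinstance(part, str):
                text_parts.append(part)
                cursor += len(part)
            else:
                _, cid, surface, cls = part
                text_parts.append(surface)
                mention_offsets.append((cid, cursor, cursor + len(surface), cls))
                cursor += len(surface)
        sentence = "".join(text_parts)
        start = self.add_raw(sentence + "\n", style)
        return (
            self.sentence_index,
            [(cid, start + s, start + e, cls) for cid, s, e, cls in mention_offsets],
        )

    def add_table(self, rows: Sequence[Sequence[str]]) -> int:
        self.table_index += 1
        for r, row in enumerate(rows):
            for c, cell in enumerate(row):
                start = self.pos
                span = Span(
                    cell + ("\t" if c < len(row) - 1 else "\n"),
                    "TD",
                    is_table_cell=True,
                    table_coords=(self.table_index, r, c),
                )
                self.spans.append(span)
                self.pos += len(span.text)
        return self.table_index

    def document(self) -> StyledDocument:
        return StyledDocument(self.label_id, self.spans)


def _indication_triples(cond_token: int = 9) -> list[DependencyTriple]:
    """Collapsed triples for "DRUG may be used for the treatment of COND"."""
    return [
        DependencyTriple("nsubjpass", ("used", 4), ("DRUG", 1)),
        DependencyTriple("aux", ("used", 4), ("may", 2)),
        DependencyTriple("auxpass", ("used", 4), ("be", 3)),
        DependencyTriple("root", ("ROOT", 0), ("used", 4)),
        DependencyTriple("det", ("treatment", 7), ("the", 6)),
        DependencyTriple("prep_for", ("used", 4), ("treatment", 7)),
        DependencyTriple("prep_of", ("treatment", 7), ("COND", cond_token)),
    ]


def _precondition_triples() -> list[DependencyTriple]:
    """Collapsed triples for "In patients with COND1, COND2 may occur"."""
    return [
        DependencyTriple("root", ("ROOT", 0), ("occur", 8)),
        DependencyTriple("prep_in", ("occur", 8), ("patients", 2)),
        DependencyTriple("prep_with", ("patients", 2), ("COND1", 4)),
        DependencyTriple("nsubj", ("occur", 8), ("COND2", 6)),
        DependencyTriple("aux", ("occur", 8), ("may", 7)),
    ]


def _combination_triples() -> list[DependencyTriple]:
    """Collapsed triples for "DRUG may be given in combination with DRUG2"."""
    return [
        DependencyTriple("nsubjpass", ("given", 4), ("DRUG", 1)),
        DependencyTriple("aux", ("given", 4), ("may", 2)),
        DependencyTriple("auxpass", ("given", 4), ("be", 3)),
        DependencyTriple("root", ("ROOT", 0), ("given", 4)),
        DependencyTriple("prep_in", ("given", 4), ("combination", 6)),
        DependencyTriple("prep_with", ("combination", 6), ("DRUG2", 8)),
    ]


def generate_label_corpus(
    seed: int,
    synthetic_lexicon: SyntheticLexicon,
    n_drugs: int = 20,
    labels_per_drug: int = 2,
    hedge_rate: float = 0.25,
    indication_overlap_rate: float = 0.3,
    decoy_tables: bool = True,
    n_plain_adrs: int = 2,
    force_scenarios: bool = True,
) -> SyntheticCorpus:
    """Generate a corpus of styled labels with complete ground truth.

    Guaranteed filter-scope scenario instances (when ``force_scenarios`` and
    the corpus is large enough): drug 0 exercises the sibling-label NER
    keep, drug 1 the same-label NER discard, drug 2 the table-evidence keep;
    every precondition sentence additionally exercises the any-label NLP
    discard.  Withheld permutation-only surfaces are planted in unmined
    (terminator) sections so dictionary expansion can be tested against the
    same corpus without perturbing the NER ground truth.
    """
    if synthetic_lexicon.lexicon.max_key_tokens == 0:
        raise ValueError("lexicon is empty")
    rng = random.Random(seed)
    lex = synthetic_lexicon.lexicon
    filler = synthetic_lexicon.filler_words
    plantable = safe_plant_names(lex)
    pool = sorted(plantable)
    if len(pool) < 8:
        raise ValueError("lexicon too small to plant a corpus")
    scenario_pool = pool[:6]  # reserved for the forced scenarios
    general_pool = pool[6:] or pool

    drug_names = [
        _word(rng, _DRUG_CONSONANTS, 3).capitalize() for _ in range(n_drugs)
    ]
    while len(set(drug_names)) < n_drugs:
        drug_names.append(_word(rng, _DRUG_CONSONANTS, 3).capitalize())
        drug_names = list(dict.fromkeys(drug_names))[:n_drugs]

    registry: Registry = {}
    drug_concepts: list[Concept] = []
    truth = GroundTruth()
    documents: dict[str, StyledDocument] = {}
    corpus_triples: dict[str, dict[int, list[DependencyTriple]]] = {}

    for d in range(n_drugs):
        flat = f"CIDm{d:05d}"
        stereo = f"CIDs{d:05d}"
        name = drug_names[d]
        drug_concepts.append(
            Concept(
                concept_id=flat,
                preferred_name=name,
                names=[name],
                semantic_types=["drug"],
            )
        )
        label_ids = [f"{flat}-L{j}" for j in range(labels_per_drug)]
        for label_id in label_ids:
            registry[label_id] = DrugRecord(flat, stereo, [name], label_ids)

    drug_lexicon = build_lexicon(drug_concepts, semantic_whitelist=["drug"])

    def fillers(n: int) -> list[str]:
        return [rng.choice(filler) for _ in range(n)]

    def sample(k: int) -> list[str]:
        return rng.sample(general_pool, k)

    for d in range(n_drugs):
        flat = f"CIDm{d:05d}"
        name = drug_names[d]
        label_ids = registry[next(l for l in registry if registry[l].flat_id == flat)].label_ids

        # per-drug concept casting
        picks = sample(min(8 + n_plain_adrs, len(general_pool)))
        it = iter(picks)
        cast = {
            "ind_nlp": next(it),
            "ind_ner": next(it),
            "precond": next(it),
            "adr_y": next(it),
            "plain": [next(it) for _ in range(n_plain_adrs)],
            "table": [next(it), next(it)],
            "decoy": next(it),
        }
        overlap_concept = None
        if force_scenarios and d == 0 and labels_per_drug >= 2:
            truth.scenarios["sibling_label_ner_keep"] = (flat, scenario_pool[0])
        elif force_scenarios and d == 1:
            truth.scenarios["same_label_ner_discard"] = (flat, scenario_pool[1])
        elif force_scenarios and d == 2:
            truth.scenarios["table_evidence_keep"] = (flat, scenario_pool[2])
        elif rng.random() < indication_overlap_rate:
            overlap_concept = cast["ind_ner"]
        truth.scenarios.setdefault("any_label_nlp_discard", (flat, cast["precond"]))

        for j, label_id in enumerate(label_ids):
            b = _LabelBuilder(label_id)
            label_triples: dict[int, list[DependencyTriple]] = {}

            def plant(cid: str) -> tuple:
                return ("mention", cid, plantable[cid], "condition")

            def record_mentions(offsets: Iterable[tuple[str, int, int, str]]) -> None:
                for cid, s, e, cls in offsets:
                    if cls == "condition":
                        truth.mentions.add((label_id, cid, s, e))

            # --- preamble (two sentences in one paragraph, no mentions)
            pre = (
                " ".join(fillers(3)).capitalize()
                + ". "
                + " ".join(fillers(4)).capitalize()
                + "."
            )
            b.sentence_index += 2
            b.add_raw(pre + "\n", "P")

            # --- indications section
            b.add_heading("INDICATIONS AND USAGE")

            # NLP indication sentence (worked construction) on the first label
            if j == 0:
                idx, offs = b.add_sentence(
                    [
                        ("mention", flat, name, "drug"),
                        " may be used for the treatment of ",
                        plant(cast["ind_nlp"]),
                        ".",
                    ]
                )
                record_mentions(offs)
                label_triples[idx] = _indication_triples()
                truth.relations.add((label_id, "indication", cast["ind_nlp"]))
                truth.expected_indications.add(
                    (flat, cast["ind_nlp"], NLP_INDICATION, label_id)
                )
                truth.expected_indications.add(
                    (flat, cast["ind_nlp"], NER_INDICATION_SECTION, label_id)
                )

            # NER-only indication mention
            ner_ind = cast["ind_ner"]
            if force_scenarios and d == 0 and labels_per_drug >= 2:
                # sibling-keep: the scenario concept is an indication on L1 only
                ner_ind = scenario_pool[0] if j == 1 else cast["ind_ner"]
            if force_scenarios and d == 1:
                ner_ind = scenario_pool[1]
            if force_scenarios and d == 2:
                ner_ind = scenario_pool[2]
            _, offs = b.add_sentence(
                [
                    " ".join(fillers(2)).capitalize() + " ",
                    plant(ner_ind),
                    " " + " ".join(fillers(2)) + ".",
                ]
            )
            record_mentions(offs)
            truth.expected_indications.add(
                (flat, ner_ind, NER_INDICATION_SECTION, label_id)
            )

            # drug combination sentence on the first label of even drugs
            partner = drug_names[(d + 1) % n_drugs]
            partner_flat = f"CIDm{(d + 1) % n_drugs:05d}"
            if j == 0 and d % 2 == 0 and n_drugs > 1:
                idx, offs = b.add_sentence(
                    [
                        ("mention", flat, name, "drug"),
                        " may be given in combination with ",
                        ("mention", partner_flat, partner, "drug"),
                        ".",
                    ]
                )
                record_mentions(offs)
                label_triples[idx] = _combination_triples()
                truth.relations.add((label_id, "combination", partner_flat))

            # --- adverse reactions section (heading carries an SPL number)
            b.add_heading("6 ADVERSE REACTIONS")

            # precondition sentence (any-label NLP discard for COND1)
            if j == 0:
                idx, offs = b.add_sentence(
                    [
                        "In patients with ",
                        plant(cast["precond"]),
                        ", ",
                        plant(cast["adr_y"]),
                        " may occur.",
                    ]
                )
                record_mentions(offs)
                label_triples[idx] = _precondition_triples()
                truth.relations.add((label_id, "precondition", cast["precond"]))
                truth.expected_indications.add(
                    (flat, cast["precond"], NLP_PRECONDITION, label_id)
                )
                truth.free_text_evidence.add((flat, label_id, cast["precond"]))
                truth.free_text_evidence.add((flat, label_id, cast["adr_y"]))

            # plain free-text ADR sentences, some hedged
            for cid in cast["plain"]:
                if rng.random() < hedge_rate:
                    surface = plantable[cid]
                    _, offs = b.add_sentence(
                        [
                            ("mention", cid, surface.capitalize(), "condition"),
                            " has not been observed.",
                        ]
                    )
                    record_mentions(offs)
                    truth.hedged_sentences.add((label_id, b.sentence_index))
                elif rng.random() < 0.15:
                    _, offs = b.add_sentence(
                        ["A causal role of ", plant(cid), " is suspected."]
                    )
                    record_mentions(offs)
                    truth.hedged_sentences.add((label_id, b.sentence_index))
                else:
                    _, offs = b.add_sentence(
                        [
                            " ".join(fillers(2)).capitalize() + " ",
                            plant(cid),
                            " " + " ".join(fillers(1)) + ".",
                        ]
                    )
                    record_mentions(offs)
                    truth.free_text_evidence.add((flat, label_id, cid))

            # same-label overlap planting: indication concept in ADR free text
            overlap_here = None
            if force_scenarios and d == 1:
                overlap_here = scenario_pool[1]
            elif force_scenarios and d == 0 and labels_per_drug >= 2 and j == 0:
                # sibling-keep: free text on L0, NER indication only on L1
                overlap_here = scenario_pool[0]
            elif overlap_concept is not None:
                overlap_here = overlap_concept
            if overlap_here is not None:
                _, offs = b.add_sentence(
                    [
                        " ".join(fillers(2)).capitalize() + " ",
                        plant(overlap_here),
                        " " + " ".join(fillers(2)) + ".",
                    ]
                )
                record_mentions(offs)
                truth.free_text_evidence.add((flat, label_id, overlap_here))

            # free-text frequency, pattern B (parenthesized percentage);
            # under hedging the evidence turns into a hedged sentence instead
            freq_cid = cast["plain"][0]
            pct = rng.choice([5, 8, 12, 23])
            if rng.random() < hedge_rate:
                _, offs = b.add_sentence(
                    [
                        ("mention", freq_cid, plantable[freq_cid].capitalize(), "condition"),
                        " has not been observed.",
                    ]
                )
                record_mentions(offs)
                truth.hedged_sentences.add((label_id, b.sentence_index))
            else:
                _, offs = b.add_sentence(
                    [
                        ("mention", freq_cid, plantable[freq_cid].capitalize(), "condition"),
                        f" ({pct}%) ",
                        " ".join(fillers(2)) + ".",
                    ]
                )
                record_mentions(offs)
                truth.free_text_evidence.add((flat, label_id, freq_cid))
                truth.freq_records.add(
                    (label_id, freq_cid, "drug", pct / 100, pct / 100, "text")
                )

            # free-text frequency, pattern A (descriptor list)
            da, db = cast["plain"][-1], cast["adr_y"]
            if rng.random() < hedge_rate:
                _, offs = b.add_sentence(
                    [
                        ("mention", da, plantable[da].capitalize(), "condition"),
                        " and ",
                        plant(db),
                        " have not been observed.",
                    ]
                )
                record_mentions(offs)
                truth.hedged_sentences.add((label_id, b.sentence_index))
            else:
                _, offs = b.add_sentence(
                    ["Frequent: ", plant(da), ", ", plant(db), "."]
                )
                record_mentions(offs)
                for cid in (da, db):
                    truth.free_text_evidence.add((flat, label_id, cid))
                    truth.freq_records.add((label_id, cid, "drug", 0.01, 0.10, "text"))

            # frequency table (drug + placebo arms); adr_y is always
            # tabulated so every drug retains at least one table-backed pair
            table_cids = list(cast["table"]) + [cast["adr_y"]]
            if force_scenarios and d == 2 and j == 0:
                table_cids[0] = scenario_pool[2]  # table-keep scenario concept
            rows: list[list[str]] = [["Adverse event", f"{name} 50 mg", "Placebo"]]
            for cid in table_cids:
                p_drug = rng.randint(2, 30)
                p_plac = rng.randint(0, p_drug)
                rows.append([plantable[cid], f"{p_drug}%", f"{p_plac}%"])
                truth.table_evidence.add((flat, label_id, cid))
                truth.freq_records.add(
                    (label_id, cid, "drug", p_drug / 100, p_drug / 100, "table")
                )
                truth.freq_records.add(
                    (label_id, cid, "placebo", p_plac / 100, p_plac / 100, "table")
                )
            b.add_table(rows)

            # decoy table that the classifier must reject
            if decoy_tables:
                decoy_rows = [
                    ["Adverse event", "Discontinuation due to adverse events"],
                    [plantable[cast["decoy"]], f"{rng.randint(1, 9)}%"],
                ]
                t_idx = b.add_table(decoy_rows)
                truth.reject_tables.add((label_id, t_idx))

            # terminator section: content here must never be mined
            b.add_heading("Interactions with other drugs")
            b.add_sentence(
                [
                    " ".join(fillers(2)).capitalize() + " ",
                    plant(cast["plain"][0]),  # planted but OUT of scope
                    " " + " ".join(fillers(1)) + ".",
                ]
            )
            # withheld permutation-only surface, recoverable by expansion
            if synthetic_lexicon.withheld:
                w_cid, w_surface = synthetic_lexicon.withheld[
                    rng.randrange(len(synthetic_lexicon.withheld))
                ]
                b.add_sentence(
                    [
                        " ".join(fillers(1)).capitalize() + " ",
                        w_surface,
                        " " + " ".join(fillers(1)) + ".",
                    ]
                )
                truth.planted_withheld.add((w_cid, w_surface))

            documents[label_id] = b.document()
            corpus_triples[label_id] = label_triples

    _derive_expected(truth)
    return SyntheticCorpus(
        documents=documents,
        triples=corpus_triples,
        registry=registry,
        drug_lexicon=drug_lexicon,
        lexicon=lex,
        truth=truth,
    )


def _derive_expected(truth: GroundTruth) -> None:
    """Expected final pairs from the planted evidence + filter semantics."""
    nlp_any = {
        (flat, cid)
        for flat, cid, method, _ in truth.expected_indications
        if method in (NLP_INDICATION, NLP_PRECONDITION)
    }
    ner_same = {
        (label, cid)
        for _, cid, method, label in truth.expected_indications
        if method == NER_INDICATION_SECTION
    }
    pairs: set[tuple[str, str]] = set()
    for flat, label, cid in truth.free_text_evidence:
        if (flat, cid) in nlp_any or (label, cid) in ner_same:
            continue
        pairs.add((flat, cid))
    for flat, _label, cid in truth.table_evidence:
        pairs.add((flat, cid))
    truth.expected_pairs = pairs


# ---------------------------------------------------------------------------
# Scoring

@dataclass
class Score:
    precision: float
    recall: float
    false_positives: list
    false_negatives: list


def _score_sets(extracted: set, expected: set) -> Score:
    fp = sorted(extracted - expected)
    fn = sorted(expected - extracted)
    if not extracted:
        if expected:
            logger.warning("empty extraction against %d expected items", len(expected))
        precision = 1.0  # degenerate convention
    else:
        precision = (len(extracted) - len(fp)) / len(extracted)
    recall = 1.0 if not expected else (len(expected) - len(fn)) / len(expected)
    return Score(precision, recall, fp, fn)


def score_extraction(
    truth: GroundTruth,
    mentions: set[tuple[str, str, int, int]] | None = None,
    indications: set[tuple[str, str, str, str]] | None = None,
    pairs: set[tuple[str, str]] | None = None,
    relations: set[tuple[str, str, str]] | None = None,
) -> dict[str, Score]:
    """Exact-match precision/recall per artifact kind."""
    out: dict[str, Score] = {}
    if mentions is not None:
        out["mentions"] = _score_sets(mentions, truth.mentions)
    if indications is not None:
        out["indications"] = _score_sets(indications, truth.expected_indications)
    if pairs is not None:
        out["pairs"] = _score_sets(pairs, truth.expected_pairs)
    if relations is not None:
        out["relations"] = _score_sets(relations, truth.relations)
    return out
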