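"""Dictionary NER with orthographic variation and hedge suppression.

Matching is longest-match, left-to-right, anchored at word-token boundaries.
Orthographic variation covers case and insertion/removal of hyphens and
spaces: candidate substrings are compared to dictionary keys after
normalization, and again after removing separators entirely, so
"X-linked" == "X linked" and "bloodpressure" == "blood pressure".

Sentences in the adverse-reactions section that contain a negation cue
("has not been observed") or a speculation cue ("is suspected") do not
support ADR evidence; their mentions are flagged suppressed rather than
deleted, so that highlighted output can still show them with the reason.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from ._util import normalize_surface, word_spans
from .config import ADVERSE_REACTIONS, MinerConfig
from .label_ingest import Section, Sentence
from .lexicon import Lexicon

__all__ = ["Mention", "normalize_surface", "find_mentions", "match_text", "filter_hedged_sentences"]

HEDGED_SENTENCE = "hedged_sentence"
BLOCKED = "blocked"
INDICATION_FILTER = "indication_filter"


@dataclass
class Mention:
    label_id: str
    section_kind: str
    sentence_index: int
    char_start: int
    char_end: int
    surface: str
    concept_id: str
    entity_class: str = "condition"  # condition | drug
    suppressed: bool = False
    suppression_reason: str | None = None

    def suppress(self, reason: str) -> None:
        self.suppressed = True
        self.suppression_reason = reason

    @property
    def key(self) -> tuple[str, str, int, int]:
        return (self.label_id, self.concept_id, self.char_start, self.char_end)


def match_text(text: str, lexicon: Lexicon) -> list[tuple[int, int, str]]:
    """Longest-match left-to-right dictionary scan of a raw string.

    Returns (start, end, concept_id) triples with offsets into *text*.
    Matches start and end at word-token boundaries and never overlap.
    """
    spans = word_spans(text)
    out: list[tuple[int, int, str]] = []
    i = 0
    n = len(spans)
    max_tokens = max(lexicon.max_key_tokens, 1)
    while i < n:
        hit = None
        for j in range(min(n, i + max_tokens) - 1, i - 1, -1):
            candidate = text[spans[i][0] : spans[j][1]]
            cid = lexicon.lookup(normalize_surface(candidate))
            if cid is not None:
                hit = (spans[i][0], spans[j][1], cid, j)
                break
        if hit is None:
            i += 1
        else:
            out.append(hit[:3])
            i = hit[3] + 1
    return out


def find_mentions(
    section: Section,
    lexicon: Lexicon,
    label_id: str,
    entity_class: str = "condition",
) -> list[Mention]:
    """Scan every sentence of a section for dictionary mentions."""
    mentions: list[Mention] = []
    for para in section.paragraphs:
        for sent in para.sentences:
            for start, end, cid in match_text(sent.text, lexicon):
                mentions.append(
                    Mention(
                        label_id=label_id,
                        section_kind=section.kind,
                        sentence_index=sent.index,
                        char_start=sent.char_start + start,
                        char_end=sent.char_start + end,
                        surface=sent.text[start:end],
                        concept_id=cid,
                        entity_class=entity_class,
                    )
                )
    return mentions


def filter_hedged_sentences(
    mentions: Iterable[Mention],
    sentences: Sequence[Sentence] | dict[int, Sentence],
    config: MinerConfig = MinerConfig(),
) -> list[Mention]:
    """Suppress mentions in hedged (negated/speculative) ADR-section sentences.

    The whole sentence is the hedge scope; cue matching is normalized
    substring containment.  Mention count is preserved — only flags change.
    """
    if not isinstance(sentences, dict):
        sentences = {s.index: s for s in sentences}
    cues = [normalize_surface(c) for c in config.hedge_cues]
    hedged: dict[int, bool] = {}
    out = list(mentions)
    for mention in out:
        if mention.section_kind != ADVERSE_REACTIONS:
            continue
        idx = mention.sentence_index
        if idx not in hedged:
            sent = sentences.get(idx)
            norm = normalize_surface(sent.text) if sent is not None else ""
            hedged[idx] = any(cue in norm for cue in cues)
        if hedged[idx]:
            mention.suppress(HEDGED_SENTENCE)
    return out


def hedged_sentence_indices(
    sentences: Iterable[Sentence], config: MinerConfig = MinerConfig()
) -> set[int]:
    """Indices of sentences containing any hedge cue (for reporting)."""
    cues = [normalize_surface(c) for c in config.hedge_cues]
    return {
        s.index
        for s in sentences
        if any(cue in normalize_surface(s.text) for cue in cues)
    }
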