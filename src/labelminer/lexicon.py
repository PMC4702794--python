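"""Concept dictionary construction and word-permutation expansion.

The dictionary pools every name of every medical concept (UMLS-CUI-like ids
with MedDRA-style codes), filtered to a semantic-type whitelist, minus a
manually curated concept exclusion list (concepts of the right semantic type
that are not adverse reactions, e.g. "HIV positive") and a blocked-name list
(surfaces too ambiguous to match safely).

Because source vocabularies rarely list every word-order permutation of a
name ("blood pressure decreased" vs "decreased blood pressure") or every
common word swap ("decreased"/"lower"), the expansion step pools each
concept's name words, augments them with configured synonym words, scans the
corpus for token runs that are permutations of an existing name under those
substitutions, and queues the most frequent novel surfaces for curation.
Only explicitly accepted candidates enter the dictionary.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from ._util import normalize_surface, squash, word_tokens
from .config import DEFAULT_BAG_STOPWORDS

logger = logging.getLogger(__name__)


@dataclass
class Concept:
    concept_id: str
    preferred_name: str
    names: list[str]
    semantic_types: list[str]
    meddra_code: str | None = None
    level: str = "unknown"  # PT | LLT | unknown

    def __post_init__(self) -> None:
        if not self.names:
            raise ValueError(f"concept {self.concept_id} has no names")
        if self.preferred_name not in self.names:
            self.names.insert(0, self.preferred_name)


@dataclass
class Lexicon:
    concepts: dict[str, Concept] = field(default_factory=dict)
    excluded_concepts: set[str] = field(default_factory=set)
    blocked_names: set[str] = field(default_factory=set)  # normalized
    synonym_groups: list[frozenset[str]] = field(default_factory=list)
    name_index: dict[str, str] = field(default_factory=dict)  # norm name -> cid
    squash_index: dict[str, str] = field(default_factory=dict)  # squashed -> cid
    max_key_tokens: int = 0

    def term_of(self, concept_id: str) -> str:
        return self.concepts[concept_id].preferred_name

    def lookup(self, candidate: str) -> str | None:
        """Resolve a normalized candidate surface to a concept id.

        Falls back to the separator-free form so that "bloodpressure"
        matches "blood pressure" and vice versa (orthographic variation).
        """
        cid = self.name_index.get(candidate)
        if cid is not None:
            return cid
        return self.squash_index.get(squash(candidate))

    def copy(self) -> "Lexicon":
        return Lexicon(
            concepts={
                cid: replace(c, names=list(c.names), semantic_types=list(c.semantic_types))
                for cid, c in self.concepts.items()
            },
            excluded_concepts=set(self.excluded_concepts),
            blocked_names=set(self.blocked_names),
            synonym_groups=list(self.synonym_groups),
            name_index=dict(self.name_index),
            squash_index=dict(self.squash_index),
            max_key_tokens=self.max_key_tokens,
        )


@dataclass
class CandidateName:
    concept_id: str
    surface: str
    corpus_count: int
    status: str = "pending"  # pending | accepted | rejected


def build_lexicon(
    concept_records: Iterable[Concept],
    semantic_whitelist: Iterable[str],
    excluded_concepts: Iterable[str] = (),
    blocked_names: Iterable[str] = (),
    synonym_groups: Iterable[Iterable[str]] = (),
) -> Lexicon:
    """Assemble the searchable dictionary.

    Concepts with no whitelisted semantic type are dropped entirely;
    excluded concepts stay in the concept map but contribute no searchable
    names; blocked names never enter the index.  A surface claimed by two
    concepts is ambiguous and is auto-blocked (fail safe, logged).
    """
    whitelist = set(semantic_whitelist)
    if not whitelist:
        raise ValueError("semantic whitelist must be non-empty")
    lex = Lexicon(
        excluded_concepts=set(excluded_concepts),
        blocked_names={normalize_surface(b) for b in blocked_names},
        synonym_groups=[frozenset(w.casefold() for w in g) for g in synonym_groups],
    )
    for concept in concept_records:
        if concept.concept_id in lex.concepts:
            raise ValueError(f"duplicate concept id: {concept.concept_id}")
        if not set(concept.semantic_types) & whitelist:
            continue
        lex.concepts[concept.concept_id] = concept
    for cid, concept in lex.concepts.items():
        if cid in lex.excluded_concepts:
            continue
        for name in concept.names:
            _index_name(lex, cid, name)
    _rebuild_squash_index(lex)
    return lex


def _index_name(lex: Lexicon, cid: str, name: str) -> None:
    key = normalize_surface(name)
    if not key or key in lex.blocked_names:
        return
    owner = lex.name_index.get(key)
    if owner is not None and owner != cid:
        logger.warning(
            "ambiguous name %r claimed by %s and %s: auto-blocked", key, owner, cid
        )
        del lex.name_index[key]
        lex.blocked_names.add(key)
        return
    lex.name_index[key] = cid
    lex.max_key_tokens = max(lex.max_key_tokens, len(key.split(" ")))


def _rebuild_squash_index(lex: Lexicon) -> None:
    lex.squash_index = {}
    dropped: set[str] = set()
    for key, cid in lex.name_index.items():
        sq = squash(key)
        other = lex.squash_index.get(sq)
        if other is not None and other != cid:
            dropped.add(sq)
            continue
        lex.squash_index[sq] = cid
    for sq in dropped:
        logger.warning("squashed form %r ambiguous across concepts: dropped", sq)
        lex.squash_index.pop(sq, None)


def _group_representative(lex: Lexicon) -> dict[str, str]:
    """word -> canonical representative of its synonym group (min in group)."""
    rep: dict[str, str] = {}
    for group in lex.synonym_groups:
        canon = min(group)
        for word in group:
            rep[word] = canon
    return rep


def _bag(tokens: Sequence[str], rep: dict[str, str], stopwords: frozenset[str]) -> frozenset:
    counts = Counter(
        rep.get(t, t) for t in tokens if len(t) > 1 and t not in stopwords
    )
    return frozenset(counts.items())


def generate_candidate_names(
    lexicon: Lexicon,
    corpus_sentences: Iterable[str],
    stopwords: frozenset[str] = DEFAULT_BAG_STOPWORDS,
) -> list[CandidateName]:
    """Scan a corpus for word-permutation variants of known names.

    A token run qualifies as a candidate for a concept when it has the same
    raw token count as one of the concept's names and, after substituting
    each word by its synonym-group representative and dropping stopwords and
    single-character tokens, the same word multiset.  Surfaces already in the
    dictionary are never emitted.  Output is sorted by corpus count, most
    frequent first (the manual-review order).
    """
    if not lexicon.concepts:
        raise ValueError("lexicon has no concepts")
    rep = _group_representative(lexicon)
    # (token_count, bag) -> concept ids
    targets: dict[tuple[int, frozenset], set[str]] = {}
    for cid, concept in lexicon.concepts.items():
        if cid in lexicon.excluded_concepts:
            continue
        for name in concept.names:
            toks = word_tokens(name)
            if not toks:
                continue
            targets.setdefault((len(toks), _bag(toks, rep, stopwords)), set()).add(cid)
    window_sizes = sorted({k for k, _ in targets})

    counts: Counter[tuple[str, str]] = Counter()
    for sentence in corpus_sentences:
        toks = word_tokens(sentence)
        for k in window_sizes:
            for i in range(len(toks) - k + 1):
                window = toks[i : i + k]
                hit = targets.get((k, _bag(window, rep, stopwords)))
                if not hit:
                    continue
                surface = " ".join(window)
                if lexicon.lookup(normalize_surface(surface)) is not None:
                    continue
                for cid in hit:
                    counts[(cid, surface)] += 1

    out = [
        CandidateName(cid, surface, n)
        for (cid, surface), n in counts.items()
    ]
    out.sort(key=lambda c: (-c.corpus_count, c.concept_id, c.surface))
    return out


def review_queue(
    candidates: Sequence[CandidateName], min_review_count: int = 100
) -> list[CandidateName]:
    """Candidates frequent enough to warrant manual annotation."""
    return [c for c in candidates if c.corpus_count >= min_review_count]


def curate_candidates(
    lexicon: Lexicon,
    candidates: Sequence[CandidateName],
    accept_list: Iterable[str],
) -> Lexicon:
    """Fold accepted candidate surfaces into the dictionary (append-only).

    Surfaces not offered as candidates, or blocked, raise; everything else
    leaves the lexicon untouched.  Idempotent and order-insensitive.
    """
    accepted = set(accept_list)
    offered = {c.surface for c in candidates}
    unknown = accepted - offered
    if unknown:
        raise ValueError(f"accept list contains non-candidate surfaces: {sorted(unknown)}")
    out = lexicon.copy()
    for cand in candidates:
        if cand.surface not in accepted:
            continue
        key = normalize_surface(cand.surface)
        if key in out.blocked_names:
            raise ValueError(f"surface {cand.surface!r} is blocked")
        concept = out.concepts[cand.concept_id]
        if cand.surface not in concept.names:
            concept.names.append(cand.surface)
        _index_name(out, cand.concept_id, cand.surface)
    _rebuild_squash_index(out)
    return out
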