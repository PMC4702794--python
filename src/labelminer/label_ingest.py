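"""Styled-label parsing: heading-style inference, section segmentation, tables.

Drug labels converted from PDF lose their logical structure; what survives is
a flat sequence of text spans, each carrying an opaque style identifier.  The
heuristic recovery implemented here searches for known section-heading
wordings ("indications and usage", "adverse reactions", ...) to learn which
styles mark headings, then segments the document into typed sections at every
heading-styled span.  Structured (SPL XML) labels bypass the inference: their
LOINC section codes map directly onto section kinds.

All character offsets are 0-based, half-open, into the concatenated span
text, so that every downstream artifact (mentions, highlighted HTML) can be
traced back to an exact slice of the original document.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator

from .config import ADVERSE_REACTIONS, INDICATIONS, OTHER, TERMINATOR, MinerConfig

_DIGIT_DOT_RE = re.compile(r"[\d.]+")
_WS_RE = re.compile(r"\s+")
_CAPTION_RE = re.compile(r"^\s*table\b", re.IGNORECASE)


@dataclass(frozen=True)
class Span:
    """One styled run of text; the atomic unit of the input format."""

    text: str
    style_id: str
    is_table_cell: bool = False
    table_coords: tuple[int, int, int] | None = None  # (table, row, col)

    def __post_init__(self) -> None:
        if self.is_table_cell != (self.table_coords is not None):
            raise ValueError("table_coords must be present iff is_table_cell")


@dataclass
class StyledDocument:
    label_id: str
    spans: list[Span]

    @property
    def text(self) -> str:
        return "".join(s.text for s in self.spans)


@dataclass
class Sentence:
    text: str
    char_start: int
    char_end: int
    index: int = -1  # global index within the label, assigned by ingest()


@dataclass
class Paragraph:
    text: str
    char_start: int
    char_end: int
    sentences: list[Sentence] = field(default_factory=list)


@dataclass
class TableBlock:
    header_rows: list[list[str]]
    body_rows: list[list[str]]
    n_cols: int
    caption: str = ""
    index: int = 0  # table index within the label, for provenance

    @property
    def has_header(self) -> bool:
        return bool(self.header_rows)


@dataclass
class Section:
    kind: str
    heading_text: str
    char_start: int
    char_end: int
    paragraphs: list[Paragraph] = field(default_factory=list)
    tables: list[TableBlock] = field(default_factory=list)


@dataclass
class IngestedLabel:
    """A fully segmented label: the unit consumed by every later stage."""

    label_id: str
    text: str
    sections: list[Section]

    def sentences(self) -> Iterator[tuple[Section, Sentence]]:
        for section in self.sections:
            for para in section.paragraphs:
                for sent in para.sentences:
                    yield section, sent

    def mined_sections(self) -> Iterator[Section]:
        """Sections subject to NER/NLP (indications and adverse reactions)."""
        for section in self.sections:
            if section.kind in (INDICATIONS, ADVERSE_REACTIONS):
                yield section


def normalize_heading(text: str) -> str:
    """Casefold, drop digits/dots (SPL numbering), collapse whitespace."""
    return _WS_RE.sub(" ", _DIGIT_DOT_RE.sub(" ", text.casefold())).strip()


def infer_heading_styles(
    doc: StyledDocument, heading_phrases: Iterable[str]
) -> set[str]:
    """Styles of spans whose normalized text equals a known heading wording.

    Returns the empty set when nothing matches; callers then fall back to
    phrase-only segmentation.
    """
    phrases = {normalize_heading(p) for p in heading_phrases}
    phrases.discard("")
    styles: set[str] = set()
    for span in doc.spans:
        if span.is_table_cell:
            continue
        if normalize_heading(span.text) in phrases:
            styles.add(span.style_id)
    return styles


def classify_heading(heading_text: str, config: MinerConfig) -> str:
    key = normalize_heading(heading_text)
    if not key:
        return OTHER
    if key in {normalize_heading(p) for p in config.indication_headings}:
        return INDICATIONS
    if key in {normalize_heading(p) for p in config.adr_headings}:
        return ADVERSE_REACTIONS
    if key in {normalize_heading(p) for p in config.terminator_headings}:
        return TERMINATOR
    return OTHER


def split_sentences(
    text: str, abbreviations: Iterable[str] = ()
) -> list[tuple[int, int]]:
    """(start, end) sentence offsets within *text*.

    A sentence ends at [.!?] followed by whitespace and an upper-case letter,
    digit or quote, unless the period terminates a stoplisted abbreviation.
    """
    abbr = {a.casefold() for a in abbreviations}
    spans: list[tuple[int, int]] = []
    start = 0
    i = 0
    n = len(text)
    while i < n:
        ch = text[i]
        if ch in ".!?":
            # scan past closing quotes/brackets
            j = i + 1
            while j < n and text[j] in ")\"'”’]":
                j += 1
            if j < n and text[j].isspace():
                k = j
                while k < n and text[k].isspace():
                    k += 1
                if k < n and (text[k].isupper() or text[k].isdigit() or text[k] in "\"'“‘("):
                    if ch == "." and _ends_with_abbreviation(text, i, abbr):
                        i += 1
                        continue
                    spans.append((start, j))
                    start = k
                    i = k
                    continue
        i += 1
    if start < n and text[start:].strip():
        spans.append((start, n))
    # trim whitespace from sentence edges
    out = []
    for s, e in spans:
        while s < e and text[s].isspace():
            s += 1
        while e > s and text[e - 1].isspace():
            e -= 1
        if s < e:
            out.append((s, e))
    return out


def _ends_with_abbreviation(text: str, dot_index: int, abbreviations: set[str]) -> bool:
    prefix = text[: dot_index + 1].casefold()
    return any(prefix.endswith(a) for a in abbreviations)


def _is_heading_span(span: Span, heading_styles: set[str], config: MinerConfig) -> bool:
    if span.is_table_cell:
        return False
    if heading_styles:
        return span.style_id in heading_styles
    # Fallback for degraded documents with no inferable heading style:
    # a span that exactly equals a configured wording acts as a heading.
    return normalize_heading(span.text) in {
        normalize_heading(p) for p in config.heading_phrases
    }


def segment_sections(
    doc: StyledDocument,
    heading_styles: set[str],
    config: MinerConfig = MinerConfig(),
) -> list[Section]:
    """Split the document at heading-styled spans into typed sections.

    Subsection headings (kind ``other``) inside an open indications/ADR
    section do not close it; indications/ADR/terminator headings always
    start a new section.  Text before the first heading becomes a heading-less
    ``other`` section so that offsets remain lossless.
    """
    if not doc.spans:
        return []

    # Pass 1: split the span stream into (heading, content-spans) groups.
    sections: list[Section] = []
    pos = 0
    current: Section | None = None
    content: list[tuple[int, Span]] = []  # (abs offset, span) of current section

    def flush(end: int) -> None:
        nonlocal current, content
        if current is None:
            if content:
                pre = Section(OTHER, "", content[0][0], end)
                _fill_section(pre, content, doc, config)
                sections.append(pre)
        else:
            current.char_end = end
            _fill_section(current, content, doc, config)
            sections.append(current)
        content = []

    for span in doc.spans:
        span_start = pos
        pos += len(span.text)
        if _is_heading_span(span, heading_styles, config):
            kind = classify_heading(span.text, config)
            absorb = (
                kind == OTHER
                and current is not None
                and current.kind in (INDICATIONS, ADVERSE_REACTIONS)
            )
            if absorb:
                # subsection heading: its text stays inside the open section
                content.append((span_start, span))
                continue
            flush(span_start)
            current = Section(kind, span.text.strip(), span_start, span_start)
            continue
        content.append((span_start, span))
    flush(pos)
    return sections


def _fill_section(
    section: Section,
    content: list[tuple[int, Span]],
    doc: StyledDocument,
    config: MinerConfig,
) -> None:
    """Build paragraphs (sentence-split) and tables from a section's spans."""
    # group table cells by table index
    cells: dict[int, dict[tuple[int, int], str]] = {}
    text_runs: list[tuple[int, str]] = []  # (abs offset, text) for non-table spans
    for offset, span in content:
        if span.is_table_cell:
            t, r, c = span.table_coords  # type: ignore[misc]
            cells.setdefault(t, {})[(r, c)] = span.text.strip()
        else:
            text_runs.append((offset, span.text))

    # paragraphs: merge adjacent text runs, split on newlines
    paragraphs: list[Paragraph] = []
    merged: list[tuple[int, str]] = []
    for offset, text in text_runs:
        if merged and merged[-1][0] + len(merged[-1][1]) == offset:
            merged[-1] = (merged[-1][0], merged[-1][1] + text)
        else:
            merged.append((offset, text))
    for offset, blob in merged:
        for m in re.finditer(r"[^\n]+", blob):
            raw = m.group(0)
            if not raw.strip():
                continue
            lead = len(raw) - len(raw.lstrip())
            trail = len(raw) - len(raw.rstrip())
            p_start = offset + m.start() + lead
            p_text = raw.strip()
            para = Paragraph(p_text, p_start, p_start + len(p_text))
            for s, e in split_sentences(p_text, config.abbreviations):
                para.sentences.append(
                    Sentence(p_text[s:e], p_start + s, p_start + e)
                )
            paragraphs.append(para)
    section.paragraphs = paragraphs

    # tables: first row is the header row; rows padded to rectangular shape
    for t_idx in sorted(cells):
        grid = cells[t_idx]
        n_rows = max(r for r, _ in grid) + 1
        n_cols = max(c for _, c in grid) + 1
        rows = [[grid.get((r, c), "") for c in range(n_cols)] for r in range(n_rows)]
        caption = ""
        for para in paragraphs:
            if _CAPTION_RE.match(para.text):
                caption = para.text
        table = TableBlock(
            header_rows=rows[:1],
            body_rows=rows[1:],
            n_cols=n_cols,
            caption=caption,
            index=t_idx,
        )
        section.tables.append(table)


def ingest(doc: StyledDocument, config: MinerConfig = MinerConfig()) -> IngestedLabel:
    """Full ingest: infer heading styles, segment, assign sentence indices."""
    styles = infer_heading_styles(doc, config.heading_phrases)
    sections = segment_sections(doc, styles, config)
    index = 0
    for section in sections:
        for para in section.paragraphs:
            for sent in para.sentences:
                sent.index = index
                index += 1
    return IngestedLabel(doc.label_id, doc.text, sections)
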