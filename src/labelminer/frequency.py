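"""ADR frequency extraction from tables and free text.

Tables: the header row decides which columns report drug-arm and which
placebo-arm frequencies; tables about anything other than ADR frequencies
(discontinuation counts, demographics, ...) are rejected outright.

Free text: two patterns, a descriptor list ("frequent: headache, fatigue")
and a parenthesized percentage immediately after a term ("headache (12%)").
Free-text frequencies are attributed to the drug arm — labels report placebo
rates in tables, not prose.

Displays are normalized to closed fractional intervals [lower, upper] of 1;
"12%" becomes (0.12, 0.12), descriptors map through a shipped CIOMS-style
convention table ("frequent" -> (0.01, 0.10)) that can be overridden.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Sequence

from ._util import normalize_surface
from .config import MinerConfig
from .label_ingest import Sentence, TableBlock
from .lexicon import Lexicon
from .ner import Mention, match_text

logger = logging.getLogger(__name__)

DRUG_ARM = "drug"
PLACEBO_ARM = "placebo"
IGNORE = "ignore"
REJECT = "REJECT"  # classify_table verdict for non-frequency tables

_PCT_RE = re.compile(
    r"^\s*([<>≤≥]?)\s*(\d+(?:\.\d+)?)\s*(?:[-–—~]\s*(\d+(?:\.\d+)?))?\s*%\s*$"
)
_RATIO_RE = re.compile(r"^\s*(\d+)\s*/\s*([1-9]\d*)\s*$")
_DOSE_RE = re.compile(r"\d+(?:\.\d+)?\s*(?:mg|mcg|µg|g\b|ml|units?|iu)", re.IGNORECASE)
_PAREN_RE = re.compile(r"\s*\(([^()]{1,40})\)")


@dataclass
class FrequencyRecord:
    concept_id: str
    arm: str  # drug | placebo
    freq_lower: float | None
    freq_upper: float | None
    display: str
    source: str  # table | text
    label_id: str = ""
    locator: str = ""  # "table:<idx>" or "sentence:<idx>"

    def __post_init__(self) -> None:
        if not self.display:
            raise ValueError("display must be non-empty")
        if self.freq_lower is not None and self.freq_upper is not None:
            if not 0 <= self.freq_lower <= self.freq_upper <= 1:
                raise ValueError(
                    f"bad interval ({self.freq_lower}, {self.freq_upper}) for {self.display!r}"
                )

    @property
    def interval(self) -> tuple[float | None, float | None]:
        return (self.freq_lower, self.freq_upper)


def normalize_frequency(
    display: str, descriptor_map: dict[str, tuple[float, float]] | None = None
) -> tuple[float, float] | None:
    """Numeric interval for a frequency display string, or None if unknown.

    Handles "N%", "N-M%", ">N%", "<N%", count ratios "a/b" and mapped
    descriptors.  Percent parses are exact: re-rendering the interval
    reproduces the printed number.
    """
    m = _PCT_RE.match(display)
    if m:
        cmp_sign, lo_s, hi_s = m.groups()
        lo = float(lo_s) / 100.0
        if hi_s is not None:
            return (lo, float(hi_s) / 100.0)
        if cmp_sign in (">", "≥"):
            return (lo, 1.0)
        if cmp_sign in ("<", "≤"):
            return (0.0, lo)
        return (lo, lo)
    m = _RATIO_RE.match(display)
    if m:
        frac = int(m.group(1)) / int(m.group(2))
        if frac <= 1:
            return (frac, frac)
        return None
    if descriptor_map:
        key = normalize_surface(display)
        if key in descriptor_map:
            return descriptor_map[key]
        norm_map = {normalize_surface(k): v for k, v in descriptor_map.items()}
        if key in norm_map:
            return norm_map[key]
    return None


def render_percentage(fraction: float) -> str:
    """Inverse of the percent parse: 0.12 -> "12"."""
    return f"{round(fraction * 100, 6):g}"


def classify_table(
    table: TableBlock,
    drug_names: Sequence[str],
    config: MinerConfig = MinerConfig(),
) -> dict[int, str] | str:
    """Column-role map (drug / placebo / ignore) or REJECT.

    The table is rejected when any header cell or the caption contains a
    rejection keyword.  Otherwise: a column whose header mentions "placebo"
    is the placebo arm; one naming the drug or a dose ("50 mg") is a drug
    arm; the first column holds the ADR terms.  If no column carries either
    keyword the table is treated as single-arm: all non-first columns are
    drug columns.
    """
    if not table.has_header:
        return REJECT
    reject_keys = [normalize_surface(k) for k in config.table_reject_keywords]
    scan_texts = [table.caption] + [c for row in table.header_rows for c in row]
    for text in scan_texts:
        norm = normalize_surface(text)
        if any(key in norm for key in reject_keys):
            return REJECT

    drug_keys = [normalize_surface(d) for d in drug_names if d]
    roles: dict[int, str] = {0: IGNORE}
    any_arm = False
    for col in range(1, table.n_cols):
        header = normalize_surface(
            " ".join(row[col] for row in table.header_rows if col < len(row))
        )
        if "placebo" in header:
            roles[col] = PLACEBO_ARM
            any_arm = True
        elif any(d in header for d in drug_keys) or _DOSE_RE.search(header):
            roles[col] = DRUG_ARM
            any_arm = True
        else:
            roles[col] = IGNORE
    if not any_arm:
        for col in range(1, table.n_cols):
            roles[col] = DRUG_ARM
    return roles


def parse_frequency_table(
    table: TableBlock,
    roles: dict[int, str],
    lexicon: Lexicon,
    config: MinerConfig = MinerConfig(),
    label_id: str = "",
) -> list[FrequencyRecord]:
    """One record per (term row, arm column) cell with a parsable frequency.

    The term cell (first column) is matched against the lexicon with the
    same engine as sentence NER, so orthographic variants resolve; rows with
    no lexicon hit are skipped and logged.
    """
    records: list[FrequencyRecord] = []
    locator = f"table:{table.index}"
    for row in table.body_rows:
        term_cell = row[0] if row else ""
        hits = match_text(term_cell, lexicon)
        if not hits:
            if term_cell.strip():
                logger.debug("table %s: no lexicon hit for term cell %r", locator, term_cell)
            continue
        concepts = sorted({cid for _, _, cid in hits})
        for col, role in roles.items():
            if role not in (DRUG_ARM, PLACEBO_ARM) or col >= len(row):
                continue
            display = row[col].strip()
            if not display:
                continue
            interval = normalize_frequency(display, config.descriptor_map)
            if interval is None:
                continue
            for cid in concepts:
                records.append(
                    FrequencyRecord(
                        concept_id=cid,
                        arm=role,
                        freq_lower=interval[0],
                        freq_upper=interval[1],
                        display=display,
                        source="table",
                        label_id=label_id,
                        locator=locator,
                    )
                )
    return records


def _descriptor_regex(descriptor_map: dict[str, tuple[float, float]]) -> re.Pattern:
    alts = sorted((normalize_surface(k) for k in descriptor_map), key=len, reverse=True)
    body = "|".join(re.escape(a).replace(r"\ ", r"[\s\-]+") for a in alts)
    return re.compile(rf"\b({body})\s*:", re.IGNORECASE)


def parse_frequency_text(
    sentence: Sentence,
    mentions: Sequence[Mention],
    config: MinerConfig = MinerConfig(),
    label_id: str = "",
) -> list[FrequencyRecord]:
    """Free-text frequencies for the mentions located in one sentence.

    Pattern A: "<descriptor>: m1, m2, ..." — the descriptor applies to every
    mention between its colon and the next descriptor (or sentence end).
    Pattern B: "<mention> (12%)" — the parenthesized value applies to that
    mention only.  All records are drug-arm.
    """
    text = sentence.text
    records: list[FrequencyRecord] = []
    locator = f"sentence:{sentence.index}"
    in_sentence = [
        m for m in mentions if m.sentence_index == sentence.index
    ]

    # Pattern B: parenthetical right after the mention
    for m in in_sentence:
        rel_end = m.char_end - sentence.char_start
        pm = _PAREN_RE.match(text, rel_end)
        if not pm:
            continue
        display = pm.group(1).strip()
        interval = normalize_frequency(display, config.descriptor_map)
        if interval is None:
            continue
        records.append(
            FrequencyRecord(
                concept_id=m.concept_id,
                arm=DRUG_ARM,
                freq_lower=interval[0],
                freq_upper=interval[1],
                display=display,
                source="text",
                label_id=label_id or m.label_id,
                locator=locator,
            )
        )

    # Pattern A: descriptor lists
    desc_re = _descriptor_regex(config.descriptor_map)
    marks = list(desc_re.finditer(text))
    for i, dm in enumerate(marks):
        seg_start = dm.end()
        seg_end = marks[i + 1].start() if i + 1 < len(marks) else len(text)
        display = dm.group(1)
        interval = normalize_frequency(display, config.descriptor_map)
        for m in in_sentence:
            rel_start = m.char_start - sentence.char_start
            if seg_start <= rel_start < seg_end:
                records.append(
                    FrequencyRecord(
                        concept_id=m.concept_id,
                        arm=DRUG_ARM,
                        freq_lower=None if interval is None else interval[0],
                        freq_upper=None if interval is None else interval[1],
                        display=display,
                        source="text",
                        label_id=label_id or m.label_id,
                        locator=locator,
                    )
                )
    return records
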