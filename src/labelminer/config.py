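"""Pipeline configuration with documented defaults.

Every wordlist here is a configurable stand-in: real label-mining systems
curate these lists against their own corpora, and the shipped defaults make
no claim of completeness.  All of them can be overridden from a YAML file
(``MinerConfig.from_yaml``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

# Section kinds
INDICATIONS = "indications"
ADVERSE_REACTIONS = "adverse_reactions"
OTHER = "other"
TERMINATOR = "terminator"

DEFAULT_INDICATION_HEADINGS = (
    "indications",
    "indications and usage",
    "indications and use",
    "therapeutic indications",
    "uses",
    "what the product is used for",
)

DEFAULT_ADR_HEADINGS = (
    "adverse reactions",
    "adverse effects",
    "adverse events",
    "side effects",
    "undesirable effects",
)

# Section titles that signal the indications/ADR section has ended.
DEFAULT_TERMINATOR_HEADINGS = (
    "interactions with other drugs",
    "drug interactions",
    "contraindications",
    "warnings",
    "warnings and precautions",
    "dosage and administration",
    "overdosage",
    "how supplied",
    "clinical pharmacology",
    "nonclinical toxicology",
    "references",
)

# Extra phrases used only for inferring heading text styles (common
# subsection titles that are heading-styled but keep the open section's kind).
DEFAULT_SUBSECTION_PHRASES = (
    "clinical trials experience",
    "postmarketing experience",
    "post-marketing experience",
)

DEFAULT_NEGATION_CUES = (
    "has not been observed",
    "have not been observed",
    "was not observed",
    "were not observed",
    "not been reported",
    "no reports of",
    "no cases of",
)

DEFAULT_SPECULATION_CUES = (
    "is suspected",
    "are suspected",
    "causal relationship has not been established",
    "cannot be ruled out",
)

# Descriptor -> frequency interval, CIOMS convention.  Fractions of 1.
DEFAULT_DESCRIPTOR_MAP: dict[str, tuple[float, float]] = {
    "very common": (0.10, 1.0),
    "very frequent": (0.10, 1.0),
    "common": (0.01, 0.10),
    "frequent": (0.01, 0.10),
    "uncommon": (0.001, 0.01),
    "infrequent": (0.001, 0.01),
    "rare": (0.0001, 0.001),
    "very rare": (0.0, 0.0001),
}

# A table whose header or caption contains one of these is not an ADR
# frequency table (discontinuation counts, cohort demographics, ...).
DEFAULT_TABLE_REJECT_KEYWORDS = (
    "discontinuation",
    "discontinued",
    "withdrawal",
    "demographic",
    "baseline",
)

# Sentence-splitter abbreviation stoplist (a period after these never ends
# a sentence).
DEFAULT_ABBREVIATIONS = (
    "e.g.",
    "i.e.",
    "vs.",
    "etc.",
    "approx.",
    "no.",
    "dr.",
    "mr.",
    "mrs.",
    "st.",
)

# Words ignored when comparing word bags for synonym-permutation candidates.
DEFAULT_BAG_STOPWORDS = frozenset({"of", "the", "and"})

# LOINC section codes used by structured (SPL XML) labels.
DEFAULT_SPL_SECTION_CODES = {
    "34067-9": INDICATIONS,
    "34084-4": ADVERSE_REACTIONS,
}


@dataclass(frozen=True)
class MinerConfig:
    indication_headings: tuple[str, ...] = DEFAULT_INDICATION_HEADINGS
    adr_headings: tuple[str, ...] = DEFAULT_ADR_HEADINGS
    terminator_headings: tuple[str, ...] = DEFAULT_TERMINATOR_HEADINGS
    subsection_phrases: tuple[str, ...] = DEFAULT_SUBSECTION_PHRASES
    negation_cues: tuple[str, ...] = DEFAULT_NEGATION_CUES
    speculation_cues: tuple[str, ...] = DEFAULT_SPECULATION_CUES
    descriptor_map: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_DESCRIPTOR_MAP)
    )
    table_reject_keywords: tuple[str, ...] = DEFAULT_TABLE_REJECT_KEYWORDS
    abbreviations: tuple[str, ...] = DEFAULT_ABBREVIATIONS
    bag_stopwords: frozenset[str] = DEFAULT_BAG_STOPWORDS
    spl_section_codes: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_SPL_SECTION_CODES)
    )
    # Names seen at least this often are queued for manual review.
    min_review_count: int = 100
    # Digits for overlap-report percentages (integers in the benchmark table).
    overlap_pct_digits: int = 0

    @property
    def heading_phrases(self) -> tuple[str, ...]:
        """All phrases used to infer which text styles mark headings."""
        return (
            self.indication_headings
            + self.adr_headings
            + self.terminator_headings
            + self.subsection_phrases
        )

    @property
    def hedge_cues(self) -> tuple[str, ...]:
        return self.negation_cues + self.speculation_cues

    @classmethod
    def from_yaml(cls, path: str | Path) -> "MinerConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        kwargs = {}
        tuple_fields = {
            "indication_headings",
            "adr_headings",
            "terminator_headings",
            "subsection_phrases",
            "negation_cues",
            "speculation_cues",
            "table_reject_keywords",
            "abbreviations",
        }
        for key, value in raw.items():
            if key in tuple_fields:
                kwargs[key] = tuple(value)
            elif key == "bag_stopwords":
                kwargs[key] = frozenset(value)
            elif key == "descriptor_map":
                kwargs[key] = {k: (float(v[0]), float(v[1])) for k, v in value.items()}
            else:
                kwargs[key] = value
        return cls(**kwargs)

    def with_overrides(self, **kwargs) -> "MinerConfig":
        return replace(self, **kwargs)


DEFAULT_CONFIG = MinerConfig()
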