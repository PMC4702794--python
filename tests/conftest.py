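"""Shared fixtures: a small hand-built medical lexicon and document builders."""

from __future__ import annotations

import pytest

from labelminer.config import MinerConfig
from labelminer.label_ingest import Span, StyledDocument
from labelminer.lexicon import Concept, build_lexicon


def make_doc(label_id: str, pieces: list[tuple]) -> StyledDocument:
    """Build a StyledDocument from (kind, ...) tuples.

    ("h", text) -> H1 heading span; ("p", text) -> body paragraph span;
    ("table", rows) -> one cell span per table cell.
    """
    spans: list[Span] = []
    table_counter = -1
    for piece in pieces:
        kind = piece[0]
        if kind == "h":
            spans.append(Span(piece[1] + "\n", "H1"))
        elif kind == "h2":
            spans.append(Span(piece[1] + "\n", "H2"))
        elif kind == "p":
            spans.append(Span(piece[1] + "\n", "P"))
        elif kind == "table":
            table_counter += 1
            for r, row in enumerate(piece[1]):
                for c, cell in enumerate(row):
                    sep = "\t" if c < len(row) - 1 else "\n"
                    spans.append(
                        Span(cell + sep, "TD", is_table_cell=True,
                             table_coords=(table_counter, r, c))
                    )
        else:
            raise ValueError(kind)
    return StyledDocument(label_id, spans)


MEDICAL_CONCEPTS = [
    ("C001", "headache", ["headache"], "10019211"),
    ("C002", "fatigue", ["fatigue"], "10016256"),
    ("C003", "blood pressure", ["blood pressure"], "10005727"),
    ("C004", "blood pressure decreased", ["blood pressure decreased"], "10005734"),
    ("C005", "myocardial infarction", ["myocardial infarction"], "10028596"),
    ("C006", "nausea", ["nausea", "feeling sick"], "10028813"),
    ("C007", "agranulocytosis", ["agranulocytosis"], "10001507"),
]


@pytest.fixture
def med_lexicon():
    concepts = [
        Concept(cid, pref, list(names), ["sign_or_symptom"], meddra_code=code, level="PT")
        for cid, pref, names, code in MEDICAL_CONCEPTS
    ]
    return build_lexicon(
        concepts,
        semantic_whitelist=["sign_or_symptom"],
        synonym_groups=[("decreased", "lower")],
    )


@pytest.fixture
def config():
    return MinerConfig()
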