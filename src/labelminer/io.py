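"""File formats: styled-label JSONL, lexicon TSV, triples TSV, registries.

The canonical document format is deliberately minimal — one JSON object per
label with its styled spans — because that is all the miner consumes.  An
adapter (`read_html_label`) maps real HTML onto it via lxml.  All TSVs are
UTF-8, tab-separated, header row, no quoting.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Iterator

from lxml import html as lxml_html

from .aggregate import DrugRecord, Registry
from .label_ingest import Span, StyledDocument
from .lexicon import Concept, Lexicon, build_lexicon
from .ner import Mention
from .relations import DependencyTriple


# --- styled documents -------------------------------------------------------

def document_to_json(doc: StyledDocument) -> dict:
    return {
        "label_id": doc.label_id,
        "spans": [
            {
                "text": s.text,
                "style": s.style_id,
                **({"cell": list(s.table_coords)} if s.is_table_cell else {}),
            }
            for s in doc.spans
        ],
    }


def document_from_json(obj: dict) -> StyledDocument:
    spans = []
    for s in obj["spans"]:
        cell = s.get("cell")
        spans.append(
            Span(
                s["text"],
                s["style"],
                is_table_cell=cell is not None,
                table_coords=tuple(cell) if cell is not None else None,
            )
        )
    return StyledDocument(obj["label_id"], spans)


def write_documents(docs: Iterable[StyledDocument], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for doc in docs:
            fh.write(json.dumps(document_to_json(doc), sort_keys=True) + "\n")


def read_documents(path: str | Path) -> Iterator[StyledDocument]:
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                yield document_from_json(json.loads(line))


def read_html_label(path: str | Path, label_id: str | None = None) -> StyledDocument:
    """Adapter: flatten an HTML label into styled spans.

    Headings (h1–h6) become spans styled by their tag; table cells carry
    (table, row, col) coordinates; everything else is body text.
    """
    tree = lxml_html.parse(str(path))
    root = tree.getroot()
    spans: list[Span] = []
    table_counter = -1
    body = root.find("body")
    if body is None:
        body = root
    for el in body.iter():
        tag = el.tag if isinstance(el.tag, str) else ""
        if tag in ("h1", "h2", "h3", "h4", "h5", "h6"):
            text = (el.text_content() or "").strip()
            if text:
                spans.append(Span(text + "\n", tag.upper()))
        elif tag == "p":
            text = (el.text_content() or "").strip()
            if text:
                spans.append(Span(text + "\n", "P"))
        elif tag == "table":
            table_counter += 1
            for r, tr in enumerate(el.findall(".//tr")):
                cells = tr.findall("th") + tr.findall("td")
                for c, cell in enumerate(cells):
                    text = (cell.text_content() or "").strip()
                    sep = "\t" if c < len(cells) - 1 else "\n"
                    spans.append(
                        Span(
                            text + sep,
                            "TD",
                            is_table_cell=True,
                            table_coords=(table_counter, r, c),
                        )
                    )
    return StyledDocument(label_id or Path(path).stem, spans)


# --- lexicon ----------------------------------------------------------------

_LEX_HEADER = ["concept_id", "meddra_code", "level", "semantic_types", "name", "is_preferred"]


def write_lexicon_tsv(concepts: Iterable[Concept], path: str | Path) -> None:
    lines = ["\t".join(_LEX_HEADER)]
    for c in sorted(concepts, key=lambda c: c.concept_id):
        for name in c.names:
            lines.append(
                "\t".join(
                    [
                        c.concept_id,
                        c.meddra_code or "",
                        c.level,
                        "|".join(c.semantic_types),
                        name,
                        "1" if name == c.preferred_name else "0",
                    ]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_lexicon_tsv(path: str | Path) -> list[Concept]:
    concepts: dict[str, Concept] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _LEX_HEADER:
            raise ValueError(f"unexpected lexicon header: {header}")
        for line in fh:
            if not line.strip():
                continue
            cid, code, level, semtypes, name, pref = line.rstrip("\n").split("\t")
            if cid not in concepts:
                concepts[cid] = Concept(
                    concept_id=cid,
                    preferred_name=name,
                    names=[name],
                    semantic_types=semtypes.split("|") if semtypes else [],
                    meddra_code=code or None,
                    level=level,
                )
            else:
                c = concepts[cid]
                if name not in c.names:
                    c.names.append(name)
            if pref == "1":
                concepts[cid].preferred_name = name
    return list(concepts.values())


def read_wordlist(path: str | Path) -> list[str]:
    out = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def read_synonym_groups(path: str | Path) -> list[list[str]]:
    """One group per line, words separated by whitespace or commas."""
    groups = []
    for line in read_wordlist(path):
        words = [w for w in line.replace(",", " ").split() if w]
        if len(words) >= 2:
            groups.append(words)
    return groups


def load_lexicon(
    lexicon_tsv: str | Path,
    semantic_whitelist: Iterable[str],
    excluded_path: str | Path | None = None,
    blocked_path: str | Path | None = None,
    synonym_groups_path: str | Path | None = None,
) -> Lexicon:
    return build_lexicon(
        read_lexicon_tsv(lexicon_tsv),
        semantic_whitelist,
        excluded_concepts=read_wordlist(excluded_path) if excluded_path else (),
        blocked_names=read_wordlist(blocked_path) if blocked_path else (),
        synonym_groups=read_synonym_groups(synonym_groups_path)
        if synonym_groups_path
        else (),
    )


# --- drug registry ----------------------------------------------------------

_REG_HEADER = ["label_id", "flat_id", "stereo_id", "drug_names"]


def write_registry(registry: Registry, path: str | Path) -> None:
    lines = ["\t".join(_REG_HEADER)]
    for label_id in sorted(registry):
        d = registry[label_id]
        lines.append(
            "\t".join([label_id, d.flat_id, d.stereo_id or "", "|".join(d.names)])
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_registry(path: str | Path) -> Registry:
    registry: Registry = {}
    drugs: dict[str, DrugRecord] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _REG_HEADER:
            raise ValueError(f"unexpected registry header: {header}")
        for line in fh:
            if not line.strip():
                continue
            label_id, flat, stereo, names = line.rstrip("\n").split("\t")
            if flat not in drugs:
                drugs[flat] = DrugRecord(
                    flat, stereo or None, names.split("|") if names else [], []
                )
            drugs[flat].label_ids.append(label_id)
            registry[label_id] = drugs[flat]
    return registry


# --- dependency triples -----------------------------------------------------

_TRIPLE_HEADER = ["sentence_index", "relation", "gov_word", "gov_idx", "dep_word", "dep_idx"]


def write_triples(
    triples: dict[int, list[DependencyTriple]], path: str | Path
) -> None:
    lines = ["\t".join(_TRIPLE_HEADER)]
    for sent_idx in sorted(triples):
        for t in triples[sent_idx]:
            lines.append(
                "\t".join(
                    [
                        str(sent_idx),
                        t.relation,
                        t.governor[0],
                        str(t.governor[1]),
                        t.dependent[0],
                        str(t.dependent[1]),
                    ]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_triples(path: str | Path) -> dict[int, list[DependencyTriple]]:
    out: dict[int, list[DependencyTriple]] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _TRIPLE_HEADER:
            raise ValueError(f"unexpected triples header: {header}")
        for line in fh:
            if not line.strip():
                continue
            sent, rel, gw, gi, dw, di = line.rstrip("\n").split("\t")
            out.setdefault(int(sent), []).append(
                DependencyTriple(rel, (gw, int(gi)), (dw, int(di)))
            )
    return out


# --- mentions ---------------------------------------------------------------

_MENTION_HEADER = [
    "label_id", "section", "sentence", "start", "end",
    "surface", "concept_id", "suppressed", "reason",
]


def write_mentions(mentions: Iterable[Mention], path: str | Path) -> None:
    lines = ["\t".join(_MENTION_HEADER)]
    ordered = sorted(mentions, key=lambda m: (m.label_id, m.char_start, m.concept_id))
    for m in ordered:
        lines.append(
            "\t".join(
                [
                    m.label_id,
                    m.section_kind,
                    str(m.sentence_index),
                    str(m.char_start),
                    str(m.char_end),
                    m.surface,
                    m.concept_id,
                    "1" if m.suppressed else "0",
                    m.suppression_reason or "",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# --- reference pair sets (benchmarking) -------------------------------------

def read_pair_set(path: str | Path) -> set[tuple[str, str]]:
    """(drug, concept) pairs from a two-plus-column TSV with a header row."""
    pairs: set[tuple[str, str]] = set()
    with open(path, encoding="utf-8") as fh:
        fh.readline()
        for line in fh:
            if not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            pairs.add((cols[0], cols[1]))
    return pairs
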