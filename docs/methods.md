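# Methods

This note documents the models, heuristics and defaults behind `labelminer`,
the choices made where the design was genuinely open, and what the synthetic
evaluation does and does not demonstrate.

## Document model and segmentation

The canonical input is a flat sequence of styled spans `(text, style_id,
optional table coordinates)` per label; concatenated span texts reconstruct
the document exactly, and every downstream offset (sections, sentences,
mentions) indexes into that text as 0-based half-open ranges. This mirrors
what PDF→HTML conversion of package inserts actually yields: visual styles
survive, logical structure does not.

Heading-style inference searches the spans for known wordings of section
headings ("indications and usage", "adverse reactions", common subsection
titles); the styles of matching spans are taken to mark headings everywhere
in that document. If no style can be inferred (heavily degraded documents),
any paragraph exactly equal to a configured wording acts as a heading.
Structured (SPL XML) labels would bypass inference entirely — the config
carries a LOINC section-code map for that path.

Heading classification casefolds, strips digits and dots (SPL section
numbering) and collapses whitespace before matching the indications, ADR and
terminator wordlists. The terminator list ("Interactions with other drugs",
"Contraindications", …) exists because a section only ends where the next
recognized heading begins: a subsection heading that classifies as `other`
("Post-marketing experience") is absorbed into the open indications/ADR
section rather than closing it. None of the shipped wordlists claims to be
complete; all are config.

Sentence splitting is rule-based: sentence-final punctuation followed by
whitespace and an upper-case letter/digit/quote, with an abbreviation
stoplist ("e.g.", "vs.", …). No published splitter is claimed; downstream
stages only need consistent per-sentence scoping for hedge exclusion and
masking.

Tables take their first row as the header row. A caption is attached when a
paragraph in the same section starts with "Table"; both header cells and the
caption are scanned for rejection keywords, since real labels put
"Discontinuation" sometimes in the caption and sometimes in a column head.

## Dictionary construction and matching

Concepts carry an opaque id, an optional MedDRA-style code and level
(PT/LLT), names, and semantic types. Building the searchable index applies,
in order: a semantic-type whitelist (concepts with no whitelisted type are
dropped), a concept exclusion list (kept in the concept map, contribute no
names — for concepts of the right type that are not ADRs, such as
"HIV positive"), and a blocked-name list. A surface claimed by two concepts
is auto-blocked and logged: ambiguity resolution is a curation decision, and
the automated path must fail safe.

Matching is longest-match left-to-right anchored at word-token boundaries
(no mid-word matches). Orthographic variation is handled by key
normalization — casefold, hyphen ≡ space, separator runs collapsed — plus a
separator-free fallback index so "bloodpressure" finds "blood pressure" and
vice versa. Separator-free collisions across concepts are dropped from the
fallback index. The matcher is verified against a brute-force oracle that
enumerates every token-boundary substring and re-applies the same
resolution.

Dictionary expansion pools each concept name's words, substitutes synonym
group representatives (groups are symmetric word classes supplied as
config), and scans the corpus for token windows with the same raw token
count and the same filtered word multiset as an existing name. Multiset
(not set) semantics were chosen so word repetitions cannot silently match;
single-character tokens and a three-word stopword list ("of", "the", "and")
are ignored in comparison so "treatment of X" parity does not depend on
function words. Candidates are queued by corpus frequency; the review
threshold `min_review_count` defaults to 100, matching the curation
practice of inspecting names seen at least 100 times. Curation is
append-only, idempotent and order-insensitive; accepting a blocked surface
is an error.

## Hedge suppression

Any ADR-section sentence containing a negation or speculation cue
(normalized substring match) has its mentions flagged `hedged_sentence`.
The scope is the whole sentence — the source texts exclude sentences, not
clauses, and clause-level scope parsing would add a parser dependency for
little gain on label prose. The shipped cue lists contain the canonical
negation/speculation examples plus conservative variants; deliberately
excluded are weak cues like "may be associated", which over-suppress.
Suppression never deletes: mention counts are invariant under filtering,
which is what makes the highlighted HTML a faithful provenance record.

## Relation extraction

Entities are masked to single placeholder tokens before parsing — multiword
medical terms are the main source of parse errors, and a placeholder noun
parses cleanly. Masking precedes all filtering (suppressed mentions are
masked too) and is lossless by construction.

The dependency parser is deliberately out of scope: triples arrive from
files (or any adapter) in the collapsed-preposition dialect
(`prep_of(treatment, X)`); a normalizer folds the modern two-edge
`nmod` + `case` dialect onto it. Parser choice and version would otherwise
dominate the behavior of everything downstream.

Rules are declarative: pattern lines of `(relation-alternation, governor
slot, dependent slot)` with three slot kinds — entity-typed variables, free
variables (`?v`), and lexical literals matched on casefolded lemmas from a
small built-in lemma table, with `|` alternation. A rule fires for every
injective assignment of slots to token indices satisfying all patterns;
results deduplicate on (type, drug, concept), so neither triple order nor
rule order matters. The shipped rule file covers the worked constructions:
indication via "used/indicated for the treatment|management|relief of X"
and "indicated for X", preconditions via "in patients with X", "patients
receiving X" and "history of X", and combinations via "in combination with
DRUG" — documented analogues of the printed examples, not a claim to any
system's full internal inventory. The `combination` production carries the
partner drug (there is no condition argument); indication/precondition
carry a condition concept. The drug slot grounds on drug-class placeholders
or the label's own product name token.

## Frequency extraction

Column roles come from the header: "placebo" marks the placebo arm; the
drug's name or a dose pattern (`50 mg`, `10 mcg`, …) marks a drug arm; the
first column holds the terms. With neither keyword present the table is
treated as single-arm (all non-first columns drug). Multi-dose columns all
map to the drug arm; intervals are not merged at extraction, preserving the
raw records. Term cells go through the same matcher as sentences, so
orthographic variants resolve; rows without a dictionary hit are skipped
and logged.

Free-text patterns: a descriptor followed by a colon applies to every
mention up to the next descriptor or sentence end; a parenthesized
percentage or range immediately after a mention applies to that mention
only. Free-text records are attributed to the drug arm — labels report
placebo rates in tables, not prose.

Display normalization: `N%` → (N/100, N/100) exactly (re-rendering
reproduces the printed number); `N–M%` → range; `>`/`≥` and `<`/`≤` open
one end; `a/b` count ratios are parsed (common SPL dialect); descriptors
map through the CIOMS convention table (very common ≥ 10 %, common/frequent
1–10 %, uncommon/infrequent 0.1–1 %, rare 0.01–0.1 %, very rare < 0.01 %),
shipped as overridable config since no authoritative mapping exists for
historical labels. Unknown displays keep their text with no interval.
When a concept has both table and text frequencies on a label, both records
are kept with their sources — consumers can prefer either.

## Aggregation, the indication filter, and the benchmark

Pairs key on the flat compound id (stereoisomers and salt forms merged);
the stereo id is carried as annotation. The filter discards a free-text ADR
candidate for (drug, concept) iff an NLP indication/precondition exists for
that drug on any label, or an NER indication-section record exists on the
same label — NER indications are noisier, hence the narrower scope. Table
evidence is exempt: a tabulated frequency is strong evidence the term is a
real ADR even when the same concept is also an indication. Filtered
mentions are flagged `indication_filter` and stay visible in the HTML.
Adding indication records can only shrink the pair set (monotonicity, under
property test).

Benchmark overlap restricts both pair sets to drugs and concepts present on
both sides, then counts only-A / intersection / only-B with percentages
relative to each restricted set. Matching is exact on shared identifiers or
normalized term strings — no fuzzy matching, so reported overlap is a lower
bound. Percentages round half-up (integer for overlap reports, one decimal
for the contradiction rate); the matched-fraction report uses the
unrestricted pair count of the extracted set as denominator. Percentages on
an empty restricted set are reported blank rather than zero.

## Synthetic fixtures: what passing proves

The generator is a pure function of (seed, parameters). Lexicon words,
filler words and drug names draw from three disjoint consonant pools, so no
concept name can occur in text by accident: on generated corpora, any false
positive is an engine defect, which is what licenses asserting
precision = recall = 1 exactly. Labels contain heading-styled sections, the
rule-covered sentence constructions with their dependency triples, hedged
sentences at a configurable rate, both free-text frequency patterns,
drug+placebo tables, one rejectable decoy table per label, and concepts
planted both as indications and as ADR free text to exercise every filter
scope (sibling-label keep, same-label discard, table keep, any-label NLP
discard are each forced into every corpus). Withheld permutation-only name
variants are planted in unmined sections so dictionary expansion is
testable on the same corpus without perturbing the NER ground truth.
Expected final pairs are derived from the planted evidence by the filter
semantics; the test suite re-derives them with an independent
implementation.

What this does **not** show: robustness to real label prose (the filler is
not English), to OCR noise or inconsistent styling beyond the modeled
degradations, to parser errors (triples are template-generated, not
parsed), to abbreviations or coreference, or to the ambiguity load of a
full medical vocabulary. Corpus-scale statistics of real releases
(thousands of drugs, hundreds of thousands of pairs) depend on licensed
resources and are out of reach of this artifact; the acceptance checks are
therefore worked examples, oracle equivalences and exact-recovery
properties at desk scale (default: 20 drugs × 2 labels per corpus, ten
seeds — sizes chosen to exercise every code path several times over while
keeping the suite fast).

## Numerical and degenerate-input conventions

Percentages use decimal half-up rounding (never binary-float `round`).
Empty documents segment to an empty section list; a pre-heading preamble
becomes a heading-less `other` section so offsets stay lossless. Empty
match results, empty candidate lists and empty corpora are ordinary values,
not errors; hard errors are reserved for contract violations (duplicate
concept ids, overlapping mentions, out-of-range triple indices, dangling
references at output time, orphan labels missing from the drug registry).
Scoring conventions for degenerate cases: empty extraction reports
precision 1 with a warning; empty truth reports precision = recall = 1.
All outputs are deterministically ordered, so identical inputs give
byte-identical files.
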