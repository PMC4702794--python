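# labelminer

Drug package inserts are the primary public record of what a drug is
approved to treat and which adverse drug reactions (ADRs) were observed in
its clinical trials. `labelminer` turns a corpus of such labels — flattened
to styled text spans, the way PDF-converted documents arrive — into a
filtered, frequency-annotated database of drug–ADR pairs and drug–indication
pairs, together with highlighted HTML so every extracted fact can be traced
to its exact place in the source document. It is aimed at
pharmacovigilance and computational drug-safety researchers who need a
reproducible, inspectable extraction pipeline rather than a black box.

## The pipeline

1. **Section segmentation** (`label_ingest`). Heading styles are inferred by
   searching for known wordings of the indications/ADR section headings;
   the document is then split into typed sections (`indications`,
   `adverse_reactions`, `other`, `terminator`), with tables preserved and
   0-based half-open character offsets kept throughout.
2. **Dictionary NER** (`lexicon`, `ner`). A concept dictionary (UMLS-CUI-like
   ids, MedDRA-style codes) is filtered by semantic type and curated with
   concept-exclusion and blocked-name lists. Matching is longest-match
   left-to-right with orthographic variation (case; insertion/removal of
   hyphens and spaces). The dictionary is expanded by scanning the corpus
   for word-order permutations and word-synonym swaps of known names
   ("blood pressure decreased" → "decreased blood pressure",
   "lower blood pressure"); frequent novel surfaces enter a review queue and
   only explicitly accepted ones join the dictionary. Sentences in the ADR
   section containing negation ("has not been observed") or speculation
   ("is suspected") cues are suppressed — flagged, never deleted.
3. **Relation extraction** (`relations`). Recognized entities are collapsed
   to single placeholder tokens; an external dependency parser (consumed as
   input, collapsed-preposition dialect) supplies triples like
   `prep_of(treatment-7, INDICATION-9)`; a declarative rule set classifies
   entity roles as *indication*, *pre-existing condition* or *drug
   combination*.
4. **Frequency extraction** (`frequency`). Table headers decide drug-arm vs
   placebo-arm columns (tables about discontinuation, demographics etc. are
   rejected); free text is scanned for descriptor lists
   ("frequent: headache, fatigue") and parenthesized percentages
   ("headache (12%)"). Displays normalize to fractional intervals,
   descriptors via a CIOMS-convention mapping (common/frequent = 1–10 %, …).
5. **Aggregation and filtering** (`aggregate`). Evidence pools per drug
   (flat compound id; stereo forms merged). A free-text ADR candidate for
   drug *d* on label *L* is discarded iff the same concept was found as an
   indication (i) by NLP on *any* label of *d*, or (ii) by NER in the
   indications section of *L* itself; table-derived frequency evidence is
   exempt. Overlap against a reference indication set is reported on
   exactly matching identifiers, restricted to shared drugs and concepts,
   with half-up rounded percentages.

Because real concept vocabularies and label corpora are licensed, the
package ships a first-class synthetic-fixture generator (`synthetic`) that
emits styled labels, dependency triples, registries and reference sets with
exhaustive ground truth from disjoint vocabularies, so the whole pipeline is
testable at exact precision/recall.

## Worked example

```bash
mine simulate --seed 3 --n-drugs 4 --out sim
# 8 labels, 22 expected pairs -> sim

mine run --labels sim/labels.jsonl --lexicon sim/lexicon.tsv \
    --whitelist sign_or_symptom --registry sim/registry.tsv \
    --drug-lexicon sim/drug_lexicon.tsv --triples sim/triples --out out
# 22 drug-ADR pairs, 20 indication records, 11 files -> out

head -3 out/pairs.tsv
# flat_id  stereo_id  concept_id  meddra_code  term  arm  freq_display  freq_lower  freq_upper  source  label_id
# CIDm00000  CIDs00000  C0000  10000000  mudi                                CIDm00000-L0
# CIDm00000  CIDs00000  C0008  10000008  gori mige  drug  Frequent  0.01  0.1  text  CIDm00000-L0
```

The first data row is a pair supported by a free-text mention alone (no
frequency); the second carries a drug-arm descriptor frequency ("Frequent",
normalized to the interval 1–10 %) extracted from free text of the ADR
section. `out/html/` holds one HTML file per label with every mention
highlighted — suppressed mentions (hedged sentences, indication-filtered
concepts) are struck through with the reason attached, not dropped.
Self-benchmarking the output against itself sanity-checks the overlap
report:

```bash
mine benchmark --pairs out/pairs.tsv --reference out/pairs.tsv
# ... pct_rel_extracted  100
```

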