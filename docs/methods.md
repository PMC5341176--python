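# Methods

## The standardization model

The package treats drug–adverse-event evidence integration as a
three-layer problem.

**Vocabulary layer.** A standard vocabulary holds one `Concept` per
terminology entry (RxNorm, SNOMED-CT, MedDRA, MeSH; UMLS enters only
through a CUI crosswalk). Standardness is structural: only RxNorm drug
concepts and SNOMED conditions may carry `is_standard = true`, and every
`MAPS_TO` relationship must land on a standard concept. The drug
hierarchy (clinical drug → ingredient) is a `ConceptAncestor` table kept
transitively closed and irreflexive; because closure plus irreflexivity
rules out cycles, acyclicity needs no separate check. The reflexive case
(an ingredient is its own ingredient) is added by `ingredient_for`
rather than stored, keeping the table minimal.

Cross-terminology translation (`map_to_standard`) is a filtered scan of
the mapping table with one identity shortcut: a concept already standard
in the target vocabulary returns itself. Fan-out is preserved — a source
code with several standard targets duplicates downstream records per
target, because collapsing many-to-many mappings would silently discard
evidence.

Drug-name matching (for the EU label source) is deliberately exact:
case-fold, trim, collapse internal whitespace, optionally strip one
trailing salt suffix ("sodium", "hydrochloride", ...). No fuzzy
matching: an exact pipeline is deterministic and testable, and coverage
loss from unmatched names is reported, not hidden.

**Annotation layer.** Every accepted raw record becomes an Open
Annotation resource: one target (source document URI plus a selector —
exact text for literature sources, label section for product-label
sources, none for count-based sources) and one body per normalized
drug–HOI pair (drug concept, ingredient, HOI, evidence-type tag,
identification-method tag). The EU label shape carries no section of its
own, so its annotations get the fixed SmPC adverse-reactions section
"UNDESIRABLE EFFECTS".

The annotation exists in two forms. The RDF form emits a fixed pattern —
typing triple, `oa:hasTarget`, `oa:hasSource`, selector triples,
`oa:hasBody`, `ohdsi:ImedsDrug`, `ohdsi:ImedsHoi`, and an evidence-type
literal — so the triple count is a closed function of the body and
selector counts (3 + 2·[selector] + 4·bodies). All nodes get minted URIs
(`ohdsi:annotation/{uid}` etc.); avoiding blank nodes makes graph
equality decidable term for term. The relational form
(`adr_annotation`, `target`, `adr_body`) is the lossless inverse, and
the test suite asserts set-level equality between a direct triple
emission and a rebuild through the relational rows.

**Summary layer.** Aggregation groups normalized pairs by
(relationship, source, evidence type, statistic type):

* `RECORD_COUNT` — the number of annotations in the group;
* `CASE_COUNT` — the sum of the source's case counts;
* `PRR` — pass-through; two *different* PRR values for one pair from one
  source are an aggregation error, because the input is then ambiguous.

Each record is minted a linkout at aggregation time. The long form is a
canonical URL with sorted percent-encoded parameters; the short form is
a base62 rendering of a persistent counter, so keys are bijective by
construction and survive store reopening. Minting requires at least one
matching annotation — a dangling linkout is a hard error — and the map
records the matched annotation uids, so resolution returns exactly the
counted set.

Rollups attribute clinical-drug evidence to its ingredient(s) before
grouping at four levels (ingredient; ingredient × HOI; ingredient ×
clinical drug; full detail). Drugs with several ingredients contribute
to each. Counts aggregate by sum and are conserved across levels; PRR is
excluded below full detail because a reporting ratio is not additive
across drugs or outcomes. A drug with no ingredient ancestor is routed
to an explicit reject list.

**Clinical join.** `count_exposed_cases` reproduces the standard
evidence-to-CDM query: join `drug_era` × `condition_era` on person,
keep pairs where the condition starts strictly after and within
`window_days` (default 30) calendar days of drug-era start, match
evidence on exact concept ids, and count distinct persons per (drug
name, HOI name, evidence type, linkout). The drug-era end date is
selected but plays no role in the filter; date arithmetic is
timezone-free calendar-day difference. No ingredient expansion is
applied to the patient data — callers wanting an ingredient-level join
pre-map their drug eras.

## Evidence-type vocabulary

Literature tags encode the indexing method and study type:
`MEDLINE_MeSH_CR` / `MEDLINE_MeSH_ClinTrial` / `MEDLINE_MeSH_Other` and
the `MEDLINE_SemMedDB_*` triple. Labels carry `SPL_SPLICER` (US, NLP at
clinical-drug level) and `SPL_EU_SPC`. The curated chemical–disease
source is `CTD_ChemicalDisease`; the spontaneous-report source emits two
streams per pair, `FAERS_CaseCount` and `FAERS_PRR`. Modality is
`SUPPORTS` for every shipped adapter; `REFUTES` is carried in the schema
for future adapters with an explicit refutation rule.

## The synthetic fixtures

The generators are pure functions of (parameters, seed) and define the
study conditions for all tests:

* **Vocabulary** — `n_ingredients` RxNorm ingredients (ingredient 0 is
  always simvastatin, concept 1539403, with "Simvastatin 20 MG Oral
  Tablet", 1539411, as its first clinical drug), `drugs_per_ingredient`
  clinical drugs each, `n_conditions` SNOMED conditions each with one
  MedDRA and one MeSH synonym, one MeSH synonym per ingredient, and one
  SNOMED is-a parent above condition 0 for hierarchy tests. All mappings
  are 1:1, so mapped-pair counts are predictable. Concept-id ranges are
  partitioned by vocabulary (RxNorm ≥ 1 000 000, SNOMED ≥ 4 000 000,
  MedDRA ≥ 5 000 000, MeSH ≥ 6 000 000), making id collisions
  structurally impossible.
* **Sources** — mappable records are sampled *without replacement* from
  the native drug × condition cross product, so native pairs are
  distinct; exactly `round(n_records × unmappable_fraction)` records get
  syntactically valid but unregistered codes, cycling the unmapped side
  through drug / HOI / both (this exercises the mapping-miss path, not
  the parser). The LAST condition is reserved: no source ever samples
  it, so its pairing with every ingredient is a guaranteed-evidence-free
  negative-control set — a structural guarantee, not rejection sampling.
* **CDM** — each planted (drug, condition, day-offset) triple creates
  one person with the condition era exactly that many days after the
  drug-era start; background persons carry a drug era *or* a condition
  era, never both, so the in-window ground truth is exact by
  construction. Dates are ISO-8601 day strings; offsets of 0, negative,
  or > 30 plant deliberate non-cases at the window boundaries.

What the fixtures do **not** emulate: real terminology breadth and
many-to-many mapping density, realistic incidence or reporting-rate
models, free-text narratives (mention text is an opaque selector
string), combination products, or temporal source updates. Passing tests
therefore demonstrate the correctness of the standardization, storage,
aggregation and join machinery — not real-world mapping coverage, which
depends on the vocabularies and NLP tools a deployment brings.

## Numerical and design choices

* Percentages (coverage, overlap) use round-half-even at one decimal via
  `decimal.Decimal`; a zero denominator renders as an em dash, never as
  0%.
* Overlap between source groups is 100 × |intersection| / |union| on
  distinct ingredient-level pair sets; groups must be disjoint.
* Default generator sizes (6 ingredients × 2 drugs, 8 conditions, 20–45
  records per source, 100–500 persons) keep every suite deterministic
  and under a few seconds while leaving the sampling pools comfortably
  larger than the draws; the acceptance script uses 45 records per
  source (≥ 200 annotations across the six kinds) and a 500-person
  population for the join oracle.
* ETL reruns: the same (source, version tag) requires an explicit
  replace flag, then deletes and reloads that source's annotations,
  evidence and linkout-annotation rows. The linkout URL↔key map is kept,
  so short keys are stable across reloads.
* Distinct-pair reporting happens at the source's native level (clinical
  drug for the US label source, ingredient elsewhere), since comparing a
  clinical-drug source to ingredient sources at a single level would
  misstate its coverage.
* Storage is stdlib sqlite3 in a single file; the deterministic export
  (sorted TSV per table plus sorted N-Triples) exists so that
  reproducibility can be asserted byte-for-byte.

## Known limitations

* Level-1 rollups aggregate over *all* HOIs of an ingredient, which is
  the coarsest reading of "by ingredient"; per-use-case filtering should
  happen at level 2.
* HOI-hierarchy rollups (aggregating across SNOMED is-a levels) are out
  of scope; the vocabulary carries the is-a chain needed to build them,
  but choosing the right aggregation level per disease family is an open
  modelling question.
* The drill-down query matches body fields exactly; it does not expand a
  clinical-drug filter to its ingredient (that is what rollups are for).
* No credibility weighting across evidence types; the tags exist so a
  consumer can apply their own.
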