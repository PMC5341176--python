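# adekb — a drug / adverse-drug-event evidence knowledge base

Post-market drug safety assessment means triaging a suspected association
between a drug and a health outcome of interest (HOI) across many
disconnected evidence sources: adverse reactions mined from US product
labels, EU Summary-of-Product-Characteristics listings, MEDLINE
co-indexing and sentence-level NLP, spontaneous-report databases with
disproportionality statistics, and curated chemical–disease links. Each
source codes drugs and outcomes in its own terminology (RxNorm strings,
MedDRA, MeSH, UMLS CUIs), so the evidence cannot be queried as a whole.

`adekb` is a small, fully testable implementation of the standard recipe
for this problem, aimed at pharmacovigilance and OHDSI-style
informatics work:

1. **Terminology standardization.** An OMOP-style vocabulary store maps
   every source's coding onto standard concepts — drugs to RxNorm
   (ingredient and clinical-drug levels, linked by a transitively closed
   ancestor table), HOIs to SNOMED-CT — via explicit `MAPS_TO`
   relationships, drug-name string matching, and a UMLS crosswalk.
2. **Open Annotation evidence items.** Every accepted record becomes an
   annotation with one *target* (the source document plus a selector: the
   exact indexed text for literature, the label section for product
   labels) and one or more *bodies* (drug, ingredient, HOI, evidence-type
   tag). Annotations exist in two mutually lossless forms: RDF triples
   under the `oa:`/`ohdsi:` namespaces, and relational rows
   (`adr_annotation` / `target` / `adr_body`).
3. **Aggregation with drill-down.** Per (drug–HOI pair, source, evidence
   type, statistic type) the store holds one summary record — annotation
   counts, summed case counts, or a pass-through proportional reporting
   ratio (PRR) — each carrying a *linkout*: a deterministic
   `laertes://evidence?...` URL (shortened to a bijective base62 key)
   that resolves to exactly the annotations that were counted.
4. **Rollups.** Evidence attaches at the clinical-drug or ingredient
   level; four rollup granularities — (1) ingredient, (2) ingredient ×
   HOI, (3) ingredient × clinical drug, (4) full detail — make the levels
   comparable. Counts are conserved: level-1 totals equal the sums of the
   level-2 and level-3 rows. PRR, not being additive, appears only at
   full detail.
5. **Clinical join and negative controls.** The evidence table joins
   against OMOP-CDM-shaped patient data (`drug_era` / `condition_era`) to
   count distinct patients whose condition starts within 30 days after
   drug start, and a search over the evidence-free cross product yields
   negative-control drug–HOI pairs for calibrating observational
   estimates.

A seeded fixtures module generates the whole miniature ecosystem —
vocabulary, all six raw source shapes, CDM tables — with a ground-truth
manifest, so every pipeline property is checked against exhaustive
oracles.

## Worked example

`examples/build_knowledge_base.py` generates a vocabulary (6 ingredients
× 2 clinical drugs, 8 conditions with MedDRA/MeSH synonyms), emits 20
records per source with a quarter carrying unregistered codes, and runs
all six ETLs:

```
     source_id  pairs_in_source  pairs_mapped percent_display
        spl_us               20            15           75.0%
        eu_spc               20            15           75.0%
  medline_mesh               20            15           75.0%
medline_semmed               20            15           75.0%
         faers               20            15           75.0%
           ctd               20            15           75.0%

annotations loaded: 105
```

Each row compares the distinct drug–HOI pairs in the source's native
coding with those surviving normalization; coverage is exactly 75.0%
because 5 of 20 records per source are unmappable by construction and
every fixture mapping is 1:1. The 105 annotations are 15 per source plus
a second statistic stream for the spontaneous-report source (a case-count
and a PRR record per pair).

`examples/drill_down.py` then follows one summary row back to its
evidence:

```
summary row: prugipril / guvaemia [MEDLINE_MeSH_Other] RECORD_COUNT=1
linkout:     laertes://evidence?drug=1001000&hoi=4000010&source=medline_mesh&type=MEDLINE_MeSH_Other
resolved 1 annotation(s); equals drill-down query: True
```

The other examples cover rollups/overlap/negative controls and the
30-day CDM join. The same workflow is available as a thin CLI:

```bash
adekb gen-fixtures --seed 7 --out fx/
adekb load-vocab --store kb.db --dir fx/
adekb etl --store kb.db --kind FAERS --input fx/faers.tsv
adekb rollup --store kb.db
adekb cdm-join --store kb.db --drug-era fx/drug_era.tsv \
      --condition-era fx/condition_era.tsv --types MEDLINE_MeSH_CR,SPL_EU_SPC
```

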