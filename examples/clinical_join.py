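"""Join the evidence base against CDM-shaped patient data.

Generates a patient population with drug and condition eras (including
planted day offsets of 1, 10 and 30 days — plus 0, 31 and -5, which must
NOT count), then counts, per evidenced drug-HOI pair, the distinct
patients whose condition began within 30 days after drug start.
"""

import tempfile
from pathlib import Path

from adekb import (
    EvidenceStore,
    count_exposed_cases,
    generate_cdm,
    generate_source,
    generate_vocabulary,
    load_cdm,
    run_etl,
)
from adekb.cdm_join import exposed_cases_to_tsv
from adekb.fixtures import SourceKind

workdir = Path(tempfile.mkdtemp())
vocab, manifest = generate_vocabulary(6, 2, 8, seed=7, out_dir=workdir)
store = EvidenceStore()
store.attach_vocabulary(vocab)
for kind in SourceKind:
    raw = generate_source(kind, vocab, 20, 0.25, 7, workdir, manifest)
    run_etl(kind, raw, vocab, store)

offsets = [1, 10, 30, 0, 31, -5]
plants = []
for i, pair in enumerate(manifest.planted_pairs[:24]):
    drug = pair.clinical_drug_id or pair.ingredient_id
    plants.append((drug, pair.hoi_id, offsets[i % len(offsets)]))
drug_path, cond_path, truth = generate_cdm(vocab, 100, plants, 7, workdir)

rows = count_exposed_cases(
    load_cdm(drug_path, cond_path), store,
    ["MEDLINE_MeSH_CR", "MEDLINE_MeSH_ClinTrial", "MEDLINE_SemMedDB_CR",
     "MEDLINE_SemMedDB_ClinTrial", "SPL_EU_SPC", "SPL_SPLICER"],
    window_days=30,
)
print(exposed_cases_to_tsv(rows), end="")
print()
in_window = sum(len(v) for v in truth.values())
print(f"planted in-window persons: {in_window}; "
      f"rows returned: {len(rows)} (pairs also need evidence of a queried type)")
# pcount is the number of distinct exposed patients per (drug, HOI,
# evidence type); the linkout column leads back to the source annotations.
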