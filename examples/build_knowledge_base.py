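"""Build a miniature evidence base and report mapping coverage.

Generates a small OMOP-style vocabulary plus raw files for all six
evidence sources (a quarter of the records carry codes absent from the
vocabulary), runs every source's ETL, and prints the per-source coverage:
how many distinct native drug-HOI pairs each source held and how many
survived normalization to RxNorm + SNOMED-CT.
"""

import tempfile
from pathlib import Path

from adekb import EvidenceStore, generate_source, generate_vocabulary, run_etl
from adekb.fixtures import SourceKind
from adekb.summary import coverage_report

workdir = Path(tempfile.mkdtemp())
vocab, manifest = generate_vocabulary(
    n_ingredients=6, drugs_per_ingredient=2, n_conditions=8, seed=7,
    out_dir=workdir,
)
store = EvidenceStore(workdir / "store.db")
store.attach_vocabulary(vocab)

reports = []
for kind in SourceKind:
    raw = generate_source(kind, vocab, n_records=20, unmappable_fraction=0.25,
                          seed=7, out_dir=workdir, manifest=manifest)
    reports.append(run_etl(kind, raw, vocab, store))

print(coverage_report(reports)[
    ["source_id", "pairs_in_source", "pairs_mapped", "percent_display"]
].to_string(index=False))
print()
print(f"annotations loaded: {store.annotation_count()}")
# Each row: distinct pairs in the source's native coding vs pairs that
# mapped to standard concepts; 75.0% everywhere because exactly 5 of 20
# records per source carry unregistered codes and every mapping is 1:1.
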