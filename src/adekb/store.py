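"""Single-file relational evidence store (stdlib sqlite3).

Holds the vocabulary snapshot, the source registry, the annotation tables
(adr_annotation / target / adr_body), the aggregated evidence tables
(drug_hoi_relationship / drug_hoi_evidence), the four-level rollup table
(laertes_summary), the linkout maps, and per-source ETL reports.
:meth:`EvidenceStore.export_tables` writes a byte-deterministic dump (one
sorted TSV per table plus a sorted N-Triples graph) used for
reproducibility checks.
"""

from __future__ import annotations

import csv
import sqlite3
from dataclasses import dataclass
from pathlib import Path

from rdflib import Graph

from .annotation import Annotation, RelationalRows, rebuild_from_relational, to_relational, to_triples
from .errors import EtlError, UsageError
from .vocabulary import (
    Concept,
    ConceptAncestor,
    ConceptClass,
    ConceptMapping,
    Vocabulary,
    VocabularyStore,
)

__all__ = ["EvidenceSourceMeta", "EvidenceStore"]


@dataclass(frozen=True)
class EvidenceSourceMeta:
    """Metadata row for one loaded evidence source."""

    source_id: str
    title: str
    coverage_level: str  # CLINICAL_DRUG or INGREDIENT
    coding: str
    version_tag: str


_SCHEMA = """
CREATE TABLE IF NOT EXISTS concept(
    concept_id INTEGER PRIMARY KEY, source_code TEXT, name TEXT,
    vocabulary_id TEXT, concept_class TEXT, is_standard INTEGER);
CREATE TABLE IF NOT EXISTS concept_relationship(
    source_concept_id INTEGER, target_concept_id INTEGER, relationship TEXT);
CREATE TABLE IF NOT EXISTS concept_ancestor(
    ancestor_concept_id INTEGER, descendant_concept_id INTEGER);
CREATE TABLE IF NOT EXISTS evidence_sources(
    source_id TEXT PRIMARY KEY, title TEXT, coverage_level TEXT,
    coding TEXT, version_tag TEXT);
CREATE TABLE IF NOT EXISTS drug_hoi_relationship(
    id TEXT PRIMARY KEY, drug_concept_id INTEGER, rxnorm_drug TEXT,
    hoi_concept_id INTEGER, snomed_hoi TEXT);
CREATE TABLE IF NOT EXISTS drug_hoi_evidence(
    id TEXT, source_id TEXT, evidence_type TEXT, modality TEXT,
    statistic_type TEXT, statistic_value REAL, evidence_linkout TEXT,
    PRIMARY KEY(id, source_id, evidence_type, statistic_type));
CREATE TABLE IF NOT EXISTS adr_annotation(
    annotation_uid INTEGER PRIMARY KEY, annotation_type TEXT, source_id TEXT);
CREATE TABLE IF NOT EXISTS "target"(
    annotation_uid INTEGER PRIMARY KEY, source_document_uri TEXT,
    exact_text TEXT, section TEXT);
CREATE TABLE IF NOT EXISTS adr_body(
    annotation_uid INTEGER, body_index INTEGER, drug_concept_id INTEGER,
    ingredient_concept_id INTEGER, hoi_concept_id INTEGER,
    evidence_type TEXT, method_tag TEXT,
    PRIMARY KEY(annotation_uid, body_index));
CREATE TABLE IF NOT EXISTS linkout_map(
    short_key TEXT PRIMARY KEY, long_url TEXT UNIQUE);
CREATE TABLE IF NOT EXISTS linkout_annotation(
    short_key TEXT, annotation_uid INTEGER,
    PRIMARY KEY(short_key, annotation_uid));
CREATE TABLE IF NOT EXISTS laertes_summary(
    rollup_level INTEGER, ingredient_concept_id INTEGER,
    clinical_drug_concept_id INTEGER, hoi_concept_id INTEGER,
    evidence_type TEXT, statistic_type TEXT, aggregate_value REAL);
CREATE TABLE IF NOT EXISTS etl_report(
    source_id TEXT PRIMARY KEY, records_read INTEGER,
    records_normalized INTEGER, pairs_in_source INTEGER,
    pairs_mapped INTEGER, rejects TEXT);
CREATE TABLE IF NOT EXISTS counters(name TEXT PRIMARY KEY, value INTEGER);
"""

_EXPORT_TABLES = {
    "concept": "concept_id",
    "concept_relationship": "source_concept_id, target_concept_id",
    "concept_ancestor": "ancestor_concept_id, descendant_concept_id",
    "evidence_sources": "source_id",
    "drug_hoi_relationship": "id",
    "drug_hoi_evidence": "id, source_id, evidence_type, statistic_type",
    "adr_annotation": "annotation_uid",
    "target": "annotation_uid",
    "adr_body": "annotation_uid, body_index",
    "linkout_map": "short_key",
    "linkout_annotation": "short_key, annotation_uid",
    "laertes_summary": (
        "rollup_level, ingredient_concept_id, clinical_drug_concept_id, "
        "hoi_concept_id, evidence_type, statistic_type"
    ),
    "etl_report": "source_id",
}


class EvidenceStore:
    """sqlite-backed store; pass ``":memory:"`` (default) for transient use."""

    def __init__(self, path: str | Path = ":memory:") -> None:
        self.path = str(path)
        self._conn = sqlite3.connect(self.path)
        self._conn.executescript(_SCHEMA)
        self._conn.commit()
        self._vocab_cache: VocabularyStore | None = None

    def close(self) -> None:
        self._conn.close()

    # -- counters ---------------------------------------------------------

    def next_counter(self, name: str) -> int:
        cur = self._conn.execute("SELECT value FROM counters WHERE name=?", (name,))
        row = cur.fetchone()
        value = 0 if row is None else row[0]
        self._conn.execute(
            "INSERT INTO counters(name, value) VALUES(?, ?) "
            "ON CONFLICT(name) DO UPDATE SET value=excluded.value",
            (name, value + 1),
        )
        self._conn.commit()
        return value

    def next_annotation_uid(self) -> int:
        return self.next_counter("annotation_uid") + 1  # uids start at 1

    # -- vocabulary -------------------------------------------------------

    def attach_vocabulary(self, vocab: VocabularyStore) -> None:
        c = self._conn
        c.execute("DELETE FROM concept")
        c.execute("DELETE FROM concept_relationship")
        c.execute("DELETE FROM concept_ancestor")
        c.executemany(
            "INSERT INTO concept VALUES(?,?,?,?,?,?)",
            [
                (x.concept_id, x.source_code, x.name, x.vocabulary_id.value,
                 x.concept_class.value, int(x.is_standard))
                for x in vocab.concepts
            ],
        )
        c.executemany(
            "INSERT INTO concept_relationship VALUES(?,?,?)",
            [(m.source_concept_id, m.target_concept_id, m.relationship)
             for m in vocab.mappings],
        )
        c.executemany(
            "INSERT INTO concept_ancestor VALUES(?,?)",
            [(a.ancestor_concept_id, a.descendant_concept_id)
             for a in vocab.ancestors],
        )
        c.commit()
        self._vocab_cache = vocab

    def vocabulary(self) -> VocabularyStore:
        if self._vocab_cache is None:
            concepts = [
                Concept(cid, code, name, Vocabulary(v), ConceptClass(cc), bool(std))
                for cid, code, name, v, cc, std in self._conn.execute(
                    "SELECT * FROM concept"
                )
            ]
            if not concepts:
                raise EtlError("no vocabulary loaded in the store")
            mappings = [
                ConceptMapping(s, t, r)
                for s, t, r in self._conn.execute("SELECT * FROM concept_relationship")
            ]
            ancestors = [
                ConceptAncestor(a, d)
                for a, d in self._conn.execute("SELECT * FROM concept_ancestor")
            ]
            self._vocab_cache = VocabularyStore(concepts, mappings, ancestors)
        return self._vocab_cache

    # -- sources ----------------------------------------------------------

    def register_source(self, meta: EvidenceSourceMeta) -> None:
        self._conn.execute(
            "INSERT INTO evidence_sources VALUES(?,?,?,?,?) "
            "ON CONFLICT(source_id) DO UPDATE SET title=excluded.title, "
            "coverage_level=excluded.coverage_level, coding=excluded.coding, "
            "version_tag=excluded.version_tag",
            (meta.source_id, meta.title, meta.coverage_level, meta.coding,
             meta.version_tag),
        )
        self._conn.commit()

    def source(self, source_id: str) -> EvidenceSourceMeta | None:
        row = self._conn.execute(
            "SELECT * FROM evidence_sources WHERE source_id=?", (source_id,)
        ).fetchone()
        return EvidenceSourceMeta(*row) if row else None

    def sources(self) -> list[EvidenceSourceMeta]:
        return [
            EvidenceSourceMeta(*row)
            for row in self._conn.execute(
                "SELECT * FROM evidence_sources ORDER BY source_id"
            )
        ]

    # -- annotations ------------------------------------------------------

    def add_annotation(self, annotation: Annotation, source_id: str) -> None:
        rows = to_relational(annotation)
        uid, ann_type = rows.annotation_row
        self._conn.execute(
            "INSERT INTO adr_annotation VALUES(?,?,?)", (uid, ann_type, source_id)
        )
        self._conn.execute('INSERT INTO "target" VALUES(?,?,?,?)', rows.target_row)
        self._conn.executemany("INSERT INTO adr_body VALUES(?,?,?,?,?,?,?)", rows.body_rows)
        self._conn.commit()

    def annotation(self, uid: int) -> Annotation | None:
        row = self._conn.execute(
            "SELECT annotation_uid, annotation_type FROM adr_annotation "
            "WHERE annotation_uid=?",
            (uid,),
        ).fetchone()
        if row is None:
            return None
        target_row = self._conn.execute(
            'SELECT * FROM "target" WHERE annotation_uid=?', (uid,)
        ).fetchone()
        body_rows = self._conn.execute(
            "SELECT * FROM adr_body WHERE annotation_uid=? ORDER BY body_index", (uid,)
        ).fetchall()
        return rebuild_from_relational(
            RelationalRows(tuple(row), tuple(target_row),
                           tuple(tuple(b) for b in body_rows))
        )

    def annotations(self, source_id: str | None = None) -> list[Annotation]:
        if source_id is None:
            uids = [r[0] for r in self._conn.execute(
                "SELECT annotation_uid FROM adr_annotation ORDER BY annotation_uid")]
        else:
            uids = [r[0] for r in self._conn.execute(
                "SELECT annotation_uid FROM adr_annotation WHERE source_id=? "
                "ORDER BY annotation_uid", (source_id,))]
        return [self.annotation(u) for u in uids]

    def annotation_count(self, source_id: str | None = None) -> int:
        if source_id is None:
            return self._conn.execute("SELECT COUNT(*) FROM adr_annotation").fetchone()[0]
        return self._conn.execute(
            "SELECT COUNT(*) FROM adr_annotation WHERE source_id=?", (source_id,)
        ).fetchone()[0]

    def delete_source_data(self, source_id: str) -> None:
        """Remove a source's annotations, evidence rows, linkout-annotation
        rows and report; linkout_map survives so short keys stay stable."""
        c = self._conn
        uids = [r[0] for r in c.execute(
            "SELECT annotation_uid FROM adr_annotation WHERE source_id=?", (source_id,))]
        if uids:
            marks = ",".join("?" * len(uids))
            c.execute(f"DELETE FROM adr_body WHERE annotation_uid IN ({marks})", uids)
            c.execute(f'DELETE FROM "target" WHERE annotation_uid IN ({marks})', uids)
            c.execute(
                f"DELETE FROM linkout_annotation WHERE annotation_uid IN ({marks})", uids
            )
        c.execute("DELETE FROM adr_annotation WHERE source_id=?", (source_id,))
        c.execute("DELETE FROM drug_hoi_evidence WHERE source_id=?", (source_id,))
        c.execute("DELETE FROM etl_report WHERE source_id=?", (source_id,))
        # drop relationships no longer referenced by any evidence record
        c.execute(
            "DELETE FROM drug_hoi_relationship WHERE id NOT IN "
            "(SELECT DISTINCT id FROM drug_hoi_evidence)"
        )
        c.commit()

    # -- relationships / evidence ----------------------------------------

    def upsert_relationship(
        self, rel_id: str, drug_concept_id: int, rxnorm_drug: str,
        hoi_concept_id: int, snomed_hoi: str,
    ) -> None:
        self._conn.execute(
            "INSERT OR REPLACE INTO drug_hoi_relationship VALUES(?,?,?,?,?)",
            (rel_id, drug_concept_id, rxnorm_drug, hoi_concept_id, snomed_hoi),
        )
        self._conn.commit()

    def relationship(self, rel_id: str):
        return self._conn.execute(
            "SELECT * FROM drug_hoi_relationship WHERE id=?", (rel_id,)
        ).fetchone()

    def add_evidence(
        self, rel_id: str, source_id: str, evidence_type: str, modality: str,
        statistic_type: str, statistic_value: float, evidence_linkout: str,
    ) -> None:
        self._conn.execute(
            "INSERT INTO drug_hoi_evidence VALUES(?,?,?,?,?,?,?)",
            (rel_id, source_id, evidence_type, modality, statistic_type,
             statistic_value, evidence_linkout),
        )
        self._conn.commit()

    def evidence_rows(self, source_id: str | None = None) -> list[tuple]:
        q = (
            "SELECT e.id, e.source_id, e.evidence_type, e.modality, "
            "e.statistic_type, e.statistic_value, e.evidence_linkout, "
            "r.drug_concept_id, r.rxnorm_drug, r.hoi_concept_id, r.snomed_hoi "
            "FROM drug_hoi_evidence e JOIN drug_hoi_relationship r ON e.id = r.id"
        )
        if source_id is None:
            rows = self._conn.execute(
                q + " ORDER BY e.id, e.source_id, e.evidence_type, e.statistic_type")
        else:
            rows = self._conn.execute(
                q + " WHERE e.source_id=? ORDER BY e.id, e.evidence_type, "
                "e.statistic_type", (source_id,))
        return [tuple(r) for r in rows]

    # -- linkouts ---------------------------------------------------------

    def short_key_for(self, long_url: str) -> str | None:
        row = self._conn.execute(
            "SELECT short_key FROM linkout_map WHERE long_url=?", (long_url,)
        ).fetchone()
        return row[0] if row else None

    def long_url_for(self, short_key: str) -> str | None:
        row = self._conn.execute(
            "SELECT long_url FROM linkout_map WHERE short_key=?", (short_key,)
        ).fetchone()
        return row[0] if row else None

    def record_linkout(self, short_key: str, long_url: str, uids: list[int]) -> None:
        self._conn.execute(
            "INSERT OR REPLACE INTO linkout_map VALUES(?,?)", (short_key, long_url)
        )
        self._conn.execute(
            "DELETE FROM linkout_annotation WHERE short_key=?", (short_key,)
        )
        self._conn.executemany(
            "INSERT INTO linkout_annotation VALUES(?,?)",
            [(short_key, u) for u in uids],
        )
        self._conn.commit()

    def linkout_uids(self, short_key: str) -> list[int]:
        return [
            r[0]
            for r in self._conn.execute(
                "SELECT annotation_uid FROM linkout_annotation WHERE short_key=? "
                "ORDER BY annotation_uid",
                (short_key,),
            )
        ]

    # -- summary ----------------------------------------------------------

    def replace_summary(self, rows: list[tuple]) -> None:
        self._conn.execute("DELETE FROM laertes_summary")
        self._conn.executemany(
            "INSERT INTO laertes_summary VALUES(?,?,?,?,?,?,?)", rows
        )
        self._conn.commit()

    def summary_rows(self, rollup_level: int | None = None) -> list[tuple]:
        if rollup_level is None:
            cur = self._conn.execute(
                "SELECT * FROM laertes_summary ORDER BY rollup_level, "
                "ingredient_concept_id, clinical_drug_concept_id, hoi_concept_id, "
                "evidence_type, statistic_type"
            )
        else:
            cur = self._conn.execute(
                "SELECT * FROM laertes_summary WHERE rollup_level=? ORDER BY "
                "ingredient_concept_id, clinical_drug_concept_id, hoi_concept_id, "
                "evidence_type, statistic_type",
                (rollup_level,),
            )
        return [tuple(r) for r in cur]

    # -- reports ----------------------------------------------------------

    def save_etl_report(self, source_id: str, records_read: int,
                        records_normalized: int, pairs_in_source: int,
                        pairs_mapped: int, rejects_json: str) -> None:
        self._conn.execute(
            "INSERT OR REPLACE INTO etl_report VALUES(?,?,?,?,?,?)",
            (source_id, records_read, records_normalized, pairs_in_source,
             pairs_mapped, rejects_json),
        )
        self._conn.commit()

    def etl_report_rows(self) -> list[tuple]:
        return [
            tuple(r)
            for r in self._conn.execute("SELECT * FROM etl_report ORDER BY source_id")
        ]

    # -- graph / export ---------------------------------------------------

    def graph(self) -> Graph:
        """Union RDF graph rebuilt from the relational annotation rows."""
        g = Graph()
        g.bind("oa", "http://www.w3.org/ns/oa#")
        g.bind("ohdsi", "http://purl.org/net/ohdsi#")
        for ann in self.annotations():
            for triple in to_triples(ann):
                g.add(triple)
        return g

    def export_tables(self, out_dir: str | Path) -> list[Path]:
        """Byte-deterministic dump: sorted TSV per table + sorted graph.nt."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        written = []
        for table, order in _EXPORT_TABLES.items():
            cur = self._conn.execute(f'SELECT * FROM "{table}" ORDER BY {order}')
            cols = [d[0] for d in cur.description]
            path = out / f"{table}.tsv"
            with open(path, "w", newline="") as fh:
                w = csv.writer(fh, delimiter="\t", lineterminator="\n")
                w.writerow(cols)
                for row in cur:
                    w.writerow(["" if v is None else v for v in row])
            written.append(path)
        nt_path = out / "graph.nt"
        lines = sorted(
            self.graph().serialize(format="nt11").strip().splitlines()
        )
        nt_path.write_text("\n".join(lines) + "\n")
        written.append(nt_path)
        return written
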