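"""Per-source ETL adapters: raw evidence files -> annotations + evidence.

Every source follows the same three-step pattern: (1) transform each raw
record into normalized drug-HOI pairs (drug to RxNorm, HOI to SNOMED-CT,
by the source's own route), (2) load one annotation per accepted pair into
the store, (3) aggregate per-pair statistics and mint linkouts. Mapping
misses are *rejections* (expected coverage loss, reported per record);
malformed files are parse errors and abort the load.

Normalization routes:

* SPL_US        — RxNorm clinical-drug code lookup, ingredient via hierarchy;
                  MedDRA HOI -> SNOMED via MAPS_TO.
* EU_SPC        — drug name string match against RxNorm ingredients;
                  MedDRA HOI -> SNOMED.
* MEDLINE_MESH  — MeSH drug -> RxNorm, MeSH HOI -> SNOMED via MAPS_TO.
* MEDLINE_SEMMED— UMLS CUI crosswalk, then MAPS_TO where the crosswalk
                  lands on a non-standard concept.
* FAERS         — direct RxNorm code lookup; MedDRA HOI -> SNOMED; emits a
                  case-count pair AND a PRR pair per record.
* CTD           — same MeSH route as MEDLINE_MESH.

Mapping fan-out (one source code with several standard targets) duplicates
the pair per target; nothing is silently collapsed.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .annotation import Annotation, build_annotation
from .errors import EtlError, ParseError
from .fixtures import RAW_COLUMNS, SourceKind
from .store import EvidenceSourceMeta, EvidenceStore
from .vocabulary import (
    Concept,
    ConceptClass,
    Vocabulary,
    VocabularyStore,
    ingredient_for,
    map_to_standard,
    match_drug_by_name,
)

__all__ = [
    "RawRecord",
    "NormalizedPair",
    "Rejection",
    "RejectReason",
    "EtlReport",
    "SOURCE_META",
    "EVIDENCE_TYPES",
    "evidence_type_for",
    "parse_raw",
    "normalize_record",
    "run_etl",
]

MODALITY_SUPPORTS = "SUPPORTS"
MODALITY_REFUTES = "REFUTES"  # carried in the schema; no shipped adapter emits it

STAT_RECORD_COUNT = "RECORD_COUNT"
STAT_CASE_COUNT = "CASE_COUNT"
STAT_PRR = "PRR"


class RejectReason(str, enum.Enum):
    DRUG_UNMAPPED = "DRUG_UNMAPPED"
    HOI_UNMAPPED = "HOI_UNMAPPED"
    BOTH_UNMAPPED = "BOTH_UNMAPPED"


@dataclass(frozen=True)
class RawRecord:
    kind: SourceKind
    index: int
    fields: dict

    @property
    def ref(self) -> str:
        return f"{self.kind.value}:{self.index}"


@dataclass(frozen=True)
class NormalizedPair:
    """One standardized drug-HOI evidence unit from one raw record."""

    drug_concept_id: int          # clinical drug or ingredient, per source level
    ingredient_concept_id: int
    hoi_concept_id: int
    evidence_type: str
    modality: str
    statistic_type: str
    statistic_value: float
    provenance: str


@dataclass(frozen=True)
class Rejection:
    record_ref: str
    reason: RejectReason


@dataclass
class EtlReport:
    source_id: str
    records_read: int = 0
    records_normalized: int = 0
    pairs_in_source: int = 0
    pairs_mapped: int = 0
    rejects: list[Rejection] = field(default_factory=list)

    @property
    def coverage_percent(self) -> float | None:
        if self.pairs_in_source == 0:
            return None
        from .summary import percent_one_decimal

        return percent_one_decimal(self.pairs_mapped, self.pairs_in_source)


#: Default source registry (metadata per Fig.-4-style evidence_sources rows).
SOURCE_META: dict[SourceKind, EvidenceSourceMeta] = {
    SourceKind.SPL_US: EvidenceSourceMeta(
        "spl_us", "US product labels (SPLICER NLP)", "CLINICAL_DRUG",
        "RxNorm drug / MedDRA HOI", "1"),
    SourceKind.EU_SPC: EvidenceSourceMeta(
        "eu_spc", "EU SmPC adverse reactions", "INGREDIENT",
        "drug name / MedDRA HOI", "1"),
    SourceKind.MEDLINE_MESH: EvidenceSourceMeta(
        "medline_mesh", "MEDLINE MeSH co-indexing", "INGREDIENT",
        "MeSH drug / MeSH HOI", "1"),
    SourceKind.MEDLINE_SEMMED: EvidenceSourceMeta(
        "medline_semmed", "Semantic MEDLINE sentence spans", "INGREDIENT",
        "UMLS CUI drug / UMLS CUI HOI", "1"),
    SourceKind.FAERS: EvidenceSourceMeta(
        "faers", "FAERS counts and PRR", "INGREDIENT",
        "RxNorm drug / MedDRA HOI", "1"),
    SourceKind.CTD: EvidenceSourceMeta(
        "ctd", "CTD chemical-disease associations", "INGREDIENT",
        "MeSH chemical / MeSH disease", "1"),
}

_MEDLINE_TAGS = {"CASE_REPORT": "CR", "CLIN_TRIAL": "ClinTrial", "OTHER": "Other"}

#: All evidence-type tags any adapter can emit.
EVIDENCE_TYPES = (
    "SPL_SPLICER",
    "SPL_EU_SPC",
    "MEDLINE_MeSH_CR",
    "MEDLINE_MeSH_ClinTrial",
    "MEDLINE_MeSH_Other",
    "MEDLINE_SemMedDB_CR",
    "MEDLINE_SemMedDB_ClinTrial",
    "MEDLINE_SemMedDB_Other",
    "CTD_ChemicalDisease",
    "FAERS_CaseCount",
    "FAERS_PRR",
)


def evidence_type_for(
    kind: SourceKind,
    pub_type: str | None = None,
    statistic_type: str | None = None,
) -> str:
    """The evidence-type tag for one (source kind, publication type) case.

    MEDLINE kinds require a publication type; FAERS yields one tag per
    statistic stream (case count vs PRR), selected by ``statistic_type``.
    """
    if kind is SourceKind.SPL_US:
        return "SPL_SPLICER"
    if kind is SourceKind.EU_SPC:
        return "SPL_EU_SPC"
    if kind is SourceKind.CTD:
        return "CTD_ChemicalDisease"
    if kind is SourceKind.FAERS:
        return "FAERS_PRR" if statistic_type == STAT_PRR else "FAERS_CaseCount"
    if kind in (SourceKind.MEDLINE_MESH, SourceKind.MEDLINE_SEMMED):
        if pub_type is None:
            raise EtlError(f"{kind.value}: publication type is required")
        try:
            suffix = _MEDLINE_TAGS[pub_type]
        except KeyError:
            raise EtlError(f"unknown publication type {pub_type!r}") from None
        stem = "MeSH" if kind is SourceKind.MEDLINE_MESH else "SemMedDB"
        return f"MEDLINE_{stem}_{suffix}"
    raise EtlError(f"unknown source kind {kind!r}")


# -- parsing --------------------------------------------------------------


def parse_raw(path: str | Path, kind: SourceKind) -> list[RawRecord]:
    """Read a raw source file; a header or field-count mismatch is a parse
    error (data corruption), never a rejection."""
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        return []
    except OSError as exc:
        raise ParseError(f"cannot read {path}: {exc}") from exc
    expected = RAW_COLUMNS[kind]
    if list(df.columns) != expected:
        raise ParseError(
            f"{path}: expected columns {expected}, got {list(df.columns)}"
        )
    return [
        RawRecord(kind, i, dict(zip(expected, row)))
        for i, row in enumerate(df.itertuples(index=False, name=None))
    ]


# -- normalization --------------------------------------------------------


def _drug_targets(
    record: RawRecord,
    kind: SourceKind,
    vocab: VocabularyStore,
    crosswalk: dict[str, int] | None,
    strip_salts: bool,
) -> list[tuple[Concept, Concept]]:
    """Resolve the drug side to [(drug_level_concept, ingredient)] pairs."""
    f = record.fields
    if kind is SourceKind.SPL_US:
        concept = vocab.concept_by_code(Vocabulary.RXNORM, f["rxnorm_clinical_drug_code"])
        if concept is None:
            return []
        return [(concept, ing) for ing in ingredient_for(vocab, concept.concept_id)]
    if kind is SourceKind.EU_SPC:
        matches = match_drug_by_name(vocab, f["drug_name"], strip_salts=strip_salts)
        return [(m, m) for m in matches]
    if kind in (SourceKind.MEDLINE_MESH, SourceKind.CTD):
        code = f["mesh_drug_code"] if kind is SourceKind.MEDLINE_MESH else f["mesh_chemical_code"]
        concept = vocab.concept_by_code(Vocabulary.MESH, code)
        if concept is None:
            return []
        out = []
        for t in map_to_standard(vocab, concept.concept_id, Vocabulary.RXNORM):
            out.extend((t, ing) for ing in ingredient_for(vocab, t.concept_id))
        return out
    if kind is SourceKind.MEDLINE_SEMMED:
        if crosswalk is None:
            raise EtlError("MEDLINE_SEMMED requires a UMLS crosswalk")
        cid = crosswalk.get(f["cui_drug"])
        if cid is None:
            return []
        concept = vocab.concept(cid)
        if concept.vocabulary_id is Vocabulary.RXNORM:
            targets = [concept]
        else:
            targets = map_to_standard(vocab, cid, Vocabulary.RXNORM)
        out = []
        for t in targets:
            out.extend((t, ing) for ing in ingredient_for(vocab, t.concept_id))
        return out
    if kind is SourceKind.FAERS:
        concept = vocab.concept_by_code(Vocabulary.RXNORM, f["drug_code"])
        if concept is None:
            return []
        return [(concept, ing) for ing in ingredient_for(vocab, concept.concept_id)]
    raise EtlError(f"unknown source kind {kind!r}")


def _hoi_targets(
    record: RawRecord,
    kind: SourceKind,
    vocab: VocabularyStore,
    crosswalk: dict[str, int] | None,
) -> list[Concept]:
    f = record.fields
    if kind in (SourceKind.SPL_US, SourceKind.EU_SPC, SourceKind.FAERS):
        code = f.get("meddra_hoi_code") or f.get("hoi_code")
        concept = vocab.concept_by_code(Vocabulary.MEDDRA, code)
    elif kind in (SourceKind.MEDLINE_MESH, SourceKind.CTD):
        code = f["mesh_hoi_code"] if kind is SourceKind.MEDLINE_MESH else f["mesh_disease_code"]
        concept = vocab.concept_by_code(Vocabulary.MESH, code)
    elif kind is SourceKind.MEDLINE_SEMMED:
        cid = crosswalk.get(f["cui_hoi"]) if crosswalk else None
        concept = vocab.concept(cid) if cid is not None else None
    else:
        raise EtlError(f"unknown source kind {kind!r}")
    if concept is None:
        return []
    return map_to_standard(vocab, concept.concept_id, Vocabulary.SNOMED)


def normalize_record(
    record: RawRecord,
    kind: SourceKind,
    vocab: VocabularyStore,
    crosswalk: dict[str, int] | None = None,
    strip_salts: bool = True,
) -> list[NormalizedPair] | Rejection:
    """Map one raw record to normalized pairs, or a rejection.

    Fan-out yields one pair per (drug target x HOI target); a FAERS record
    additionally splits into a case-count pair and a PRR pair.
    """
    if set(record.fields) != set(RAW_COLUMNS[kind]):
        raise ParseError(f"{record.ref}: fields do not match the {kind.value} shape")
    drugs = _drug_targets(record, kind, vocab, crosswalk, strip_salts)
    hois = _hoi_targets(record, kind, vocab, crosswalk)
    if not drugs or not hois:
        if not drugs and not hois:
            reason = RejectReason.BOTH_UNMAPPED
        elif not drugs:
            reason = RejectReason.DRUG_UNMAPPED
        else:
            reason = RejectReason.HOI_UNMAPPED
        return Rejection(record.ref, reason)
    pairs: list[NormalizedPair] = []
    for drug, ingredient in drugs:
        for hoi in hois:
            if kind is SourceKind.FAERS:
                f = record.fields
                try:
                    count = int(f["case_count"])
                    prr = float(f["prr"])
                except ValueError as exc:
                    raise ParseError(f"{record.ref}: bad FAERS statistics: {exc}") from exc
                streams = [
                    (STAT_CASE_COUNT, float(count)),
                    (STAT_PRR, prr),
                ]
            else:
                streams = [(STAT_RECORD_COUNT, 1.0)]
            for stat_type, value in streams:
                pairs.append(
                    NormalizedPair(
                        drug_concept_id=drug.concept_id,
                        ingredient_concept_id=ingredient.concept_id,
                        hoi_concept_id=hoi.concept_id,
                        evidence_type=evidence_type_for(
                            kind, record.fields.get("pub_type"), stat_type
                        ),
                        modality=MODALITY_SUPPORTS,
                        statistic_type=stat_type,
                        statistic_value=value,
                        provenance=record.ref,
                    )
                )
    return pairs


# -- the full per-source run ---------------------------------------------


def load_crosswalk(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if list(df.columns) != ["cui", "concept_id"]:
        raise ParseError(f"{path}: expected columns ['cui', 'concept_id']")
    return {r.cui: int(r.concept_id) for r in df.itertuples(index=False)}


def _native_pair_key(record: RawRecord) -> tuple[str, str]:
    f = record.fields
    k = record.kind
    if k is SourceKind.SPL_US:
        return (f["rxnorm_clinical_drug_code"], f["meddra_hoi_code"])
    if k is SourceKind.EU_SPC:
        return (f["drug_name"], f["meddra_hoi_code"])
    if k is SourceKind.MEDLINE_MESH:
        return (f["mesh_drug_code"], f["mesh_hoi_code"])
    if k is SourceKind.MEDLINE_SEMMED:
        return (f["cui_drug"], f["cui_hoi"])
    if k is SourceKind.FAERS:
        return (f["drug_code"], f["hoi_code"])
    return (f["mesh_chemical_code"], f["mesh_disease_code"])


def run_etl(
    kind: SourceKind,
    raw_path: str | Path,
    vocab: VocabularyStore,
    store: EvidenceStore,
    version_tag: str = "1",
    replace: bool = False,
    strip_salts: bool = True,
    crosswalk_path: str | Path | None = None,
    source_id: str | None = None,
    collect_annotations: list[Annotation] | None = None,
) -> EtlReport:
    """Transform, load and aggregate one raw source file.

    Idempotent per (source_id, version_tag): loading the same pair again
    requires ``replace=True`` and then replaces, never duplicates. Distinct
    pairs in the report are counted at the source's native level (clinical
    drug for SPL_US, ingredient otherwise).
    """
    meta_default = SOURCE_META[kind]
    sid = source_id or meta_default.source_id
    meta = EvidenceSourceMeta(
        sid, meta_default.title, meta_default.coverage_level,
        meta_default.coding, version_tag,
    )
    existing = store.source(sid)
    if existing is not None and existing.version_tag == version_tag and not replace:
        raise EtlError(
            f"source {sid!r} version {version_tag!r} already loaded; "
            "pass replace=True to reload"
        )
    crosswalk = None
    if kind is SourceKind.MEDLINE_SEMMED:
        if crosswalk_path is None:
            crosswalk_path = Path(raw_path).with_name("medline_semmed_crosswalk.tsv")
        crosswalk = load_crosswalk(crosswalk_path)

    records = parse_raw(raw_path, kind)
    store.delete_source_data(sid)
    store.register_source(meta)

    report = EtlReport(source_id=sid, records_read=len(records))
    native_pairs: set[tuple[str, str]] = set()
    mapped_pairs: set[tuple[int, int]] = set()
    pairs_with_uids: list[tuple[NormalizedPair, int]] = []
    for record in records:
        native_pairs.add(_native_pair_key(record))
        result = normalize_record(record, kind, vocab, crosswalk, strip_salts)
        if isinstance(result, Rejection):
            report.rejects.append(result)
            continue
        report.records_normalized += 1
        for pair in result:
            if kind is SourceKind.SPL_US:
                mapped_pairs.add((pair.drug_concept_id, pair.hoi_concept_id))
            else:
                mapped_pairs.add((pair.ingredient_concept_id, pair.hoi_concept_id))
            uid = store.next_annotation_uid()
            ann = build_annotation(pair, record, kind, uid)
            store.add_annotation(ann, sid)
            if collect_annotations is not None:
                collect_annotations.append(ann)
            pairs_with_uids.append((pair, uid))
    report.pairs_in_source = len(native_pairs)
    report.pairs_mapped = len(mapped_pairs)

    from .summary import aggregate_evidence  # deferred: summary imports etl types

    aggregate_evidence(store, vocab, pairs_with_uids, meta)
    store.save_etl_report(
        sid, report.records_read, report.records_normalized,
        report.pairs_in_source, report.pairs_mapped,
        json.dumps([[r.record_ref, r.reason.value] for r in report.rejects]),
    )
    return report
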