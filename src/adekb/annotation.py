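"""Open Annotation evidence items with dual graph/relational form.

Every evidence item is an annotation: one *target* (the source document,
with an optional selector carrying the exact text span or label section)
and one or more *bodies* (the drug, its ingredient, the HOI, and the
evidence-type tag). The same annotation can be rendered as RDF triples
under the ``oa:`` and ``ohdsi:`` namespaces or as rows of the
``adr_annotation`` / ``target`` / ``adr_body`` relational tables; the two
renderings are mutually lossless, which the test suite checks as exact
set-of-triples equality.

All annotation nodes get minted URIs (``ohdsi:annotation/{uid}`` etc.) —
no blank nodes, so graph equality is decidable term for term.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

from rdflib import Graph, Literal, Namespace, URIRef
from rdflib.namespace import RDF

from .errors import EtlError, UsageError
from .fixtures import SourceKind

if TYPE_CHECKING:  # pragma: no cover
    from .etl import NormalizedPair, RawRecord
    from .store import EvidenceStore

__all__ = [
    "OA",
    "OHDSI",
    "Selector",
    "AnnotationTarget",
    "AnnotationBody",
    "Annotation",
    "ANNOTATION_TYPES",
    "build_annotation",
    "to_triples",
    "to_relational",
    "rebuild_from_relational",
    "query_annotations",
]

OA = Namespace("http://www.w3.org/ns/oa#")
OHDSI = Namespace("http://purl.org/net/ohdsi#")

#: Registered annotation type (CURIE) per source kind.
ANNOTATION_TYPES: dict[SourceKind, str] = {
    SourceKind.MEDLINE_MESH: "ohdsi:PubMedDrugHOIAnnotation",
    SourceKind.MEDLINE_SEMMED: "ohdsi:PubMedDrugHOIAnnotation",
    SourceKind.SPL_US: "ohdsi:SPLDrugHOIAnnotation",
    SourceKind.EU_SPC: "ohdsi:SPLDrugHOIAnnotation",
    SourceKind.FAERS: "ohdsi:FAERSDrugHOIAnnotation",
    SourceKind.CTD: "ohdsi:CTDDrugHOIAnnotation",
}

# SmPC adverse-reaction section; the EU source shape carries no section of
# its own but label-type annotations always carry one.
EU_SPC_SECTION = "UNDESIRABLE EFFECTS"

METHOD_TAGS: dict[SourceKind, str] = {
    SourceKind.MEDLINE_MESH: "MeSH-co-indexing",
    SourceKind.MEDLINE_SEMMED: "SemMedDB-NLP",
    SourceKind.SPL_US: "SPLICER-NLP",
    SourceKind.EU_SPC: "drug-name-string-match",
    SourceKind.FAERS: "spontaneous-report-aggregation",
    SourceKind.CTD: "curated-chemical-disease",
}


@dataclass(frozen=True)
class Selector:
    exact_text: str | None = None
    section: str | None = None


@dataclass(frozen=True)
class AnnotationTarget:
    source_document_uri: str
    selector: Selector | None = None


@dataclass(frozen=True)
class AnnotationBody:
    drug_concept_id: int
    ingredient_concept_id: int
    hoi_concept_id: int
    evidence_type: str
    method_tag: str


@dataclass(frozen=True)
class Annotation:
    annotation_uid: int
    annotation_type: str
    target: AnnotationTarget
    bodies: tuple[AnnotationBody, ...]

    def __post_init__(self) -> None:
        if not self.bodies:
            raise EtlError(f"annotation {self.annotation_uid} has no bodies")


def _target_uri(kind: SourceKind, record: "RawRecord") -> str:
    f = record.fields
    if kind in (SourceKind.MEDLINE_MESH, SourceKind.MEDLINE_SEMMED):
        return f"http://www.ncbi.nlm.nih.gov/pubmed/{f['pmid']}"
    if kind is SourceKind.SPL_US:
        return f"http://dailymed.nlm.nih.gov/dailymed/lookup.cfm?setid={f['set_id']}"
    if kind is SourceKind.EU_SPC:
        return f"urn:eu-spc:{f['doc_id']}"
    if kind is SourceKind.FAERS:
        return f"urn:faers:{f['drug_code']}-{f['hoi_code']}"
    if kind is SourceKind.CTD:
        return f"urn:ctd:{f['mesh_chemical_code']}-{f['mesh_disease_code']}"
    raise EtlError(f"no target URI rule for kind {kind}")


def _selector(kind: SourceKind, record: "RawRecord") -> Selector | None:
    f = record.fields
    if kind is SourceKind.MEDLINE_MESH:
        return Selector(exact_text=f["title_abstract_text"])
    if kind is SourceKind.MEDLINE_SEMMED:
        return Selector(exact_text=f["sentence_span"])
    if kind is SourceKind.SPL_US:
        return Selector(section=f["section_name"])
    if kind is SourceKind.EU_SPC:
        return Selector(section=EU_SPC_SECTION)
    return None  # FAERS / CTD carry no selector


def build_annotation(
    pair: "NormalizedPair", record: "RawRecord", kind: SourceKind, uid: int
) -> Annotation:
    """Wrap one normalized drug-HOI pair from one raw record as an
    annotation; the type, target URI and selector follow the per-kind
    registry."""
    if kind not in ANNOTATION_TYPES:
        raise EtlError(f"no registered annotation type for kind {kind}")
    body = AnnotationBody(
        drug_concept_id=pair.drug_concept_id,
        ingredient_concept_id=pair.ingredient_concept_id,
        hoi_concept_id=pair.hoi_concept_id,
        evidence_type=pair.evidence_type,
        method_tag=METHOD_TAGS[kind],
    )
    return Annotation(
        annotation_uid=uid,
        annotation_type=ANNOTATION_TYPES[kind],
        target=AnnotationTarget(_target_uri(kind, record), _selector(kind, record)),
        bodies=(body,),
    )


# -- graph form -----------------------------------------------------------


def _expand(curie: str) -> URIRef:
    prefix, _, local = curie.partition(":")
    if prefix == "ohdsi":
        return OHDSI[local]
    if prefix == "oa":
        return OA[local]
    raise EtlError(f"unknown CURIE prefix in {curie!r}")


def to_triples(annotation: Annotation) -> Graph:
    """Emit the fixed triple pattern for one annotation.

    Per annotation: a typing triple, oa:hasTarget, the target's
    oa:hasSource and (if present) selector triples; per body: oa:hasBody
    plus ohdsi:ImedsDrug, ohdsi:ImedsHoi and the evidence-type literal.
    The triple count is therefore 3 + 2*[selector] + 4*len(bodies).
    """
    g = Graph()
    g.bind("oa", OA)
    g.bind("ohdsi", OHDSI)
    uid = annotation.annotation_uid
    ann = OHDSI[f"annotation/{uid}"]
    tgt = OHDSI[f"target/{uid}"]
    g.add((ann, RDF.type, _expand(annotation.annotation_type)))
    g.add((ann, OA.hasTarget, tgt))
    g.add((tgt, OA.hasSource, URIRef(annotation.target.source_document_uri)))
    sel = annotation.target.selector
    if sel is not None:
        sel_node = OHDSI[f"selector/{uid}"]
        g.add((tgt, OA.hasSelector, sel_node))
        if sel.exact_text is not None:
            g.add((sel_node, OA.exact, Literal(sel.exact_text)))
        if sel.section is not None:
            g.add((sel_node, OHDSI.adrSection, Literal(sel.section)))
    for i, body in enumerate(annotation.bodies):
        b = OHDSI[f"body/{uid}/{i}"]
        g.add((ann, OA.hasBody, b))
        g.add((b, OHDSI.ImedsDrug, OHDSI[str(body.drug_concept_id)]))
        g.add((b, OHDSI.ImedsHoi, OHDSI[str(body.hoi_concept_id)]))
        g.add((b, OHDSI.evidenceType, Literal(body.evidence_type)))
    return g


# -- relational form ------------------------------------------------------


@dataclass(frozen=True)
class RelationalRows:
    """Rows for adr_annotation, target and adr_body (one annotation)."""

    annotation_row: tuple[int, str]
    target_row: tuple[int, str, str | None, str | None]
    body_rows: tuple[tuple[int, int, int, int, int, str, str], ...]


def to_relational(annotation: Annotation) -> RelationalRows:
    """Lossless relational projection: one adr_annotation row, one target
    row, one adr_body row per body."""
    sel = annotation.target.selector
    return RelationalRows(
        annotation_row=(annotation.annotation_uid, annotation.annotation_type),
        target_row=(
            annotation.annotation_uid,
            annotation.target.source_document_uri,
            sel.exact_text if sel else None,
            sel.section if sel else None,
        ),
        body_rows=tuple(
            (
                annotation.annotation_uid,
                i,
                b.drug_concept_id,
                b.ingredient_concept_id,
                b.hoi_concept_id,
                b.evidence_type,
                b.method_tag,
            )
            for i, b in enumerate(annotation.bodies)
        ),
    )


def rebuild_from_relational(rows: RelationalRows) -> Annotation:
    """Invert :func:`to_relational`."""
    uid, ann_type = rows.annotation_row
    _, uri, exact_text, section = rows.target_row
    selector = (
        None
        if exact_text is None and section is None
        else Selector(exact_text=exact_text, section=section)
    )
    bodies = tuple(
        AnnotationBody(drug, ing, hoi, etype, method)
        for (_, _, drug, ing, hoi, etype, method) in sorted(rows.body_rows, key=lambda r: r[1])
    )
    return Annotation(uid, ann_type, AnnotationTarget(uri, selector), bodies)


# -- querying -------------------------------------------------------------


def query_annotations(
    store: "EvidenceStore",
    drug_concept_id: int | None = None,
    hoi_concept_id: int | None = None,
    annotation_type: str | None = None,
    evidence_type: str | None = None,
) -> list[Annotation]:
    """Annotations having at least one body matching every provided filter.

    The drug filter matches exactly on either drug-level body field
    (drug_concept_id or ingredient_concept_id); no hierarchy expansion —
    that is the rollup module's job. Ordered by annotation_uid.
    """
    if all(
        f is None
        for f in (drug_concept_id, hoi_concept_id, annotation_type, evidence_type)
    ):
        raise UsageError("query_annotations requires at least one filter")
    out = []
    for ann in store.annotations():
        if annotation_type is not None and ann.annotation_type != annotation_type:
            continue
        for body in ann.bodies:
            if drug_concept_id is not None and drug_concept_id not in (
                body.drug_concept_id,
                body.ingredient_concept_id,
            ):
                continue
            if hoi_concept_id is not None and body.hoi_concept_id != hoi_concept_id:
                continue
            if evidence_type is not None and body.evidence_type != evidence_type:
                continue
            out.append(ann)
            break
    return sorted(out, key=lambda a: a.annotation_uid)
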