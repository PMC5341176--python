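"""Evidence linkouts: the bridge between summary rows and drill-down.

Each aggregated evidence record carries a URL that encodes the query
(drug, HOI, source, evidence type) needed to retrieve the exact annotation
set it was computed from. The long form is a deterministic
``laertes://evidence?...`` URI with sorted, percent-encoded parameters;
the short form is a base62 key from a persistent sequential counter
(bijective by construction — no hashing, no collisions). A persisted map
ties each key to the annotation uids recorded at mint time, so resolving
either form returns exactly the annotations that were counted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from urllib.parse import parse_qsl, urlencode

from .annotation import Annotation, query_annotations
from .errors import MintError, NotFoundError
from .store import EvidenceStore

__all__ = ["Linkout", "encode", "resolve", "long_url_for", "annotations_to_json"]

_ALPHABET = "0123456789ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz"
_SCHEME = "laertes://evidence"


def base62(n: int) -> str:
    if n < 0:
        raise ValueError("base62 requires a nonnegative integer")
    if n == 0:
        return _ALPHABET[0]
    digits = []
    while n:
        n, r = divmod(n, 62)
        digits.append(_ALPHABET[r])
    return "".join(reversed(digits))


def long_url_for(
    drug_concept_id: int, hoi_concept_id: int, source_id: str, evidence_type: str
) -> str:
    params = sorted(
        {
            "drug": str(drug_concept_id),
            "hoi": str(hoi_concept_id),
            "source": source_id,
            "type": evidence_type,
        }.items()
    )
    return f"{_SCHEME}?{urlencode(params)}"


@dataclass(frozen=True)
class Linkout:
    long_url: str
    short_key: str
    annotation_uids: frozenset[int]


def encode(
    store: EvidenceStore,
    drug_concept_id: int,
    hoi_concept_id: int,
    source_id: str,
    evidence_type: str,
) -> Linkout:
    """Mint (or re-use) the linkout for one evidence record's filters.

    Idempotent: the same arguments always yield the same short key, and the
    annotation map is refreshed to the currently matching set. Minting with
    zero matching annotations is an error — dangling linkouts are
    forbidden.
    """
    matching = [
        a.annotation_uid
        for a in query_annotations(
            store,
            drug_concept_id=drug_concept_id,
            hoi_concept_id=hoi_concept_id,
            evidence_type=evidence_type,
        )
    ]
    if not matching:
        raise MintError(
            f"no annotations match drug={drug_concept_id} hoi={hoi_concept_id} "
            f"source={source_id} type={evidence_type}"
        )
    url = long_url_for(drug_concept_id, hoi_concept_id, source_id, evidence_type)
    key = store.short_key_for(url)
    if key is None:
        key = base62(store.next_counter("linkout"))
    store.record_linkout(key, url, matching)
    return Linkout(url, key, frozenset(matching))


def resolve(store: EvidenceStore, key_or_url: str) -> list[Annotation]:
    """Return the annotation set recorded at mint time, ordered by uid.

    Accepts either the short key or the long URL; both forms resolve
    identically (the persisted map is bijective).
    """
    if "://" in key_or_url:
        key = store.short_key_for(key_or_url)
        if key is None:
            raise NotFoundError(f"unknown linkout URL {key_or_url!r}")
    else:
        key = key_or_url
        if store.long_url_for(key) is None:
            raise NotFoundError(f"unknown linkout key {key_or_url!r}")
    return [store.annotation(uid) for uid in store.linkout_uids(key)]


def parse_long_url(url: str) -> dict[str, str]:
    prefix, _, query = url.partition("?")
    if prefix != _SCHEME:
        raise NotFoundError(f"not a linkout URL: {url!r}")
    return dict(parse_qsl(query))


def annotations_to_json(annotations: list[Annotation]) -> str:
    """Stable JSON rendering of resolved annotations (one object per
    annotation with type, target and bodies)."""
    objs = []
    for a in annotations:
        sel = a.target.selector
        objs.append(
            {
                "annotation_uid": a.annotation_uid,
                "annotation_type": a.annotation_type,
                "target": {
                    "source_document_uri": a.target.source_document_uri,
                    "selector": None
                    if sel is None
                    else {"exact_text": sel.exact_text, "section": sel.section},
                },
                "bodies": [
                    {
                        "drug_concept_id": b.drug_concept_id,
                        "ingredient_concept_id": b.ingredient_concept_id,
                        "hoi_concept_id": b.hoi_concept_id,
                        "evidence_type": b.evidence_type,
                        "method_tag": b.method_tag,
                    }
                    for b in a.bodies
                ],
            }
        )
    return json.dumps(objs, indent=2)
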