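"""Aggregated evidence, four-level rollups, coverage/overlap reports and
negative-control search.

Aggregation produces one ``drug_hoi_evidence`` row per (drug-HOI
relationship, source, evidence type, statistic type): record counts count
annotations, case counts sum the source's case counts, and PRR values pass
through unchanged (a disproportionality ratio is not additive, so PRR is
carried only at full detail and never summed across drugs). Rollups
attribute clinical-drug-level evidence to the drug's ingredient(s) before
grouping at four granularities: (1) ingredient, (2) ingredient + HOI,
(3) ingredient + clinical drug, (4) full detail.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_EVEN, Decimal

import pandas as pd

from .errors import AggregationError, DomainError, UsageError
from .etl import (
    EtlReport,
    NormalizedPair,
    STAT_CASE_COUNT,
    STAT_PRR,
    STAT_RECORD_COUNT,
)
from .linkout import encode
from .store import EvidenceSourceMeta, EvidenceStore
from .vocabulary import ConceptClass, Vocabulary, VocabularyStore, ingredient_for

__all__ = [
    "EvidenceRecord",
    "SummaryRow",
    "RollupReject",
    "aggregate_evidence",
    "build_rollups",
    "coverage_report",
    "overlap_report",
    "find_negative_controls",
    "percent_one_decimal",
    "format_percent",
]


def percent_one_decimal(numerator: float, denominator: float) -> float | None:
    """100 * numerator / denominator, round-half-even at one decimal;
    None when the denominator is zero (rendered as an em dash)."""
    if denominator == 0:
        return None
    value = Decimal(numerator) * 100 / Decimal(denominator)
    return float(value.quantize(Decimal("0.1"), rounding=ROUND_HALF_EVEN))


def format_percent(value: float | None) -> str:
    return "—" if value is None else f"{value:.1f}%"


@dataclass(frozen=True)
class EvidenceRecord:
    """One aggregated statistic for a drug-HOI pair from one source."""

    relationship_id: str
    source_id: str
    evidence_type: str
    modality: str
    statistic_type: str
    statistic_value: float
    evidence_linkout: str


@dataclass(frozen=True)
class SummaryRow:
    rollup_level: int
    ingredient_concept_id: int
    clinical_drug_concept_id: int | None
    hoi_concept_id: int | None
    evidence_type: str
    statistic_type: str
    aggregate_value: float


@dataclass(frozen=True)
class RollupReject:
    relationship_id: str
    reason: str


def relationship_id_for(drug_concept_id: int, hoi_concept_id: int) -> str:
    return f"{drug_concept_id}-{hoi_concept_id}"


def aggregate_evidence(
    store: EvidenceStore,
    vocab: VocabularyStore,
    pairs_with_uids: list[tuple[NormalizedPair, int]],
    source: EvidenceSourceMeta,
) -> list[EvidenceRecord]:
    """Aggregate one ETL run's pairs into drug_hoi_evidence rows.

    Every record's linkout resolves to exactly the annotations counted
    into it; conflicting PRR values for one pair in one source are an
    aggregation error (ambiguous input), not a silent overwrite.
    """
    groups: dict[tuple[str, str, str], list[tuple[NormalizedPair, int]]] = {}
    for pair, uid in pairs_with_uids:
        rel_id = relationship_id_for(pair.drug_concept_id, pair.hoi_concept_id)
        groups.setdefault((rel_id, pair.evidence_type, pair.statistic_type), []).append(
            (pair, uid)
        )
    records: list[EvidenceRecord] = []
    for (rel_id, evidence_type, stat_type), members in sorted(groups.items()):
        pair0 = members[0][0]
        drug = vocab.concept(pair0.drug_concept_id)
        hoi = vocab.concept(pair0.hoi_concept_id)
        store.upsert_relationship(
            rel_id, drug.concept_id, drug.name, hoi.concept_id, hoi.name
        )
        if stat_type == STAT_RECORD_COUNT:
            value = float(len(members))
        elif stat_type == STAT_CASE_COUNT:
            value = float(sum(p.statistic_value for p, _ in members))
        elif stat_type == STAT_PRR:
            values = {p.statistic_value for p, _ in members}
            if len(values) > 1:
                raise AggregationError(
                    f"conflicting PRR values {sorted(values)} for {rel_id} "
                    f"in source {source.source_id}"
                )
            value = values.pop()
        else:
            raise AggregationError(f"unknown statistic type {stat_type!r}")
        link = encode(
            store, pair0.drug_concept_id, pair0.hoi_concept_id,
            source.source_id, evidence_type,
        )
        record = EvidenceRecord(
            rel_id, source.source_id, evidence_type, pair0.modality,
            stat_type, value, link.long_url,
        )
        store.add_evidence(
            rel_id, source.source_id, evidence_type, pair0.modality,
            stat_type, value, link.long_url,
        )
        records.append(record)
    return records


# -- rollups --------------------------------------------------------------


def _ingredient_split(
    vocab: VocabularyStore, drug_concept_id: int
) -> tuple[list[int], int | None]:
    """(ingredient ids, clinical_drug id or None) for one evidence drug."""
    concept = vocab.concept(drug_concept_id)
    if concept.concept_class is ConceptClass.INGREDIENT:
        return [drug_concept_id], None
    ings = [c.concept_id for c in ingredient_for(vocab, drug_concept_id)]
    return ings, drug_concept_id


def build_rollups(
    store: EvidenceStore, vocab: VocabularyStore | None = None
) -> tuple[list[SummaryRow], list[RollupReject]]:
    """Populate laertes_summary at all four levels.

    Record and case counts aggregate by sum; PRR appears only at level 4
    (full detail). A drug with no ingredient ancestor is routed to the
    reject list, never silently dropped. Drugs mapping to several
    ingredients contribute to each ingredient's rollup.
    """
    vocab = vocab or store.vocabulary()
    contributions: list[tuple[int, int | None, int, str, str, float]] = []
    rejects: list[RollupReject] = []
    for row in store.evidence_rows():
        (rel_id, _source, etype, _modality, stype, value, _link,
         drug_id, _dname, hoi_id, _hname) = row
        ings, clinical = _ingredient_split(vocab, drug_id)
        if not ings:
            rejects.append(RollupReject(rel_id, "drug has no ingredient ancestor"))
            continue
        for ing in ings:
            contributions.append((ing, clinical, hoi_id, etype, stype, value))

    def _group(keyfunc, level: int, keep_prr: bool) -> list[SummaryRow]:
        agg: dict[tuple, float] = {}
        for ing, clinical, hoi, etype, stype, value in contributions:
            if stype == STAT_PRR and not keep_prr:
                continue
            key = keyfunc(ing, clinical, hoi) + (etype, stype)
            if stype == STAT_PRR:
                if key in agg and agg[key] != value:
                    raise AggregationError(
                        f"conflicting PRR values at rollup level {level} for {key}"
                    )
                agg[key] = value
            else:
                agg[key] = agg.get(key, 0.0) + value
        rows = []
        for key, value in sorted(agg.items(), key=lambda kv: tuple(map(str, kv[0]))):
            ing, clinical, hoi = key[0], key[1], key[2]
            rows.append(SummaryRow(level, ing, clinical, hoi, key[3], key[4], value))
        return rows

    rows: list[SummaryRow] = []
    rows += _group(lambda i, c, h: (i, None, None), 1, keep_prr=False)
    rows += _group(lambda i, c, h: (i, None, h), 2, keep_prr=False)
    rows += _group(lambda i, c, h: (i, c, None), 3, keep_prr=False)
    rows += _group(lambda i, c, h: (i, c, h), 4, keep_prr=True)
    store.replace_summary(
        [
            (r.rollup_level, r.ingredient_concept_id, r.clinical_drug_concept_id,
             r.hoi_concept_id, r.evidence_type, r.statistic_type, r.aggregate_value)
            for r in rows
        ]
    )
    return rows, rejects


# -- reports --------------------------------------------------------------


def coverage_report(etl_reports: list[EtlReport]) -> pd.DataFrame:
    """One row per source: distinct native pairs, mapped pairs, percent
    (one decimal; an em dash when the source had zero pairs)."""
    if not etl_reports:
        raise UsageError("coverage_report requires at least one ETL report")
    rows = []
    for r in etl_reports:
        pct = percent_one_decimal(r.pairs_mapped, r.pairs_in_source)
        rows.append(
            {
                "source_id": r.source_id,
                "pairs_in_source": r.pairs_in_source,
                "pairs_mapped": r.pairs_mapped,
                "percent": pct,
                "percent_display": format_percent(pct),
            }
        )
    return pd.DataFrame(rows)


def ingredient_pair_set(
    store: EvidenceStore, source_ids: set[str], vocab: VocabularyStore | None = None
) -> set[tuple[int, int]]:
    """Distinct (ingredient, HOI) pairs carried by the given sources."""
    vocab = vocab or store.vocabulary()
    pairs: set[tuple[int, int]] = set()
    for row in store.evidence_rows():
        (_rel, source, _etype, _mod, _stype, _value, _link,
         drug_id, _dn, hoi_id, _hn) = row
        if source not in source_ids:
            continue
        ings, _clinical = _ingredient_split(vocab, drug_id)
        for ing in ings:
            pairs.add((ing, hoi_id))
    return pairs


def overlap_report(
    store: EvidenceStore, groups: dict[str, set[str]]
) -> pd.DataFrame:
    """Pairwise (and all-groups) overlap of distinct ingredient-level
    drug-HOI pair sets: union size n, intersection size, percent =
    100 * intersection / union at one decimal."""
    names = list(groups)
    if len(names) < 2:
        raise UsageError("overlap_report requires at least two groups")
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            common = groups[a] & groups[b]
            if common:
                raise UsageError(
                    f"groups {a!r} and {b!r} overlap on sources {sorted(common)}"
                )
    known = {s.source_id for s in store.sources()}
    for name, members in groups.items():
        missing = members - known
        if missing:
            raise UsageError(f"group {name!r} names unknown sources {sorted(missing)}")
    vocab = store.vocabulary()
    sets = {name: ingredient_pair_set(store, members, vocab) for name, members in groups.items()}
    rows = []

    def _row(label: str, parts: list[set[tuple[int, int]]]) -> None:
        union = set().union(*parts)
        inter = set(parts[0]).intersection(*parts[1:])
        pct = percent_one_decimal(len(inter), len(union))
        rows.append(
            {
                "comparison": label,
                "n_union": len(union),
                "n_intersection": len(inter),
                "percent": pct,
                "percent_display": format_percent(pct),
            }
        )

    for i, a in enumerate(names):
        for b in names[i + 1:]:
            _row(f"{a} vs {b}", [sets[a], sets[b]])
    if len(names) > 2:
        _row("all", [sets[n] for n in names])
    return pd.DataFrame(rows)


def find_negative_controls(
    store: EvidenceStore,
    drug_ids: list[int],
    hoi_ids: list[int],
    vocab: VocabularyStore | None = None,
) -> list[tuple[int, int]]:
    """Candidate (ingredient, HOI) pairs with zero evidence in any source.

    Evidence presence is judged at the ingredient rollup level, so a
    clinical-drug record blocks its ingredient's pair too. Sorted output;
    used to pick calibration negative controls for observational studies.
    """
    if not drug_ids or not hoi_ids:
        raise UsageError("candidate drug and HOI lists must be nonempty")
    vocab = vocab or store.vocabulary()
    for d in drug_ids:
        c = vocab.concept(d)  # raises UnknownConceptError if absent
        if (
            c.vocabulary_id is not Vocabulary.RXNORM
            or c.concept_class is not ConceptClass.INGREDIENT
        ):
            raise DomainError(f"candidate drug {d} is not an RxNorm ingredient")
    for h in hoi_ids:
        c = vocab.concept(h)
        if c.vocabulary_id is not Vocabulary.SNOMED:
            raise DomainError(f"candidate HOI {h} is not a SNOMED condition")
    evidenced = ingredient_pair_set(store, {s.source_id for s in store.sources()}, vocab)
    return sorted(
        (d, h) for d in set(drug_ids) for h in set(hoi_ids) if (d, h) not in evidenced
    )
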