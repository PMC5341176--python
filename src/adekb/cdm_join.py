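"""Join the evidence base against CDM-shaped patient data.

Counts distinct patients whose condition era starts strictly after, and
within ``window_days`` calendar days of, a drug era start — restricted to
drug-HOI pairs that have evidence of the requested types. The join is on
exact concept ids (no ingredient expansion of the patient data); callers
wanting an ingredient-level join pre-map their drug eras. Date arithmetic
is timezone-free calendar-day difference; the drug era end date plays no
role in the filter.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .errors import ParseError, UsageError
from .etl import EVIDENCE_TYPES
from .store import EvidenceStore

__all__ = ["CdmTables", "ExposedCaseRow", "load_cdm", "count_exposed_cases"]

DRUG_ERA_COLUMNS = ["person_id", "drug_concept_id", "drug_era_start_date", "drug_era_end_date"]
CONDITION_ERA_COLUMNS = ["person_id", "condition_concept_id", "condition_era_start_date"]


@dataclass
class CdmTables:
    drug_era: pd.DataFrame
    condition_era: pd.DataFrame


@dataclass(frozen=True)
class ExposedCaseRow:
    rxnorm_drug: str
    snomed_hoi: str
    evidence_type: str
    evidence_linkout: str
    pcount: int


def load_cdm(drug_era_path: str | Path, condition_era_path: str | Path) -> CdmTables:
    """Read drug_era.tsv / condition_era.tsv; validates columns, ISO dates
    and start <= end."""
    drug = pd.read_csv(drug_era_path, sep="\t", dtype=str, keep_default_na=False)
    cond = pd.read_csv(condition_era_path, sep="\t", dtype=str, keep_default_na=False)
    if list(drug.columns) != DRUG_ERA_COLUMNS:
        raise ParseError(f"{drug_era_path}: expected columns {DRUG_ERA_COLUMNS}")
    if list(cond.columns) != CONDITION_ERA_COLUMNS:
        raise ParseError(f"{condition_era_path}: expected columns {CONDITION_ERA_COLUMNS}")
    try:
        drug = drug.assign(
            person_id=drug.person_id.astype(int),
            drug_concept_id=drug.drug_concept_id.astype(int),
            drug_era_start_date=pd.to_datetime(drug.drug_era_start_date, format="%Y-%m-%d"),
            drug_era_end_date=pd.to_datetime(drug.drug_era_end_date, format="%Y-%m-%d"),
        )
        cond = cond.assign(
            person_id=cond.person_id.astype(int),
            condition_concept_id=cond.condition_concept_id.astype(int),
            condition_era_start_date=pd.to_datetime(
                cond.condition_era_start_date, format="%Y-%m-%d"
            ),
        )
    except (ValueError, TypeError) as exc:
        raise ParseError(f"bad CDM value: {exc}") from exc
    if (drug.drug_era_start_date > drug.drug_era_end_date).any():
        raise ParseError("drug era with start after end")
    return CdmTables(drug, cond)


def count_exposed_cases(
    cdm: CdmTables,
    store: EvidenceStore,
    evidence_types: list[str],
    window_days: int = 30,
) -> list[ExposedCaseRow]:
    """Exposed-case counts per (drug, HOI, evidence type, linkout).

    A person qualifies for a pair when some condition era starts in
    (0, window_days] days after some drug era start; each person counts
    once per output row regardless of how many qualifying era pairs they
    have. Rows are sorted by pcount descending, ties broken by
    (rxnorm_drug, snomed_hoi, evidence_type) ascending.
    """
    if not evidence_types:
        raise UsageError("evidence_types must be nonempty")
    unknown = set(evidence_types) - set(EVIDENCE_TYPES)
    if unknown:
        raise UsageError(
            f"unknown evidence types {sorted(unknown)}; valid tags: "
            f"{', '.join(EVIDENCE_TYPES)}"
        )
    if window_days < 1:
        raise UsageError("window_days must be >= 1")

    eras = cdm.drug_era.merge(cdm.condition_era, on="person_id")
    delta = (eras.condition_era_start_date - eras.drug_era_start_date).dt.days
    eras = eras[(delta > 0) & (delta <= window_days)]

    evidence = pd.DataFrame(
        store.evidence_rows(),
        columns=[
            "relationship_id", "source_id", "evidence_type", "modality",
            "statistic_type", "statistic_value", "evidence_linkout",
            "drug_concept_id", "rxnorm_drug", "hoi_concept_id", "snomed_hoi",
        ],
    )
    if evidence.empty or eras.empty:
        return []
    evidence = evidence[evidence.evidence_type.isin(evidence_types)]
    # one row per (relationship, evidence_type): drop the statistic split
    evidence = evidence.drop_duplicates(
        subset=["relationship_id", "evidence_type", "evidence_linkout"]
    )
    joined = eras.merge(
        evidence,
        left_on=["drug_concept_id", "condition_concept_id"],
        right_on=["drug_concept_id", "hoi_concept_id"],
    )
    if joined.empty:
        return []
    grouped = (
        joined.groupby(["rxnorm_drug", "snomed_hoi", "evidence_type", "evidence_linkout"])
        .person_id.nunique()
        .reset_index(name="pcount")
    )
    grouped = grouped.sort_values(
        by=["pcount", "rxnorm_drug", "snomed_hoi", "evidence_type"],
        ascending=[False, True, True, True],
        kind="mergesort",
    )
    return [
        ExposedCaseRow(r.rxnorm_drug, r.snomed_hoi, r.evidence_type,
                       r.evidence_linkout, int(r.pcount))
        for r in grouped.itertuples(index=False)
    ]


def exposed_cases_to_tsv(rows: list[ExposedCaseRow]) -> str:
    header = "rxnorm_drug\tsnomed_hoi\tevidence_type\tevidence_linkout\tpcount"
    lines = [header] + [
        f"{r.rxnorm_drug}\t{r.snomed_hoi}\t{r.evidence_type}\t{r.evidence_linkout}\t{r.pcount}"
        for r in rows
    ]
    return "\n".join(lines) + "\n"
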