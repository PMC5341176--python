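"""Deterministic, seeded generators for a miniature evidence ecosystem.

Three generators cover everything the pipeline consumes:

* :func:`generate_vocabulary` — a small OMOP-style vocabulary with RxNorm
  ingredients and clinical drugs, SNOMED conditions, and MedDRA/MeSH
  synonyms wired up with ``MAPS_TO`` rows (1:1 by construction).
* :func:`generate_source` — raw evidence files in the native shape of each
  of the six supported sources, with a controllable fraction of records
  that carry syntactically valid but unregistered codes (the mapping-miss
  path, not the parser path).
* :func:`generate_cdm` — CDM-shaped patient tables (drug_era /
  condition_era) with planted drug-condition day offsets.

Every generator is a pure function of its parameters and seed, and records
ground truth in a :class:`FixtureManifest` so tests can use exhaustive
recounts as oracles. The LAST generated condition is reserved: no source
generator ever samples it, so its pairing with every ingredient forms a
set of guaranteed evidence-free negative-control pairs.
"""

from __future__ import annotations

import enum
import json
import random
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import DomainError
from .vocabulary import (
    Concept,
    ConceptAncestor,
    ConceptClass,
    ConceptMapping,
    Vocabulary,
    VocabularyStore,
    save_vocabulary,
)

__all__ = [
    "SourceKind",
    "PlantedPair",
    "FixtureManifest",
    "generate_vocabulary",
    "generate_source",
    "generate_cdm",
    "SOURCE_FILENAMES",
]


class SourceKind(str, enum.Enum):
    """The six raw evidence source shapes."""

    SPL_US = "SPL_US"          # US label NLP output (clinical-drug level)
    EU_SPC = "EU_SPC"          # EU SmPC adverse reactions (drug name strings)
    MEDLINE_MESH = "MEDLINE_MESH"      # MeSH co-indexing of MEDLINE records
    MEDLINE_SEMMED = "MEDLINE_SEMMED"  # Semantic-MEDLINE sentence spans (UMLS)
    FAERS = "FAERS"            # spontaneous-report counts + PRR
    CTD = "CTD"                # chemical-disease pairs (MeSH both sides)


SOURCE_FILENAMES = {
    SourceKind.SPL_US: "spl_us.tsv",
    SourceKind.EU_SPC: "eu_spc.tsv",
    SourceKind.MEDLINE_MESH: "medline_mesh.tsv",
    SourceKind.MEDLINE_SEMMED: "medline_semmed.tsv",
    SourceKind.FAERS: "faers.tsv",
    SourceKind.CTD: "ctd.tsv",
}

RAW_COLUMNS: dict[SourceKind, list[str]] = {
    SourceKind.SPL_US: [
        "label_id",
        "set_id",
        "section_name",
        "rxnorm_clinical_drug_code",
        "meddra_hoi_code",
        "mention_text",
    ],
    SourceKind.EU_SPC: ["doc_id", "drug_name", "meddra_hoi_code"],
    SourceKind.MEDLINE_MESH: [
        "pmid",
        "mesh_drug_code",
        "mesh_hoi_code",
        "pub_type",
        "title_abstract_text",
    ],
    SourceKind.MEDLINE_SEMMED: ["pmid", "cui_drug", "cui_hoi", "sentence_span", "pub_type"],
    SourceKind.FAERS: ["drug_code", "hoi_code", "case_count", "prr"],
    SourceKind.CTD: ["mesh_chemical_code", "mesh_disease_code"],
}

PUB_TYPES = ("CLIN_TRIAL", "CASE_REPORT", "OTHER")

# Fixed reference concepts: simvastatin and its 20 MG oral tablet, with
# the OMOP concept ids practitioners will recognize.
SIMVASTATIN_INGREDIENT_ID = 1539403
SIMVASTATIN_TABLET_ID = 1539411


@dataclass
class PlantedPair:
    """One drug-HOI pair planted into one source file."""

    ingredient_id: int
    clinical_drug_id: int | None
    hoi_id: int
    source: str
    expected_record_count: int


@dataclass
class FixtureManifest:
    """Ground truth for everything the generators emitted."""

    planted_pairs: list[PlantedPair] = field(default_factory=list)
    unmappable_records: list[str] = field(default_factory=list)
    negative_pairs: list[tuple[int, int]] = field(default_factory=list)
    cdm_truth: dict[tuple[int, int], list[int]] = field(default_factory=dict)
    vocabulary: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "planted_pairs": [vars(p) for p in self.planted_pairs],
                "unmappable_records": self.unmappable_records,
                "negative_pairs": [list(p) for p in self.negative_pairs],
                "cdm_truth": {f"{d}:{h}": v for (d, h), v in self.cdm_truth.items()},
                "vocabulary": self.vocabulary,
            },
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "FixtureManifest":
        raw = json.loads(text)
        m = cls()
        m.planted_pairs = [PlantedPair(**p) for p in raw["planted_pairs"]]
        m.unmappable_records = raw["unmappable_records"]
        m.negative_pairs = [tuple(p) for p in raw["negative_pairs"]]
        m.cdm_truth = {
            tuple(int(x) for x in k.split(":")): v for k, v in raw["cdm_truth"].items()
        }
        m.vocabulary = raw["vocabulary"]
        return m

    def check(self) -> None:
        planted = {(p.ingredient_id, p.hoi_id) for p in self.planted_pairs}
        if planted & set(self.negative_pairs):
            raise DomainError("negative_pairs overlap planted pairs")
        for p in self.planted_pairs:
            if p.expected_record_count < 0:
                raise DomainError("negative expected_record_count")


# -- pseudo-name generation ----------------------------------------------

_ONSETS = "b c d f g l m n p r s t v z br cl dr fl pr tr".split()
_VOWELS = list("aeiou")
_ING_SUFFIXES = ["statin", "pril", "olol", "mycin", "azole", "cillin", "dipine", "oxetine"]
_COND_SUFFIXES = ["itis", "emia", "osis", "algia", "opathy", "oma"]


def _word(rng: random.Random, n_syllables: int = 2) -> str:
    return "".join(rng.choice(_ONSETS) + rng.choice(_VOWELS) for _ in range(n_syllables))


# -- vocabulary generator -------------------------------------------------


def generate_vocabulary(
    n_ingredients: int,
    drugs_per_ingredient: int,
    n_conditions: int,
    seed: int,
    out_dir: str | Path,
) -> tuple[VocabularyStore, FixtureManifest]:
    """Emit CONCEPT / CONCEPT_RELATIONSHIP / CONCEPT_ANCESTOR TSVs.

    Ingredient 0 is always simvastatin (concept 1539403) with
    "Simvastatin 20 MG Oral Tablet" (1539411) as its first clinical drug.
    Condition 0 gets a SNOMED is-a parent (one extra concept and ancestor
    row) for HOI-hierarchy tests. Each condition carries one MedDRA and one
    MeSH synonym, each ingredient one MeSH synonym; all MAPS_TO rows are
    1:1. Concept-id ranges are partitioned by vocabulary so collisions are
    structurally impossible.
    """
    if min(n_ingredients, drugs_per_ingredient, n_conditions) < 1:
        raise DomainError("all generator counts must be >= 1")
    if n_ingredients >= 500:
        raise DomainError("fixture vocabulary supports < 500 ingredients")
    rng = random.Random(seed)
    concepts: list[Concept] = []
    mappings: list[ConceptMapping] = []
    ancestors: list[ConceptAncestor] = []

    ingredient_ids: list[int] = []
    clinical_by_ingredient: dict[int, list[int]] = {}
    mesh_drug_by_ingredient: dict[int, int] = {}
    for i in range(n_ingredients):
        if i == 0:
            ing_id, ing_name = SIMVASTATIN_INGREDIENT_ID, "simvastatin"
        else:
            ing_id = 1_000_000 + i * 1000
            ing_name = _word(rng) + _ING_SUFFIXES[i % len(_ING_SUFFIXES)]
        ingredient_ids.append(ing_id)
        concepts.append(
            Concept(ing_id, str(ing_id % 1_000_000), ing_name, Vocabulary.RXNORM,
                    ConceptClass.INGREDIENT, True)
        )
        clinical_by_ingredient[ing_id] = []
        for j in range(drugs_per_ingredient):
            if i == 0:
                drug_id = SIMVASTATIN_TABLET_ID + j
                strength = 20 if j == 0 else rng.choice([5, 10, 40, 80])
            else:
                drug_id = 1_000_000 + i * 1000 + 1 + j
                strength = rng.choice([5, 10, 20, 40, 80])
            drug_name = f"{ing_name.capitalize()} {strength} MG Oral Tablet"
            concepts.append(
                Concept(drug_id, str(drug_id % 1_000_000), drug_name, Vocabulary.RXNORM,
                        ConceptClass.CLINICAL_DRUG, True)
            )
            ancestors.append(ConceptAncestor(ing_id, drug_id))
            clinical_by_ingredient[ing_id].append(drug_id)
        # MeSH synonym for the ingredient (drug-side literature coding)
        mesh_drug_id = 6_500_000 + i * 10
        concepts.append(
            Concept(mesh_drug_id, f"D{mesh_drug_id % 1_000_000:06d}", ing_name,
                    Vocabulary.MESH, ConceptClass.OTHER, False)
        )
        mappings.append(ConceptMapping(mesh_drug_id, ing_id))
        mesh_drug_by_ingredient[ing_id] = mesh_drug_id

    condition_ids: list[int] = []
    meddra_by_condition: dict[int, int] = {}
    mesh_by_condition: dict[int, int] = {}
    for c in range(n_conditions):
        cond_id = 4_000_000 + c * 10
        cond_name = _word(rng) + _COND_SUFFIXES[c % len(_COND_SUFFIXES)]
        condition_ids.append(cond_id)
        concepts.append(
            Concept(cond_id, str(20_000_000 + c * 10), cond_name, Vocabulary.SNOMED,
                    ConceptClass.CONDITION, True)
        )
        meddra_id = 5_000_000 + c * 10
        concepts.append(
            Concept(meddra_id, str(10_000_000 + c * 10), cond_name, Vocabulary.MEDDRA,
                    ConceptClass.CONDITION, False)
        )
        mappings.append(ConceptMapping(meddra_id, cond_id))
        meddra_by_condition[cond_id] = meddra_id
        mesh_id = 6_000_000 + c * 10
        concepts.append(
            Concept(mesh_id, f"D{mesh_id % 1_000_000:06d}", cond_name, Vocabulary.MESH,
                    ConceptClass.CONDITION, False)
        )
        mappings.append(ConceptMapping(mesh_id, cond_id))
        mesh_by_condition[cond_id] = mesh_id

    # One small SNOMED is-a chain: a parent disorder group above condition 0.
    parent_id = 4_990_000
    child_concept = concepts[[c.concept_id for c in concepts].index(condition_ids[0])]
    concepts.append(
        Concept(parent_id, str(29_990_000), f"{child_concept.name} disorder group",
                Vocabulary.SNOMED, ConceptClass.CONDITION, True)
    )
    ancestors.append(ConceptAncestor(parent_id, condition_ids[0]))

    store = VocabularyStore(concepts, mappings, ancestors)
    save_vocabulary(store, out_dir)

    manifest = FixtureManifest()
    reserved = condition_ids[-1] if n_conditions >= 2 else None
    manifest.negative_pairs = (
        [(ing, reserved) for ing in ingredient_ids] if reserved is not None else []
    )
    manifest.vocabulary = {
        "n_ingredients": n_ingredients,
        "drugs_per_ingredient": drugs_per_ingredient,
        "n_conditions": n_conditions,
        "seed": seed,
        "ingredient_ids": ingredient_ids,
        "clinical_by_ingredient": {str(k): v for k, v in clinical_by_ingredient.items()},
        "condition_ids": condition_ids,
        "meddra_by_condition": {str(k): v for k, v in meddra_by_condition.items()},
        "mesh_by_condition": {str(k): v for k, v in mesh_by_condition.items()},
        "mesh_drug_by_ingredient": {str(k): v for k, v in mesh_drug_by_ingredient.items()},
        "hierarchy_parent_id": parent_id,
        "hierarchy_child_id": condition_ids[0],
        "negative_condition_id": reserved,
    }
    return store, manifest


# -- source generator -----------------------------------------------------


def _sampling_frame(vocab: VocabularyStore, manifest: FixtureManifest):
    """Ingredients, clinical drugs and sampleable conditions (excludes the
    reserved negative condition and the hierarchy parent)."""
    info = manifest.vocabulary
    excluded = {info.get("negative_condition_id"), info.get("hierarchy_parent_id")}
    ingredients = [vocab.concept(i) for i in info["ingredient_ids"]]
    clinical = {
        int(k): [vocab.concept(d) for d in v]
        for k, v in info["clinical_by_ingredient"].items()
    }
    conditions = [vocab.concept(c) for c in info["condition_ids"] if c not in excluded]
    return ingredients, clinical, conditions


def generate_source(
    kind: SourceKind,
    vocab: VocabularyStore,
    n_records: int,
    unmappable_fraction: float,
    seed: int,
    out_dir: str | Path,
    manifest: FixtureManifest,
) -> Path:
    """Write one raw source file; extend the manifest with its ground truth.

    Exactly ``round(n_records * unmappable_fraction)`` records carry
    unregistered (but well-formed) codes; their unmapped side cycles
    through drug / HOI / both. Mappable records are sampled WITHOUT
    replacement from the native drug x condition cross product, so native
    pairs are distinct and every planted pair has expected_record_count 1.
    """
    if not isinstance(kind, SourceKind):
        raise DomainError(f"unknown source kind {kind!r}")
    if not (0 <= unmappable_fraction < 1):
        raise DomainError("unmappable_fraction must be in [0, 1)")
    rng = random.Random(f"{seed}:{kind.value}")  # str seeds hash deterministically
    ingredients, clinical_by_ing, conditions = _sampling_frame(vocab, manifest)
    info = manifest.vocabulary
    meddra_of = {int(k): v for k, v in info["meddra_by_condition"].items()}
    mesh_of = {int(k): v for k, v in info["mesh_by_condition"].items()}
    mesh_drug_of = {int(k): v for k, v in info["mesh_drug_by_ingredient"].items()}

    if kind is SourceKind.SPL_US:
        drug_pool: list[tuple[int | None, int]] = [
            (ing.concept_id, d.concept_id)
            for ing in ingredients
            for d in clinical_by_ing[ing.concept_id]
        ]
    else:
        drug_pool = [(ing.concept_id, None) for ing in ingredients]
    pool = [(dp, cond.concept_id) for dp in drug_pool for cond in conditions]
    n_unmappable = round(n_records * unmappable_fraction)
    n_mappable = n_records - n_unmappable
    if n_mappable > len(pool):
        raise DomainError(
            f"{kind.value}: cannot sample {n_mappable} distinct pairs from a "
            f"pool of {len(pool)}; enlarge the vocabulary"
        )
    sampled = rng.sample(pool, n_mappable)
    unmappable_positions = set(rng.sample(range(n_records), n_unmappable))

    # SemMedDB needs a UMLS crosswalk: CUI -> concept_id. Drug CUIs point at
    # RxNorm ingredients; HOI CUIs alternate between direct SNOMED and
    # MedDRA (the "map where needed" path).
    crosswalk: dict[str, int] = {}
    if kind is SourceKind.MEDLINE_SEMMED:
        for ing in ingredients:
            crosswalk[f"C1{ing.concept_id % 1_000_000:06d}"] = ing.concept_id
        for idx, cond in enumerate(conditions):
            target = cond.concept_id if idx % 2 == 0 else meddra_of[cond.concept_id]
            crosswalk[f"C2{cond.concept_id % 1_000_000:06d}"] = target

    rows: list[list[str]] = []
    mappable_iter = iter(sampled)
    unmap_side = 0  # cycles drug -> hoi -> both
    fresh = iter(range(900_000, 999_999))
    for i in range(n_records):
        if i in unmappable_positions:
            side = ("DRUG", "HOI", "BOTH")[unmap_side % 3]
            unmap_side += 1
            ing_id = rng.choice(ingredients).concept_id
            cond_id = rng.choice(conditions).concept_id
            drug_bad = side in ("DRUG", "BOTH")
            hoi_bad = side in ("HOI", "BOTH")
            manifest.unmappable_records.append(f"{kind.value}:{i}")
        else:
            (ing_id, clin_id), cond_id = next(mappable_iter)
            drug_bad = hoi_bad = False
            manifest.planted_pairs.append(
                PlantedPair(
                    ingredient_id=ing_id,
                    clinical_drug_id=clin_id if kind is SourceKind.SPL_US else None,
                    hoi_id=cond_id,
                    source=kind.value,
                    expected_record_count=1,
                )
            )
        cond = vocab.concept(cond_id)
        ing = vocab.concept(ing_id)
        if kind is SourceKind.SPL_US:
            if drug_bad:
                drug_code = str(next(fresh))
            else:
                if i in unmappable_positions:
                    clin_id = clinical_by_ing[ing_id][0].concept_id
                drug_code = vocab.concept(clin_id).source_code
            hoi_code = (
                str(100_000_000 + next(fresh)) if hoi_bad
                else vocab.concept(meddra_of[cond_id]).source_code
            )
            rows.append(
                [f"SPL{i:05d}", f"set-{seed}-{i:05d}", "ADVERSE REACTIONS",
                 drug_code, hoi_code, f"{cond.name} was reported"]
            )
        elif kind is SourceKind.EU_SPC:
            drug_name = f"zz{_word(rng)}ium" if drug_bad else ing.name
            hoi_code = (
                str(100_000_000 + next(fresh)) if hoi_bad
                else vocab.concept(meddra_of[cond_id]).source_code
            )
            rows.append([f"EU-SPC-{i:05d}", drug_name, hoi_code])
        elif kind is SourceKind.MEDLINE_MESH:
            drug_code = f"D9{next(fresh):05d}" if drug_bad else vocab.concept(mesh_drug_of[ing_id]).source_code
            hoi_code = f"D9{next(fresh):05d}" if hoi_bad else vocab.concept(mesh_of[cond_id]).source_code
            pub = rng.choice(PUB_TYPES)
            rows.append(
                [str(20_000_000 + i), drug_code, hoi_code, pub,
                 f"{ing.name} associated with {cond.name}"]
            )
        elif kind is SourceKind.MEDLINE_SEMMED:
            cui_drug = f"C9{next(fresh):06d}" if drug_bad else f"C1{ing_id % 1_000_000:06d}"
            cui_hoi = f"C9{next(fresh):06d}" if hoi_bad else f"C2{cond_id % 1_000_000:06d}"
            pub = rng.choice(PUB_TYPES)
            rows.append(
                [str(21_000_000 + i), cui_drug, cui_hoi,
                 f"{ing.name} caused {cond.name} in this patient", pub]
            )
        elif kind is SourceKind.FAERS:
            drug_code = str(next(fresh)) if drug_bad else ing.source_code
            hoi_code = (
                str(100_000_000 + next(fresh)) if hoi_bad
                else vocab.concept(meddra_of[cond_id]).source_code
            )
            rows.append(
                [drug_code, hoi_code, str(rng.randint(1, 40)),
                 f"{rng.uniform(0.2, 8.0):.2f}"]
            )
        elif kind is SourceKind.CTD:
            drug_code = f"D9{next(fresh):05d}" if drug_bad else vocab.concept(mesh_drug_of[ing_id]).source_code
            hoi_code = f"D9{next(fresh):05d}" if hoi_bad else vocab.concept(mesh_of[cond_id]).source_code
            rows.append([drug_code, hoi_code])

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / SOURCE_FILENAMES[kind]
    pd.DataFrame(rows, columns=RAW_COLUMNS[kind]).to_csv(path, sep="\t", index=False)
    if kind is SourceKind.MEDLINE_SEMMED:
        xwalk_path = out / "medline_semmed_crosswalk.tsv"
        pd.DataFrame(
            sorted(crosswalk.items()), columns=["cui", "concept_id"]
        ).to_csv(xwalk_path, sep="\t", index=False)
    manifest.check()
    return path


# -- CDM generator --------------------------------------------------------

CDM_BASE_DATE = pd.Timestamp("2020-01-01")


def generate_cdm(
    vocab: VocabularyStore,
    n_persons: int,
    planted: list[tuple[int, int, int]],
    seed: int,
    out_dir: str | Path,
) -> tuple[Path, Path, dict[tuple[int, int], list[int]]]:
    """Write drug_era.tsv / condition_era.tsv with planted day offsets.

    Each planted (drug_concept, condition_concept, day_offset) triple
    creates one person whose condition era starts exactly ``day_offset``
    calendar days after their drug era start (offsets of 0, negative, or
    > 30 plant non-cases). Background persons carry either a drug era or a
    condition era, never both, so the returned truth — persons per pair
    with offset in (0, 30] — is exact by construction.
    """
    if n_persons < len(planted):
        raise DomainError("n_persons must cover all planted triples")
    rng = random.Random(f"{seed}:cdm")
    drug_rows: list[list[str]] = []
    cond_rows: list[list[str]] = []
    truth: dict[tuple[int, int], list[int]] = {}
    for pid, (drug_id, cond_id, offset) in enumerate(planted, start=1):
        start = CDM_BASE_DATE + pd.Timedelta(days=rng.randint(0, 364))
        end = start + pd.Timedelta(days=rng.randint(7, 90))
        drug_rows.append([str(pid), str(drug_id), start.date().isoformat(),
                          end.date().isoformat()])
        cond_rows.append([str(pid), str(cond_id),
                          (start + pd.Timedelta(days=offset)).date().isoformat()])
        if 0 < offset <= 30:
            truth.setdefault((drug_id, cond_id), []).append(pid)
    drug_concepts = [c.concept_id for c in vocab.concepts
                     if c.vocabulary_id is Vocabulary.RXNORM]
    cond_concepts = [c.concept_id for c in vocab.concepts
                     if c.vocabulary_id is Vocabulary.SNOMED]
    for pid in range(len(planted) + 1, n_persons + 1):
        start = CDM_BASE_DATE + pd.Timedelta(days=rng.randint(0, 364))
        if rng.random() < 0.5:
            end = start + pd.Timedelta(days=rng.randint(7, 90))
            drug_rows.append([str(pid), str(rng.choice(drug_concepts)),
                              start.date().isoformat(), end.date().isoformat()])
        else:
            cond_rows.append([str(pid), str(rng.choice(cond_concepts)),
                              start.date().isoformat()])
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    drug_path = out / "drug_era.tsv"
    cond_path = out / "condition_era.tsv"
    pd.DataFrame(
        drug_rows,
        columns=["person_id", "drug_concept_id", "drug_era_start_date",
                 "drug_era_end_date"],
    ).to_csv(drug_path, sep="\t", index=False)
    pd.DataFrame(
        cond_rows,
        columns=["person_id", "condition_concept_id", "condition_era_start_date"],
    ).to_csv(cond_path, sep="\t", index=False)
    return drug_path, cond_path, {k: sorted(v) for k, v in sorted(truth.items())}
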