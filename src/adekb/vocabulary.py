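"""OMOP-style standard-vocabulary store.

Drugs are standardized to RxNorm and health outcomes of interest (HOIs) to
SNOMED-CT. Source terminologies (MedDRA, MeSH, UMLS) reach the standard
concepts through explicit ``MAPS_TO`` rows, and the RxNorm drug hierarchy
(clinical drug -> ingredient) is carried as a transitively closed,
irreflexive ancestor table, mirroring the layout of an OMOP vocabulary
download (CONCEPT / CONCEPT_RELATIONSHIP / CONCEPT_ANCESTOR).
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

from .errors import DomainError, UnknownConceptError, VocabularyLoadError

__all__ = [
    "Vocabulary",
    "ConceptClass",
    "Concept",
    "ConceptMapping",
    "ConceptAncestor",
    "VocabularyStore",
    "load_vocabulary",
    "save_vocabulary",
    "map_to_standard",
    "ingredient_for",
    "match_drug_by_name",
    "normalize_drug_name",
    "DEFAULT_SALT_SUFFIXES",
]


class Vocabulary(str, enum.Enum):
    RXNORM = "RXNORM"
    SNOMED = "SNOMED"
    MEDDRA = "MEDDRA"
    MESH = "MESH"
    UMLS = "UMLS"


class ConceptClass(str, enum.Enum):
    INGREDIENT = "INGREDIENT"
    CLINICAL_DRUG = "CLINICAL_DRUG"
    BRAND = "BRAND"
    CONDITION = "CONDITION"
    OTHER = "OTHER"


MAPS_TO = "MAPS_TO"

#: Salt suffixes stripped (once, from the end) by the optional
#: salt-stripping step of the drug-name normalization pipeline.
DEFAULT_SALT_SUFFIXES = (
    "sodium",
    "hydrochloride",
    "sulfate",
    "tartrate",
    "maleate",
    "citrate",
    "besylate",
    "mesylate",
    "potassium",
    "calcium",
)


@dataclass(frozen=True)
class Concept:
    """One terminology entry.

    ``is_standard`` is true only for RxNorm drug concepts and SNOMED
    conditions; every other terminology reaches the standard layer through
    ``MAPS_TO`` relationships.
    """

    concept_id: int
    source_code: str
    name: str
    vocabulary_id: Vocabulary
    concept_class: ConceptClass
    is_standard: bool

    def __post_init__(self) -> None:
        if self.concept_id <= 0:
            raise VocabularyLoadError(f"concept_id must be positive: {self.concept_id}")
        if self.concept_class in (ConceptClass.INGREDIENT, ConceptClass.CLINICAL_DRUG):
            if self.vocabulary_id is not Vocabulary.RXNORM:
                raise VocabularyLoadError(
                    f"concept {self.concept_id}: class {self.concept_class.value} "
                    f"is only valid under RXNORM, got {self.vocabulary_id.value}"
                )
        if self.is_standard:
            ok = (
                self.vocabulary_id is Vocabulary.RXNORM
                and self.concept_class
                in (ConceptClass.INGREDIENT, ConceptClass.CLINICAL_DRUG, ConceptClass.BRAND)
            ) or (
                self.vocabulary_id is Vocabulary.SNOMED
                and self.concept_class is ConceptClass.CONDITION
            )
            if not ok:
                raise VocabularyLoadError(
                    f"concept {self.concept_id}: is_standard is true only for "
                    "RXNORM drugs and SNOMED conditions"
                )


@dataclass(frozen=True)
class ConceptMapping:
    source_concept_id: int
    target_concept_id: int
    relationship: str = MAPS_TO


@dataclass(frozen=True)
class ConceptAncestor:
    ancestor_concept_id: int
    descendant_concept_id: int


def normalize_drug_name(
    name: str,
    strip_salts: bool = False,
    salt_suffixes: Iterable[str] = DEFAULT_SALT_SUFFIXES,
) -> str:
    """Name-matching pipeline: case-fold, trim, collapse internal
    whitespace, and optionally strip one trailing salt suffix."""
    tokens = re.split(r"\s+", name.casefold().strip())
    tokens = [t for t in tokens if t]
    if strip_salts and len(tokens) > 1 and tokens[-1] in set(salt_suffixes):
        tokens = tokens[:-1]
    return " ".join(tokens)


class VocabularyStore:
    """Indexed, immutable collection of concepts, mappings and ancestors.

    All referential and structural invariants are checked eagerly at
    construction time: every mapping/ancestor endpoint must resolve, every
    ``MAPS_TO`` target must be standard, the ancestor table must be
    irreflexive, transitively closed and therefore acyclic.
    """

    def __init__(
        self,
        concepts: Iterable[Concept],
        mappings: Iterable[ConceptMapping] = (),
        ancestors: Iterable[ConceptAncestor] = (),
    ) -> None:
        self._concepts: dict[int, Concept] = {}
        self._by_code: dict[tuple[Vocabulary, str], Concept] = {}
        for c in concepts:
            if c.concept_id in self._concepts:
                raise VocabularyLoadError(f"duplicate concept_id {c.concept_id}")
            code_key = (c.vocabulary_id, c.source_code)
            if code_key in self._by_code:
                raise VocabularyLoadError(
                    f"duplicate (vocabulary_id, source_code) "
                    f"({c.vocabulary_id.value}, {c.source_code!r})"
                )
            self._concepts[c.concept_id] = c
            self._by_code[code_key] = c

        self._mappings: list[ConceptMapping] = []
        self._map_targets: dict[int, list[Concept]] = {}
        seen_pairs: set[tuple[int, int]] = set()
        for m in mappings:
            for endpoint in (m.source_concept_id, m.target_concept_id):
                if endpoint not in self._concepts:
                    raise VocabularyLoadError(
                        f"mapping ({m.source_concept_id} -> {m.target_concept_id}) "
                        f"references unknown concept_id {endpoint}"
                    )
            if m.source_concept_id == m.target_concept_id:
                raise VocabularyLoadError(f"self-map on concept {m.source_concept_id}")
            pair = (m.source_concept_id, m.target_concept_id)
            if pair in seen_pairs:
                raise VocabularyLoadError(f"duplicate mapping pair {pair}")
            seen_pairs.add(pair)
            target = self._concepts[m.target_concept_id]
            if not target.is_standard:
                raise VocabularyLoadError(
                    f"mapping target {target.concept_id} is not a standard concept"
                )
            self._mappings.append(m)
            self._map_targets.setdefault(m.source_concept_id, []).append(target)

        self._ancestors: list[ConceptAncestor] = []
        pairs: set[tuple[int, int]] = set()
        for a in ancestors:
            for endpoint in (a.ancestor_concept_id, a.descendant_concept_id):
                if endpoint not in self._concepts:
                    raise VocabularyLoadError(
                        f"ancestor row ({a.ancestor_concept_id}, {a.descendant_concept_id}) "
                        f"references unknown concept_id {endpoint}"
                    )
            if a.ancestor_concept_id == a.descendant_concept_id:
                raise VocabularyLoadError(
                    f"reflexive ancestor pair on concept {a.ancestor_concept_id}"
                )
            pair = (a.ancestor_concept_id, a.descendant_concept_id)
            if pair in pairs:
                raise VocabularyLoadError(f"duplicate ancestor pair {pair}")
            pairs.add(pair)
            self._ancestors.append(a)
        # Transitive closure check; together with irreflexivity this also
        # rules out cycles (a cycle would force a reflexive pair).
        by_desc: dict[int, set[int]] = {}
        for anc, desc in pairs:
            by_desc.setdefault(desc, set()).add(anc)
        for anc, desc in pairs:
            for grand in by_desc.get(anc, ()):
                if (grand, desc) not in pairs:
                    raise VocabularyLoadError(
                        f"ancestor table not transitively closed: "
                        f"({grand}, {anc}) and ({anc}, {desc}) present "
                        f"but ({grand}, {desc}) missing"
                    )
        self._ancestors_of: dict[int, set[int]] = by_desc

        self._name_index: dict[str, list[Concept]] = {}
        self._name_index_desalted: dict[str, list[Concept]] = {}
        for c in self._concepts.values():
            if (
                c.vocabulary_id is Vocabulary.RXNORM
                and c.concept_class is ConceptClass.INGREDIENT
            ):
                self._name_index.setdefault(normalize_drug_name(c.name), []).append(c)
                self._name_index_desalted.setdefault(
                    normalize_drug_name(c.name, strip_salts=True), []
                ).append(c)

    # -- accessors ---------------------------------------------------------

    def concept(self, concept_id: int) -> Concept:
        try:
            return self._concepts[concept_id]
        except KeyError:
            raise UnknownConceptError(f"unknown concept_id {concept_id}") from None

    def concept_by_code(self, vocabulary_id: Vocabulary, source_code: str) -> Concept | None:
        return self._by_code.get((vocabulary_id, source_code))

    @property
    def concepts(self) -> list[Concept]:
        return sorted(self._concepts.values(), key=lambda c: c.concept_id)

    @property
    def mappings(self) -> list[ConceptMapping]:
        return sorted(
            self._mappings, key=lambda m: (m.source_concept_id, m.target_concept_id)
        )

    @property
    def ancestors(self) -> list[ConceptAncestor]:
        return sorted(
            self._ancestors,
            key=lambda a: (a.ancestor_concept_id, a.descendant_concept_id),
        )

    def concepts_where(
        self,
        vocabulary_id: Vocabulary | None = None,
        concept_class: ConceptClass | None = None,
        is_standard: bool | None = None,
    ) -> list[Concept]:
        out = []
        for c in self.concepts:
            if vocabulary_id is not None and c.vocabulary_id is not vocabulary_id:
                continue
            if concept_class is not None and c.concept_class is not concept_class:
                continue
            if is_standard is not None and c.is_standard != is_standard:
                continue
            out.append(c)
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, VocabularyStore):
            return NotImplemented
        return (
            self.concepts == other.concepts
            and self.mappings == other.mappings
            and self.ancestors == other.ancestors
        )


# -- operations -----------------------------------------------------------


def map_to_standard(
    store: VocabularyStore, concept_id: int, target_vocabulary: Vocabulary
) -> list[Concept]:
    """Translate a concept to its standard equivalents in ``target_vocabulary``.

    A concept that already is standard in the target vocabulary maps to
    itself; otherwise all ``MAPS_TO`` targets in the target vocabulary are
    returned (ascending concept_id); an unmappable concept yields [].
    """
    concept = store.concept(concept_id)
    if concept.is_standard and concept.vocabulary_id is target_vocabulary:
        return [concept]
    targets = [
        t
        for t in store._map_targets.get(concept_id, [])
        if t.vocabulary_id is target_vocabulary
    ]
    return sorted(targets, key=lambda c: c.concept_id)


def ingredient_for(store: VocabularyStore, drug_concept_id: int) -> list[Concept]:
    """All RxNorm ingredient ancestors of a drug concept.

    The ancestor table is stored without reflexive pairs, so an ingredient
    returns itself explicitly. A clinical drug with no ingredient ancestor
    yields [].
    """
    concept = store.concept(drug_concept_id)
    if concept.vocabulary_id is not Vocabulary.RXNORM:
        raise DomainError(
            f"ingredient_for requires an RxNorm concept, "
            f"got {concept.vocabulary_id.value} concept {drug_concept_id}"
        )
    if concept.concept_class is ConceptClass.INGREDIENT:
        return [concept]
    out = [
        store.concept(a)
        for a in store._ancestors_of.get(drug_concept_id, ())
        if store.concept(a).concept_class is ConceptClass.INGREDIENT
    ]
    return sorted(out, key=lambda c: c.concept_id)


def match_drug_by_name(
    store: VocabularyStore,
    name: str,
    strip_salts: bool = False,
    salt_suffixes: Iterable[str] = DEFAULT_SALT_SUFFIXES,
) -> list[Concept]:
    """Exact-equality drug-name match against RxNorm ingredients.

    Both the query and the stored names pass through the same normalization
    pipeline (case-fold, trim, collapse whitespace, optional salt strip).
    No fuzzy matching. No match yields [].
    """
    if not name.strip():
        raise DomainError("match_drug_by_name requires a non-empty name")
    if strip_salts and tuple(salt_suffixes) != DEFAULT_SALT_SUFFIXES:
        # non-default salt list: match against freshly normalized names
        query = normalize_drug_name(name, True, salt_suffixes)
        out = [
            c
            for c in store.concepts_where(Vocabulary.RXNORM, ConceptClass.INGREDIENT)
            if normalize_drug_name(c.name, True, salt_suffixes) == query
        ]
        return sorted(out, key=lambda c: c.concept_id)
    index = store._name_index_desalted if strip_salts else store._name_index
    query = normalize_drug_name(name, strip_salts)
    return sorted(index.get(query, []), key=lambda c: c.concept_id)


# -- file I/O -------------------------------------------------------------

CONCEPT_COLUMNS = [
    "concept_id",
    "source_code",
    "name",
    "vocabulary_id",
    "concept_class",
    "is_standard",
]
RELATIONSHIP_COLUMNS = ["source_concept_id", "target_concept_id", "relationship"]
ANCESTOR_COLUMNS = ["ancestor_concept_id", "descendant_concept_id"]


def _read_tsv(path: str | Path, columns: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if list(df.columns) != columns:
        raise VocabularyLoadError(
            f"{path}: expected columns {columns}, got {list(df.columns)}"
        )
    return df


def load_vocabulary(
    concept_path: str | Path,
    mapping_path: str | Path,
    ancestor_path: str | Path,
) -> VocabularyStore:
    """Load a vocabulary from OMOP-download-dialect TSV files.

    Referential and uniqueness checks run eagerly; a violation raises
    :class:`VocabularyLoadError` naming the offending row or id.
    """
    cdf = _read_tsv(concept_path, CONCEPT_COLUMNS)
    concepts = []
    for row in cdf.itertuples(index=False):
        try:
            concepts.append(
                Concept(
                    concept_id=int(row.concept_id),
                    source_code=row.source_code,
                    name=row.name,
                    vocabulary_id=Vocabulary(row.vocabulary_id),
                    concept_class=ConceptClass(row.concept_class),
                    is_standard=row.is_standard == "1",
                )
            )
        except ValueError as exc:
            raise VocabularyLoadError(f"{concept_path}: bad row {tuple(row)}: {exc}") from exc
    mdf = _read_tsv(mapping_path, RELATIONSHIP_COLUMNS)
    mappings = []
    for row in mdf.itertuples(index=False):
        if row.relationship != MAPS_TO:
            raise VocabularyLoadError(
                f"{mapping_path}: unsupported relationship {row.relationship!r}"
            )
        mappings.append(
            ConceptMapping(int(row.source_concept_id), int(row.target_concept_id))
        )
    adf = _read_tsv(ancestor_path, ANCESTOR_COLUMNS)
    ancestors = [
        ConceptAncestor(int(r.ancestor_concept_id), int(r.descendant_concept_id))
        for r in adf.itertuples(index=False)
    ]
    return VocabularyStore(concepts, mappings, ancestors)


def save_vocabulary(store: VocabularyStore, out_dir: str | Path) -> dict[str, Path]:
    """Serialize a store back to the three TSV files (a fixed point under
    reload). Returns the written paths keyed by table name."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "concept": out / "CONCEPT.tsv",
        "concept_relationship": out / "CONCEPT_RELATIONSHIP.tsv",
        "concept_ancestor": out / "CONCEPT_ANCESTOR.tsv",
    }
    pd.DataFrame(
        [
            (
                c.concept_id,
                c.source_code,
                c.name,
                c.vocabulary_id.value,
                c.concept_class.value,
                int(c.is_standard),
            )
            for c in store.concepts
        ],
        columns=CONCEPT_COLUMNS,
    ).to_csv(paths["concept"], sep="\t", index=False)
    pd.DataFrame(
        [
            (m.source_concept_id, m.target_concept_id, m.relationship)
            for m in store.mappings
        ],
        columns=RELATIONSHIP_COLUMNS,
    ).to_csv(paths["concept_relationship"], sep="\t", index=False)
    pd.DataFrame(
        [(a.ancestor_concept_id, a.descendant_concept_id) for a in store.ancestors],
        columns=ANCESTOR_COLUMNS,
    ).to_csv(paths["concept_ancestor"], sep="\t", index=False)
    return paths
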