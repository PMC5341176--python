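"""Shared fixtures: a generated miniature ecosystem plus a tiny hand-built
vocabulary for targeted edge cases (fan-out mappings, salts, missing
hierarchy)."""

import pytest

from adekb import EvidenceStore, generate_source, generate_vocabulary
from adekb.etl import run_etl
from adekb.fixtures import SourceKind
from adekb.vocabulary import (
    Concept,
    ConceptAncestor,
    ConceptClass,
    ConceptMapping,
    Vocabulary,
    VocabularyStore,
)

SEED = 7


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    d = tmp_path_factory.mktemp("fixtures")
    vocab, manifest = generate_vocabulary(6, 2, 8, seed=SEED, out_dir=d)
    paths = {}
    for kind in SourceKind:
        paths[kind] = generate_source(kind, vocab, 20, 0.25, SEED, d, manifest)
    return {"dir": d, "vocab": vocab, "manifest": manifest, "paths": paths}


@pytest.fixture(scope="session")
def vocab(fixture_dir):
    return fixture_dir["vocab"]


@pytest.fixture(scope="session")
def manifest(fixture_dir):
    return fixture_dir["manifest"]


@pytest.fixture(scope="session")
def loaded_store(fixture_dir):
    """Store with all six sources loaded. Treated as read-only by tests;
    anything that mutates builds its own store."""
    store = EvidenceStore()
    store.attach_vocabulary(fixture_dir["vocab"])
    reports = {}
    for kind, path in fixture_dir["paths"].items():
        reports[kind] = run_etl(kind, path, fixture_dir["vocab"], store)
    store._test_reports = reports  # stashed for report-based tests
    return store


@pytest.fixture
def mini_vocab():
    """Hand-built vocabulary exercising fan-out, salts and hierarchy gaps.

    - simvastatin (1539403) with clinical drug 1539411
    - warfarin (1310149) — name-match / salt-strip target
    - orphan clinical drug 1999001 with no ingredient ancestor
    - MeSH drug D000077154 mapping to TWO RxNorm ingredients (fan-out)
    - MeSH HOI D012206 mapping to TWO SNOMED conditions (fan-out)
    - MedDRA 10039020 -> SNOMED 45619309 (rhabdomyolysis)
    """
    concepts = [
        Concept(1539403, "36567", "simvastatin", Vocabulary.RXNORM,
                ConceptClass.INGREDIENT, True),
        Concept(1539411, "198211", "Simvastatin 20 MG Oral Tablet",
                Vocabulary.RXNORM, ConceptClass.CLINICAL_DRUG, True),
        Concept(1310149, "11289", "warfarin", Vocabulary.RXNORM,
                ConceptClass.INGREDIENT, True),
        Concept(1999001, "999001", "Orphanol 5 MG Oral Tablet",
                Vocabulary.RXNORM, ConceptClass.CLINICAL_DRUG, True),
        Concept(1200001, "120001", "co-drugol", Vocabulary.RXNORM,
                ConceptClass.INGREDIENT, True),
        Concept(45619309, "240131006", "rhabdomyolysis", Vocabulary.SNOMED,
                ConceptClass.CONDITION, True),
        Concept(36516876, "26544005", "muscle weakness", Vocabulary.SNOMED,
                ConceptClass.CONDITION, True),
        Concept(5100001, "10039020", "rhabdomyolysis", Vocabulary.MEDDRA,
                ConceptClass.CONDITION, False),
        Concept(6100001, "D012206", "rhabdomyolysis", Vocabulary.MESH,
                ConceptClass.CONDITION, False),
        Concept(6200001, "D000077154", "simvastatin mixture", Vocabulary.MESH,
                ConceptClass.OTHER, False),
    ]
    mappings = [
        ConceptMapping(5100001, 45619309),
        ConceptMapping(6100001, 45619309),
        ConceptMapping(6100001, 36516876),   # HOI fan-out
        ConceptMapping(6200001, 1539403),
        ConceptMapping(6200001, 1200001),    # drug fan-out
    ]
    ancestors = [ConceptAncestor(1539403, 1539411)]
    return VocabularyStore(concepts, mappings, ancestors)
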