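"""ETL adapters: normalization routes, fan-out, rejection accounting,
evidence-type tags, idempotent reruns."""

import pytest

from adekb import EvidenceStore
from adekb.errors import EtlError, ParseError
from adekb.etl import (
    RawRecord,
    RejectReason,
    Rejection,
    evidence_type_for,
    normalize_record,
    parse_raw,
    run_etl,
)
from adekb.fixtures import SourceKind
from adekb.summary import percent_one_decimal


def _record(kind, **fields):
    return RawRecord(kind, 0, fields)


class TestEvidenceTypeFor:
    @pytest.mark.parametrize(
        "kind,pub,stat,expected",
        [
            (SourceKind.MEDLINE_MESH, "CASE_REPORT", None, "MEDLINE_MeSH_CR"),
            (SourceKind.MEDLINE_MESH, "CLIN_TRIAL", None, "MEDLINE_MeSH_ClinTrial"),
            (SourceKind.MEDLINE_MESH, "OTHER", None, "MEDLINE_MeSH_Other"),
            (SourceKind.MEDLINE_SEMMED, "CASE_REPORT", None, "MEDLINE_SemMedDB_CR"),
            (SourceKind.MEDLINE_SEMMED, "CLIN_TRIAL", None, "MEDLINE_SemMedDB_ClinTrial"),
            (SourceKind.MEDLINE_SEMMED, "OTHER", None, "MEDLINE_SemMedDB_Other"),
            (SourceKind.EU_SPC, None, None, "SPL_EU_SPC"),
            (SourceKind.SPL_US, None, None, "SPL_SPLICER"),
            (SourceKind.CTD, None, None, "CTD_ChemicalDisease"),
            (SourceKind.FAERS, None, "CASE_COUNT", "FAERS_CaseCount"),
            (SourceKind.FAERS, None, "PRR", "FAERS_PRR"),
        ],
    )
    def test_total_over_all_cases(self, kind, pub, stat, expected):
        assert evidence_type_for(kind, pub, stat) == expected

    def test_medline_without_pub_type_errors(self):
        with pytest.raises(EtlError):
            evidence_type_for(SourceKind.MEDLINE_MESH)


class TestNormalizeRecord:
    def test_spl_single_fanout(self, mini_vocab):
        rec = _record(
            SourceKind.SPL_US,
            label_id="L1", set_id="s1", section_name="ADVERSE REACTIONS",
            rxnorm_clinical_drug_code="198211", meddra_hoi_code="10039020",
            mention_text="rhabdomyolysis was reported",
        )
        pairs = normalize_record(rec, SourceKind.SPL_US, mini_vocab)
        assert len(pairs) == 1
        p = pairs[0]
        assert p.drug_concept_id == 1539411
        assert p.ingredient_concept_id == 1539403
        assert p.hoi_concept_id == 45619309
        assert p.evidence_type == "SPL_SPLICER"
        assert p.modality == "SUPPORTS"

    def test_eu_spc_unmatched_name_rejected(self, mini_vocab):
        rec = _record(SourceKind.EU_SPC, doc_id="D1", drug_name="unobtainium",
                      meddra_hoi_code="10039020")
        result = normalize_record(rec, SourceKind.EU_SPC, mini_vocab)
        assert isinstance(result, Rejection)
        assert result.reason is RejectReason.DRUG_UNMAPPED

    def test_both_unmapped_reason(self, mini_vocab):
        rec = _record(SourceKind.EU_SPC, doc_id="D1", drug_name="unobtainium",
                      meddra_hoi_code="99999999")
        result = normalize_record(rec, SourceKind.EU_SPC, mini_vocab)
        assert result.reason is RejectReason.BOTH_UNMAPPED

    def test_hoi_fanout_duplicates_pair_per_target(self, mini_vocab):
        """MeSH HOI D012206 maps to two SNOMED targets -> two pairs sharing
        provenance (enumerated by hand from the mapping table)."""
        rec = _record(SourceKind.MEDLINE_MESH, pmid="1", mesh_drug_code="D000077154",
                      mesh_hoi_code="D012206", pub_type="CASE_REPORT",
                      title_abstract_text="t")
        pairs = normalize_record(rec, SourceKind.MEDLINE_MESH, mini_vocab)
        # drug also fans out to 2 ingredients -> 2 x 2 pairs
        assert len(pairs) == 4
        assert {p.hoi_concept_id for p in pairs} == {45619309, 36516876}
        assert {p.ingredient_concept_id for p in pairs} == {1539403, 1200001}
        assert len({p.provenance for p in pairs}) == 1

    def test_faers_emits_both_statistic_streams(self, mini_vocab):
        rec = _record(SourceKind.FAERS, drug_code="36567", hoi_code="10039020",
                      case_count="12", prr="2.4")
        pairs = normalize_record(rec, SourceKind.FAERS, mini_vocab)
        by_stat = {p.statistic_type: p for p in pairs}
        assert by_stat["CASE_COUNT"].statistic_value == 12.0
        assert by_stat["CASE_COUNT"].evidence_type == "FAERS_CaseCount"
        assert by_stat["PRR"].statistic_value == 2.4
        assert by_stat["PRR"].evidence_type == "FAERS_PRR"

    def test_shape_mismatch_is_parse_error(self, mini_vocab):
        rec = _record(SourceKind.FAERS, wrong="x")
        with pytest.raises(ParseError):
            normalize_record(rec, SourceKind.FAERS, mini_vocab)

    def test_accepted_pairs_satisfy_invariants(self, fixture_dir):
        """Ingredient consistency and standard-SNOMED HOI for every
        accepted record of every source."""
        from adekb.vocabulary import Vocabulary, ingredient_for

        vocab = fixture_dir["vocab"]
        crosswalk = None
        for kind, path in fixture_dir["paths"].items():
            if kind is SourceKind.MEDLINE_SEMMED:
                from adekb.etl import load_crosswalk
                crosswalk = load_crosswalk(
                    path.with_name("medline_semmed_crosswalk.tsv"))
            for rec in parse_raw(path, kind):
                result = normalize_record(rec, kind, vocab, crosswalk)
                if isinstance(result, Rejection):
                    continue
                for p in result:
                    ings = [c.concept_id for c in ingredient_for(vocab, p.drug_concept_id)]
                    assert p.ingredient_concept_id in ings
                    hoi = vocab.concept(p.hoi_concept_id)
                    assert hoi.is_standard and hoi.vocabulary_id is Vocabulary.SNOMED


class TestRunEtl:
    def test_report_arithmetic(self, fixture_dir):
        """20 records at 25% unmappable with 1:1 maps -> 15/20 mapped,
        percentage 75.0 (recomputed via the same rounding convention)."""
        vocab = fixture_dir["vocab"]
        store = EvidenceStore()
        store.attach_vocabulary(vocab)
        report = run_etl(SourceKind.SPL_US, fixture_dir["paths"][SourceKind.SPL_US],
                         vocab, store)
        assert (report.pairs_mapped, report.pairs_in_source) == (15, 20)
        assert report.records_read == 20
        assert report.records_normalized == 15
        assert len(report.rejects) == 5
        assert report.coverage_percent == percent_one_decimal(15, 20) == 75.0

    def test_pairs_mapped_equals_exhaustive_recount(self, loaded_store, fixture_dir):
        """Report distinct-pair counts equal a recount over the stored
        annotation bodies at the source's native level."""
        for kind, report in loaded_store._test_reports.items():
            native_level_pairs = set()
            for ann in loaded_store.annotations(source_id=report.source_id):
                for b in ann.bodies:
                    if kind is SourceKind.SPL_US:
                        native_level_pairs.add((b.drug_concept_id, b.hoi_concept_id))
                    else:
                        native_level_pairs.add(
                            (b.ingredient_concept_id, b.hoi_concept_id))
            assert report.pairs_mapped == len(native_level_pairs)

    def test_empty_file_zero_report(self, vocab, tmp_path):
        empty = tmp_path / "ctd.tsv"
        empty.write_text("mesh_chemical_code\tmesh_disease_code\n")
        store = EvidenceStore()
        store.attach_vocabulary(vocab)
        report = run_etl(SourceKind.CTD, empty, vocab, store)
        assert report.records_read == 0
        assert report.pairs_in_source == 0
        assert report.coverage_percent is None
        assert store.annotation_count() == 0

    def test_rerun_requires_replace_then_is_idempotent(self, fixture_dir):
        vocab = fixture_dir["vocab"]
        path = fixture_dir["paths"][SourceKind.FAERS]
        store = EvidenceStore()
        store.attach_vocabulary(vocab)
        run_etl(SourceKind.FAERS, path, vocab, store)
        before = store.annotation_count()
        evidence_before = store.evidence_rows()
        with pytest.raises(EtlError):
            run_etl(SourceKind.FAERS, path, vocab, store)
        report = run_etl(SourceKind.FAERS, path, vocab, store, replace=True)
        assert store.annotation_count() == before
        assert report.records_read == 20
        # aggregated statistics and linkout URLs unchanged by the rerun
        assert [r[:7] for r in store.evidence_rows()] == [r[:7] for r in evidence_before]

    def test_bad_header_aborts(self, vocab, tmp_path):
        bad = tmp_path / "faers.tsv"
        bad.write_text("a\tb\n1\t2\n")
        store = EvidenceStore()
        store.attach_vocabulary(vocab)
        with pytest.raises(ParseError):
            run_etl(SourceKind.FAERS, bad, vocab, store)
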