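"""ETL engine: hierarchy construction, provenance, information preservation."""

from collections import Counter

import pandas as pd
import pytest

from gdmetl import qc
from gdmetl.etl import EtlEngine, EtlError, run_etl
from gdmetl.schema import validate
from gdmetl.synth import (
    SEER_VARIABLES,
    SourceBeneficiary,
    SourceCarrierClaim,
    SourceCprdTestRecord,
    SourceDataset,
    SourceDrugEvent,
    SourceInpatientClaim,
    SourceLine,
    SourceSeerRecord,
    example_carrier_claim,
)
from gdmetl.vocabulary import seer_grade_concepts


def _bene(bene_id=1, death=None):
    return SourceBeneficiary(
        bene_id=bene_id, birth_date="1940-05-01", sex_code="2", race_code="3",
        death_date=death, part_a_start="2008-01-01", part_a_end="2010-12-31",
        part_b_start="2008-06-01", part_b_end="2010-12-31")


def _codes_of(db):
    """(vocabulary, code, provenance code, seq) for every clinical code."""
    codes = db["concepts"].set_index("id")["concept_code"]
    cc = db["clinical_codes"]
    return [
        (r["clinical_code_source_vocabulary"],
         codes.loc[int(r["clinical_code_concept_id"])],
         codes.loc[int(r["provenance_concept_id"])],
         int(r["seq_num"]))
        for _, r in cc.iterrows()
    ]


class TestBeneficiaries:
    def test_coverage_spans_become_two_period_types(self):
        eng = EtlEngine()
        eng.etl_beneficiaries([_bene()])
        db = eng.finish()
        ip = db["information_periods"]
        assert len(ip) == 2
        assert ip["information_type_concept_id"].nunique() == 2
        assert len(db["deaths"]) == 0  # no death date -> no Deaths row

    def test_death_date_creates_single_death_row(self):
        eng = EtlEngine()
        eng.etl_beneficiaries([_bene(death="2010-03-04")])
        db = eng.finish()
        assert list(db["deaths"]["date"]) == ["2010-03-04"]

    def test_duplicate_bene_rejected(self):
        eng = EtlEngine()
        with pytest.raises(EtlError, match="duplicate bene_id"):
            eng.etl_beneficiaries([_bene(1), _bene(1)])

    def test_bulk_load_counts_and_integrity(self, small_etl):
        ds, db, _ = small_etl
        assert len(db["patients"]) == len(ds.beneficiaries)
        assert validate(db) == []


class TestCarrierClaim:
    def test_worked_example_one_collection_three_contexts(self):
        eng = EtlEngine()
        eng.etl_carrier_claim(example_carrier_claim())
        db = eng.finish()
        assert len(db["collections"]) == 1
        ctx = db["contexts"]
        assert len(ctx) == 3
        assert ctx["collection_id"].nunique() == 1
        # one claim-level + two line-level contexts
        codes = db["concepts"].set_index("id")["concept_code"]
        types = sorted(codes.loc[int(i)] for i in ctx["record_type_concept_id"])
        assert types == ["carrier_claim", "carrier_line", "carrier_line"]

    def test_every_source_code_is_one_row(self):
        claim = example_carrier_claim()
        eng = EtlEngine()
        eng.etl_carrier_claim(claim)
        db = eng.finish()
        expected = Counter(
            [("icd9_dx", c) for c in claim.header_dx_codes]
            + [("icd9_dx", ln.line_dx_code) for ln in claim.lines]
            + [("hcpcs", ln.hcpcs_code) for ln in claim.lines]
        )
        got = Counter((v, c) for v, c, _, _ in _codes_of(db))
        assert got == expected

    def test_minimal_claim_counts(self):
        claim = SourceCarrierClaim(
            claim_id=1, bene_id=1, from_date="2009-01-01",
            thru_date="2009-01-01", header_dx_codes=("401.9",),
            lines=(SourceLine(1, "250.00", "99213", "11", 10.0),))
        eng = EtlEngine()
        eng.etl_carrier_claim(claim)
        db = eng.finish()
        assert len(db["contexts"]) == 2
        assert len(db["clinical_codes"]) == 3

    def test_header_order_preserved_in_seq_num(self):
        claim = SourceCarrierClaim(
            claim_id=1, bene_id=1, from_date="2009-01-01",
            thru_date="2009-01-01",
            header_dx_codes=("486", "401.9", "250.00"),
            lines=(SourceLine(1, "250.00", "99213", "11", 10.0),))
        eng = EtlEngine()
        eng.etl_carrier_claim(claim)
        db = eng.finish()
        header = [(c, s) for v, c, p, s in _codes_of(db) if p == "header_dx"]
        assert header == [("486", 1), ("401.9", 2), ("250.00", 3)]

    def test_line_payment_attaches_to_line_context(self):
        eng = EtlEngine()
        eng.etl_carrier_claim(example_carrier_claim())
        db = eng.finish()
        codes = db["concepts"].set_index("id")["concept_code"]
        ctx_type = db["contexts"].set_index("id")["record_type_concept_id"]
        pr = db["payer_reimbursements"]
        assert len(pr) == 2
        assert all(
            codes.loc[int(ctx_type.loc[int(c)])] == "carrier_line"
            for c in pr["context_id"]
        )
        assert sorted(pr["paid_amount"]) == [42.5, 85.0]

    def test_claim_without_lines_rejected(self):
        claim = SourceCarrierClaim(
            claim_id=1, bene_id=1, from_date="2009-01-01",
            thru_date="2009-01-01", header_dx_codes=("486",), lines=())
        with pytest.raises(EtlError, match="no lines"):
            EtlEngine().etl_carrier_claim(claim)


class TestInpatientClaim:
    CLAIM = SourceInpatientClaim(
        claim_id=5, bene_id=1, admit_date="2009-02-01",
        discharge_date="2009-02-07", header_dx_codes=("486", "428.0", "599.0"),
        proc_codes=("81.54",), discharge_status="20", claim_payment=12000.0)

    def test_single_context_with_admission_detail(self):
        eng = EtlEngine()
        eng.etl_inpatient_claim(self.CLAIM)
        db = eng.finish()
        assert len(db["collections"]) == 1
        assert len(db["contexts"]) == 1
        assert len(db["clinical_codes"]) == 4
        assert len(db["admissions_details"]) == 1

    def test_expired_status_recorded_without_death_row(self):
        eng = EtlEngine()
        eng.etl_inpatient_claim(self.CLAIM)  # status 20 = expired
        db = eng.finish()
        codes = db["concepts"].set_index("id")["concept_code"]
        status = db["admissions_details"]["discharge_status_concept_id"].iloc[0]
        assert codes.loc[int(status)] == "20"
        assert len(db["deaths"]) == 0

    def test_collection_spans_admission(self):
        eng = EtlEngine()
        eng.etl_inpatient_claim(self.CLAIM)
        db = eng.finish()
        coll = db["collections"].iloc[0]
        assert (coll["start_date"], coll["end_date"]) == (
            "2009-02-01", "2009-02-07")

    def test_claim_payment_at_claim_level(self):
        eng = EtlEngine()
        eng.etl_inpatient_claim(self.CLAIM)
        db = eng.finish()
        pr = db["payer_reimbursements"]
        assert len(pr) == 1
        assert float(pr["paid_amount"].iloc[0]) == 12000.0
        assert int(pr["context_id"].iloc[0]) == int(db["contexts"]["id"].iloc[0])

    def test_discharge_before_admission_rejected(self):
        bad = SourceInpatientClaim(
            claim_id=6, bene_id=1, admit_date="2009-02-07",
            discharge_date="2009-02-01", header_dx_codes=("486",),
            proc_codes=(), discharge_status="01", claim_payment=1.0)
        with pytest.raises(EtlError, match="discharge before admission"):
            EtlEngine().etl_inpatient_claim(bad)


class TestDrugEvent:
    EVENT = SourceDrugEvent(event_id=1, bene_id=1, service_date="2009-04-01",
                            ndc_code="00093310905", days_supply=30,
                            quantity=60.0)

    def test_simplest_chain_is_1_1_1_1(self):
        eng = EtlEngine()
        eng.etl_drug_event(self.EVENT)
        db = eng.finish()
        for table in ("collections", "contexts", "clinical_codes",
                      "drug_exposure_details"):
            assert len(db[table]) == 1
        code = db["clinical_codes"].iloc[0]
        assert int(code["drug_exposure_detail_id"]) == 1
        detail = db["drug_exposure_details"].iloc[0]
        assert int(detail["days_supply"]) == 30
        assert float(detail["quantity"]) == 60.0

    def test_n_events_n_collections(self, small_etl):
        ds, db, _ = small_etl
        codes = db["concepts"].set_index("id")["concept_code"]
        coll_types = db["collections"]["collection_type_concept_id"].map(codes)
        assert (coll_types == "prescription").sum() == len(ds.drug_events)


class TestSeerRecord:
    RECORD = SourceSeerRecord(
        case_id=1, diagnosis_date="2009-06-15",
        variables=tuple((v, pool[0]) for v, pool in SEER_VARIABLES.items()))

    def test_each_variable_becomes_its_own_vocabulary(self):
        eng = EtlEngine()
        eng.etl_seer_record(self.RECORD)
        db = eng.finish()
        vocabs = set(db["clinical_codes"]["clinical_code_source_vocabulary"])
        assert len(vocabs) == 31
        assert all(v.startswith("naaccr_") for v in vocabs)
        assert vocabs <= set(db["vocabularies"]["id"])

    def test_one_context_per_record(self):
        eng = EtlEngine()
        eng.etl_seer_record(self.RECORD)
        db = eng.finish()
        assert len(db["contexts"]) == 1
        assert len(db["collections"]) == 1
        assert db["clinical_codes"]["context_id"].nunique() == 1

    def test_grade_value_resolves_to_curated_concept(self):
        eng = EtlEngine()
        eng.store.load_concepts(seer_grade_concepts())
        record = SourceSeerRecord(case_id=1, diagnosis_date="2009-06-15",
                                  variables=(("grade", "5"),))
        eng.etl_seer_record(record)
        db = eng.finish()
        assert int(db["clinical_codes"]["clinical_code_concept_id"].iloc[0]) \
            == 100010947

    def test_empty_record_no_rows(self):
        eng = EtlEngine()
        eng.etl_seer_record(SourceSeerRecord(1, "2009-06-15", ()))
        db = eng.finish()
        assert len(db["clinical_codes"]) == 0
        assert len(db["collections"]) == 0


class TestCprdTest:
    RECORD = SourceCprdTestRecord(patient_id=1, event_date="2009-07-01",
                                  read_code="44P..", entity_type="163",
                                  value=5.2, unit="mmol/L")

    def test_read_code_and_entity_share_context_and_detail(self):
        eng = EtlEngine()
        eng.etl_cprd_test(self.RECORD)
        db = eng.finish()
        cc = db["clinical_codes"]
        assert len(cc) == 2
        assert cc["context_id"].nunique() == 1
        assert cc["measurement_detail_id"].nunique() == 1
        assert len(db["measurement_details"]) == 1
        assert float(db["measurement_details"]["value_as_number"].iloc[0]) == 5.2

    def test_ten_records_twenty_codes(self):
        eng = EtlEngine()
        for i in range(10):
            eng.etl_cprd_test(SourceCprdTestRecord(
                patient_id=1, event_date=f"2009-07-{i + 1:02d}",
                read_code="44P..", entity_type="163", value=float(i),
                unit="mmol/L"))
        db = eng.finish()
        assert len(db["clinical_codes"]) == 20
        assert len(db["measurement_details"]) == 10


class TestRunEtl:
    def test_pipeline_passes_validation(self, small_etl):
        _, db, _ = small_etl
        assert validate(db) == []

    def test_code_multiset_preserved(self, small_etl):
        ds, db, _ = small_etl
        source = Counter(
            (bene, vocab, code, date)
            for bene, vocab, code, date, _, _ in qc.enumerate_source_codes(ds)
        )
        to_src = qc.gdm_patient_to_source_id(db)
        codes = db["concepts"].set_index("id")["concept_code"]
        gdm = Counter(
            (to_src[int(r["patient_id"])],
             r["clinical_code_source_vocabulary"],
             codes.loc[int(r["clinical_code_concept_id"])],
             r["start_date"])
            for _, r in db["clinical_codes"].iterrows()
        )
        assert gdm == source

    def test_hierarchy_chains_resolve(self, small_etl):
        _, db, _ = small_etl
        ctx_ids = set(db["contexts"]["id"])
        coll_ids = set(db["collections"]["id"])
        assert set(db["clinical_codes"]["context_id"]) <= ctx_ids
        assert set(db["contexts"]["collection_id"]) <= coll_ids

    def test_cost_placement_by_context_type(self, small_etl, concept_code_by_id):
        _, db, _ = small_etl
        ctx_type = db["contexts"].set_index("id")["record_type_concept_id"]
        types = {
            concept_code_by_id.loc[int(ctx_type.loc[int(c)])]
            for c in db["payer_reimbursements"]["context_id"]
        }
        # line payments on line contexts, claim payments on claim contexts
        assert types <= {"carrier_line", "inpatient_claim"}

    def test_every_context_has_source_file(self, small_etl):
        _, db, _ = small_etl
        src = db["contexts"]["source_file"]
        assert src.notna().all() and (src != "").all()
        assert set(src) <= {
            "inpatient_claims.csv", "carrier_claims.csv", "carrier_lines.csv",
            "drug_events.csv", "seer_records.csv", "cprd_test.csv"}

    def test_empty_dataset_empty_clinical_tables(self):
        db = run_etl(SourceDataset())
        counts = db.row_counts()
        for table in ("patients", "clinical_codes", "contexts", "collections"):
            assert counts[table] == 0
        assert counts["concepts"] > 0  # preloaded vocabulary content remains

    def test_failures_aggregated_with_identifiers(self):
        ds = SourceDataset(
            beneficiaries=[_bene(1)],
            inpatient_claims=[SourceInpatientClaim(
                claim_id=77, bene_id=1, admit_date="2009-02-07",
                discharge_date="2009-02-01", header_dx_codes=("486",),
                proc_codes=(), discharge_status="01", claim_payment=1.0)],
        )
        with pytest.raises(EtlError) as err:
            run_etl(ds)
        assert any("77" in f for f in err.value.failures)

    def test_deterministic_rerun(self, small_dataset):
        assert run_etl(small_dataset) == run_etl(small_dataset)
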