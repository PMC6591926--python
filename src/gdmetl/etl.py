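"""Source → GDM transformation.

The central move of the ETL is relocation, not interpretation: every code
occurrence in the source becomes exactly one Clinical Codes row; codes
that were reported together (a claim header, one claim line, one
laboratory measurement, one registry case) share a Context carrying their
provenance (source file, record type, place of service); Contexts from
one claim or visit share a Collection.  Sequence numbers preserve the
source ordering of numbered code slots.  Costs attach to the Context they
were reported at — line payments to line-level contexts, claim payments
to claim-level contexts — and are never reconciled against each other.

Diagnosis codes that indicate death stay in Clinical Codes; the Deaths
table is populated only from the beneficiary summary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from gdmetl import synth
from gdmetl.schema import GdmDatabase
from gdmetl.synth import (
    SourceBeneficiary,
    SourceCarrierClaim,
    SourceCprdTestRecord,
    SourceDataset,
    SourceDrugEvent,
    SourceInpatientClaim,
    SourceSeerRecord,
)
from gdmetl.vocabulary import ConceptStore, load_synpuf_sentinel_mappings

# clinical-code vocabularies (shared contract with the cohort oracle)
VOCAB_ICD9_DX = "icd9_dx"
VOCAB_ICD9_PROC = "icd9_proc"
VOCAB_HCPCS = "hcpcs"
VOCAB_NDC = "ndc"
VOCAB_READ = "read"
VOCAB_ENTITY_TYPE = "cprd_entity_type"
VOCAB_SEER_PREFIX = "naaccr_"

# bookkeeping vocabularies
VOCAB_RECORD_TYPE = "gdm_record_type"
VOCAB_PROVENANCE = "gdm_provenance"
VOCAB_COLLECTION_TYPE = "gdm_collection_type"
VOCAB_INFO_TYPE = "gdm_information_type"
VOCAB_DETAIL_TYPE = "gdm_detail_type"
VOCAB_POS = "cms_place_of_service"
VOCAB_DISCHARGE_STATUS = "synpuf_discharge_status"
VOCAB_SEX = "synpuf_sex"
VOCAB_RACE = "synpuf_race"
VOCAB_UNIT = "cprd_unit"
VOCAB_UNKNOWN = "gdm_unknown"

RECORD_TYPES = {
    "inpatient_claim": "inpatient claim (claim-level context)",
    "carrier_claim": "carrier claim header (claim-level context)",
    "carrier_line": "carrier claim line (line-level context)",
    "prescription": "prescription drug event",
    "measurement": "laboratory / clinical measurement",
    "registry": "cancer registry record",
}
PROVENANCES = {
    "header_dx": "header (claim-level) diagnosis",
    "line_dx": "line diagnosis",
    "procedure": "procedure code",
    "prescription": "dispensed drug code",
    "measurement": "measurement code",
    "registry_value": "registry variable value",
}
COLLECTION_TYPES = ("claim", "prescription", "measurement", "registry")
INFO_TYPES = ("part_a", "part_b", "up_to_standard")
DETAIL_TYPES = ("source_patient_id",)


class EtlError(Exception):
    """Raised for an invalid source record, or (by ``run_etl``) with the
    aggregated per-record failures of a whole run."""

    def __init__(self, message: str, failures: list[str] | None = None):
        super().__init__(message)
        self.failures = failures or []


@dataclass
class ProvenanceRegistry:
    """Concept ids for record types, provenances and period types.

    Every id is registered in the ConceptStore before use, so the emitted
    database always passes concept-resolution validation.
    """

    store: ConceptStore
    record_type: dict[str, int] = field(default_factory=dict)
    provenance: dict[str, int] = field(default_factory=dict)
    collection_type: dict[str, int] = field(default_factory=dict)
    info_type: dict[str, int] = field(default_factory=dict)
    detail_type: dict[str, int] = field(default_factory=dict)
    unknown_concept_id: int = 0

    def __post_init__(self) -> None:
        for code, text in RECORD_TYPES.items():
            self.record_type[code] = self.store.get_or_assign(
                VOCAB_RECORD_TYPE, code, text
            )
        for code, text in PROVENANCES.items():
            self.provenance[code] = self.store.get_or_assign(
                VOCAB_PROVENANCE, code, text
            )
        for code in COLLECTION_TYPES:
            self.collection_type[code] = self.store.get_or_assign(
                VOCAB_COLLECTION_TYPE, code
            )
        for code in INFO_TYPES:
            self.info_type[code] = self.store.get_or_assign(VOCAB_INFO_TYPE, code)
        for code in DETAIL_TYPES:
            self.detail_type[code] = self.store.get_or_assign(VOCAB_DETAIL_TYPE, code)
        self.unknown_concept_id = self.store.get_or_assign(
            VOCAB_UNKNOWN, "unknown", "Unknown / not recorded"
        )


class EtlEngine:
    """Stateful ETL run: accumulates GDM rows with sequential ids.

    Primary keys are assigned from 1 within each table in deterministic
    input order, so a run under a fixed seed is exactly reproducible.
    """

    def __init__(self, store: ConceptStore | None = None,
                 preload_demographic_mappings: bool = True):
        self.store = store if store is not None else ConceptStore()
        if preload_demographic_mappings:
            load_synpuf_sentinel_mappings(self.store)
        self.registry = ProvenanceRegistry(self.store)
        self.rows: dict[str, list[dict]] = {
            "patients": [], "patient_details": [], "information_periods": [],
            "deaths": [], "collections": [], "contexts": [], "clinical_codes": [],
            "admissions_details": [], "drug_exposure_details": [],
            "measurement_details": [], "payer_reimbursements": [],
        }
        self._next: dict[str, int] = {}
        self._patient_by_bene: dict[int, int] = {}
        self.log: dict[str, int] = {}

    def _new_id(self, table: str) -> int:
        self._next[table] = self._next.get(table, 0) + 1
        return self._next[table]

    # -- patients -----------------------------------------------------

    def ensure_patient(self, bene_id: int) -> int:
        """Patient id for a source person id, creating a stub if needed."""
        if bene_id in self._patient_by_bene:
            return self._patient_by_bene[bene_id]
        unknown = self.registry.unknown_concept_id
        pid = self._new_id("patients")
        self.rows["patients"].append(
            dict(id=pid, birth_date="1900-01-01", gender_concept_id=unknown,
                 race_concept_id=unknown, ethnicity_concept_id=unknown,
                 address_id=None, practitioner_id=None)
        )
        self._register_source_id(pid, bene_id)
        self._patient_by_bene[bene_id] = pid
        return pid

    def _register_source_id(self, patient_id: int, bene_id: int) -> None:
        self.rows["patient_details"].append(
            dict(id=self._new_id("patient_details"), patient_id=patient_id,
                 start_date=None, end_date=None,
                 detail_concept_id=self.registry.detail_type["source_patient_id"],
                 value_as_text=str(bene_id))
        )

    def etl_beneficiaries(self, beneficiaries: list[SourceBeneficiary]) -> None:
        """Load the beneficiary summary: patients, enrollment periods, deaths."""
        seen: set[int] = set()
        for b in sorted(beneficiaries, key=lambda b: b.bene_id):
            if b.bene_id in seen:
                raise EtlError(f"duplicate bene_id {b.bene_id}")
            seen.add(b.bene_id)
            if b.bene_id in self._patient_by_bene:
                raise EtlError(f"bene_id {b.bene_id} already loaded")
            pid = self._new_id("patients")
            sex = self.store.get_or_assign(VOCAB_SEX, b.sex_code)
            race = self.store.get_or_assign(VOCAB_RACE, b.race_code)
            self.rows["patients"].append(
                dict(id=pid, birth_date=b.birth_date, gender_concept_id=sex,
                     race_concept_id=race, ethnicity_concept_id=race,
                     address_id=None, practitioner_id=None)
            )
            self._register_source_id(pid, b.bene_id)
            self._patient_by_bene[b.bene_id] = pid
            for span, info in ((b.part_a_start, "part_a"), (b.part_b_start, "part_b")):
                end = b.part_a_end if info == "part_a" else b.part_b_end
                self.rows["information_periods"].append(
                    dict(id=self._new_id("information_periods"), patient_id=pid,
                         start_date=span, end_date=end,
                         information_type_concept_id=self.registry.info_type[info])
                )
            if b.death_date is not None:
                self.rows["deaths"].append(
                    dict(id=self._new_id("deaths"), patient_id=pid,
                         date=b.death_date, cause_concept_id=None,
                         cause_type_concept_id=None)
                )

    # -- claims -------------------------------------------------------

    def _new_collection(self, pid: int, start: str, end: str, ctype: str) -> int:
        cid = self._new_id("collections")
        self.rows["collections"].append(
            dict(id=cid, patient_id=pid, start_date=start, end_date=end,
                 collection_type_concept_id=self.registry.collection_type[ctype])
        )
        return cid

    def _new_context(self, coll_id: int, pid: int, start: str, end: str,
                     record_type: str, source_file: str,
                     pos_code: str | None = None) -> int:
        ctx_id = self._new_id("contexts")
        pos_id = (
            None if pos_code is None
            else self.store.get_or_assign(VOCAB_POS, pos_code)
        )
        self.rows["contexts"].append(
            dict(id=ctx_id, collection_id=coll_id, patient_id=pid,
                 start_date=start, end_date=end,
                 record_type_concept_id=self.registry.record_type[record_type],
                 source_file=source_file, pos_concept_id=pos_id,
                 care_site_type_concept_id=None, facility_id=None)
        )
        return ctx_id

    def _new_code(self, pid: int, ctx_id: int, start: str, end: str,
                  vocabulary: str, code: str, provenance: str, seq: int,
                  drug_detail: int | None = None,
                  measurement_detail: int | None = None) -> int:
        code_id = self._new_id("clinical_codes")
        self.rows["clinical_codes"].append(
            dict(id=code_id, patient_id=pid, context_id=ctx_id,
                 start_date=start, end_date=end,
                 clinical_code_concept_id=self.store.get_or_assign(vocabulary, code),
                 clinical_code_source_vocabulary=vocabulary,
                 provenance_concept_id=self.registry.provenance[provenance],
                 seq_num=seq, drug_exposure_detail_id=drug_detail,
                 measurement_detail_id=measurement_detail)
        )
        return code_id

    def _new_reimbursement(self, ctx_id: int, paid: float) -> None:
        self.rows["payer_reimbursements"].append(
            dict(id=self._new_id("payer_reimbursements"), context_id=ctx_id,
                 clinical_code_id=None, paid_amount=paid, allowed_amount=None,
                 patient_coinsurance=None, patient_deductible=None)
        )

    def etl_carrier_claim(self, claim: SourceCarrierClaim) -> int:
        """One collection; a claim-level context with the header diagnoses;
        one line-level context per line with its diagnosis and procedure;
        the line payment attached to the line context.  Returns the
        collection id."""
        if not claim.lines:
            raise EtlError(f"carrier claim {claim.claim_id} has no lines")
        pid = self.ensure_patient(claim.bene_id)
        coll = self._new_collection(pid, claim.from_date, claim.thru_date, "claim")
        head_ctx = self._new_context(
            coll, pid, claim.from_date, claim.thru_date,
            "carrier_claim", synth.CARRIER_FILE,
        )
        for seq, dx in enumerate(claim.header_dx_codes, start=1):
            self._new_code(pid, head_ctx, claim.from_date, claim.thru_date,
                           VOCAB_ICD9_DX, dx, "header_dx", seq)
        for line in sorted(claim.lines, key=lambda x: x.line_num):
            line_ctx = self._new_context(
                coll, pid, claim.from_date, claim.thru_date,
                "carrier_line", synth.CARRIER_LINE_FILE,
                pos_code=line.place_of_service,
            )
            self._new_code(pid, line_ctx, claim.from_date, claim.thru_date,
                           VOCAB_ICD9_DX, line.line_dx_code, "line_dx", 1)
            self._new_code(pid, line_ctx, claim.from_date, claim.thru_date,
                           VOCAB_HCPCS, line.hcpcs_code, "procedure", 1)
            self._new_reimbursement(line_ctx, line.line_payment)
        return coll

    def etl_inpatient_claim(self, claim: SourceInpatientClaim) -> int:
        """One collection with a single claim-level context holding header
        diagnoses and procedures, an admissions-detail row, and the claim
        payment at claim level."""
        if claim.discharge_date < claim.admit_date:
            raise EtlError(
                f"inpatient claim {claim.claim_id}: discharge before admission"
            )
        if not claim.header_dx_codes:
            raise EtlError(f"inpatient claim {claim.claim_id} has no diagnoses")
        pid = self.ensure_patient(claim.bene_id)
        coll = self._new_collection(
            pid, claim.admit_date, claim.discharge_date, "claim"
        )
        ctx = self._new_context(
            coll, pid, claim.admit_date, claim.discharge_date,
            "inpatient_claim", synth.INPATIENT_FILE,
        )
        for seq, dx in enumerate(claim.header_dx_codes, start=1):
            self._new_code(pid, ctx, claim.admit_date, claim.discharge_date,
                           VOCAB_ICD9_DX, dx, "header_dx", seq)
        for seq, pr in enumerate(claim.proc_codes, start=1):
            self._new_code(pid, ctx, claim.admit_date, claim.discharge_date,
                           VOCAB_ICD9_PROC, pr, "procedure", seq)
        self.rows["admissions_details"].append(
            dict(id=self._new_id("admissions_details"), collection_id=coll,
                 admission_date=claim.admit_date,
                 discharge_date=claim.discharge_date,
                 admit_source_concept_id=None,
                 discharge_status_concept_id=self.store.get_or_assign(
                     VOCAB_DISCHARGE_STATUS, claim.discharge_status))
        )
        self._new_reimbursement(ctx, claim.claim_payment)
        return coll

    def etl_drug_event(self, event: SourceDrugEvent) -> int:
        """The simplest chain: one clinical code, one context, one
        collection, one drug-exposure detail."""
        pid = self.ensure_patient(event.bene_id)
        coll = self._new_collection(
            pid, event.service_date, event.service_date, "prescription"
        )
        ctx = self._new_context(
            coll, pid, event.service_date, event.service_date,
            "prescription", synth.DRUG_FILE,
        )
        detail_id = self._new_id("drug_exposure_details")
        self.rows["drug_exposure_details"].append(
            dict(id=detail_id, days_supply=event.days_supply,
                 quantity=event.quantity, refills=None, dose_form_concept_id=None)
        )
        self._new_code(pid, ctx, event.service_date, event.service_date,
                       VOCAB_NDC, event.ndc_code, "prescription", 1,
                       drug_detail=detail_id)
        return coll

    def etl_seer_record(self, record: SourceSeerRecord) -> int:
        """Registry record: one collection and one registry-type context;
        each (variable, value) becomes a clinical code in a vocabulary
        named for the variable."""
        if not record.variables:
            return 0
        pid = self.ensure_patient(record.case_id)
        d = record.diagnosis_date
        coll = self._new_collection(pid, d, d, "registry")
        ctx = self._new_context(coll, pid, d, d, "registry", synth.SEER_FILE)
        for seq, (variable, value) in enumerate(record.variables, start=1):
            self._new_code(pid, ctx, d, d, VOCAB_SEER_PREFIX + variable,
                           value, "registry_value", seq)
        return coll

    def etl_cprd_test(self, record: SourceCprdTestRecord) -> int:
        """EHR Test record: the Read code and the entity type share one
        context and one measurement-detail row holding the value."""
        pid = self.ensure_patient(record.patient_id)
        d = record.event_date
        coll = self._new_collection(pid, d, d, "measurement")
        ctx = self._new_context(coll, pid, d, d, "measurement", synth.CPRD_FILE)
        md_id = self._new_id("measurement_details")
        self.rows["measurement_details"].append(
            dict(id=md_id, value_as_number=record.value, value_as_concept_id=None,
                 unit_concept_id=self.store.get_or_assign(VOCAB_UNIT, record.unit),
                 normal_range_low=None, normal_range_high=None)
        )
        self._new_code(pid, ctx, d, d, VOCAB_READ, record.read_code,
                       "measurement", 1, measurement_detail=md_id)
        self._new_code(pid, ctx, d, d, VOCAB_ENTITY_TYPE, record.entity_type,
                       "measurement", 2, measurement_detail=md_id)
        return coll

    # -- finalize -----------------------------------------------------

    def finish(self) -> GdmDatabase:
        """Assemble the 19-table database, including the vocabulary tables."""
        db = GdmDatabase()
        for table, rows in self.rows.items():
            db.append(table, rows)
        for table, frame in self.store.to_frames().items():
            db[table] = frame
        self.log = db.row_counts()
        return db


def run_etl(dataset: SourceDataset, store: ConceptStore | None = None,
            engine: EtlEngine | None = None) -> GdmDatabase:
    """Run the full ETL over a source dataset in deterministic order.

    Per-record failures are collected and re-raised together, tagged with
    the offending record's identifier.
    """
    eng = engine if engine is not None else EtlEngine(store=store)
    failures: list[str] = []
    eng.etl_beneficiaries(dataset.beneficiaries)
    stages = [
        ("inpatient claim", sorted(dataset.inpatient_claims,
                                   key=lambda c: (c.bene_id, c.claim_id)),
         eng.etl_inpatient_claim, lambda c: c.claim_id),
        ("carrier claim", sorted(dataset.carrier_claims,
                                 key=lambda c: (c.bene_id, c.claim_id)),
         eng.etl_carrier_claim, lambda c: c.claim_id),
        ("drug event", sorted(dataset.drug_events,
                              key=lambda e: (e.bene_id, e.event_id)),
         eng.etl_drug_event, lambda e: e.event_id),
        ("registry record", sorted(dataset.seer_records,
                                   key=lambda r: r.case_id),
         eng.etl_seer_record, lambda r: r.case_id),
        ("measurement record", sorted(dataset.cprd_records,
                                      key=lambda r: (r.patient_id, r.event_date,
                                                     r.read_code, r.entity_type)),
         eng.etl_cprd_test, lambda r: r.patient_id),
    ]
    for label, records, op, ident in stages:
        for rec in records:
            try:
                op(rec)
            except EtlError as exc:
                failures.append(f"{label} {ident(rec)}: {exc}")
    if failures:
        raise EtlError(f"{len(failures)} record(s) failed", failures)
    return eng.finish()
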