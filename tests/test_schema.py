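"""Schema-level invariants: table set, validation rules, CSV, DDL."""

import re
import sqlite3

import pandas as pd
import pytest

from gdmetl.schema import (
    FOREIGN_KEYS,
    TABLE_NAMES,
    GdmDatabase,
    GdmError,
    create_database,
    emit_ddl,
    read_csv,
    validate,
    write_csv,
)

EXPECTED_TABLES = sorted(
    [
        "patients", "patient_details", "information_periods", "deaths",
        "clinical_codes", "contexts", "collections", "admissions_details",
        "drug_exposure_details", "measurement_details", "payer_reimbursements",
        "costs", "facilities", "addresses", "practitioners",
        "contexts_practitioners", "concepts", "vocabularies", "mappings",
    ]
)


def _base_db() -> GdmDatabase:
    """Minimal consistent database: one patient, one collection/context
    chain, with the concepts the rows reference."""
    db = create_database()
    db.append("vocabularies", [dict(id="v", description="test", domain=None)])
    db.append("concepts", [
        dict(id=1, vocabulary_id="v", concept_code="c1", concept_text="t"),
        dict(id=2, vocabulary_id="v", concept_code="c2", concept_text="t"),
    ])
    db.append("patients", [dict(
        id=10, birth_date="1940-01-01", gender_concept_id=1,
        race_concept_id=1, ethnicity_concept_id=1,
        address_id=None, practitioner_id=None)])
    db.append("collections", [dict(
        id=100, patient_id=10, start_date="2009-01-01", end_date="2009-01-02",
        collection_type_concept_id=1)])
    db.append("contexts", [dict(
        id=200, collection_id=100, patient_id=10, start_date="2009-01-01",
        end_date="2009-01-02", record_type_concept_id=1, source_file="f.csv",
        pos_concept_id=None, care_site_type_concept_id=None, facility_id=None)])
    return db


def _code_row(**overrides):
    row = dict(
        id=300, patient_id=10, context_id=200, start_date="2009-01-01",
        end_date="2009-01-01", clinical_code_concept_id=2,
        clinical_code_source_vocabulary="v", provenance_concept_id=1,
        seq_num=1, drug_exposure_detail_id=None, measurement_detail_id=None)
    row.update(overrides)
    return row


class TestDatabaseShape:
    def test_create_database_has_19_empty_tables(self):
        db = create_database()
        assert len(db.table_names()) == 19
        assert all(n == 0 for n in db.row_counts().values())
        assert validate(db) == []

    def test_table_names_fixed_and_sorted(self):
        assert create_database().table_names() == EXPECTED_TABLES
        assert list(TABLE_NAMES) == sorted(TABLE_NAMES)

    def test_unknown_table_rejected(self):
        with pytest.raises(GdmError):
            GdmDatabase({"bogus": pd.DataFrame()})


class TestValidate:
    def test_consistent_fixture_passes(self):
        db = _base_db()
        db.append("clinical_codes", [_code_row()])
        assert validate(db) == []

    def test_dangling_context_is_single_violation(self):
        db = _base_db()
        db.append("clinical_codes", [_code_row(context_id=999)])
        violations = validate(db)
        assert len(violations) == 1
        v = violations[0]
        assert (v.table, v.row_id, v.rule) == ("clinical_codes", 300,
                                               "dangling_context")

    def test_context_patient_differs_from_collection(self):
        db = _base_db()
        db.append("patients", [dict(
            id=11, birth_date="1950-01-01", gender_concept_id=1,
            race_concept_id=1, ethnicity_concept_id=1,
            address_id=None, practitioner_id=None)])
        ctx = db["contexts"].copy()
        ctx.loc[0, "patient_id"] = 11
        db["contexts"] = ctx
        violations = validate(db)
        assert [v.rule for v in violations] == ["patient_mismatch"]
        assert violations[0].table == "contexts"

    def test_date_order_violation(self):
        db = _base_db()
        coll = db["collections"].copy()
        coll.loc[0, "end_date"] = "2008-01-01"
        db["collections"] = coll
        assert "date_order" in {v.rule for v in validate(db)}

    def test_duplicate_seq_num_within_context_provenance(self):
        db = _base_db()
        db.append("clinical_codes", [_code_row(id=300), _code_row(id=301)])
        assert {v.rule for v in validate(db)} == {"duplicate_seq_num"}

    def test_measurement_without_value_flagged(self):
        db = _base_db()
        db.append("measurement_details", [dict(
            id=1, value_as_number=None, value_as_concept_id=None,
            unit_concept_id=None, normal_range_low=None,
            normal_range_high=None)])
        assert {v.rule for v in validate(db)} == {"measurement_empty"}

    def test_cost_code_must_share_context(self):
        db = _base_db()
        db.append("contexts", [dict(
            id=201, collection_id=100, patient_id=10, start_date="2009-01-01",
            end_date="2009-01-02", record_type_concept_id=1,
            source_file="f.csv", pos_concept_id=None,
            care_site_type_concept_id=None, facility_id=None)])
        db.append("clinical_codes", [_code_row()])
        db.append("payer_reimbursements", [dict(
            id=1, context_id=201, clinical_code_id=300, paid_amount=5.0,
            allowed_amount=None, patient_coinsurance=None,
            patient_deductible=None)])
        assert "code_context_mismatch" in {v.rule for v in validate(db)}

    def test_result_invariant_under_row_permutation(self, small_etl):
        _, db, _ = small_etl
        shuffled = GdmDatabase()
        for name in db.table_names():
            shuffled.tables[name] = (
                db[name].sample(frac=1, random_state=3).reset_index(drop=True)
            )
        assert validate(shuffled) == validate(db)

    def test_validate_is_pure(self):
        db = _base_db()
        db.append("clinical_codes", [_code_row(context_id=999)])
        before = {n: db[n].copy() for n in db.table_names()}
        validate(db)
        validate(db)
        assert all(db[n].equals(before[n]) for n in before)


class TestCsvRoundTrip:
    def test_empty_round_trip(self, tmp_path):
        db = create_database()
        manifest = write_csv(db, tmp_path)
        assert manifest["tables"] == {n: 0 for n in TABLE_NAMES}
        assert read_csv(tmp_path) == db

    def test_populated_round_trip(self, tmp_path, small_etl):
        _, db, _ = small_etl
        write_csv(db, tmp_path)
        assert read_csv(tmp_path) == db

    def test_missing_table_file(self, tmp_path):
        write_csv(create_database(), tmp_path)
        (tmp_path / "contexts.csv").unlink()
        with pytest.raises(GdmError, match="missing table: contexts"):
            read_csv(tmp_path)

    def test_unparseable_cell_reports_location(self, tmp_path):
        write_csv(create_database(), tmp_path)
        (tmp_path / "patients.csv").write_text(
            "id,birth_date,gender_concept_id,race_concept_id,"
            "ethnicity_concept_id,address_id,practitioner_id\n"
            "oops,1940-01-01,1,1,1,,\n"
        )
        with pytest.raises(GdmError, match=r"patients\.csv, line 2, column id"):
            read_csv(tmp_path)


class TestDdl:
    def test_emits_19_create_statements(self):
        ddl = emit_ddl("generic")
        assert ddl.count("CREATE TABLE") == 19

    def test_parses_in_embedded_engine(self):
        con = sqlite3.connect(":memory:")
        con.executescript(emit_ddl("generic"))
        names = {r[0] for r in con.execute(
            "select name from sqlite_master where type='table'")}
        assert names == set(TABLE_NAMES)

    def test_foreign_keys_match_validation_rules(self):
        ddl = emit_ddl("generic")
        emitted = set()
        for block in ddl.split("CREATE TABLE ")[1:]:
            table = block.split(" ", 1)[0]
            for col, ref_t, ref_c in re.findall(
                r"FOREIGN KEY \((\w+)\) REFERENCES (\w+) \((\w+)\)", block
            ):
                emitted.add((table, col, ref_t, ref_c))
        enforced = {
            (fk.table, fk.column, fk.ref_table, fk.ref_column)
            for fk in FOREIGN_KEYS
        }
        assert emitted == enforced

    def test_unknown_dialect(self):
        with pytest.raises(GdmError):
            emit_ddl("oracle")
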