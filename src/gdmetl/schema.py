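"""The 19-table GDM schema: table definitions, validation, CSV I/O, DDL.

Tables are held as :class:`pandas.DataFrame` objects with nullable dtypes
(``Int64`` for identifiers and integers, ``Float64`` for monetary and
numeric values, ``string`` for text).  Dates are carried as ISO-8601
``YYYY-MM-DD`` strings: the representation round-trips through CSV exactly
and compares in chronological order lexicographically.

Conventions
-----------
* identifiers are 64-bit integers, assigned sequentially from 1 within each
  table during ETL;
* CSV files are RFC 4180, UTF-8, with a header row; the empty string is the
  null value;
* date intervals are closed ``[start_date, end_date]``; a single-day event
  has ``start_date == end_date``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

SCHEMA_VERSION = "gdm-1.0"

# column kinds -> pandas nullable dtype
_KIND_DTYPE = {
    "id": "Int64",
    "int": "Int64",
    "num": "Float64",
    "money": "Float64",
    "date": "string",
    "text": "string",
}

_KIND_SQL = {
    "id": "BIGINT",
    "int": "BIGINT",
    "num": "DOUBLE PRECISION",
    "money": "DOUBLE PRECISION",
    "date": "DATE",
    "text": "VARCHAR",
}


@dataclass(frozen=True)
class Column:
    name: str
    kind: str  # one of _KIND_DTYPE keys
    nullable: bool = False

    @property
    def dtype(self) -> str:
        return _KIND_DTYPE[self.kind]


@dataclass(frozen=True)
class ForeignKey:
    """A foreign-key rule: ``table.column`` references ``ref_table.ref_column``."""

    table: str
    column: str
    ref_table: str
    ref_column: str
    rule: str  # violation rule name emitted when the key dangles


@dataclass(frozen=True)
class TableSchema:
    name: str
    columns: tuple[Column, ...]
    primary_key: tuple[str, ...]

    def column(self, name: str) -> Column:
        for c in self.columns:
            if c.name == name:
                return c
        raise KeyError(name)

    @property
    def column_names(self) -> list[str]:
        return [c.name for c in self.columns]

    def empty_frame(self) -> pd.DataFrame:
        return pd.DataFrame({c.name: pd.Series([], dtype=c.dtype) for c in self.columns})


def _t(name: str, pk: Sequence[str], *cols: tuple) -> TableSchema:
    return TableSchema(name, tuple(Column(*c) for c in cols), tuple(pk))


#: The 19 GDM tables, in canonical order.
SCHEMAS: dict[str, TableSchema] = {
    s.name: s
    for s in [
        _t(
            "patients",
            ["id"],
            ("id", "id"),
            ("birth_date", "date"),
            ("gender_concept_id", "id"),
            ("race_concept_id", "id"),
            ("ethnicity_concept_id", "id"),
            ("address_id", "id", True),
            ("practitioner_id", "id", True),
        ),
        _t(
            "patient_details",
            ["id"],
            ("id", "id"),
            ("patient_id", "id"),
            ("start_date", "date", True),
            ("end_date", "date", True),
            ("detail_concept_id", "id"),
            ("value_as_text", "text", True),
        ),
        _t(
            "information_periods",
            ["id"],
            ("id", "id"),
            ("patient_id", "id"),
            ("start_date", "date"),
            ("end_date", "date"),
            ("information_type_concept_id", "id"),
        ),
        _t(
            "deaths",
            ["id"],
            ("id", "id"),
            ("patient_id", "id"),
            ("date", "date"),
            ("cause_concept_id", "id", True),
            ("cause_type_concept_id", "id", True),
        ),
        _t(
            "collections",
            ["id"],
            ("id", "id"),
            ("patient_id", "id"),
            ("start_date", "date"),
            ("end_date", "date"),
            ("collection_type_concept_id", "id"),
        ),
        _t(
            "contexts",
            ["id"],
            ("id", "id"),
            ("collection_id", "id"),
            ("patient_id", "id"),
            ("start_date", "date"),
            ("end_date", "date"),
            ("record_type_concept_id", "id"),
            ("source_file", "text"),
            ("pos_concept_id", "id", True),
            ("care_site_type_concept_id", "id", True),
            ("facility_id", "id", True),
        ),
        _t(
            "clinical_codes",
            ["id"],
            ("id", "id"),
            ("patient_id", "id"),
            ("context_id", "id"),
            ("start_date", "date"),
            ("end_date", "date"),
            ("clinical_code_concept_id", "id"),
            ("clinical_code_source_vocabulary", "text"),
            ("provenance_concept_id", "id"),
            ("seq_num", "int"),
            ("drug_exposure_detail_id", "id", True),
            ("measurement_detail_id", "id", True),
        ),
        _t(
            "admissions_details",
            ["id"],
            ("id", "id"),
            ("collection_id", "id"),
            ("admission_date", "date"),
            ("discharge_date", "date"),
            ("admit_source_concept_id", "id", True),
            ("discharge_status_concept_id", "id", True),
        ),
        _t(
            "drug_exposure_details",
            ["id"],
            ("id", "id"),
            ("days_supply", "int", True),
            ("quantity", "num", True),
            ("refills", "int", True),
            ("dose_form_concept_id", "id", True),
        ),
        _t(
            "measurement_details",
            ["id"],
            ("id", "id"),
            ("value_as_number", "num", True),
            ("value_as_concept_id", "id", True),
            ("unit_concept_id", "id", True),
            ("normal_range_low", "num", True),
            ("normal_range_high", "num", True),
        ),
        _t(
            "payer_reimbursements",
            ["id"],
            ("id", "id"),
            ("context_id", "id"),
            ("clinical_code_id", "id", True),
            ("paid_amount", "money"),
            ("allowed_amount", "money", True),
            ("patient_coinsurance", "money", True),
            ("patient_deductible", "money", True),
        ),
        _t(
            "costs",
            ["id"],
            ("id", "id"),
            ("context_id", "id"),
            ("clinical_code_id", "id", True),
            ("value", "money"),
            ("value_type_concept_id", "id"),
        ),
        _t(
            "facilities",
            ["id"],
            ("id", "id"),
            ("name", "text", True),
            ("facility_type_concept_id", "id", True),
            ("address_id", "id", True),
        ),
        _t(
            "addresses",
            ["id"],
            ("id", "id"),
            ("line1", "text", True),
            ("city", "text", True),
            ("state", "text", True),
            ("zip", "text", True),
        ),
        _t(
            "practitioners",
            ["id"],
            ("id", "id"),
            ("name", "text", True),
            ("specialty_concept_id", "id", True),
            ("address_id", "id", True),
        ),
        _t(
            "contexts_practitioners",
            ["context_id", "practitioner_id", "role_type_concept_id"],
            ("context_id", "id"),
            ("practitioner_id", "id"),
            ("role_type_concept_id", "id", True),
        ),
        _t(
            "concepts",
            ["id"],
            ("id", "id"),
            ("vocabulary_id", "text"),
            ("concept_code", "text"),
            ("concept_text", "text"),
        ),
        _t(
            "vocabularies",
            ["id"],
            ("id", "text"),
            ("description", "text", True),
            ("domain", "text", True),
        ),
        _t(
            "mappings",
            ["concept_id_1", "relationship_id", "concept_id_2"],
            ("concept_id_1", "id"),
            ("relationship_id", "text"),
            ("concept_id_2", "id"),
        ),
    ]
}

TABLE_NAMES: tuple[str, ...] = tuple(sorted(SCHEMAS))
assert len(TABLE_NAMES) == 19

#: Every foreign-key rule enforced by :func:`validate` and emitted by
#: :func:`emit_ddl`.  Concept-valued columns all reference ``concepts.id``.
FOREIGN_KEYS: tuple[ForeignKey, ...] = tuple(
    ForeignKey(*fk)
    for fk in [
        ("patients", "gender_concept_id", "concepts", "id", "dangling_concept"),
        ("patients", "race_concept_id", "concepts", "id", "dangling_concept"),
        ("patients", "ethnicity_concept_id", "concepts", "id", "dangling_concept"),
        ("patients", "address_id", "addresses", "id", "dangling_address"),
        ("patients", "practitioner_id", "practitioners", "id", "dangling_practitioner"),
        ("patient_details", "patient_id", "patients", "id", "dangling_patient"),
        ("patient_details", "detail_concept_id", "concepts", "id", "dangling_concept"),
        ("information_periods", "patient_id", "patients", "id", "dangling_patient"),
        ("information_periods", "information_type_concept_id", "concepts", "id", "dangling_concept"),
        ("deaths", "patient_id", "patients", "id", "dangling_patient"),
        ("deaths", "cause_concept_id", "concepts", "id", "dangling_concept"),
        ("deaths", "cause_type_concept_id", "concepts", "id", "dangling_concept"),
        ("collections", "patient_id", "patients", "id", "dangling_patient"),
        ("collections", "collection_type_concept_id", "concepts", "id", "dangling_concept"),
        ("contexts", "collection_id", "collections", "id", "dangling_collection"),
        ("contexts", "patient_id", "patients", "id", "dangling_patient"),
        ("contexts", "record_type_concept_id", "concepts", "id", "dangling_concept"),
        ("contexts", "pos_concept_id", "concepts", "id", "dangling_concept"),
        ("contexts", "care_site_type_concept_id", "concepts", "id", "dangling_concept"),
        ("contexts", "facility_id", "facilities", "id", "dangling_facility"),
        ("clinical_codes", "patient_id", "patients", "id", "dangling_patient"),
        ("clinical_codes", "context_id", "contexts", "id", "dangling_context"),
        ("clinical_codes", "clinical_code_concept_id", "concepts", "id", "dangling_concept"),
        ("clinical_codes", "provenance_concept_id", "concepts", "id", "dangling_concept"),
        ("clinical_codes", "drug_exposure_detail_id", "drug_exposure_details", "id", "dangling_drug_exposure_detail"),
        ("clinical_codes", "measurement_detail_id", "measurement_details", "id", "dangling_measurement_detail"),
        ("admissions_details", "collection_id", "collections", "id", "dangling_collection"),
        ("admissions_details", "admit_source_concept_id", "concepts", "id", "dangling_concept"),
        ("admissions_details", "discharge_status_concept_id", "concepts", "id", "dangling_concept"),
        ("drug_exposure_details", "dose_form_concept_id", "concepts", "id", "dangling_concept"),
        ("measurement_details", "value_as_concept_id", "concepts", "id", "dangling_concept"),
        ("measurement_details", "unit_concept_id", "concepts", "id", "dangling_concept"),
        ("payer_reimbursements", "context_id", "contexts", "id", "dangling_context"),
        ("payer_reimbursements", "clinical_code_id", "clinical_codes", "id", "dangling_clinical_code"),
        ("costs", "context_id", "contexts", "id", "dangling_context"),
        ("costs", "clinical_code_id", "clinical_codes", "id", "dangling_clinical_code"),
        ("costs", "value_type_concept_id", "concepts", "id", "dangling_concept"),
        ("facilities", "facility_type_concept_id", "concepts", "id", "dangling_concept"),
        ("facilities", "address_id", "addresses", "id", "dangling_address"),
        ("practitioners", "specialty_concept_id", "concepts", "id", "dangling_concept"),
        ("practitioners", "address_id", "addresses", "id", "dangling_address"),
        ("contexts_practitioners", "context_id", "contexts", "id", "dangling_context"),
        ("contexts_practitioners", "practitioner_id", "practitioners", "id", "dangling_practitioner"),
        ("contexts_practitioners", "role_type_concept_id", "concepts", "id", "dangling_concept"),
        ("concepts", "vocabulary_id", "vocabularies", "id", "dangling_vocabulary"),
        ("mappings", "concept_id_1", "concepts", "id", "dangling_concept"),
        ("mappings", "concept_id_2", "concepts", "id", "dangling_concept"),
    ]
)

# (table, start column, end column) pairs with the closed-interval ordering rule
_DATE_ORDER: tuple[tuple[str, str, str], ...] = (
    ("information_periods", "start_date", "end_date"),
    ("collections", "start_date", "end_date"),
    ("contexts", "start_date", "end_date"),
    ("clinical_codes", "start_date", "end_date"),
    ("admissions_details", "admission_date", "discharge_date"),
)


class GdmError(Exception):
    """Structural error in a GDM database or its serialized form."""


@dataclass(frozen=True, order=True)
class Violation:
    """One referential-integrity or invariant violation found by :func:`validate`."""

    table: str
    row_id: int
    rule: str
    message: str


class GdmDatabase:
    """The full 19-table bundle.

    ``tables`` maps each canonical table name to a DataFrame whose columns
    and dtypes follow :data:`SCHEMAS`.
    """

    def __init__(self, tables: Mapping[str, pd.DataFrame] | None = None):
        self.tables: dict[str, pd.DataFrame] = {}
        for name in TABLE_NAMES:
            if tables is not None and name in tables:
                self.tables[name] = coerce_frame(name, tables[name])
            else:
                self.tables[name] = SCHEMAS[name].empty_frame()
        if tables is not None:
            extra = set(tables) - set(TABLE_NAMES)
            if extra:
                raise GdmError(f"unknown tables: {sorted(extra)}")

    def __getitem__(self, name: str) -> pd.DataFrame:
        return self.tables[name]

    def __setitem__(self, name: str, frame: pd.DataFrame) -> None:
        if name not in SCHEMAS:
            raise GdmError(f"unknown table: {name}")
        self.tables[name] = coerce_frame(name, frame)

    def table_names(self) -> list[str]:
        """The fixed, sorted list of the 19 table names."""
        return list(TABLE_NAMES)

    def row_counts(self) -> dict[str, int]:
        return {name: len(frame) for name, frame in self.tables.items()}

    def append(self, name: str, rows: Iterable[Mapping | object]) -> None:
        """Append records (mappings or dataclass instances) to a table."""
        rows = [
            dataclasses.asdict(r) if dataclasses.is_dataclass(r) else dict(r)
            for r in rows
        ]
        if not rows:
            return
        frame = pd.DataFrame(rows)
        frame = coerce_frame(name, frame)
        base = self.tables[name]
        self.tables[name] = frame if base.empty else pd.concat(
            [base, frame], ignore_index=True
        )

    def canonical(self) -> "GdmDatabase":
        """A copy with every table sorted by primary key, index reset."""
        out = GdmDatabase()
        for name, frame in self.tables.items():
            pk = list(SCHEMAS[name].primary_key)
            out.tables[name] = frame.sort_values(pk, kind="mergesort").reset_index(
                drop=True
            )
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GdmDatabase):
            return NotImplemented
        a, b = self.canonical(), other.canonical()
        return all(a.tables[n].equals(b.tables[n]) for n in TABLE_NAMES)

    def __repr__(self) -> str:
        n = sum(self.row_counts().values())
        return f"<GdmDatabase: {len(TABLE_NAMES)} tables, {n} rows>"


def create_database() -> GdmDatabase:
    """Return an empty database with all 19 tables present."""
    return GdmDatabase()


def coerce_frame(name: str, frame: pd.DataFrame) -> pd.DataFrame:
    """Cast a DataFrame to the declared schema of table ``name``.

    Missing nullable columns are added as null; unknown or missing required
    columns raise :class:`GdmError`.
    """
    if name not in SCHEMAS:
        raise GdmError(f"unknown table: {name}")
    schema = SCHEMAS[name]
    frame = frame.copy()
    extra = set(frame.columns) - set(schema.column_names)
    if extra:
        raise GdmError(f"table {name}: unknown columns {sorted(extra)}")
    out = {}
    for col in schema.columns:
        if col.name not in frame.columns:
            if not col.nullable:
                raise GdmError(f"table {name}: missing column {col.name}")
            series = pd.Series([pd.NA] * len(frame), dtype=col.dtype)
        else:
            series = frame[col.name]
            if series.dtype == object or series.dtype == "string":
                # empty string means null for non-text kinds
                series = series.mask(series.isna() | (series == ""), pd.NA)
            try:
                if col.kind in ("id", "int") and series.dtype in (object, "string"):
                    series = series.astype("Float64").astype(col.dtype)
                else:
                    series = series.astype(col.dtype)
            except (ValueError, TypeError) as exc:
                raise GdmError(
                    f"table {name}, column {col.name}: cannot cast to "
                    f"{col.dtype}: {exc}"
                ) from exc
        out[col.name] = series.reset_index(drop=True)
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# validation


def _row_ids(name: str, frame: pd.DataFrame, mask: pd.Series) -> list[int]:
    schema = SCHEMAS[name]
    if "id" in schema.column_names:
        return [int(v) for v in frame.loc[mask, "id"]]
    return [int(i) for i in frame.index[mask]]


def validate(db: GdmDatabase) -> list[Violation]:
    """Check every referential-integrity and invariant rule of the model.

    Returns a deterministic list ordered by ``(table, row_id, rule)``;
    empty iff the database is consistent.  Pure: never mutates ``db``, and
    the result is invariant under row permutation of the input tables.
    """
    if set(db.tables) != set(TABLE_NAMES):
        raise GdmError("database does not have the 19-table shape")
    out: list[Violation] = []

    # primary-key uniqueness
    for name in TABLE_NAMES:
        frame = db[name]
        pk = list(SCHEMAS[name].primary_key)
        dup = frame.duplicated(subset=pk, keep=False)
        if name == "contexts_practitioners":
            rule = "duplicate_link"
        elif name == "mappings":
            rule = "duplicate_mapping"
        else:
            rule = "duplicate_id"
        for rid in _row_ids(name, frame, dup):
            out.append(Violation(name, rid, rule, f"duplicate key {pk} in {name}"))

    # foreign keys
    for fk in FOREIGN_KEYS:
        frame = db[fk.table]
        if frame.empty:
            continue
        ref = db[fk.ref_table][fk.ref_column]
        col = frame[fk.column]
        bad = col.notna() & ~col.isin(set(ref.dropna()))
        for rid in _row_ids(fk.table, frame, bad):
            out.append(
                Violation(
                    fk.table,
                    rid,
                    fk.rule,
                    f"{fk.table}.{fk.column} does not resolve in "
                    f"{fk.ref_table}.{fk.ref_column}",
                )
            )

    # closed-interval date ordering
    for name, lo, hi in _DATE_ORDER:
        frame = db[name]
        if frame.empty:
            continue
        bad = frame[lo].notna() & frame[hi].notna() & (frame[lo] > frame[hi])
        for rid in _row_ids(name, frame, bad):
            out.append(Violation(name, rid, "date_order", f"{lo} after {hi}"))

    # patient consistency along the hierarchy
    ctx = db["contexts"]
    if not ctx.empty:
        coll_pat = db["collections"].set_index("id")["patient_id"]
        parent = ctx["collection_id"].map(coll_pat)
        bad = parent.notna() & (parent != ctx["patient_id"])
        for rid in _row_ids("contexts", ctx, bad):
            out.append(
                Violation(
                    "contexts", rid, "patient_mismatch",
                    "context patient differs from its collection's patient",
                )
            )
    cc = db["clinical_codes"]
    if not cc.empty:
        ctx_pat = ctx.set_index("id")["patient_id"]
        parent = cc["context_id"].map(ctx_pat)
        bad = parent.notna() & (parent != cc["patient_id"])
        for rid in _row_ids("clinical_codes", cc, bad):
            out.append(
                Violation(
                    "clinical_codes", rid, "patient_mismatch",
                    "clinical code patient differs from its context's patient",
                )
            )

    # seq_num unique within (context, provenance)
    if not cc.empty:
        dup = cc.duplicated(
            subset=["context_id", "provenance_concept_id", "seq_num"], keep=False
        )
        for rid in _row_ids("clinical_codes", cc, dup):
            out.append(
                Violation(
                    "clinical_codes", rid, "duplicate_seq_num",
                    "seq_num repeats within (context, provenance)",
                )
            )

    # information periods: no duplicate (patient, type, start, end)
    ip = db["information_periods"]
    if not ip.empty:
        dup = ip.duplicated(
            subset=["patient_id", "information_type_concept_id", "start_date", "end_date"],
            keep=False,
        )
        for rid in _row_ids("information_periods", ip, dup):
            out.append(
                Violation(
                    "information_periods", rid, "duplicate_information_period",
                    "repeated (patient, information type, date range)",
                )
            )

    # at most one death record per patient
    deaths = db["deaths"]
    if not deaths.empty:
        dup = deaths.duplicated(subset=["patient_id"], keep=False)
        for rid in _row_ids("deaths", deaths, dup):
            out.append(
                Violation("deaths", rid, "multiple_death_records",
                          "more than one death record for patient")
            )

    # one admission per collection
    adm = db["admissions_details"]
    if not adm.empty:
        dup = adm.duplicated(subset=["collection_id"], keep=False)
        for rid in _row_ids("admissions_details", adm, dup):
            out.append(
                Violation("admissions_details", rid, "duplicate_admission",
                          "collection has more than one admission row")
            )

    # measurement details must carry a value
    md = db["measurement_details"]
    if not md.empty:
        bad = md["value_as_number"].isna() & md["value_as_concept_id"].isna()
        for rid in _row_ids("measurement_details", md, bad):
            out.append(
                Violation("measurement_details", rid, "measurement_empty",
                          "neither numeric nor coded value present")
            )

    # concepts: (vocabulary, code) unique
    con = db["concepts"]
    if not con.empty:
        dup = con.duplicated(subset=["vocabulary_id", "concept_code"], keep=False)
        for rid in _row_ids("concepts", con, dup):
            out.append(
                Violation("concepts", rid, "duplicate_concept_code",
                          "repeated (vocabulary_id, concept_code)")
            )

    # cost rows naming a clinical code must stay within their context
    cc_ctx = cc.set_index("id")["context_id"] if not cc.empty else pd.Series(dtype="Int64")
    for name in ("payer_reimbursements", "costs"):
        frame = db[name]
        if frame.empty:
            continue
        code_ctx = frame["clinical_code_id"].map(cc_ctx)
        bad = (
            frame["clinical_code_id"].notna()
            & code_ctx.notna()
            & (code_ctx != frame["context_id"])
        )
        for rid in _row_ids(name, frame, bad):
            out.append(
                Violation(name, rid, "code_context_mismatch",
                          "clinical_code_id belongs to a different context")
            )

    return sorted(out)


# ---------------------------------------------------------------------------
# CSV round-trip


def write_csv(db: GdmDatabase, directory: str | Path) -> dict:
    """Write one ``<table>.csv`` per table plus ``manifest.json``.

    Nulls are written as empty strings; returns the manifest dict.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name in TABLE_NAMES:
        frame = db[name].copy()
        # integers must not pick up a trailing ".0"
        for col in SCHEMAS[name].columns:
            if col.kind in ("id", "int"):
                frame[col.name] = frame[col.name].astype(object).map(
                    lambda v: "" if pd.isna(v) else str(int(v))
                )
        frame.to_csv(directory / f"{name}.csv", index=False, na_rep="")
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "tables": {name: int(len(db[name])) for name in TABLE_NAMES},
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def read_csv(directory: str | Path) -> GdmDatabase:
    """Read a database written by :func:`write_csv`.

    Raises :class:`GdmError` naming the table when a file is missing, or
    naming file, line and column when a cell cannot be parsed.
    """
    directory = Path(directory)
    tables = {}
    for name in TABLE_NAMES:
        path = directory / f"{name}.csv"
        if not path.exists():
            raise GdmError(f"missing table: {name}")
        raw = pd.read_csv(path, dtype=str, keep_default_na=False)
        raw = raw.mask(raw == "", pd.NA)
        try:
            tables[name] = coerce_frame(name, raw)
        except GdmError:
            _locate_bad_cell(name, path, raw)
            raise
    return GdmDatabase(tables)


def _locate_bad_cell(name: str, path: Path, raw: pd.DataFrame) -> None:
    """Re-raise a cast failure with file, line and column coordinates."""
    for col in SCHEMAS[name].columns:
        if col.name not in raw.columns or col.kind not in ("id", "int", "num", "money"):
            continue
        for i, value in raw[col.name].items():
            if pd.isna(value):
                continue
            try:
                float(value)
            except ValueError:
                raise GdmError(
                    f"unparseable cell in {path.name}, line {i + 2}, "
                    f"column {col.name}: {value!r}"
                ) from None


# ---------------------------------------------------------------------------
# DDL


def emit_ddl(dialect: str = "generic") -> str:
    """Emit one ``CREATE TABLE`` statement per GDM table.

    Primary and foreign keys match exactly the rules enforced by
    :func:`validate` (both derive from :data:`FOREIGN_KEYS`).
    """
    if dialect != "generic":
        raise GdmError(f"unknown dialect: {dialect}")
    statements = []
    for name in TABLE_NAMES:
        schema = SCHEMAS[name]
        lines = []
        for col in schema.columns:
            null = "" if col.nullable or col.name not in schema.primary_key else " NOT NULL"
            lines.append(f"    {col.name} {_KIND_SQL[col.kind]}{null}")
        lines.append(f"    PRIMARY KEY ({', '.join(schema.primary_key)})")
        for fk in FOREIGN_KEYS:
            if fk.table == name:
                lines.append(
                    f"    FOREIGN KEY ({fk.column}) "
                    f"REFERENCES {fk.ref_table} ({fk.ref_column})"
                )
        statements.append(
            f"CREATE TABLE {name} (\n" + ",\n".join(lines) + "\n);"
        )
    return "\n\n".join(statements) + "\n"
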