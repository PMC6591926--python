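"""GDM → Sentinel-style export.

Demographic, Enrollment and Death are renames plus vocabulary mapping
(the ``is_a`` edges from the source demographic codings onto the Sentinel
codings).  Diagnosis, Procedure and Dispensing are produced by splitting
the Clinical Codes table by source vocabulary.  The Encounter table is
built in two steps: a "pre-Encounter" table with one row per Context and
the encounter identifier set to the Context id, then a provenance-based
roll-up that groups pre-encounters into visits under a new sequential
identifier, after which Diagnosis and Procedure are relabeled with the
new ids.

This is a structural export, not a certified Sentinel CDM implementation:
column names follow Sentinel conventions but full column parity with the
Sentinel specification is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from gdmetl import etl
from gdmetl.schema import GdmDatabase
from gdmetl.vocabulary import ConceptStore

#: Default routing of clinical-code vocabularies to Sentinel tables.
DEFAULT_ROUTING: dict[str, str] = {
    etl.VOCAB_ICD9_DX: "diagnosis",
    etl.VOCAB_ICD9_PROC: "procedure",
    etl.VOCAB_HCPCS: "procedure",
    etl.VOCAB_NDC: "dispensing",
}

#: Sentinel code-type flags by source vocabulary.
CODETYPES = {etl.VOCAB_ICD9_DX: "09", etl.VOCAB_ICD9_PROC: "09",
             etl.VOCAB_HCPCS: "C4"}

#: Default encounter type by context record type.  CMS place of service
#: 23 (emergency room) overrides a carrier line to ED.
DEFAULT_ENCOUNTER_TYPES: dict[str, str] = {
    "inpatient_claim": "IP",
    "carrier_claim": "AV",
    "carrier_line": "AV",
}
ED_POS_CODE = "23"
FALLBACK_ENCOUNTER_TYPE = "OA"

UNKNOWN_SEX = "U"
UNKNOWN_RACE = "0"
UNKNOWN_HISPANIC = "U"


class SentinelError(Exception):
    pass


@dataclass
class SentinelTables:
    demographic: pd.DataFrame
    enrollment: pd.DataFrame
    death: pd.DataFrame
    diagnosis: pd.DataFrame
    procedure: pd.DataFrame
    dispensing: pd.DataFrame
    encounter: pd.DataFrame
    log: dict = field(default_factory=dict)


def _concept_codes(db: GdmDatabase) -> pd.Series:
    return db["concepts"].set_index("id")["concept_code"]


def _map_to_code(store: ConceptStore, source_id: int, target_vocabulary: str,
                 unknown: str) -> tuple[str, bool]:
    targets = sorted(store.map_concepts(source_id, "is_a", target_vocabulary))
    if not targets:
        return unknown, False
    return store.concepts[targets[0]].concept_code, True


def export_demographics(db: GdmDatabase, store: ConceptStore) -> pd.DataFrame:
    """Map each patient's demographic concepts onto the Sentinel codings.

    Unmapped source concepts get the designated unknown value.  If the
    store carries no mappings into the Sentinel vocabularies at all while
    patients need them, the export refuses and lists the unmapped
    concepts.
    """
    pats = db["patients"]
    rows, unmapped = [], set()
    for _, p in pats.iterrows():
        sex, ok_s = _map_to_code(store, int(p["gender_concept_id"]),
                                 "sentinel_sex", UNKNOWN_SEX)
        race, ok_r = _map_to_code(store, int(p["race_concept_id"]),
                                  "sentinel_race", UNKNOWN_RACE)
        hisp, ok_h = _map_to_code(store, int(p["race_concept_id"]),
                                  "sentinel_hispanic", UNKNOWN_HISPANIC)
        for ok, cid in ((ok_s, p["gender_concept_id"]),
                        (ok_r, p["race_concept_id"]),
                        (ok_h, p["race_concept_id"])):
            if not ok:
                unmapped.add(int(cid))
        rows.append(dict(patient_id=int(p["id"]), birth_date=p["birth_date"],
                         sex=sex, hispanic=hisp, race=race))
    has_sentinel_mappings = any(
        store.concepts[m.concept_id_2].vocabulary_id.startswith("sentinel_")
        for m in store.mappings
    )
    if rows and unmapped and not has_sentinel_mappings:
        raise SentinelError(
            f"no Sentinel mapping table loaded; unmapped concepts: "
            f"{sorted(unmapped)}"
        )
    return pd.DataFrame(
        rows, columns=["patient_id", "birth_date", "sex", "hispanic", "race"]
    )


def export_enrollment(db: GdmDatabase) -> pd.DataFrame:
    codes = _concept_codes(db)
    ip = db["information_periods"]
    cov = {"part_a": "A", "part_b": "B"}
    rows = []
    for _, r in ip.iterrows():
        code = codes.get(r["information_type_concept_id"])
        if code in cov:
            rows.append(dict(patient_id=int(r["patient_id"]),
                             enr_start=r["start_date"], enr_end=r["end_date"],
                             coverage=cov[code]))
    return pd.DataFrame(
        rows, columns=["patient_id", "enr_start", "enr_end", "coverage"]
    )


def export_death(db: GdmDatabase) -> pd.DataFrame:
    d = db["deaths"]
    return pd.DataFrame(
        {"patient_id": d["patient_id"].astype("Int64"),
         "death_date": d["date"]},
        columns=["patient_id", "death_date"],
    )


def split_clinical_codes(
    db: GdmDatabase, routing: dict[str, str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, dict]:
    """Split Clinical Codes by source vocabulary into diagnosis /
    procedure / dispensing rows.

    Every routed code lands in exactly one table; unrouted vocabularies
    are counted in the returned log, never silently dropped.  Encounter
    ids are the originating Context ids (pre-roll-up).
    """
    routing = DEFAULT_ROUTING if routing is None else routing
    cc = db["clinical_codes"]
    codes = _concept_codes(db)
    days = db["drug_exposure_details"].set_index("id")["days_supply"]
    dx_rows, px_rows, rx_rows = [], [], []
    unrouted: dict[str, int] = {}
    for _, r in cc.iterrows():
        vocab = r["clinical_code_source_vocabulary"]
        table = routing.get(vocab)
        code = codes.get(r["clinical_code_concept_id"])
        if table == "diagnosis":
            dx_rows.append(dict(
                patient_id=int(r["patient_id"]), adate=r["start_date"], dx=code,
                dx_codetype=CODETYPES.get(vocab, ""),
                encounter_id=int(r["context_id"])))
        elif table == "procedure":
            px_rows.append(dict(
                patient_id=int(r["patient_id"]), adate=r["start_date"], px=code,
                px_codetype=CODETYPES.get(vocab, ""),
                encounter_id=int(r["context_id"])))
        elif table == "dispensing":
            supply = None
            if pd.notna(r["drug_exposure_detail_id"]):
                supply = days.get(r["drug_exposure_detail_id"])
            rx_rows.append(dict(
                patient_id=int(r["patient_id"]), rxdate=r["start_date"], ndc=code,
                rxsup=None if pd.isna(supply) else int(supply)))
        else:
            unrouted[vocab] = unrouted.get(vocab, 0) + 1
    log = {"unrouted_by_vocabulary": unrouted,
           "unrouted_total": sum(unrouted.values()),
           "routed_total": len(dx_rows) + len(px_rows) + len(rx_rows)}
    return (
        pd.DataFrame(dx_rows, columns=["patient_id", "adate", "dx",
                                       "dx_codetype", "encounter_id"]),
        pd.DataFrame(px_rows, columns=["patient_id", "adate", "px",
                                       "px_codetype", "encounter_id"]),
        pd.DataFrame(rx_rows, columns=["patient_id", "rxdate", "ndc", "rxsup"]),
        log,
    )


def build_pre_encounter(
    db: GdmDatabase, type_map: dict[str, str] | None = None
) -> tuple[pd.DataFrame, dict]:
    """One pre-encounter row per Context, id equal to the Context id.

    The encounter type derives from the context's provenance: its record
    type, overridden to ED when the place of service denotes an emergency
    room.  Contexts of unmapped record types fall back to OA and are
    counted in the log.
    """
    type_map = DEFAULT_ENCOUNTER_TYPES if type_map is None else type_map
    codes = _concept_codes(db)
    ctx = db["contexts"]
    rows = []
    fallback = 0
    for _, r in ctx.iterrows():
        rt = codes.get(r["record_type_concept_id"])
        etype = type_map.get(rt)
        if etype is None:
            etype = FALLBACK_ENCOUNTER_TYPE
            fallback += 1
        elif (rt == "carrier_line" and pd.notna(r["pos_concept_id"])
              and codes.get(r["pos_concept_id"]) == ED_POS_CODE):
            etype = "ED"
        rows.append(dict(
            encounter_id=int(r["id"]), patient_id=int(r["patient_id"]),
            adate=r["start_date"], ddate=r["end_date"], enctype=etype,
            facility_id=None if pd.isna(r["facility_id"]) else int(r["facility_id"]),
        ))
    frame = pd.DataFrame(
        rows, columns=["encounter_id", "patient_id", "adate", "ddate",
                       "enctype", "facility_id"],
    )
    return frame, {"fallback_type_count": fallback}


def roll_up_encounters(
    pre: pd.DataFrame,
) -> tuple[pd.DataFrame, dict[int, int]]:
    """Group pre-encounters into visits and assign new sequential ids.

    The roll-up key is (patient, start date, encounter type, facility);
    each group becomes one encounter with start = min start and
    end = max end.  Returns the encounter table and the Context-id →
    encounter-id remap.
    """
    if pre.empty:
        empty = pd.DataFrame(columns=["encounter_id", "patient_id", "adate",
                                      "ddate", "enctype", "facility_id"])
        return empty, {}
    work = pre.copy()
    work["_fac"] = work["facility_id"].map(lambda v: -1 if v is None or pd.isna(v) else int(v))
    keys = sorted(
        set(zip(work["patient_id"], work["adate"], work["enctype"], work["_fac"]))
    )
    new_ids = {key: i + 1 for i, key in enumerate(keys)}
    remap: dict[int, int] = {}
    groups: dict[int, dict] = {}
    for _, r in work.iterrows():
        key = (r["patient_id"], r["adate"], r["enctype"], r["_fac"])
        eid = new_ids[key]
        remap[int(r["encounter_id"])] = eid
        g = groups.setdefault(eid, dict(
            encounter_id=eid, patient_id=int(r["patient_id"]), adate=r["adate"],
            ddate=r["ddate"], enctype=r["enctype"],
            facility_id=None if r["_fac"] == -1 else r["_fac"]))
        g["adate"] = min(g["adate"], r["adate"])
        g["ddate"] = max(g["ddate"], r["ddate"])
    frame = pd.DataFrame(
        [groups[e] for e in sorted(groups)],
        columns=["encounter_id", "patient_id", "adate", "ddate", "enctype",
                 "facility_id"],
    )
    return frame, remap


def export_sentinel(
    db: GdmDatabase, store: ConceptStore,
    routing: dict[str, str] | None = None,
    type_map: dict[str, str] | None = None,
) -> SentinelTables:
    """Full GDM → Sentinel export with visit roll-up.

    Deterministic: the same database always yields the same grouping and
    the same new encounter ids.  No pre-encounter id survives into the
    final Diagnosis/Procedure tables.
    """
    diagnosis, procedure, dispensing, split_log = split_clinical_codes(db, routing)
    pre, pre_log = build_pre_encounter(db, type_map)
    encounter, remap = roll_up_encounters(pre)
    for frame in (diagnosis, procedure):
        if len(frame):
            frame["encounter_id"] = frame["encounter_id"].map(remap).astype("Int64")
    return SentinelTables(
        demographic=export_demographics(db, store),
        enrollment=export_enrollment(db),
        death=export_death(db),
        diagnosis=diagnosis,
        procedure=procedure,
        dispensing=dispensing,
        encounter=encounter,
        log={**split_log, **pre_log,
             "context_count": int(len(db["contexts"])),
             "encounter_count": int(len(encounter))},
    )


def write_sentinel_csv(tables: SentinelTables, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name in ("demographic", "enrollment", "death", "diagnosis",
                 "procedure", "dispensing", "encounter"):
        getattr(tables, name).to_csv(directory / f"{name}.csv", index=False,
                                     na_rep="")
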