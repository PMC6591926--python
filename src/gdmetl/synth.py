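"""Seeded generator of synthetic claims / EHR / registry source data.

Three source families are emulated, each structurally faithful to the
class of data it stands in for while using a documented simplified layout
(the contract is the header/line hierarchy and the coding slots, not
byte-compatibility with any vendor format):

* Medicare-style claims — a beneficiary summary, inpatient claims with
  header diagnoses and procedures, carrier (physician) claims with
  numbered lines carrying a line diagnosis, a HCPCS procedure, a place of
  service and a line payment, and prescription drug events;
* a UK primary-care EHR "Test" file — laboratory measurements keyed by a
  Read code plus a numeric entity type;
* a cancer-registry extract — one record per case with 31 coded
  variables, each variable its own vocabulary.

All generation is driven by ``numpy.random.default_rng(seed)``; the same
parameters always regenerate the identical dataset.  The generator draws
claim counts from Poisson distributions and dates uniformly in the study
window — it is test infrastructure, not an epidemiological simulator.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd


class SynthError(Exception):
    pass


# ---------------------------------------------------------------------------
# code pools (small fixed sets of real-looking codes, for readable tests)

ICD9_DX_POOL = [
    "250.00", "401.9", "272.4", "414.01", "428.0",
    "486", "599.0", "715.90", "780.79", "V58.69",
]
ICD9_PROC_POOL = ["81.54", "36.06", "45.23", "88.72", "99.04"]
HCPCS_POOL = ["99213", "99214", "93000", "80053", "71020", "36415"]
NDC_POOL = [
    "00093310905", "00781185901", "68180051202", "00071015523", "00378395101",
]
READ_CODE_POOL = ["44P..", "246..", "44U..", "423..", "44J3."]
ENTITY_TYPE_POOL = ["163", "131", "288", "214"]
UNIT_POOL = ["mmol/L", "mg/dL", "mmHg", "IU/L"]
POS_POOL = ["11", "22", "23", "21", "81"]  # CMS place of service; 23 = ER
DISCHARGE_STATUS_POOL = ["01", "02", "03", "20"]  # 20 = expired
SEX_POOL = ["1", "2"]
RACE_POOL = ["1", "2", "3", "5"]

#: The 31 registry variables, each with its code pool.  The ``grade``
#: variable uses the NAACCR tumor-grade codes 1..9.
SEER_VARIABLES: dict[str, list[str]] = {
    "histology_icdo3": ["8000", "8070", "8140", "8041", "9050"],
    "primary_site": ["C34.1", "C34.3", "C18.7", "C50.4", "C61.9"],
    "behavior": ["2", "3"],
    "grade": [str(i) for i in range(1, 10)],
    "laterality": ["0", "1", "2", "4"],
    "diagnostic_confirmation": ["1", "2", "4", "8"],
    "summary_stage": ["1", "2", "7"],
    "ajcc_stage": ["10", "32", "40", "70"],
    "tumor_size": ["005", "015", "040", "999"],
    "regional_nodes_positive": ["00", "02", "98"],
    "regional_nodes_examined": ["00", "06", "12"],
    "surgery_primary_site": ["00", "30", "50"],
    "radiation": ["0", "1", "5"],
    "radiation_sequence": ["0", "2", "3"],
    "chemotherapy": ["00", "01", "85"],
    "reporting_source": ["1", "2", "3"],
    "marital_status": ["1", "2", "3", "5"],
    "urban_rural": ["1", "2", "3"],
    "poverty_indicator": ["1", "2", "3"],
    "race_recode": ["1", "2", "3", "7"],
    "sex": ["1", "2"],
    "age_at_diagnosis": ["055", "064", "072", "081"],
    "year_of_diagnosis": ["2008", "2009", "2010"],
    "sequence_number": ["00", "01", "02"],
    "vital_status": ["1", "4"],
    "cause_of_death": ["00000", "22030", "50130"],
    "survival_months": ["0012", "0036", "0060"],
    "insurance": ["1", "2", "3"],
    "first_malignant_indicator": ["0", "1"],
    "histology_behavior": ["8000/3", "8070/3", "8140/3"],
    "microscopic_confirmation": ["1", "2"],
}

# documented, stable source file names (recorded as Contexts.source_file)
BENEFICIARY_FILE = "beneficiary_summary.csv"
INPATIENT_FILE = "inpatient_claims.csv"
CARRIER_FILE = "carrier_claims.csv"
CARRIER_LINE_FILE = "carrier_lines.csv"
DRUG_FILE = "drug_events.csv"
SEER_FILE = "seer_records.csv"
CPRD_FILE = "cprd_test.csv"


# ---------------------------------------------------------------------------
# record types


@dataclass(frozen=True)
class SourceBeneficiary:
    bene_id: int
    birth_date: str
    sex_code: str
    race_code: str
    death_date: str | None
    part_a_start: str
    part_a_end: str
    part_b_start: str
    part_b_end: str


@dataclass(frozen=True)
class SourceLine:
    line_num: int
    line_dx_code: str
    hcpcs_code: str
    place_of_service: str
    line_payment: float


@dataclass(frozen=True)
class SourceCarrierClaim:
    claim_id: int
    bene_id: int
    from_date: str
    thru_date: str
    header_dx_codes: tuple[str, ...]
    lines: tuple[SourceLine, ...]


@dataclass(frozen=True)
class SourceInpatientClaim:
    claim_id: int
    bene_id: int
    admit_date: str
    discharge_date: str
    header_dx_codes: tuple[str, ...]
    proc_codes: tuple[str, ...]
    discharge_status: str
    claim_payment: float


@dataclass(frozen=True)
class SourceDrugEvent:
    event_id: int
    bene_id: int
    service_date: str
    ndc_code: str
    days_supply: int
    quantity: float


@dataclass(frozen=True)
class SourceSeerRecord:
    case_id: int
    diagnosis_date: str
    variables: tuple[tuple[str, str], ...]  # ordered (variable, code)


@dataclass(frozen=True)
class SourceCprdTestRecord:
    patient_id: int
    event_date: str
    read_code: str
    entity_type: str
    value: float
    unit: str


@dataclass
class SynthParams:
    """Study conditions for the generator.

    ``mean_*`` are per-patient Poisson means for each claim type;
    ``seer_fraction`` is the share of patients carrying a registry record;
    ``death_fraction`` the share with a recorded death.
    """

    n_patients: int = 100
    seed: int = 0
    window_start: str = "2008-01-01"
    window_end: str = "2010-12-31"
    mean_inpatient: float = 0.5
    mean_carrier: float = 2.0
    mean_drug: float = 2.0
    mean_cprd: float = 1.0
    seer_fraction: float = 0.3
    death_fraction: float = 0.1
    code_pools: dict = field(
        default_factory=lambda: {
            "icd9_dx": list(ICD9_DX_POOL),
            "icd9_proc": list(ICD9_PROC_POOL),
            "hcpcs": list(HCPCS_POOL),
            "ndc": list(NDC_POOL),
            "read": list(READ_CODE_POOL),
            "cprd_entity_type": list(ENTITY_TYPE_POOL),
            "pos": list(POS_POOL),
            "discharge_status": list(DISCHARGE_STATUS_POOL),
        }
    )

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise SynthError("n_patients must be non-negative")
        for name, pool in self.code_pools.items():
            if not pool:
                raise SynthError(f"empty code pool: {name}")
        for name, pool in SEER_VARIABLES.items():
            if not pool:
                raise SynthError(f"empty code pool: seer:{name}")


@dataclass
class SourceDataset:
    beneficiaries: list[SourceBeneficiary] = field(default_factory=list)
    inpatient_claims: list[SourceInpatientClaim] = field(default_factory=list)
    carrier_claims: list[SourceCarrierClaim] = field(default_factory=list)
    drug_events: list[SourceDrugEvent] = field(default_factory=list)
    seer_records: list[SourceSeerRecord] = field(default_factory=list)
    cprd_records: list[SourceCprdTestRecord] = field(default_factory=list)


# ---------------------------------------------------------------------------
# generation


def _iso(d: dt.date) -> str:
    return d.isoformat()


def _rand_date(rng: np.random.Generator, lo: dt.date, hi: dt.date) -> dt.date:
    span = (hi - lo).days
    return lo + dt.timedelta(days=int(rng.integers(0, span + 1)))


def _choice(rng: np.random.Generator, pool: Sequence[str]) -> str:
    return str(pool[int(rng.integers(0, len(pool)))])


def generate(params: SynthParams) -> SourceDataset:
    """Generate a full synthetic source dataset under ``params``.

    Deterministic under the seed; every generated code comes from the
    declared pools, every date falls inside the study window, and every
    claim references an existing beneficiary.
    """
    rng = np.random.default_rng(params.seed)
    lo = dt.date.fromisoformat(params.window_start)
    hi = dt.date.fromisoformat(params.window_end)
    pools = params.code_pools
    ds = SourceDataset()

    claim_id = 5000000
    event_id = 7000000

    for i in range(params.n_patients):
        bene_id = 1001 + i
        birth_year = int(rng.integers(1920, 1949))
        birth = dt.date(birth_year, int(rng.integers(1, 13)), int(rng.integers(1, 29)))
        sex = _choice(rng, SEX_POOL)
        race = str(RACE_POOL[int(rng.choice(4, p=[0.55, 0.2, 0.15, 0.1]))])
        dead = rng.random() < params.death_fraction
        death = _rand_date(rng, max(lo, birth), hi) if dead else None
        last = death if death is not None else hi
        # enrollment spans: within the window, never before birth / after death
        a_start = _rand_date(rng, lo, min(dt.date(lo.year, 12, 31), last))
        b_start = _rand_date(rng, lo, min(dt.date(lo.year, 12, 31), last))
        ds.beneficiaries.append(
            SourceBeneficiary(
                bene_id=bene_id,
                birth_date=_iso(birth),
                sex_code=sex,
                race_code=race,
                death_date=None if death is None else _iso(death),
                part_a_start=_iso(a_start),
                part_a_end=_iso(last),
                part_b_start=_iso(b_start),
                part_b_end=_iso(last),
            )
        )

        for _ in range(int(rng.poisson(params.mean_inpatient))):
            admit = _rand_date(rng, lo, last)
            disc = min(admit + dt.timedelta(days=int(rng.integers(1, 15))), last)
            n_dx = int(rng.integers(1, 6))
            n_pr = int(rng.integers(0, 3))
            claim_id += 1
            ds.inpatient_claims.append(
                SourceInpatientClaim(
                    claim_id=claim_id,
                    bene_id=bene_id,
                    admit_date=_iso(admit),
                    discharge_date=_iso(disc),
                    header_dx_codes=tuple(
                        _choice(rng, pools["icd9_dx"]) for _ in range(n_dx)
                    ),
                    proc_codes=tuple(
                        _choice(rng, pools["icd9_proc"]) for _ in range(n_pr)
                    ),
                    discharge_status=_choice(rng, pools["discharge_status"]),
                    claim_payment=round(float(rng.uniform(1000, 30000)), 2),
                )
            )

        for _ in range(int(rng.poisson(params.mean_carrier))):
            start = _rand_date(rng, lo, last)
            end = min(start + dt.timedelta(days=int(rng.integers(0, 4))), last)
            n_dx = int(rng.integers(1, 5))
            n_lines = int(rng.integers(1, 4))
            claim_id += 1
            ds.carrier_claims.append(
                SourceCarrierClaim(
                    claim_id=claim_id,
                    bene_id=bene_id,
                    from_date=_iso(start),
                    thru_date=_iso(end),
                    header_dx_codes=tuple(
                        _choice(rng, pools["icd9_dx"]) for _ in range(n_dx)
                    ),
                    lines=tuple(
                        SourceLine(
                            line_num=j + 1,
                            line_dx_code=_choice(rng, pools["icd9_dx"]),
                            hcpcs_code=_choice(rng, pools["hcpcs"]),
                            place_of_service=_choice(rng, pools["pos"]),
                            line_payment=round(float(rng.uniform(20, 500)), 2),
                        )
                        for j in range(n_lines)
                    ),
                )
            )

        for _ in range(int(rng.poisson(params.mean_drug))):
            event_id += 1
            ds.drug_events.append(
                SourceDrugEvent(
                    event_id=event_id,
                    bene_id=bene_id,
                    service_date=_iso(_rand_date(rng, lo, last)),
                    ndc_code=_choice(rng, pools["ndc"]),
                    days_supply=int(rng.integers(7, 91)),
                    quantity=float(rng.integers(10, 121)),
                )
            )

        if rng.random() < params.seer_fraction:
            ds.seer_records.append(
                SourceSeerRecord(
                    case_id=bene_id,
                    diagnosis_date=_iso(_rand_date(rng, lo, last)),
                    variables=tuple(
                        (var, _choice(rng, pool))
                        for var, pool in SEER_VARIABLES.items()
                    ),
                )
            )

        for _ in range(int(rng.poisson(params.mean_cprd))):
            ds.cprd_records.append(
                SourceCprdTestRecord(
                    patient_id=bene_id,
                    event_date=_iso(_rand_date(rng, lo, last)),
                    read_code=_choice(rng, pools["read"]),
                    entity_type=_choice(rng, pools["cprd_entity_type"]),
                    value=round(float(rng.uniform(0.5, 200.0)), 1),
                    unit=_choice(rng, UNIT_POOL),
                )
            )

    return ds


def example_carrier_claim() -> SourceCarrierClaim:
    """A deterministic single carrier claim in the canonical worked shape.

    Two header diagnoses at claim level plus two numbered lines, each line
    carrying one line diagnosis, one HCPCS procedure and a line payment —
    the smallest claim exercising the full header/line hierarchy.
    """
    return SourceCarrierClaim(
        claim_id=900001,
        bene_id=42,
        from_date="2009-03-12",
        thru_date="2009-03-12",
        header_dx_codes=("401.9", "250.00"),
        lines=(
            SourceLine(1, "401.9", "99213", "11", 85.0),
            SourceLine(2, "272.4", "80053", "81", 42.5),
        ),
    )


# ---------------------------------------------------------------------------
# CSV round-trip (ordered code lists are pipe-joined in a single cell)


def _join(codes: Sequence[str]) -> str:
    return "|".join(codes)


def _split(cell: str) -> tuple[str, ...]:
    return tuple(cell.split("|")) if cell else ()


def write_source_csv(ds: SourceDataset, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    pd.DataFrame(
        [asdict(b) for b in ds.beneficiaries],
        columns=[f.name for f in SourceBeneficiary.__dataclass_fields__.values()],
    ).to_csv(directory / BENEFICIARY_FILE, index=False, na_rep="")

    rows = []
    for c in ds.inpatient_claims:
        d = asdict(c)
        d["header_dx_codes"] = _join(c.header_dx_codes)
        d["proc_codes"] = _join(c.proc_codes)
        rows.append(d)
    pd.DataFrame(
        rows,
        columns=[f.name for f in SourceInpatientClaim.__dataclass_fields__.values()],
    ).to_csv(directory / INPATIENT_FILE, index=False)

    heads, lines = [], []
    for c in ds.carrier_claims:
        heads.append(
            {
                "claim_id": c.claim_id,
                "bene_id": c.bene_id,
                "from_date": c.from_date,
                "thru_date": c.thru_date,
                "header_dx_codes": _join(c.header_dx_codes),
            }
        )
        for ln in c.lines:
            lines.append({"claim_id": c.claim_id, **asdict(ln)})
    pd.DataFrame(
        heads,
        columns=["claim_id", "bene_id", "from_date", "thru_date", "header_dx_codes"],
    ).to_csv(directory / CARRIER_FILE, index=False)
    pd.DataFrame(
        lines,
        columns=["claim_id", "line_num", "line_dx_code", "hcpcs_code",
                 "place_of_service", "line_payment"],
    ).to_csv(directory / CARRIER_LINE_FILE, index=False)

    pd.DataFrame(
        [asdict(e) for e in ds.drug_events],
        columns=[f.name for f in SourceDrugEvent.__dataclass_fields__.values()],
    ).to_csv(directory / DRUG_FILE, index=False)

    seer_rows = [
        {
            "case_id": r.case_id,
            "diagnosis_date": r.diagnosis_date,
            "variable": var,
            "value_code": code,
        }
        for r in ds.seer_records
        for var, code in r.variables
    ]
    pd.DataFrame(
        seer_rows, columns=["case_id", "diagnosis_date", "variable", "value_code"]
    ).to_csv(directory / SEER_FILE, index=False)

    pd.DataFrame(
        [asdict(r) for r in ds.cprd_records],
        columns=[f.name for f in SourceCprdTestRecord.__dataclass_fields__.values()],
    ).to_csv(directory / CPRD_FILE, index=False)


def read_source_csv(directory: str | Path) -> SourceDataset:
    directory = Path(directory)
    for fname in (BENEFICIARY_FILE, INPATIENT_FILE, CARRIER_FILE,
                  CARRIER_LINE_FILE, DRUG_FILE, SEER_FILE, CPRD_FILE):
        if not (directory / fname).exists():
            raise SynthError(f"missing source file: {fname}")

    def load(fname: str) -> pd.DataFrame:
        return pd.read_csv(directory / fname, dtype=str, keep_default_na=False)

    ds = SourceDataset()
    for _, r in load(BENEFICIARY_FILE).iterrows():
        ds.beneficiaries.append(
            SourceBeneficiary(
                bene_id=int(r["bene_id"]),
                birth_date=r["birth_date"],
                sex_code=r["sex_code"],
                race_code=r["race_code"],
                death_date=r["death_date"] or None,
                part_a_start=r["part_a_start"],
                part_a_end=r["part_a_end"],
                part_b_start=r["part_b_start"],
                part_b_end=r["part_b_end"],
            )
        )
    for _, r in load(INPATIENT_FILE).iterrows():
        ds.inpatient_claims.append(
            SourceInpatientClaim(
                claim_id=int(r["claim_id"]),
                bene_id=int(r["bene_id"]),
                admit_date=r["admit_date"],
                discharge_date=r["discharge_date"],
                header_dx_codes=_split(r["header_dx_codes"]),
                proc_codes=_split(r["proc_codes"]),
                discharge_status=r["discharge_status"],
                claim_payment=float(r["claim_payment"]),
            )
        )
    lines_by_claim: dict[int, list[SourceLine]] = {}
    for _, r in load(CARRIER_LINE_FILE).iterrows():
        lines_by_claim.setdefault(int(r["claim_id"]), []).append(
            SourceLine(
                line_num=int(r["line_num"]),
                line_dx_code=r["line_dx_code"],
                hcpcs_code=r["hcpcs_code"],
                place_of_service=r["place_of_service"],
                line_payment=float(r["line_payment"]),
            )
        )
    for _, r in load(CARRIER_FILE).iterrows():
        cid = int(r["claim_id"])
        ds.carrier_claims.append(
            SourceCarrierClaim(
                claim_id=cid,
                bene_id=int(r["bene_id"]),
                from_date=r["from_date"],
                thru_date=r["thru_date"],
                header_dx_codes=_split(r["header_dx_codes"]),
                lines=tuple(
                    sorted(lines_by_claim.get(cid, []), key=lambda x: x.line_num)
                ),
            )
        )
    for _, r in load(DRUG_FILE).iterrows():
        ds.drug_events.append(
            SourceDrugEvent(
                event_id=int(r["event_id"]),
                bene_id=int(r["bene_id"]),
                service_date=r["service_date"],
                ndc_code=r["ndc_code"],
                days_supply=int(r["days_supply"]),
                quantity=float(r["quantity"]),
            )
        )
    seer = load(SEER_FILE)
    if len(seer):
        for (case_id, diag), grp in seer.groupby(
            ["case_id", "diagnosis_date"], sort=False
        ):
            ds.seer_records.append(
                SourceSeerRecord(
                    case_id=int(case_id),
                    diagnosis_date=diag,
                    variables=tuple(
                        (r["variable"], r["value_code"]) for _, r in grp.iterrows()
                    ),
                )
            )
    for _, r in load(CPRD_FILE).iterrows():
        ds.cprd_records.append(
            SourceCprdTestRecord(
                patient_id=int(r["patient_id"]),
                event_date=r["event_date"],
                read_code=r["read_code"],
                entity_type=r["entity_type"],
                value=float(r["value"]),
                unit=r["unit"],
            )
        )
    return ds
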