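"""Quality control: cohort queries, information-loss check, summaries.

Cohort identification is the workload the model exists for: find the
patients with at least one code from a code set, optionally constrained
by a date window, by provenance (record type or code provenance), and by
whether the patient's *first* or *last* matching code falls in the
window.

The information-loss check runs the same cohort specification twice —
once against the GDM and once against the raw source files via an
independent brute-force scan that shares no code with the ETL — and
reports whether the two patient sets are identical.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from gdmetl import etl as _etl
from gdmetl import synth
from gdmetl.schema import GdmDatabase, TABLE_NAMES
from gdmetl.synth import SourceDataset
from gdmetl.vocabulary import ConceptStore


class QcError(Exception):
    pass


@dataclass(frozen=True)
class CohortSpec:
    """A cohort definition: code set + optional provenance/temporal logic.

    ``selector`` = ``any`` keeps patients with any matching code in the
    window; ``first``/``last`` keep patients whose first/last matching
    code (over all time) falls in the window.  Date ties cannot change
    membership because tied codes share the date.
    """

    codeset: tuple[tuple[str, str], ...]
    provenance_ids: frozenset[int] | None = None
    window: tuple[str, str] | None = None
    selector: str = "any"

    def __post_init__(self) -> None:
        if not self.codeset:
            raise QcError("codeset must be non-empty")
        if self.selector not in ("any", "first", "last"):
            raise QcError(f"unknown selector: {self.selector}")


@dataclass
class DbSummary:
    row_counts: dict[str, int]
    table_count: int
    patient_count: int
    date_range: tuple[str, str] | None


@dataclass
class LossReport:
    identical: bool
    only_source: set[int]
    only_gdm: set[int]


# ---------------------------------------------------------------------------
# GDM-side query


def _matching_dates(db: GdmDatabase, spec: CohortSpec) -> pd.DataFrame:
    """(patient_id, date) pairs of clinical codes matching codeset and
    provenance filter (window not yet applied)."""
    concepts = db["concepts"]
    known_vocabs = set(db["vocabularies"]["id"].dropna())
    wanted_ids = set()
    for vocab, code in spec.codeset:
        if vocab not in known_vocabs:
            raise QcError(f"unknown vocabulary in codeset: {vocab}")
        hit = concepts[
            (concepts["vocabulary_id"] == vocab)
            & (concepts["concept_code"] == str(code))
        ]
        wanted_ids.update(int(i) for i in hit["id"])
    cc = db["clinical_codes"]
    m = cc[cc["clinical_code_concept_id"].isin(wanted_ids)]
    if spec.provenance_ids is not None:
        rec_type = db["contexts"].set_index("id")["record_type_concept_id"]
        ctx_type = m["context_id"].map(rec_type)
        keep = m["provenance_concept_id"].isin(spec.provenance_ids) | ctx_type.isin(
            spec.provenance_ids
        )
        m = m[keep]
    return m[["patient_id", "start_date"]].rename(columns={"start_date": "date"})


def cohort_query(db: GdmDatabase, spec: CohortSpec) -> set[int]:
    """Patient ids satisfying the cohort specification against the GDM."""
    m = _matching_dates(db, spec)
    if m.empty:
        return set()
    if spec.selector == "any":
        if spec.window is not None:
            lo, hi = spec.window
            m = m[(m["date"] >= lo) & (m["date"] <= hi)]
        return {int(p) for p in m["patient_id"].unique()}
    agg = m.groupby("patient_id")["date"].min() if spec.selector == "first" \
        else m.groupby("patient_id")["date"].max()
    if spec.window is not None:
        lo, hi = spec.window
        agg = agg[(agg >= lo) & (agg <= hi)]
    return {int(p) for p in agg.index}


# ---------------------------------------------------------------------------
# source-side oracle (independent of the ETL code paths)


def enumerate_source_codes(ds: SourceDataset):
    """Every code occurrence in the raw source files.

    Yields ``(bene_id, vocabulary, code, date, provenance, record_type)``
    tuples — the flat enumeration a reviewer would produce by reading the
    source files directly.
    """
    for c in ds.inpatient_claims:
        for dx in c.header_dx_codes:
            yield (c.bene_id, _etl.VOCAB_ICD9_DX, dx, c.admit_date,
                   "header_dx", "inpatient_claim")
        for pr in c.proc_codes:
            yield (c.bene_id, _etl.VOCAB_ICD9_PROC, pr, c.admit_date,
                   "procedure", "inpatient_claim")
    for c in ds.carrier_claims:
        for dx in c.header_dx_codes:
            yield (c.bene_id, _etl.VOCAB_ICD9_DX, dx, c.from_date,
                   "header_dx", "carrier_claim")
        for ln in c.lines:
            yield (c.bene_id, _etl.VOCAB_ICD9_DX, ln.line_dx_code, c.from_date,
                   "line_dx", "carrier_line")
            yield (c.bene_id, _etl.VOCAB_HCPCS, ln.hcpcs_code, c.from_date,
                   "procedure", "carrier_line")
    for e in ds.drug_events:
        yield (e.bene_id, _etl.VOCAB_NDC, e.ndc_code, e.service_date,
               "prescription", "prescription")
    for r in ds.seer_records:
        for var, val in r.variables:
            yield (r.case_id, _etl.VOCAB_SEER_PREFIX + var, val,
                   r.diagnosis_date, "registry_value", "registry")
    for r in ds.cprd_records:
        yield (r.patient_id, _etl.VOCAB_READ, r.read_code, r.event_date,
               "measurement", "measurement")
        yield (r.patient_id, _etl.VOCAB_ENTITY_TYPE, r.entity_type,
               r.event_date, "measurement", "measurement")


def source_cohort_scan(ds: SourceDataset, spec: CohortSpec,
                       store: ConceptStore) -> set[int]:
    """Brute-force evaluation of a cohort spec directly on the source.

    ``store`` is used only to decode the concept ids of the provenance
    filter back into their (vocabulary, code) names — the scan itself
    never touches the ETL output.
    """
    prov_names: set[str] | None = None
    if spec.provenance_ids is not None:
        prov_names = set()
        for cid in spec.provenance_ids:
            c = store.concepts.get(cid)
            if c is not None:
                prov_names.add(c.concept_code)
    wanted = {(v, str(c)) for v, c in spec.codeset}
    dates: dict[int, list[str]] = {}
    for bene, vocab, code, date, prov, rtype in enumerate_source_codes(ds):
        if (vocab, code) not in wanted:
            continue
        if prov_names is not None and prov not in prov_names \
                and rtype not in prov_names:
            continue
        dates.setdefault(bene, []).append(date)
    out = set()
    for bene, ds_ in dates.items():
        if spec.selector == "any":
            hit = ds_ if spec.window is None else [
                d for d in ds_ if spec.window[0] <= d <= spec.window[1]
            ]
            if hit:
                out.add(bene)
        else:
            pick = min(ds_) if spec.selector == "first" else max(ds_)
            if spec.window is None or spec.window[0] <= pick <= spec.window[1]:
                out.add(bene)
    return out


def gdm_patient_to_source_id(db: GdmDatabase) -> dict[int, int]:
    """patient id → source person id, via the recorded patient detail."""
    codes = db["concepts"].set_index("id")["concept_code"]
    pdet = db["patient_details"]
    mask = pdet["detail_concept_id"].map(codes) == "source_patient_id"
    return {
        int(r["patient_id"]): int(r["value_as_text"])
        for _, r in pdet[mask].iterrows()
    }


def information_loss_check(source: SourceDataset, db: GdmDatabase,
                           spec: CohortSpec, store: ConceptStore) -> LossReport:
    """Compare the cohort found in the source files with the cohort found
    in the GDM; they must be identical if the ETL lost nothing."""
    gdm_patients = cohort_query(db, spec)
    to_source = gdm_patient_to_source_id(db)
    gdm_ids = {to_source[p] for p in gdm_patients}
    src_ids = source_cohort_scan(source, spec, store)
    return LossReport(
        identical=gdm_ids == src_ids,
        only_source=src_ids - gdm_ids,
        only_gdm=gdm_ids - src_ids,
    )


def random_cohort_specs(store: ConceptStore, n: int, seed: int,
                        window: tuple[str, str] = ("2008-01-01", "2010-12-31"),
                        ) -> list[CohortSpec]:
    """Seeded sample of cohort specifications over the generator's pools.

    Exercises every query dimension: code sets across vocabularies, date
    windows, provenance filters, and the any/first/last selectors.
    """
    rng = np.random.default_rng(seed)
    families: list[list[tuple[str, str]]] = [
        [(_etl.VOCAB_ICD9_DX, c) for c in synth.ICD9_DX_POOL],
        [(_etl.VOCAB_ICD9_PROC, c) for c in synth.ICD9_PROC_POOL],
        [(_etl.VOCAB_HCPCS, c) for c in synth.HCPCS_POOL],
        [(_etl.VOCAB_NDC, c) for c in synth.NDC_POOL],
        [(_etl.VOCAB_READ, c) for c in synth.READ_CODE_POOL],
        [(_etl.VOCAB_SEER_PREFIX + "grade", c)
         for c in synth.SEER_VARIABLES["grade"]],
    ]
    prov_choices = [None, {"header_dx"}, {"line_dx"}, {"procedure"},
                    {"inpatient_claim"}, {"carrier_line"}, {"prescription"}]
    lo = dt.date.fromisoformat(window[0])
    hi = dt.date.fromisoformat(window[1])
    span = (hi - lo).days
    specs = []
    for _ in range(n):
        fam = families[int(rng.integers(0, len(families)))]
        k = int(rng.integers(1, min(4, len(fam)) + 1))
        idx = rng.choice(len(fam), size=k, replace=False)
        codeset = tuple(fam[int(i)] for i in sorted(idx))
        if rng.random() < 0.5:
            a = int(rng.integers(0, span))
            b = int(rng.integers(a, span + 1))
            win = ((lo + dt.timedelta(days=a)).isoformat(),
                   (lo + dt.timedelta(days=b)).isoformat())
        else:
            win = None
        prov = prov_choices[int(rng.integers(0, len(prov_choices)))]
        prov_ids = None
        if prov is not None:
            ids = set()
            for name in prov:
                for vocab in (_etl.VOCAB_PROVENANCE, _etl.VOCAB_RECORD_TYPE):
                    c = store.lookup(vocab, name)
                    if c is not None:
                        ids.add(c.id)
            prov_ids = frozenset(ids) if ids else None
        selector = ("any", "first", "last")[int(rng.integers(0, 3))]
        specs.append(CohortSpec(codeset=codeset, provenance_ids=prov_ids,
                                window=win, selector=selector))
    return specs


# ---------------------------------------------------------------------------
# summaries


def summarize(db: GdmDatabase) -> DbSummary:
    """Deterministic per-table counts and the overall clinical date range."""
    counts = db.row_counts()
    cc = db["clinical_codes"]
    date_range = None
    if len(cc):
        date_range = (str(cc["start_date"].min()), str(cc["end_date"].max()))
    return DbSummary(
        row_counts=counts,
        table_count=len(TABLE_NAMES),
        patient_count=int(db["patients"]["id"].nunique()),
        date_range=date_range,
    )
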