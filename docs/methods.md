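# Methods

## The data model

The package implements a 19-table relational model whose clinical core is
the Clinical Codes → Contexts → Collections hierarchy. The guiding
principle is *relocation, not interpretation*: ETL moves every source code
occurrence into exactly one Clinical Codes row and records where it came
from, rather than deciding what it means. Three consequences shape the
design:

* **No visits at ETL time.** Collections represent whatever grouping the
  source itself provides (a claim, an office visit); consolidated
  encounters are constructed only in the downstream Sentinel export, where
  a visit definition is unavoidable.
* **No domains.** Codes are not routed into diagnosis/procedure/drug
  tables inside the GDM; routing by source vocabulary happens only at
  export time.
* **No vocabulary standardization of stored data.** The Mappings table
  holds `is_a` edges used at query/export time; source codes are never
  rewritten, so mappings can be updated without re-running the ETL.

Conventions: identifiers are 64-bit integers assigned sequentially from 1
per table in deterministic input order; date intervals are closed, with
single-day events having `start = end`; CSV serialization is RFC 4180,
UTF-8, header row, empty string = null, ISO-8601 dates. Dates are carried
in memory as ISO strings, which round-trip exactly and compare
chronologically under lexicographic order.

The exact column inventory beyond the core fields is the implementable
minimum: every column required by the hierarchy, provenance, costs and
details semantics, plus nullable plumbing keys (addresses, practitioners,
facilities). Concept-valued columns all reference the Concepts table and
every such reference is checked by `validate`, whose rule list and the
emitted DDL foreign keys derive from a single registry.

## Vocabulary subsystem

Concept ids are a bijection with `(vocabulary, code)` pairs within a
store. Sequential assignment starts at 100 000 001 — a readable magnitude
that keeps assigned ids clearly apart from row ids — and bulk loads of
curated tables preserve explicit ids verbatim, advancing the counter past
them. Two curated fixtures ship with the package: the nine NAACCR tumor
grade concepts (ids 100 010 943–100 010 951) and the demonstration mapping
of SynPUF sex/race codings onto Sentinel sex, race and hispanic codings.
Lookup misses are values, not exceptions, because the ETL branches on
them; `map_concepts` is read-only and reloading a superset of mappings can
only add targets (monotonicity), so query results never silently change.

## Synthetic sources

The generator emulates three source families — Medicare-style claims
(beneficiary summary, inpatient claims with header diagnoses/procedures,
carrier claims with numbered lines, drug events), a UK primary-care "Test"
file (Read code + entity type + numeric value), and a registry extract
with 31 coded variables, each variable its own vocabulary. Layouts are
documented simplifications: the contract is the header/line hierarchy and
the coding slots, not byte-compatibility with CMS or CPRD files.

Default study conditions: 3-year window (2008–2010), Medicare-age birth
years (1920–1948), per-patient Poisson claim counts with means 0.5
(inpatient), 2.0 (carrier), 2.0 (drug), 1.0 (measurement), a 30% registry
fraction and 10% mortality; dates uniform in the window; codes drawn
uniformly from small fixed pools of real-looking ICD-9-CM, HCPCS, NDC and
Read codes. These are chosen as plausible utilization rates for an elderly
claims population at test scale; the generator makes no attempt to model
disease incidence, code correlation or realistic cost distributions. Every
source record dataclass carries a `diagnosis_date`/event date because the
GDM requires dated Contexts; registry extracts in the wild carry diagnosis
dates as well. Consequently, passing tests demonstrate structural
correctness of the ETL and queries — preservation, hierarchy, ordering,
provenance — not fidelity to any real population.

## ETL

Records are processed in deterministic order (beneficiaries, inpatient,
carrier, drug, registry, measurement; sorted by person and record id), so
a run is exactly reproducible. Each GDM patient receives one Patient
Detail row holding the source person id, which lets downstream checks
translate GDM patient ids back to source ids without relying on row order.
Record-type and provenance concepts use readable codes
(`carrier_claim`/`carrier_line`, `header_dx`/`line_dx`/`procedure`, …)
registered in the store before use. Line payments attach to line-level
contexts and claim payments to claim-level contexts; line and claim totals
are stored as-is and never reconciled, since they disagree in real claims
data. Diagnosis codes that indicate death stay in Clinical Codes — the
Deaths table is populated only from the beneficiary summary, and an
"expired" discharge status is recorded on the admission detail without
creating a death row. Header diagnoses duplicating line diagnoses are
never deduplicated: the preservation contract is a multiset bijection
between source code occurrences and Clinical Codes rows, verified by an
independent enumeration of the source files.

## Cohort queries and the information-loss check

A cohort specification is a code set plus optional date window, optional
provenance filter (matching either the code's provenance concept or its
context's record type) and a selector: *any* (any matching code in the
window), *first*/*last* (the patient's first/last matching code over all
time must fall in the window). Membership under first/last depends only on
the min/max matching date, so date ties cannot change the cohort; no
further tie-break is needed.

The information-loss check evaluates the same specification twice: against
the GDM, and against the raw source files via a brute-force scan
(`enumerate_source_codes`) that shares no code with the ETL path — it
reads the source record structures directly and uses the concept store
only to decode the provenance filter's ids back to names. Identical
patient sets over randomly sampled specifications are the operational
definition of "no information loss" at this scale.

## Sentinel export

Demographic, Enrollment and Death are renames plus mapping traversal;
unmapped demographic concepts receive the designated unknown codes (sex
`U`, race `0`, hispanic `U`), but an export with patients and no Sentinel
mappings loaded at all is refused with the list of unmapped concepts.
Diagnosis/Procedure/Dispensing are produced by routing Clinical Codes on
their source vocabulary (default: ICD-9-CM diagnoses → Diagnosis; ICD-9
procedures and HCPCS → Procedure; NDC → Dispensing); unrouted vocabularies
(registry and EHR measurement codes, which Sentinel has no table for) are
counted in the export log, never silently dropped.

Encounters are built in two steps. A pre-Encounter table gets one row per
Context with the encounter id set to the Context id and a type derived
from provenance: inpatient claim contexts → IP, carrier contexts → AV,
overridden to ED when the line's place of service is 23 (emergency room);
record types without a mapping fall back to OA and are logged. The roll-up
then groups pre-encounters by **(patient, start date, encounter type,
facility)** — an operationalization of the common "unique combination of
patient, date, provider and visit type" visit definition — assigning new
sequential ids, taking the group's min start and max end, and relabelling
Diagnosis and Procedure with the new ids. Provider is excluded from the
default key because the synthetic sources carry no practitioners; the key
and the type map are arguments for callers who need different visit
semantics. Multi-day carrier claims group on their start date.

## Numerical and degenerate-input choices

* Validation is pure and order-insensitive; violations are reported sorted
  by (table, row id, rule) so diffs are stable.
* Empty datasets flow through every stage: empty database, header-only
  CSVs, empty exports, empty remap.
* Monetary values are floats rounded to cents at generation; no currency
  arithmetic is performed.
* The acceptance study uses 1,000 patients and 20 random cohort
  specifications — large enough that every vocabulary family, selector and
  provenance filter is exercised, small enough to run in seconds.

## Known limitations

* Costs beyond per-line/per-claim paid amounts (allowed amounts,
  coinsurance, the generic Costs table) and the facility, address and
  practitioner tables are schema-complete and validated but not populated
  by the synthetic ETL.
* The Sentinel export is structural, not a certified implementation of the
  Sentinel CDM specification (column parity and value sets are partial).
* The generator's independence assumptions (uniform codes, independent
  claim counts) make it unsuitable for benchmarking statistical methods;
  it exists to exercise structure.
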