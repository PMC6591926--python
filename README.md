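# gdmetl — the Generalized Data Model for observational health data

`gdmetl` implements the Generalized Data Model (GDM), a 19-table relational
schema for administrative claims, electronic health record (EHR) and cancer
registry data, together with a tested ETL pipeline into it, referential
integrity validation, cohort queries, and a downstream export to
Sentinel-style tables with visit roll-up.

It is aimed at clinical researchers and data engineers who need a stable,
provenance-preserving waypoint between raw healthcare sources and
analysis-ready common data models.

## The model

The core of the GDM is a three-level hierarchy:

* **Clinical Codes** — one source code occurrence per row (an ICD-9-CM
  diagnosis, a HCPCS procedure, an NDC drug code, a Read code, a registry
  variable value), with start/end dates, a provenance concept (header
  diagnosis vs. line diagnosis vs. procedure, …) and a sequence number that
  preserves the ordering of numbered code slots;
* **Contexts** — groups of co-reported codes (a claim header, one claim
  line, one laboratory measurement) carrying origin metadata: source file
  name, record type, CMS place of service, care site and facility keys;
* **Collections** — groups of Contexts: typically a claim (billing data) or
  a visit (EHR data).

Around this core sit patient tables (Patients, Patient Details, Information
Periods, Deaths), detail tables (Admissions, Drug Exposure, Measurement),
cost tables (Payer Reimbursements, Costs, aligned with Contexts), facility
and practitioner tables, and a vocabulary subsystem (Concepts,
Vocabularies, Mappings). Every distinct `(vocabulary, code)` pair receives
a numeric concept id; directed `is_a` mappings standardize queries (e.g.
source sex coding → Sentinel sex coding) without ever altering the stored
source codes. The model deliberately avoids constructing visits or
assigning domains at ETL time — both are lossy, study-specific decisions
that are deferred to query time or to a downstream export.

## Worked example

```python
from gdmetl.etl import EtlEngine
from gdmetl.synth import example_carrier_claim

claim = example_carrier_claim()      # 2 header diagnoses + 2 lines
engine = EtlEngine()
engine.etl_carrier_claim(claim)
db = engine.finish()
print({t: n for t, n in db.row_counts().items() if n})
```

prints (vocabulary tables elided):

```
{'clinical_codes': 6, 'collections': 1, 'contexts': 3,
 'patient_details': 1, 'patients': 1, 'payer_reimbursements': 2, ...}
```

One carrier claim becomes **1 collection** and **3 contexts** — a
claim-level context holding the two header diagnoses and one line-level
context per line, each holding that line's diagnosis and procedure — with
each of the 6 source codes as its own clinical-code row and each line
payment attached to its line context.

The same pipeline runs from the shell:

```
gdm synth --n 100 --seed 7 --out src/
gdm etl --in src/ --out gdm/
gdm validate gdm/
gdm stats gdm/
gdm export-sentinel --in gdm/ --out sentinel/
gdm cohort --in gdm/ --code icd9_dx:401.9 --selector first
```

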