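# claimcase

Fracture case ascertainment from administrative health-insurance claims.

Administrative claims databases — here modelled on Japan's national claims
repository, which covers roughly 42 million residents of the Kanto region —
record diagnoses and procedures for billing, not for epidemiology. Counting
*first-incident* fractures from them requires an explicit algorithm, and this
package implements one as a tested, reusable pipeline for epidemiologists and
health-services researchers:

1. **Code-group classification** — ICD-10 chapter-S injury codes are grouped
   into 11 fracture site groups (rib/sternum, clavicle/scapula/humerus,
   distal radius, other radius/ulna, hand, hip, other femur,
   patella/tibia/fibula, ankle, toe, other foot); nine fracture-specific
   treatment procedure codes (K044–K082) anchor the case definition.
2. **Patient linkage** — claims carry two hashed person identifiers (ID1,
   ID2) that change independently across insurer moves; a union-find
   transitive closure over shared identifiers assigns one deterministic
   patient key (ID0) per connected component.
3. **Extraction** — Dataset A (procedure **and** principal/secondary — never
   merely *suspected* — fracture diagnosis) defines cases; Dataset B
   (diagnosis-only claims not in A) refines the first-visit date.
4. **Exclusion and date resolution** — candidates whose key dates (earliest
   diagnosis documentation, each procedure application, hospitalization) are
   more than 14 days apart are excluded as hospital-acquired; the first-visit
   date is the earliest key date, pushed back through same-site Dataset B
   claims at other facilities within a 14-day lookback (referral chains).
5. **First-incidence deduplication and reporting** — one case per (patient,
   site group), clipped to the case window 2013-04-17..2016-03-15, then
   tabulated by site × calendar month (pooled across years) × five age bands
   × sex, with counts ≤ 10 suppressed to `<=10` for privacy, plus a
   days-of-exposure row and optional rates per 100,000 person-years.

A synthetic claims generator (`claimcase.synthetic`) plants ground-truth
fractures with every structural complication the pipeline must survive —
referral chains, hospital-acquired displacements, suspected-only diagnoses,
identity splits, recurrences, out-of-region and noise claims — and an
independent oracle derives the expected case set from the planted flags, so
the whole pipeline is validated end to end by exact set equality.

## Worked example

```sh
python examples/02_end_to_end_pipeline.py
```

prints (seed 42, 2,000 synthetic patients):

```
generated 5610 claims for 2000 patients (1182 planted fracture events)
linkage consolidated the claims into 1845 patients
pipeline accepted 982 first-incidence fracture cases
planted-truth oracle expects 982 cases; exact match: True
(179 planted events carry an exclusion flag)
```

1,182 fractures were planted but only 982 become cases: events flagged
hospital-acquired, suspected-only or out-of-region are excluded by design,
and first visits resolving outside the case window are not counted. The
pipeline's case set equals the oracle's exactly. The other examples
demonstrate code classification, the suppressed stratified report with its
1064-day exposure row, and referral-chain resolution.

The same stages are available as a thin CLI:

```sh
claimcase simulate bundle/ --seed 42 --n-patients 2000
claimcase cases bundle/ --out cases.csv
claimcase report cases.csv --out report.csv
```

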