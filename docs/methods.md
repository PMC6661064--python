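# Methods

## The ascertainment problem

A claim (receipt) is the monthly billing document one healthcare provider
submits for one patient. It is a poor epidemiological record in three ways
that the pipeline must correct:

* the same person appears under different hashed identifier pairs when their
  insurer changes (**linkage**);
* the claim that carries the definitive treatment procedure is often not the
  first contact — patients are referred from a clinic that billed a
  diagnosis-only claim days earlier (**first-visit resolution**);
* diagnoses are recorded for billing: `suspected` codes justify tests for
  fractures that may not exist, fractures sustained *in* hospital during an
  unrelated admission inflate incidence, and the same fracture generates
  claims for months (**role filtering, date-spread exclusion, first-incidence
  deduplication**).

## Case definition

A case is the first incidence of fracture in one of 11 ICD-10-defined site
groups within the case window. The anchor is a Dataset A claim: in-region,
in-window, carrying one of nine fracture-specific procedure codes *and* a
site-group ICD-10 code as a principal or secondary diagnosis. Multiple codes
from one site group on one claim are a single candidate; different site
groups are classed separately. Site classification operates at the
4-character ICD-10 level: codes with a 5th character are truncated, a
3-character rule (e.g. S42) covers the bare category and all subcodes, and
the shipped rule table is validated at load time so no concrete code can
belong to two groups.

The rib/sternum group's code set is not part of the published grouping table;
this package maps S22.2–S22.5 (sternum, rib, multiple ribs, flail chest) to
it. The mapping ships in `data/site_codes.csv` and can be overridden
per-run, so users who prefer a different reading can supply their own table.

### Key dates and the spread rule

Each candidate has up to three kinds of key dates: the **earliest**
documentation date of its qualifying diagnoses, **each** fracture-procedure
application date, and the hospitalization date when present. If any pair is
more than `spread_limit_days` (default 14) apart the candidate is excluded.
The inequality is strict — a gap of exactly 14 days is kept — so nosocomial
documentation lag of up to two weeks survives while genuinely
hospital-acquired fractures (treatment weeks after admission) are dropped.
The rule is applied per candidate (per claim × site group), not per merged
patient episode; a candidate with a single key date trivially passes.

### First-visit resolution

The first-visit date — the proxy for the fracture date — starts as the
minimum key date. Dataset B claims of the same patient and site group at a
*different* facility, documented strictly earlier and within `lookback_days`
(default 14), pull the date back. By default the search iterates: after
stepping to an earlier claim the lookback restarts from that claim's date and
facility, so a clinic → clinic → hospital chain with every hop ≤ 14 days
resolves to the true first contact. Whether a one-step or iterated lookback
is the better reading of "within the previous 14 days" is genuinely open; the
iterated form is the default because it is the fixpoint of the one-step rule,
and `chain_lookback: false` restores single-step behaviour. The
different-facility condition is checked against the facility of the claim
currently fixing the date. Age band and sex are taken from that same claim —
attributes at first contact win if a chain crosses a birthday.

### Deduplication and windows

Per (patient, site group) only the earliest resolved event is kept; ties on
the date collapse to one case deterministically (smallest claim id). Cases
whose first visit falls outside the case window are dropped — including a
patient whose true first incidence predates the window, who must not re-enter
via a recurrence. The claim window (2013-04-01..2016-03-31, enforced on the
claim month) deliberately overhangs the case window (2013-04-17..2016-03-15)
so the lookback and the washout have data at both edges; the 16-day margins
equal `lookback_days` plus the two-day slack between a visit and its earliest
possible claim dates. One published source states the case window as April 15
to March 17; the adopted reading is the one whose per-month exposure row sums
to the inclusive day count (1,064), which the package verifies
arithmetically.

## Linkage

Identifier values are graph nodes (ID1 and ID2 in separate namespaces), each
claim an edge; components get one key, derived from the lexicographically
smallest member so the result is order-independent and stable across runs.
This transitive closure is the most permissive deterministic reading of
"match on ID1 and ID2"; the matcher is a pluggable function, and conflicts
(empty identifiers) are rejected row-wise, never silently merged. Tests
compare the partition against an independent connected-components oracle
(networkx) on random instances.

## Reporting

Tabulation pools calendar months across years (a seasonal-variation axis;
`margin()` exposes any marginal). Cells with counts at or below the
suppression threshold (default 10, a privacy term of use of the source
database) render as `<=10`; true counts are kept internally for conservation
checks and never serialized. Suppression is cell-wise only — margins are
printed exactly, matching the published table's practice — so the rendering
is not protected against complementary disclosure; that is a property of the
emulated report, not an oversight. Incidence rates per 100,000 person-years
(population × 365.25-day years over the inclusive window) are an extension
beyond the published counts; strata suppressed in every month receive an
upper-bound rate flagged `censored`.

## Synthetic cohorts and what they show

The generator emulates the *structure* of national claims data, not its
volume or true hazard surface. Defaults: 2,000 patients per cohort; age ×
sex weights proportional to the real Kanto population table bundled with the
package; a uniform per-site monthly fracture hazard of 0.0015 (≈ 0.6 expected
events per patient over 36 months — comfortably inside the first-incidence
regime, and overridable per site with a 12-month vector to plant seasonal
excess); 20% of cases referred through 1–2 upstream clinics with gaps uniform
on 1–21 days (straddling the 14-day lookback so both intact and broken chains
occur); 5% hospital-acquired (treatment displaced 15–40 days after
admission); 5% suspected-only; 10% of patients with a split identity; 5%
recurrence (planted only for otherwise clean events so the expected case set
stays unambiguous); 5% out-of-region; Poisson(2) non-fracture noise claims
per patient drawn from a fixed non-S-chapter code list that cannot collide
with the site map.

`expected_cases` is the oracle: it never calls the pipeline, deriving the
expected case set directly from planted flags and gap arithmetic (a hop is
followed iff its gap ≤ lookback and its date is visible within the claim
window). Exact set equality between pipeline and oracle across seeds
therefore exercises every rule jointly. What passing does **not** show:
robustness to real-data features the generator omits — contradictory
demographics within one patient, probabilistic identifier collisions across
patients, coding-practice drift over time, dental/pharmacy claim types, or
realistic per-site hazard ratios. The published stratified cell counts
cannot be reproduced here at all, since the source database is not publicly
accessible; the recovery properties stand in for them.

## Numerical and interface choices

Dates are ISO-8601 and all intervals are inclusive on both ends. "Two weeks"
is 14 days everywhere. The interchange format is three co-keyed CSV tables
(claims / diagnoses / procedures) because claims carry variable numbers of
entries; round-tripping is the identity and is property-tested. Age is
carried as the five-band age-group code — exact ages never enter the
analysis. Malformed rows are rejected with reasons, and accepted + rejected
always equals input. Problem sizes in the test suite (cohorts of 2,000
patients over 30 seeds, 500 linkage instances of ≤ 200 claims, 1,000 planted
referral chains) keep the full suite under a minute while holding the
Monte-Carlo checks to 3 standard errors.
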