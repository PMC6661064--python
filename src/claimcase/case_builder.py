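"""From interim extracts to first-incidence fracture cases.

The case definition proceeds in four steps:

1. **Candidate events** — each Dataset A claim yields one candidate per
   fracture site group it qualifies for.  Multiple fractures within one site
   group on one claim are a single candidate; different site groups are
   classed separately.
2. **Date-spread exclusion** — a candidate whose key dates (earliest diagnosis
   documentation, each treatment-procedure application, hospitalization) are
   more than ``spread_limit_days`` apart is dropped.  This removes
   hospital-acquired fractures, where treatment follows an admission for
   something else by weeks, while keeping cases whose documentation lags the
   admission by a few days.  The inequality is strict: a 14-day gap is kept.
3. **First-visit resolution** — the earliest key date is taken as the visit
   date, unless Dataset B holds a claim of the same patient, same site group,
   at a different facility, documented within the ``lookback_days`` before it
   (a referral: the patient saw a clinic first and the treating hospital
   later).  Then the earlier visit becomes the first-visit date.  By default
   the lookback iterates to a fixpoint so multi-hop referral chains resolve to
   the true first contact; ``chain_lookback=False`` gives the single-step
   behaviour.  The first-visit date is the proxy for the fracture date.
4. **First-incidence deduplication** — per (patient, site group) only the
   earliest case is kept (recurrent fractures in the same site group are
   excluded), and cases whose first visit falls outside the case window are
   dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date

from .code_maps import SiteCodeMap, SiteGroup, default_site_code_map, is_fracture_procedure
from .config import StudyConfig
from .extraction import Dataset, has_qualifying_diagnosis
from .model import AgeBand, CandidateEvent, DiagnosisRole, FractureCase, Sex

__all__ = [
    "candidate_events",
    "passes_date_spread",
    "resolve_first_visit",
    "dedupe_first_incidence",
    "build_cases",
    "BLookupIndex",
    "ResolvedVisit",
]


def candidate_events(
    dataset_a: Dataset, code_map: SiteCodeMap | None = None
) -> list[CandidateEvent]:
    """One candidate per (claim, site group) with a qualifying diagnosis."""
    code_map = code_map or default_site_code_map()
    events: list[CandidateEvent] = []
    for claim in dataset_a.claims:
        patient = dataset_a.patient_keys[claim.claim_id]
        by_site: dict[SiteGroup, set[date]] = {}
        for dx in claim.diagnoses:
            if dx.role is DiagnosisRole.suspected:
                continue
            try:
                group = code_map.classify(dx.icd10)
            except ValueError:
                continue
            if group is not None:
                by_site.setdefault(group, set()).add(dx.documented_on)
        proc_dates = frozenset(
            p.applied_on for p in claim.procedures if is_fracture_procedure(p.code)
        )
        for site in sorted(by_site, key=lambda g: g.value):
            events.append(
                CandidateEvent(
                    patient=patient,
                    site=site,
                    claim_id=claim.claim_id,
                    facility_id=claim.facility_id,
                    diagnosis_dates=frozenset(by_site[site]),
                    procedure_dates=proc_dates,
                    hospitalized_on=claim.hospitalized_on,
                    age_group=claim.age_group,
                    sex=claim.sex,
                )
            )
    return events


def passes_date_spread(event: CandidateEvent, config: StudyConfig) -> bool:
    """True unless some pair of key dates is more than ``spread_limit_days``
    apart.  With a single key date there is no pair and the event passes."""
    dates = event.key_dates()
    return (max(dates) - min(dates)).days <= config.spread_limit_days


@dataclass(frozen=True)
class _BEntry:
    documented_on: date
    facility_id: str
    age_group: AgeBand
    sex: Sex


class BLookupIndex:
    """Per-(patient, site) index of Dataset B claims for the referral lookback.

    For each B claim and each site group it qualifies for, stores the earliest
    principal/secondary documentation date for that site together with the
    claim's facility and demographics.
    """

    def __init__(self, dataset_b: Dataset, code_map: SiteCodeMap | None = None) -> None:
        code_map = code_map or default_site_code_map()
        self._index: dict[tuple[str, SiteGroup], list[_BEntry]] = {}
        for claim in dataset_b.claims:
            patient = dataset_b.patient_keys[claim.claim_id]
            earliest: dict[SiteGroup, date] = {}
            for dx in claim.diagnoses:
                if dx.role is DiagnosisRole.suspected:
                    continue
                try:
                    group = code_map.classify(dx.icd10)
                except ValueError:
                    continue
                if group is not None:
                    prev = earliest.get(group)
                    if prev is None or dx.documented_on < prev:
                        earliest[group] = dx.documented_on
            for site, d in earliest.items():
                self._index.setdefault((patient, site), []).append(
                    _BEntry(d, claim.facility_id, claim.age_group, claim.sex)
                )
        for entries in self._index.values():
            entries.sort(key=lambda e: (e.documented_on, e.facility_id))

    def lookup(self, patient: str, site: SiteGroup) -> list[_BEntry]:
        return self._index.get((patient, site), [])


@dataclass(frozen=True)
class ResolvedVisit:
    """A resolved first visit with the demographics of the claim that fixed it."""

    first_visit: date
    age_group: AgeBand
    sex: Sex


def resolve_first_visit(
    event: CandidateEvent,
    b_index: BLookupIndex,
    config: StudyConfig,
) -> ResolvedVisit:
    """Resolve the first-visit date of *event* against Dataset B.

    Starting from the earliest of the event's key dates, repeatedly look for a
    same-patient, same-site B claim at a *different* facility documented within
    the previous ``lookback_days`` (strictly earlier; a same-day claim at
    another facility does not move the date).  Each accepted step restarts the
    search from the new, earlier date.  With ``chain_lookback=False`` only one
    step is taken.  Demographics follow the claim that fixes the final date:
    attributes at first contact win if the chain crosses an age-band boundary.
    """
    d = min(event.key_dates())
    facility = event.facility_id
    age_group, sex = event.age_group, event.sex
    entries = b_index.lookup(event.patient, event.site)
    while True:
        best: _BEntry | None = None
        for entry in entries:
            if entry.facility_id == facility:
                continue
            delta = (d - entry.documented_on).days
            if 0 < delta <= config.lookback_days:
                if best is None or entry.documented_on < best.documented_on:
                    best = entry
        if best is None:
            break
        d = best.documented_on
        facility = best.facility_id
        age_group, sex = best.age_group, best.sex
        if not config.chain_lookback:
            break
    return ResolvedVisit(first_visit=d, age_group=age_group, sex=sex)


def dedupe_first_incidence(
    resolved: list[tuple[CandidateEvent, ResolvedVisit]],
    config: StudyConfig,
) -> list[FractureCase]:
    """Keep the earliest resolved event per (patient, site group), then drop
    cases outside the case window.

    A patient whose first incidence at a site falls before the case window
    contributes no case for that site at all — the later recurrence is not a
    first incidence.  Ties on the date collapse to one case (deterministically,
    by claim id).
    """
    best: dict[tuple[str, SiteGroup], tuple[date, str, ResolvedVisit]] = {}
    for event, visit in resolved:
        key = (event.patient, event.site)
        cur = best.get(key)
        cand = (visit.first_visit, event.claim_id, visit)
        if cur is None or cand[:2] < cur[:2]:
            best[key] = cand
    lo, hi = config.case_window
    cases = [
        FractureCase(
            patient=patient,
            site=site,
            first_visit=visit.first_visit,
            age_group=visit.age_group,
            sex=visit.sex,
        )
        for (patient, site), (d, _, visit) in best.items()
        if lo <= d <= hi
    ]
    cases.sort(key=lambda c: (c.patient, c.site.value, c.first_visit))
    return cases


def build_cases(
    dataset_a: Dataset,
    dataset_b: Dataset,
    config: StudyConfig,
    code_map: SiteCodeMap | None = None,
) -> list[FractureCase]:
    """Run steps 1-4: candidates, spread exclusion, resolution, deduplication."""
    code_map = code_map or default_site_code_map()
    b_index = BLookupIndex(dataset_b, code_map)
    resolved = [
        (ev, resolve_first_visit(ev, b_index, config))
        for ev in candidate_events(dataset_a, code_map)
        if passes_date_spread(ev, config)
    ]
    return dedupe_first_incidence(resolved, config)
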