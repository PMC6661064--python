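"""Synthetic claims cohorts with planted ground truth.

The generator emulates the structural features of a national claims database
that the ascertainment pipeline must handle, each switchable through
:class:`SimParams`:

* fracture events drawn per (patient, site group) from a small monthly hazard,
  anchored by a Dataset-A-style claim (fracture procedure + principal or
  secondary diagnosis) at a treating facility;
* **referral chains** — the true first visit happens at one or two upstream
  clinics, which emit diagnosis-only claims (Dataset B material) 1-21 days
  apart; chains with every hop within the lookback window should resolve to
  the original visit, chains broken by a longer gap should not;
* **hospital-acquired fractures** — the admission predates diagnosis and
  treatment by more than the spread limit, so the date-spread rule must drop
  them;
* **suspected-only diagnoses** — the fracture code appears only with the
  ``suspected`` role and must never become a case;
* **identity splits** — an insurer change gives the patient a second ID1
  while ID2 persists; claims are issued under both and must still link to one
  patient;
* **out-of-region claims** and non-fracture **noise claims** (non-injury
  ICD-10 codes, unlisted procedures) that must fall out of the extracts;
* **recurrent fractures** — a later same-site claim for an already-counted
  patient, which first-incidence deduplication must ignore (planted only for
  otherwise clean events so the ground truth stays unambiguous).

:func:`expected_cases` is the independent oracle: it derives the accepted case
set directly from the planted flags and gap arithmetic, never touching the
pipeline, so end-to-end recovery can be checked by set equality.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np

from .code_maps import SiteGroup, default_site_code_map
from .config import StudyConfig
from .model import (
    AgeBand,
    ClaimRecord,
    DiagnosisEntry,
    DiagnosisRole,
    FractureCase,
    ProcedureEntry,
    Setting,
    Sex,
)

__all__ = ["SimParams", "TrueEvent", "GroundTruth", "generate_cohort", "expected_cases"]

#: Fracture procedures planted on Dataset-A-style claims.
_EVENT_PROCEDURES = ["K044", "K045", "K046", "K046-2", "K073", "K073-2", "K078", "K081", "K082"]
#: Non-fracture diagnoses for noise claims (fixed non-S-chapter list: common
#: respiratory, back-pain, hypertension, diabetes, gastritis codes — zero
#: overlap with the fracture site map by construction).
_NOISE_ICD10 = ["J06.9", "M54.5", "I10", "E11.9", "K29.7", "J20.9", "N39.0", "H10.9"]
_NOISE_PROCEDURES = ["D007", "J000", "K047", "A001"]
_NON_KANTO_PREFECTURES = [1, 4, 15, 20, 23, 26, 27, 34, 40, 47]
_NOISE_PREFS = _NON_KANTO_PREFECTURES


@dataclass(frozen=True)
class SimParams:
    """Generator settings; the defaults define the study conditions."""

    n_patients: int = 2000
    #: (age band, sex) sampling weights; None = proportional to the bundled
    #: Kanto resident population.
    age_sex_distribution: dict[tuple[AgeBand, Sex], float] | None = None
    #: per-site, per-month event probability; scalar, or a mapping from
    #: SiteGroup to a scalar or length-12 calendar-month vector (to plant
    #: seasonal patterns such as a winter excess).
    monthly_fracture_hazard: float | dict = 0.0015
    referral_prob: float = 0.20
    referral_gap_choices: tuple[int, ...] = tuple(range(1, 22))
    #: given a referral, probability of a second upstream hop
    two_hop_prob: float = 0.25
    hospital_acquired_prob: float = 0.05
    suspected_only_prob: float = 0.05
    identity_split_prob: float = 0.10
    recurrence_prob: float = 0.05
    noise_claims_per_patient: float = 2.0
    out_of_region_prob: float = 0.05
    inpatient_prob: float = 0.30
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "referral_prob", "two_hop_prob", "hospital_acquired_prob",
            "suspected_only_prob", "identity_split_prob", "recurrence_prob",
            "out_of_region_prob", "inpatient_prob",
        ):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        if any(g < 1 for g in self.referral_gap_choices):
            raise ValueError("referral gaps must be >= 1 day")


@dataclass(frozen=True)
class TrueEvent:
    """One planted fracture with everything the oracle needs."""

    patient_index: int
    site: SiteGroup
    anchor_date: date  # visit date at the treating (Dataset A) facility
    hop_gaps: tuple[int, ...]  # referral gaps, nearest hop first; () = none
    age_group: AgeBand
    sex: Sex
    hospital_acquired: bool = False
    suspected_only: bool = False
    out_of_region: bool = False

    @property
    def referral_chain(self) -> bool:
        return bool(self.hop_gaps)


@dataclass
class GroundTruth:
    events: list[TrueEvent] = field(default_factory=list)
    #: identifier strings actually used on each patient's claims, for deriving
    #: the pipeline's deterministic patient key without running the linkage
    used_ids: dict[int, set[str]] = field(default_factory=dict)

    def patient_key(self, patient_index: int) -> str:
        return "P:" + min(self.used_ids[patient_index])


def _resolve_hazard(params: SimParams) -> dict[SiteGroup, np.ndarray]:
    raw = params.monthly_fracture_hazard
    out: dict[SiteGroup, np.ndarray] = {}
    for site in SiteGroup:
        if isinstance(raw, dict):
            value = raw.get(site, raw.get(site.value, 0.0))
        else:
            value = raw
        vec = np.asarray(value, dtype=float) * np.ones(12)
        if vec.shape != (12,):
            raise ValueError("per-site hazard must be scalar or length 12")
        if (vec < 0).any() or (vec >= 1).any():
            raise ValueError("hazards must be probabilities in [0, 1)")
        out[site] = vec
    return out


def _window_months(config: StudyConfig) -> list[tuple[int, int]]:
    lo, hi = config.claim_window
    months, y, m = [], lo.year, lo.month
    while (y, m) <= (hi.year, hi.month):
        months.append((y, m))
        y, m = (y + 1, 1) if m == 12 else (y, m + 1)
    return months


def _default_age_sex_weights() -> tuple[list[tuple[AgeBand, Sex]], np.ndarray]:
    from .aggregation import load_population

    pop = load_population()
    strata = sorted(pop.entries, key=lambda k: (k[0].value, k[1].value))
    weights = np.array([pop.entries[k] for k in strata], dtype=float)
    return strata, weights / weights.sum()


class _ClaimFactory:
    """Accumulates claims with sequential ids and tracks identifiers used."""

    def __init__(self, truth: GroundTruth) -> None:
        self.claims: list[ClaimRecord] = []
        self.truth = truth
        self._n = 0

    def add(self, patient_index: int, id1: str, id2: str, **kwargs) -> None:
        self._n += 1
        self.claims.append(ClaimRecord(claim_id=f"c{self._n:07d}", id1=id1, id2=id2, **kwargs))
        self.truth.used_ids.setdefault(patient_index, set()).update({f"1:{id1}", f"2:{id2}"})


def generate_cohort(
    params: SimParams, config: StudyConfig | None = None
) -> tuple[list[ClaimRecord], GroundTruth]:
    """Generate a claims cohort and its planted ground truth.

    Deterministic given ``params.seed``: two runs with the same parameters
    produce identical claims (ids, order and all) and identical truth.
    """
    config = config or StudyConfig()
    rng = np.random.default_rng(params.seed)
    hazards = _resolve_hazard(params)
    months = _window_months(config)
    n_months = len(months)
    per_patient_expectation = sum(h.mean() for h in hazards.values()) * n_months
    if per_patient_expectation >= len(SiteGroup):
        raise ValueError(
            f"infeasible hazards: expected {per_patient_expectation:.1f} events per "
            f"patient exceeds the first-incidence capacity of {len(SiteGroup)} site groups"
        )
    win_lo, win_hi = config.claim_window
    code_map = default_site_code_map()
    site_codes = {
        site: sorted("{}.{}".format(c[:3], c[3]) for c in code_map.all_subcodes(site))
        for site in SiteGroup
    }

    truth = GroundTruth()
    factory = _ClaimFactory(truth)
    if params.n_patients == 0:
        return [], truth

    if params.age_sex_distribution is None:
        strata, weights = _default_age_sex_weights()
    else:
        strata = sorted(params.age_sex_distribution, key=lambda k: (k[0].value, k[1].value))
        weights = np.array([params.age_sex_distribution[k] for k in strata], dtype=float)
        weights = weights / weights.sum()
    stratum_idx = rng.choice(len(strata), size=params.n_patients, p=weights)
    split = rng.random(params.n_patients) < params.identity_split_prob
    home_pref = rng.choice(sorted(config.region_prefectures), size=params.n_patients)

    # vectorized first-event month per (patient, site): first success of a
    # Bernoulli sequence over the window months
    cal_month_idx = np.array([m - 1 for _, m in months])
    first_month: dict[SiteGroup, np.ndarray] = {}
    for site in SiteGroup:
        p = hazards[site][cal_month_idx]  # (n_months,)
        hits = rng.random((params.n_patients, n_months)) < p[None, :]
        any_hit = hits.any(axis=1)
        idx = np.where(any_hit, hits.argmax(axis=1), -1)
        first_month[site] = idx

    def pick_id1(i: int) -> str:
        if split[i] and rng.random() < 0.5:
            return f"G{i:06d}b"
        return f"G{i:06d}a"

    def random_day(year: int, month: int) -> date:
        # uniform over the month's days that lie inside the claim window
        from calendar import monthrange

        lo_day = win_lo.day if (year, month) == (win_lo.year, win_lo.month) else 1
        hi_day = (
            win_hi.day
            if (year, month) == (win_hi.year, win_hi.month)
            else monthrange(year, month)[1]
        )
        return date(year, month, int(rng.integers(lo_day, hi_day + 1)))

    def clamp(d: date) -> date:
        return min(max(d, win_lo), win_hi)

    for i in range(params.n_patients):
        band, sex = strata[stratum_idx[i]]
        id2 = f"H{i:06d}"
        for site in SiteGroup:
            mi = int(first_month[site][i])
            if mi < 0:
                continue
            anchor = random_day(*months[mi])
            hospital_acquired = rng.random() < params.hospital_acquired_prob
            suspected_only = rng.random() < params.suspected_only_prob
            out_of_region = rng.random() < params.out_of_region_prob
            hop_gaps: tuple[int, ...] = ()
            if not hospital_acquired and rng.random() < params.referral_prob:
                n_hops = 2 if rng.random() < params.two_hop_prob else 1
                hop_gaps = tuple(
                    int(rng.choice(params.referral_gap_choices)) for _ in range(n_hops)
                )
            pref = (
                int(rng.choice(_NOISE_PREFS))
                if out_of_region
                else int(home_pref[i])
            )
            code = str(rng.choice(site_codes[site]))
            role = (
                DiagnosisRole.suspected
                if suspected_only
                else DiagnosisRole(["principal", "secondary"][int(rng.integers(0, 2))])
            )
            inpatient = hospital_acquired or rng.random() < params.inpatient_prob

            if hospital_acquired:
                disp = int(rng.integers(15, 41))
                admit = anchor
                if admit + timedelta(days=disp) > win_hi:
                    admit = win_hi - timedelta(days=disp)
                event_day = admit + timedelta(days=disp)
                anchor = admit  # truth anchors at admission; excluded anyway
                diag_dates = [event_day]
                proc_dates = [event_day]
                hospitalized_on = admit
            else:
                diag_dates = [anchor]
                if rng.random() < 0.2:  # second same-group code on the claim
                    diag_dates.append(anchor)
                proc_dates = [clamp(anchor + timedelta(days=int(rng.integers(0, 8))))]
                hospitalized_on = anchor if inpatient else None

            diagnoses = [
                DiagnosisEntry(
                    icd10=str(rng.choice(site_codes[site])) if k else code,
                    documented_on=dd,
                    role=role,
                )
                for k, dd in enumerate(diag_dates)
            ]
            if rng.random() < 0.1:  # incidental suspected diagnosis, other site
                other = SiteGroup(str(rng.choice([s.value for s in SiteGroup if s != site])))
                diagnoses.append(
                    DiagnosisEntry(
                        icd10=str(rng.choice(site_codes[other])),
                        documented_on=diag_dates[0],
                        role=DiagnosisRole.suspected,
                    )
                )
            procedures = [
                ProcedureEntry(code=str(rng.choice(_EVENT_PROCEDURES)), applied_on=pd_)
                for pd_ in proc_dates
            ]
            claim_dates = diag_dates + proc_dates
            claim_month = max(claim_dates)
            factory.add(
                i,
                id1=pick_id1(i),
                id2=id2,
                setting=Setting.inpatient if inpatient else Setting.outpatient,
                facility_id=f"F{i:06d}X",
                prefecture_code=pref,
                age_group=band,
                sex=sex,
                claim_month=f"{claim_month.year:04d}-{claim_month.month:02d}",
                diagnoses=diagnoses,
                procedures=procedures,
                hospitalized_on=hospitalized_on if inpatient else None,
            )

            # upstream referral hops: diagnosis-only claims at other facilities
            hop_date = anchor
            for h, gap in enumerate(hop_gaps):
                hop_date = hop_date - timedelta(days=gap)
                if hop_date < win_lo.replace(day=1):
                    break
                factory.add(
                    i,
                    id1=pick_id1(i),
                    id2=id2,
                    setting=Setting.outpatient,
                    facility_id=f"F{i:06d}R{h}",
                    prefecture_code=pref,
                    age_group=band,
                    sex=sex,
                    claim_month=f"{hop_date.year:04d}-{hop_date.month:02d}",
                    diagnoses=[
                        DiagnosisEntry(
                            icd10=str(rng.choice(site_codes[site])),
                            documented_on=hop_date,
                            role=DiagnosisRole.principal,
                        )
                    ],
                    procedures=[],
                    hospitalized_on=None,
                )

            clean = not (hospital_acquired or suspected_only or out_of_region)
            if clean and rng.random() < params.recurrence_prob:
                # recurrent same-site fracture well after the first (>= 60 d)
                earliest = anchor + timedelta(days=60)
                if earliest <= win_hi:
                    span = (win_hi - earliest).days
                    rec = earliest + timedelta(days=int(rng.integers(0, span + 1)))
                    rec_proc = clamp(rec + timedelta(days=int(rng.integers(0, 8))))
                    factory.add(
                        i,
                        id1=pick_id1(i),
                        id2=id2,
                        setting=Setting.outpatient,
                        facility_id=f"F{i:06d}Q",
                        prefecture_code=pref,
                        age_group=band,
                        sex=sex,
                        claim_month=f"{rec_proc.year:04d}-{rec_proc.month:02d}",
                        diagnoses=[
                            DiagnosisEntry(
                                icd10=str(rng.choice(site_codes[site])),
                                documented_on=rec,
                                role=DiagnosisRole.principal,
                            )
                        ],
                        procedures=[
                            ProcedureEntry(
                                code=str(rng.choice(_EVENT_PROCEDURES)), applied_on=rec_proc
                            )
                        ],
                        hospitalized_on=None,
                    )

            truth.events.append(
                TrueEvent(
                    patient_index=i,
                    site=site,
                    anchor_date=anchor,
                    hop_gaps=hop_gaps,
                    age_group=band,
                    sex=sex,
                    hospital_acquired=hospital_acquired,
                    suspected_only=suspected_only,
                    out_of_region=out_of_region,
                )
            )

        # non-fracture noise claims
        n_noise = int(rng.poisson(params.noise_claims_per_patient))
        for _ in range(n_noise):
            y, m = months[int(rng.integers(0, n_months))]
            d = random_day(y, m)
            pref = (
                int(rng.choice(_NOISE_PREFS))
                if rng.random() < params.out_of_region_prob
                else int(home_pref[i])
            )
            procedures = []
            if rng.random() < 0.5:
                procedures = [
                    ProcedureEntry(code=str(rng.choice(_NOISE_PROCEDURES)), applied_on=d)
                ]
            factory.add(
                i,
                id1=pick_id1(i),
                id2=id2,
                setting=Setting.outpatient,
                facility_id=f"F{i:06d}N",
                prefecture_code=pref,
                age_group=band,
                sex=sex,
                claim_month=f"{y:04d}-{m:02d}",
                diagnoses=[
                    DiagnosisEntry(
                        icd10=str(rng.choice(_NOISE_ICD10)),
                        documented_on=d,
                        role=DiagnosisRole(
                            ["principal", "secondary"][int(rng.integers(0, 2))]
                        ),
                    )
                ],
                procedures=procedures,
                hospitalized_on=None,
            )

    order = rng.permutation(len(factory.claims))
    claims = [factory.claims[j] for j in order]
    return claims, truth


def expected_cases(truth: GroundTruth, config: StudyConfig) -> list[FractureCase]:
    """The accepted case set implied by the planted truth — the independent
    oracle the pipeline is compared against.

    Applies the ascertainment rules directly to the planted flags: drop
    hospital-acquired (date-spread rule), suspected-only (diagnosis-role
    rule) and out-of-region events; resolve the first visit by walking the
    referral gaps, stopping at the first hop that exceeds the lookback or
    falls before the claim window; keep only first visits inside the case
    window.
    """
    lo, hi = config.case_window
    visible_from = config.claim_window[0].replace(day=1)
    cases: list[FractureCase] = []
    for ev in truth.events:
        if ev.hospital_acquired or ev.suspected_only or ev.out_of_region:
            continue
        d = ev.anchor_date
        for gap in ev.hop_gaps:
            nd = d - timedelta(days=gap)
            if gap > config.lookback_days or nd < visible_from:
                break
            d = nd
        if not (lo <= d <= hi):
            continue
        cases.append(
            FractureCase(
                patient=truth.patient_key(ev.patient_index),
                site=ev.site,
                first_visit=d,
                age_group=ev.age_group,
                sex=ev.sex,
            )
        )
    cases.sort(key=lambda c: (c.patient, c.site.value, c.first_visit))
    return cases
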