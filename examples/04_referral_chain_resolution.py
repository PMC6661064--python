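"""How the 14-day cross-facility lookback resolves referral chains.

Run:  python examples/04_referral_chain_resolution.py
"""

from datetime import date, timedelta

from claimcase import StudyConfig
from claimcase.case_builder import BLookupIndex, resolve_first_visit
from claimcase.code_maps import SiteGroup
from claimcase.extraction import Dataset
from claimcase.model import (
    AgeBand,
    CandidateEvent,
    ClaimRecord,
    DiagnosisEntry,
    DiagnosisRole,
    Setting,
    Sex,
)

config = StudyConfig()
anchor = date(2014, 6, 20)  # treatment claim at the hospital (Dataset A)


def b_claim(claim_id, facility, day):
    return ClaimRecord(
        claim_id=claim_id, id1="a", id2="x", setting=Setting.outpatient,
        facility_id=facility, prefecture_code=13, age_group=AgeBand.A40_64,
        sex=Sex.M, claim_month=f"{day.year}-{day.month:02d}",
        diagnoses=[DiagnosisEntry("S62.0", day, DiagnosisRole.principal)],
    )


event = CandidateEvent(
    patient="P:1:a", site=SiteGroup.HandBone, claim_id="cA", facility_id="HOSP",
    diagnosis_dates=frozenset({anchor}), procedure_dates=frozenset({anchor}),
    hospitalized_on=None, age_group=AgeBand.A40_64, sex=Sex.M,
)

for label, gaps in [("intact chain", (10, 9)), ("broken chain", (10, 15))]:
    claims, day = [], anchor
    for j, g in enumerate(gaps):
        day -= timedelta(days=g)
        claims.append(b_claim(f"b{j}", f"CLINIC{j}", day))
    index = BLookupIndex(Dataset(claims=claims, patient_keys={c.claim_id: "P:1:a" for c in claims}))
    visit = resolve_first_visit(event, index, config)
    print(f"{label}: clinic visits at gaps {gaps} days before {anchor}")
    print(f"  resolved first-visit date: {visit.first_visit}")

# With hops of 10 then 9 days (each within the 14-day lookback) the date walks
# back to the first clinic visit, 19 days before the treatment claim.  A 15-day
# hop breaks the chain: the date stops at the last reachable visit.
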