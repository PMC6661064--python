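from datetime import date

import pytest

from claimcase import StudyConfig
from claimcase.model import (
    AgeBand,
    ClaimRecord,
    DiagnosisEntry,
    DiagnosisRole,
    ProcedureEntry,
    Setting,
    Sex,
)


@pytest.fixture(scope="session")
def config() -> StudyConfig:
    return StudyConfig()


@pytest.fixture
def make_claim():
    """Compact claim factory: diagnoses/procedures given as shorthand tuples."""

    counter = {"n": 0}

    def _make(
        dx=(),  # iterable of (icd10, iso-date, role)
        px=(),  # iterable of (code, iso-date)
        id1="a",
        id2="x",
        prefecture=13,
        setting="outpatient",
        facility="F1",
        age="40-64",
        sex="M",
        month=None,
        hospitalized=None,
        claim_id=None,
    ) -> ClaimRecord:
        counter["n"] += 1
        diagnoses = [
            DiagnosisEntry(c, date.fromisoformat(d), DiagnosisRole(r)) for c, d, r in dx
        ]
        procedures = [ProcedureEntry(c, date.fromisoformat(d)) for c, d in px]
        if month is None:
            dates = [e.documented_on for e in diagnoses] + [p.applied_on for p in procedures]
            anchor = max(dates) if dates else date(2014, 6, 1)
            month = f"{anchor.year:04d}-{anchor.month:02d}"
        return ClaimRecord(
            claim_id=claim_id or f"c{counter['n']:04d}",
            id1=id1,
            id2=id2,
            setting=Setting(setting),
            facility_id=facility,
            prefecture_code=prefecture,
            age_group=AgeBand(age),
            sex=Sex(sex),
            claim_month=month,
            diagnoses=diagnoses,
            procedures=procedures,
            hospitalized_on=date.fromisoformat(hospitalized) if hospitalized else None,
        )

    return _make
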