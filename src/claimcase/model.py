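"""Core data model for monthly health-insurance claims and derived case objects.

A claim (receipt) is the monthly billing document one provider submits for one
patient.  It carries two hashed patient identifiers (ID1, ID2), the facility
and its prefecture, coarse demographics (an age-group code and sex), a list of
diagnosis entries (ICD-10 code, documentation date, and a role flag —
``suspected`` diagnoses are recorded to justify testing and never count toward
case ascertainment), a list of procedure entries with application dates, and,
for inpatient claims, the hospitalization date.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from datetime import date

__all__ = [
    "AgeBand",
    "Sex",
    "Setting",
    "DiagnosisRole",
    "DiagnosisEntry",
    "ProcedureEntry",
    "ClaimRecord",
    "CandidateEvent",
    "FractureCase",
    "month_start",
    "month_end",
]


class AgeBand(str, enum.Enum):
    """The five NDB-style age bands used for stratification."""

    A0_19 = "0-19"
    A20_39 = "20-39"
    A40_64 = "40-64"
    A65_79 = "65-79"
    A80 = "80+"


class Sex(str, enum.Enum):
    M = "M"
    F = "F"


class Setting(str, enum.Enum):
    inpatient = "inpatient"
    outpatient = "outpatient"


class DiagnosisRole(str, enum.Enum):
    principal = "principal"
    secondary = "secondary"
    suspected = "suspected"


@dataclass(frozen=True)
class DiagnosisEntry:
    icd10: str
    documented_on: date
    role: DiagnosisRole


@dataclass(frozen=True)
class ProcedureEntry:
    code: str
    applied_on: date


def month_start(year_month: str) -> date:
    y, m = year_month.split("-")
    return date(int(y), int(m), 1)


def month_end(year_month: str) -> date:
    from calendar import monthrange

    d = month_start(year_month)
    return date(d.year, d.month, monthrange(d.year, d.month)[1])


@dataclass
class ClaimRecord:
    """One monthly claim.

    Invariants (checked by :meth:`validate`): ``claim_month`` is ``YYYY-MM``;
    no entry date falls after the end of the claim month (dates may precede it
    — a diagnosis documented late in March can appear on an April claim);
    ``hospitalized_on`` is present only on inpatient claims.
    """

    claim_id: str
    id1: str
    id2: str
    setting: Setting
    facility_id: str
    prefecture_code: int
    age_group: AgeBand
    sex: Sex
    claim_month: str
    diagnoses: list[DiagnosisEntry] = field(default_factory=list)
    procedures: list[ProcedureEntry] = field(default_factory=list)
    hospitalized_on: date | None = None

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty if the record is valid)."""
        problems: list[str] = []
        if not self.claim_id:
            problems.append("empty claim_id")
        if not (1 <= self.prefecture_code <= 47):
            problems.append(f"prefecture_code {self.prefecture_code} outside 1-47")
        try:
            end = month_end(self.claim_month)
        except Exception:
            problems.append(f"invalid claim_month {self.claim_month!r}")
            return problems
        for dx in self.diagnoses:
            if dx.documented_on > end:
                problems.append(f"diagnosis date {dx.documented_on} after claim month end")
        for px in self.procedures:
            if px.applied_on > end:
                problems.append(f"procedure date {px.applied_on} after claim month end")
        if self.hospitalized_on is not None and self.setting is not Setting.inpatient:
            problems.append("hospitalized_on on an outpatient claim")
        return problems


@dataclass
class CandidateEvent:
    """One (claim, site group) fracture candidate from Dataset A.

    Carries the three kinds of key dates used by the date-spread exclusion and
    first-visit resolution: the earliest documentation date of the qualifying
    diagnoses for this site on the claim, every procedure application date, and
    the hospitalization date when present.
    """

    patient: str
    site: "SiteGroup"  # noqa: F821 - imported lazily to avoid a cycle
    claim_id: str
    facility_id: str
    diagnosis_dates: frozenset[date]
    procedure_dates: frozenset[date]
    hospitalized_on: date | None
    age_group: AgeBand
    sex: Sex

    def key_dates(self) -> list[date]:
        """The dates entering the spread rule: earliest diagnosis date, each
        procedure date, and the hospitalization date if present."""
        dates = [min(self.diagnosis_dates)]
        dates.extend(sorted(self.procedure_dates))
        if self.hospitalized_on is not None:
            dates.append(self.hospitalized_on)
        return dates


@dataclass(frozen=True)
class FractureCase:
    """An accepted first-incidence fracture case."""

    patient: str
    site: "SiteGroup"  # noqa: F821
    first_visit: date
    age_group: AgeBand
    sex: Sex
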