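"""Reading and writing claims bundles.

A bundle is a directory of three co-keyed CSV tables (the interchange format
of this package, not the raw Japanese receipt format):

* ``claims.csv`` — one row per claim: ``claim_id, id1, id2, setting,
  facility_id, prefecture_code, age_group, sex, claim_month, hospitalized_on``
* ``diagnoses.csv`` — one row per diagnosis entry: ``claim_id, icd10,
  documented_on, role``
* ``procedures.csv`` — one row per procedure entry: ``claim_id, code,
  applied_on``

Dates are ISO-8601; ``hospitalized_on`` is empty for outpatient claims.
Malformed claims are collected into a rejects report rather than silently
dropped; read/write round-trips are the identity on the data model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import pandas as pd

from .model import (
    AgeBand,
    ClaimRecord,
    DiagnosisEntry,
    DiagnosisRole,
    ProcedureEntry,
    Setting,
    Sex,
)

__all__ = ["ReadResult", "RejectedRow", "read_claims", "write_claims"]

_CLAIM_COLS = [
    "claim_id", "id1", "id2", "setting", "facility_id", "prefecture_code",
    "age_group", "sex", "claim_month", "hospitalized_on",
]
_DIAG_COLS = ["claim_id", "icd10", "documented_on", "role"]
_PROC_COLS = ["claim_id", "code", "applied_on"]


@dataclass(frozen=True)
class RejectedRow:
    claim_id: str
    reason: str


@dataclass
class ReadResult:
    records: list[ClaimRecord] = field(default_factory=list)
    rejects: list[RejectedRow] = field(default_factory=list)

    @property
    def n_input_rows(self) -> int:
        return len(self.records) + len(self.rejects)


def _require_columns(df: pd.DataFrame, cols: list[str], name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{name} is missing required columns: {missing}")


def _parse_date(value: str) -> date:
    return date.fromisoformat(str(value))


def read_claims(path: str | Path) -> ReadResult:
    """Read a claims bundle directory into validated :class:`ClaimRecord` s.

    Row counts are conserved: every claim row ends up either in ``records`` or
    in ``rejects`` with a reason.  A missing required column is fatal; a
    malformed value (bad date, unknown role, invalid month) rejects only the
    claim that carries it.
    """
    path = Path(path)
    claims = pd.read_csv(path / "claims.csv", dtype=str, keep_default_na=False)
    diags = pd.read_csv(path / "diagnoses.csv", dtype=str, keep_default_na=False)
    procs = pd.read_csv(path / "procedures.csv", dtype=str, keep_default_na=False)
    _require_columns(claims, _CLAIM_COLS, "claims.csv")
    _require_columns(diags, _DIAG_COLS, "diagnoses.csv")
    _require_columns(procs, _PROC_COLS, "procedures.csv")

    diags_by_claim: dict[str, list] = {}
    for row in diags.itertuples(index=False):
        diags_by_claim.setdefault(row.claim_id, []).append(row)
    procs_by_claim: dict[str, list] = {}
    for row in procs.itertuples(index=False):
        procs_by_claim.setdefault(row.claim_id, []).append(row)

    result = ReadResult()
    seen: set[str] = set()
    for row in claims.itertuples(index=False):
        cid = row.claim_id
        try:
            if cid in seen:
                raise ValueError("duplicate claim_id")
            seen.add(cid)
            dx_entries = [
                DiagnosisEntry(
                    icd10=d.icd10,
                    documented_on=_parse_date(d.documented_on),
                    role=DiagnosisRole(d.role),
                )
                for d in diags_by_claim.get(cid, [])
            ]
            px_entries = [
                ProcedureEntry(code=p.code, applied_on=_parse_date(p.applied_on))
                for p in procs_by_claim.get(cid, [])
            ]
            record = ClaimRecord(
                claim_id=cid,
                id1=row.id1,
                id2=row.id2,
                setting=Setting(row.setting),
                facility_id=row.facility_id,
                prefecture_code=int(row.prefecture_code),
                age_group=AgeBand(row.age_group),
                sex=Sex(row.sex),
                claim_month=row.claim_month,
                diagnoses=dx_entries,
                procedures=px_entries,
                hospitalized_on=_parse_date(row.hospitalized_on)
                if row.hospitalized_on
                else None,
            )
            problems = record.validate()
            if problems:
                raise ValueError("; ".join(problems))
            if not record.id1 or not record.id2:
                raise ValueError("empty patient identifier")
        except (ValueError, KeyError) as exc:
            result.rejects.append(RejectedRow(claim_id=cid, reason=str(exc)))
            continue
        result.records.append(record)
    return result


def write_claims(records: list[ClaimRecord], path: str | Path) -> None:
    """Write *records* as a claims bundle such that :func:`read_claims` inverts it."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    claim_rows, diag_rows, proc_rows = [], [], []
    for r in records:
        claim_rows.append(
            {
                "claim_id": r.claim_id,
                "id1": r.id1,
                "id2": r.id2,
                "setting": r.setting.value,
                "facility_id": r.facility_id,
                "prefecture_code": r.prefecture_code,
                "age_group": r.age_group.value,
                "sex": r.sex.value,
                "claim_month": r.claim_month,
                "hospitalized_on": r.hospitalized_on.isoformat() if r.hospitalized_on else "",
            }
        )
        for d in r.diagnoses:
            diag_rows.append(
                {
                    "claim_id": r.claim_id,
                    "icd10": d.icd10,
                    "documented_on": d.documented_on.isoformat(),
                    "role": d.role.value,
                }
            )
        for p in r.procedures:
            proc_rows.append(
                {
                    "claim_id": r.claim_id,
                    "code": p.code,
                    "applied_on": p.applied_on.isoformat(),
                }
            )
    pd.DataFrame(claim_rows, columns=_CLAIM_COLS).to_csv(path / "claims.csv", index=False)
    pd.DataFrame(diag_rows, columns=_DIAG_COLS).to_csv(path / "diagnoses.csv", index=False)
    pd.DataFrame(proc_rows, columns=_PROC_COLS).to_csv(path / "procedures.csv", index=False)
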