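"""Building the two interim extracts, Dataset A and Dataset B.

Dataset A ("data for extracting cases") keeps claims that simultaneously
(1) come from a facility in the study region, (2) carry at least one of the
nine fracture-specific procedure codes, (3) carry a fracture-site ICD-10 code
as a principal or secondary — never merely suspected — diagnosis, and
(4) fall inside the claim window.  Dataset B ("data for refining the date of
the first visit") keeps claims meeting (1), (3) and (4) that are NOT in A:
diagnosis-only claims, typically from the referring clinic a patient saw days
before the treating facility.  A and B are disjoint by construction.

The window is enforced on the claim month (claims are monthly billing
documents; a diagnosis documented in late March legitimately appears on an
April claim).  Both extracts are setting-agnostic (inpatient and outpatient).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .code_maps import SiteCodeMap, default_site_code_map, is_fracture_procedure
from .config import StudyConfig
from .model import ClaimRecord, DiagnosisRole, month_start
from .code_maps import SiteGroup

__all__ = ["Dataset", "has_qualifying_diagnosis", "build_dataset_a", "build_dataset_b"]


@dataclass
class Dataset:
    """An interim extract: claims plus their patient keys (claim_id -> id0)."""

    claims: list[ClaimRecord] = field(default_factory=list)
    patient_keys: dict[str, str] = field(default_factory=dict)

    @property
    def claim_ids(self) -> set[str]:
        return {c.claim_id for c in self.claims}


def has_qualifying_diagnosis(
    claim: ClaimRecord, code_map: SiteCodeMap | None = None
) -> set[SiteGroup]:
    """Site groups for which the claim carries a principal/secondary fracture
    diagnosis.  Suspected-role diagnoses never contribute; unmapped or
    non-fracture codes are ignored."""
    code_map = code_map or default_site_code_map()
    sites: set[SiteGroup] = set()
    for dx in claim.diagnoses:
        if dx.role is DiagnosisRole.suspected:
            continue
        try:
            group = code_map.classify(dx.icd10)
        except ValueError:
            continue
        if group is not None:
            sites.add(group)
    return sites


def _in_window(claim: ClaimRecord, config: StudyConfig) -> bool:
    m = month_start(claim.claim_month)
    lo, hi = config.claim_window
    return lo.replace(day=1) <= m <= hi


def _in_region(claim: ClaimRecord, config: StudyConfig) -> bool:
    return claim.prefecture_code in config.region_prefectures


def build_dataset_a(
    claims: list[ClaimRecord],
    patient_keys: dict[str, str],
    config: StudyConfig,
    code_map: SiteCodeMap | None = None,
) -> Dataset:
    """Extract Dataset A: in-region, fracture procedure + qualifying diagnosis,
    in-window.  Order-stable."""
    code_map = code_map or default_site_code_map()
    kept = [
        c
        for c in claims
        if _in_region(c, config)
        and _in_window(c, config)
        and any(is_fracture_procedure(p.code) for p in c.procedures)
        and has_qualifying_diagnosis(c, code_map)
    ]
    return Dataset(claims=kept, patient_keys={c.claim_id: patient_keys[c.claim_id] for c in kept})


def build_dataset_b(
    claims: list[ClaimRecord],
    dataset_a: Dataset,
    patient_keys: dict[str, str],
    config: StudyConfig,
    code_map: SiteCodeMap | None = None,
) -> Dataset:
    """Extract Dataset B: in-region, qualifying diagnosis, in-window, and not
    already in Dataset A.  No procedure requirement."""
    code_map = code_map or default_site_code_map()
    a_ids = dataset_a.claim_ids
    kept = [
        c
        for c in claims
        if c.claim_id not in a_ids
        and _in_region(c, config)
        and _in_window(c, config)
        and has_qualifying_diagnosis(c, code_map)
    ]
    return Dataset(claims=kept, patient_keys={c.claim_id: patient_keys[c.claim_id] for c in kept})
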