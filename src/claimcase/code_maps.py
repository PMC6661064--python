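"""Fracture code tables: surgical procedure codes and ICD-10 site-group classification.

Case ascertainment in Japanese health-insurance claims rests on two code sets:

* a closed list of nine fracture-specific treatment procedure codes from the
  national claim (receipt) system — reduction, fixation, arthrodesis and
  arthroplasty codes (K044 … K082);
* a grouping of ICD-10 chapter-S injury codes into 11 fracture site groups
  (rib/sternum through foot), the unit at which first-incidence cases are
  deduplicated and tabulated.

The site map is shipped as an editable CSV (``data/site_codes.csv``) with one
rule per row.  A rule pattern is either a 3-character ICD-10 category (``S42``,
matching the bare category and every subcode), a single 4-character subcode
(``S52.5``), or a terminal-digit range (``S52.1-4``) expanded at load time.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = [
    "SiteGroup",
    "SiteCodeMap",
    "FRACTURE_PROCEDURE_CODES",
    "classify_site",
    "is_fracture_procedure",
    "load_site_code_map",
    "normalize_icd10",
    "InvalidCodeError",
]


class SiteGroup(str, Enum):
    """The 11 fracture site groups used for deduplication and reporting."""

    RibSternum = "RibSternum"
    ClavicleScapulaHumerus = "ClavicleScapulaHumerus"
    RadiusUlnaDistal = "RadiusUlnaDistal"
    RadiusUlnaOther = "RadiusUlnaOther"
    HandBone = "HandBone"
    FemurHip = "FemurHip"
    FemurOther = "FemurOther"
    PatellaTibiaFibula = "PatellaTibiaFibula"
    Ankle = "Ankle"
    FootToe = "FootToe"
    FootOther = "FootOther"

    @property
    def label(self) -> str:
        return _SITE_LABELS[self]


_SITE_LABELS = {
    SiteGroup.RibSternum: "Rib or sternum",
    SiteGroup.ClavicleScapulaHumerus: "Clavicle, scapula, or humerus",
    SiteGroup.RadiusUlnaDistal: "Radius or ulna - distal radius",
    SiteGroup.RadiusUlnaOther: "Radius or ulna - other",
    SiteGroup.HandBone: "Hand bone",
    SiteGroup.FemurHip: "Femur - hip",
    SiteGroup.FemurOther: "Femur - other",
    SiteGroup.PatellaTibiaFibula: "Patella, tibia, or fibula",
    SiteGroup.Ankle: "Ankle",
    SiteGroup.FootToe: "Foot bone - toe",
    SiteGroup.FootOther: "Foot bone - other",
}

#: The nine fracture-specific treatment procedure codes (claim-system codes).
FRACTURE_PROCEDURE_CODES: frozenset[str] = frozenset(
    {"K044", "K045", "K046", "K046-2", "K073", "K073-2", "K078", "K081", "K082"}
)


class InvalidCodeError(ValueError):
    """Raised for a string that is not a plausible ICD-10 code."""


_ICD10_RE = re.compile(r"^[A-Z][0-9]{2}[0-9]*$")
_RANGE_RE = re.compile(r"^([A-Z][0-9]{2})\.([0-9])-([0-9])$")
_SUBCODE_RE = re.compile(r"^([A-Z][0-9]{2})\.([0-9])$")
_CATEGORY_RE = re.compile(r"^[A-Z][0-9]{2}$")


def normalize_icd10(code: str) -> str:
    """Strip the dot and upper-case an ICD-10 code; validate its shape.

    ``"S52.5"`` and ``"s525"`` both normalize to ``"S525"``.  Raises
    :class:`InvalidCodeError` for anything that is not a letter followed by
    digits (at least the two digits of the category).
    """
    cleaned = code.strip().upper().replace(".", "")
    if not _ICD10_RE.match(cleaned):
        raise InvalidCodeError(f"not an ICD-10 code: {code!r}")
    return cleaned


@dataclass(frozen=True)
class SiteCodeMap:
    """Ordered classification rules mapping ICD-10 codes to site groups.

    ``subcodes`` holds exact dotless 4-character rules (``"S525"``),
    ``categories`` holds 3-character category rules (``"S42"``) that match the
    bare category and all ten subcodes.  Subcode rules take precedence, and the
    constructor rejects any pair of rules that would classify one concrete code
    into two groups.
    """

    subcodes: dict[str, SiteGroup] = field(default_factory=dict)
    categories: dict[str, SiteGroup] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sub, group in self.subcodes.items():
            cat = sub[:3]
            if cat in self.categories and self.categories[cat] != group:
                raise ValueError(
                    f"overlapping rules: {sub} -> {group.value} vs "
                    f"category {cat} -> {self.categories[cat].value}"
                )

    def classify(self, icd10_code: str) -> SiteGroup | None:
        """Return the unique site group for *icd10_code*, or ``None``.

        Codes with a 5th character are matched by 4-character truncation;
        a bare 3-character code matches only a category rule.
        """
        code = normalize_icd10(icd10_code)
        if len(code) > 4:
            code = code[:4]
        if len(code) == 4:
            hit = self.subcodes.get(code)
            if hit is not None:
                return hit
        return self.categories.get(code[:3])

    def all_subcodes(self, group: SiteGroup) -> set[str]:
        """All concrete dotless 4-character codes classified into *group*."""
        out = {c for c, g in self.subcodes.items() if g is group}
        for cat, g in self.categories.items():
            if g is group:
                out |= {f"{cat}{d}" for d in "0123456789"}
        return out


def _expand_pattern(pattern: str) -> tuple[list[str], list[str]]:
    """Expand one CSV rule pattern into (subcode rules, category rules)."""
    pattern = pattern.strip().upper()
    m = _RANGE_RE.match(pattern)
    if m:
        cat, lo, hi = m.group(1), int(m.group(2)), int(m.group(3))
        if lo > hi:
            raise ValueError(f"empty range: {pattern}")
        return [f"{cat}{d}" for d in range(lo, hi + 1)], []
    m = _SUBCODE_RE.match(pattern)
    if m:
        return [f"{m.group(1)}{m.group(2)}"], []
    if _CATEGORY_RE.match(pattern):
        return [], [pattern]
    raise ValueError(f"unrecognized code-map pattern: {pattern!r}")


def load_site_code_map(path: str | Path | None = None) -> SiteCodeMap:
    """Load the site code map from *path*, or the bundled default table."""
    if path is None:
        with resources.files("claimcase.data").joinpath("site_codes.csv").open() as fh:
            df = pd.read_csv(fh, dtype=str)
    else:
        df = pd.read_csv(path, dtype=str)
    missing = {"pattern", "site_group"} - set(df.columns)
    if missing:
        raise ValueError(f"code-map file missing columns: {sorted(missing)}")
    subcodes: dict[str, SiteGroup] = {}
    categories: dict[str, SiteGroup] = {}
    for row in df.itertuples(index=False):
        group = SiteGroup(row.site_group)
        subs, cats = _expand_pattern(row.pattern)
        for s in subs:
            if s in subcodes and subcodes[s] != group:
                raise ValueError(f"overlapping subcode rule for {s}")
            subcodes[s] = group
        for c in cats:
            if c in categories and categories[c] != group:
                raise ValueError(f"overlapping category rule for {c}")
            categories[c] = group
    return SiteCodeMap(subcodes=subcodes, categories=categories)


_DEFAULT_MAP: SiteCodeMap | None = None


def default_site_code_map() -> SiteCodeMap:
    global _DEFAULT_MAP
    if _DEFAULT_MAP is None:
        _DEFAULT_MAP = load_site_code_map()
    return _DEFAULT_MAP


def classify_site(icd10_code: str, code_map: SiteCodeMap | None = None) -> SiteGroup | None:
    """Classify an ICD-10 code into a fracture site group (or ``None``)."""
    return (code_map or default_site_code_map()).classify(icd10_code)


def is_fracture_procedure(code: str) -> bool:
    """True iff *code* is one of the nine fracture-specific procedure codes.

    Membership is exact string match; there are no prefix semantics
    (``"K046-2"`` and ``"K046"`` are distinct codes).
    """
    return code.strip().upper() in FRACTURE_PROCEDURE_CODES
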