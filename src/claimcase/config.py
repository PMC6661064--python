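"""Study configuration: observation windows, lookback/spread limits, region, suppression.

The defaults encode the Kanto-area fracture study design: claims billed for
April 2013 through March 2016, cases counted between 2013-04-17 and 2016-03-15
(the claim window extends beyond the case window on both ends so that the
14-day cross-facility lookback and first-incidence washout have data to work
with at the edges), a 14-day date-spread limit to drop hospital-acquired
fractures, the seven Kanto prefectures (JIS codes 8-14: Ibaraki, Tochigi,
Gunma, Saitama, Chiba, Tokyo, Kanagawa), and a small-cell suppression
threshold of 10 cases imposed by the database's terms of use.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date
from pathlib import Path

import yaml

__all__ = ["StudyConfig", "load_config", "KANTO_PREFECTURES"]

KANTO_PREFECTURES: frozenset[int] = frozenset({8, 9, 10, 11, 12, 13, 14})


@dataclass(frozen=True)
class StudyConfig:
    claim_window: tuple[date, date] = (date(2013, 4, 1), date(2016, 3, 31))
    case_window: tuple[date, date] = (date(2013, 4, 17), date(2016, 3, 15))
    lookback_days: int = 14
    spread_limit_days: int = 14
    region_prefectures: frozenset[int] = KANTO_PREFECTURES
    suppression_threshold: int = 10
    #: iterate the cross-facility lookback to a fixpoint (multi-hop referral
    #: chains resolve to the true first contact); False = single step
    chain_lookback: bool = True

    def __post_init__(self) -> None:
        cs, ce = self.claim_window
        ks, ke = self.case_window
        if cs > ce or ks > ke:
            raise ValueError("window start after end")
        if ks < cs or ke > ce:
            raise ValueError("case_window must lie within claim_window")
        if self.lookback_days <= 0 or self.spread_limit_days <= 0:
            raise ValueError("lookback_days and spread_limit_days must be positive")
        if self.suppression_threshold < 0:
            raise ValueError("suppression_threshold must be >= 0")

    def with_overrides(self, **kwargs) -> "StudyConfig":
        return replace(self, **kwargs)


def _parse_date(value) -> date:
    if isinstance(value, date):
        return value
    return date.fromisoformat(str(value))


def load_config(path: str | Path | None = None) -> StudyConfig:
    """Load a :class:`StudyConfig` from a YAML file.

    Missing keys (or ``path=None`` / an empty file) fall back to the study
    defaults above.  Recognized keys: ``claim_window`` and ``case_window``
    (two-element lists of ISO dates, inclusive on both ends),
    ``lookback_days``, ``spread_limit_days``, ``region_prefectures``,
    ``suppression_threshold``, ``chain_lookback``.
    """
    if path is None:
        return StudyConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config file must contain a YAML mapping")
    kwargs = {}
    for key in ("claim_window", "case_window"):
        if key in raw:
            lo, hi = raw[key]
            kwargs[key] = (_parse_date(lo), _parse_date(hi))
    for key in ("lookback_days", "spread_limit_days", "suppression_threshold"):
        if key in raw:
            kwargs[key] = int(raw[key])
    if "region_prefectures" in raw:
        kwargs["region_prefectures"] = frozenset(int(p) for p in raw["region_prefectures"])
    if "chain_lookback" in raw:
        kwargs["chain_lookback"] = bool(raw["chain_lookback"])
    unknown = set(raw) - {
        "claim_window", "case_window", "lookback_days", "spread_limit_days",
        "region_prefectures", "suppression_threshold", "chain_lookback",
    }
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return StudyConfig(**kwargs)
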