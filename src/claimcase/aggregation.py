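"""Stratified tabulation, small-cell suppression, and incidence reporting.

Cases are cross-tabulated by age band, sex, fracture site group and calendar
month.  Calendar months are pooled across years (one Jan-Dec axis for the
roughly three-year window), which is the natural axis for seasonal-variation
questions; per-year tabulation is available via ``pool_years=False``.

The database's terms of use forbid reporting strata with ten or fewer cases,
so the public rendering replaces any count at or below the suppression
threshold with the bound ``"<=10"``.  True counts are retained internally for
margin-conservation checks but never serialized into the public report.
Because the study window starts and ends mid-month, each pooled calendar month
covers a different number of days; :func:`days_in_month_within` computes that
exposure row.

Incidence rates per 100,000 person-years are an extension beyond the raw
counts: denominators come from an external population table (thousands of
residents per age band and sex) multiplied by the window length in years.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .code_maps import SiteGroup
from .config import StudyConfig
from .model import AgeBand, FractureCase, Sex

__all__ = [
    "StratifiedTable",
    "PopulationTable",
    "tabulate",
    "suppress_small_cells",
    "days_in_month_within",
    "consistency_report",
    "incidence_rates",
    "render_report",
    "load_population",
]

_MONTH_NAMES = ["Jan", "Feb", "Mar", "Apr", "May", "Jun",
                "Jul", "Aug", "Sep", "Oct", "Nov", "Dec"]


@dataclass
class StratifiedTable:
    """Counts keyed by (age band, sex, site group, calendar month 1-12).

    ``counts`` holds the true counts; ``suppressed`` marks cells whose true
    count must not be published.  Only the long-form accessors below and
    :func:`render_report` should be used for output.
    """

    counts: pd.Series  # MultiIndex (age_group, sex, site, month) -> int
    window: tuple[date, date]
    threshold: int | None = None
    suppressed: pd.Series | None = None  # same index, bool

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def margin(self, *levels: str) -> pd.Series:
        """True-count margin summed over the remaining axes (pre-suppression)."""
        return self.counts.groupby(level=list(levels)).sum()


def _full_index() -> pd.MultiIndex:
    return pd.MultiIndex.from_product(
        [
            [a.value for a in AgeBand],
            [s.value for s in Sex],
            [g.value for g in SiteGroup],
            range(1, 13),
        ],
        names=["age_group", "sex", "site", "month"],
    )


def tabulate(cases: list[FractureCase], config: StudyConfig) -> StratifiedTable:
    """Cross-tabulate accepted cases; every case increments exactly one cell.

    Raises ``ValueError`` for a case outside the case window — such a case
    indicates an upstream deduplication bug, not a reporting choice.
    """
    lo, hi = config.case_window
    for c in cases:
        if not (lo <= c.first_visit <= hi):
            raise ValueError(f"case outside case_window: {c}")
    idx = _full_index()
    counts = pd.Series(0, index=idx, dtype=int)
    if cases:
        df = pd.DataFrame(
            {
                "age_group": [c.age_group.value for c in cases],
                "sex": [c.sex.value for c in cases],
                "site": [c.site.value for c in cases],
                "month": [c.first_visit.month for c in cases],
            }
        )
        grouped = df.groupby(["age_group", "sex", "site", "month"]).size()
        counts = counts.add(grouped.reindex(idx, fill_value=0), fill_value=0).astype(int)
    return StratifiedTable(counts=counts, window=config.case_window)


def suppress_small_cells(table: StratifiedTable, threshold: int) -> StratifiedTable:
    """Mark every cell with true count <= *threshold* as suppressed.

    Suppression is cell-wise only; margins are still published exactly, as in
    the source table (no complementary suppression).
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    return StratifiedTable(
        counts=table.counts,
        window=table.window,
        threshold=threshold,
        suppressed=table.counts <= threshold,
    )


def days_in_month_within(window: tuple[date, date]) -> dict[int, int]:
    """Days of each calendar month (pooled across years) inside the inclusive window."""
    start, end = window
    if start > end:
        raise ValueError("window start after end")
    days = pd.date_range(start, end, freq="D")
    out = {m: 0 for m in range(1, 13)}
    for m, n in days.month.value_counts().items():
        out[int(m)] = int(n)
    return out


def render_report(table: StratifiedTable) -> pd.DataFrame:
    """Public report: age-band blocks x site rows x 12 month columns, plus the
    days-of-exposure row.  Suppressed cells print ``"<=T"``; sexes pooled.

    The table must have been through :func:`suppress_small_cells` first.
    """
    if table.suppressed is None or table.threshold is None:
        raise ValueError("render_report requires a suppressed table")
    pooled = table.counts.groupby(level=["age_group", "site", "month"]).sum()
    bound = f"<={table.threshold}"
    rows = []
    for band in AgeBand:
        for site in SiteGroup:
            row: dict[str, object] = {"age_group": band.value, "site": site.label}
            for m in range(1, 13):
                n = int(pooled.loc[(band.value, site.value, m)])
                row[_MONTH_NAMES[m - 1]] = bound if n <= table.threshold else str(n)
            rows.append(row)
    days = days_in_month_within(table.window)
    rows.append(
        {"age_group": "", "site": "Number of days during the study period"}
        | {_MONTH_NAMES[m - 1]: str(days[m]) for m in range(1, 13)}
    )
    return pd.DataFrame(rows, columns=["age_group", "site"] + _MONTH_NAMES)


def consistency_report(counts: pd.DataFrame) -> dict[str, object]:
    """Marginal sums of a per-(age band, sex) count table.

    *counts* needs columns ``age_group``, ``sex``, ``cases``.  Returns the
    per-sex totals, per-age-band totals (sexes pooled), and the grand total —
    the arithmetic used to check a stratified table against published
    marginals.
    """
    required = {"age_group", "sex", "cases"}
    if not required <= set(counts.columns):
        raise ValueError(f"counts needs columns {sorted(required)}")
    by_sex = counts.groupby("sex")["cases"].sum()
    by_age = counts.groupby("age_group")["cases"].sum()
    return {
        "by_sex": {str(k): int(v) for k, v in by_sex.items()},
        "by_age_group": {str(k): int(v) for k, v in by_age.items()},
        "grand_total": int(counts["cases"].sum()),
    }


@dataclass
class PopulationTable:
    """Denominators: thousands of residents per (age band, sex)."""

    entries: dict[tuple[AgeBand, Sex], float] = field(default_factory=dict)

    def population(self, age_group: AgeBand, sex: Sex) -> float:
        return self.entries[(age_group, sex)]

    @property
    def total_thousands(self) -> float:
        return float(sum(self.entries.values()))


def load_population(path: str | Path | None = None) -> PopulationTable:
    """Load a population table; the bundled default is the Kanto-area resident
    population for the 2013-2016 study period."""
    if path is None:
        with resources.files("claimcase.data").joinpath("kanto_reference.csv").open() as fh:
            df = pd.read_csv(fh)
    else:
        df = pd.read_csv(path)
    entries = {
        (AgeBand(row.age_group), Sex(row.sex)): float(row.population_thousands)
        for row in df.itertuples(index=False)
    }
    if set(entries) != {(a, s) for a in AgeBand for s in Sex}:
        raise ValueError("population table must cover every (age band, sex) stratum")
    return PopulationTable(entries=entries)


def incidence_rates(
    table: StratifiedTable,
    population: PopulationTable,
    window: tuple[date, date] | None = None,
) -> pd.DataFrame:
    """Incidence per 100,000 person-years by (age band, sex, site).

    Person-years = population (thousands x 1000) x inclusive window length /
    365.25.  For a suppressed table, cells whose every contributing month was
    suppressed get an upper-bound rate flagged ``censored``.
    """
    start, end = window or table.window
    years = ((end - start).days + 1) / 365.25
    per_stratum = table.counts.groupby(level=["age_group", "sex", "site"]).sum()
    if table.suppressed is not None:
        all_supp = table.suppressed.groupby(level=["age_group", "sex", "site"]).all()
    else:
        all_supp = pd.Series(False, index=per_stratum.index)
    rows = []
    for (age, sex, site), n in per_stratum.items():
        pop = population.population(AgeBand(age), Sex(sex)) * 1000.0
        censored = bool(all_supp.loc[(age, sex, site)])
        if censored and table.threshold is not None:
            n = 12 * table.threshold  # upper bound: every month at the threshold
        if pop == 0:
            rate = np.nan if n == 0 else np.inf
            flag = "zero-population" if n > 0 else ""
        else:
            rate = n / (pop * years) * 1e5
            flag = "censored" if censored else ""
        rows.append(
            {"age_group": age, "sex": sex, "site": site,
             "cases": int(n), "rate_per_100k_py": rate, "flag": flag}
        )
    return pd.DataFrame(rows)
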