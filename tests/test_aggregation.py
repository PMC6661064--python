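"""Stratified tabulation, suppression, calendar accounting, margins and rates."""

from datetime import date

import numpy as np
import pandas as pd
import pytest

from claimcase import StudyConfig
from claimcase.aggregation import (
    consistency_report,
    days_in_month_within,
    incidence_rates,
    load_population,
    render_report,
    suppress_small_cells,
    tabulate,
)
from claimcase.code_maps import SiteGroup
from claimcase.model import AgeBand, FractureCase, Sex

# published Kanto-area marginals: (age band) -> (men, women)
KANTO_CASES = {
    "0-19": (79756, 34019),
    "20-39": (28985, 11329),
    "40-64": (45394, 46180),
    "65-79": (30560, 84423),
    "80+": (26580, 120825),
}
KANTO_POP_THOUSANDS = {
    "0-19": (3700, 3512),
    "20-39": (5513, 5137),
    "40-64": (7522, 7195),
    "65-79": (3563, 3961),
    "80+": (970, 1714),
}


def _case(day, site=SiteGroup.FemurHip, age="65-79", sex="F", patient="p1"):
    return FractureCase(
        patient=patient,
        site=site,
        first_visit=date.fromisoformat(day),
        age_group=AgeBand(age),
        sex=Sex(sex),
    )


def _reference_counts() -> pd.DataFrame:
    rows = []
    for band, (men, women) in KANTO_CASES.items():
        rows.append({"age_group": band, "sex": "M", "cases": men})
        rows.append({"age_group": band, "sex": "F", "cases": women})
    return pd.DataFrame(rows)


class TestTabulate:
    def test_single_case_lands_in_its_cell(self, config):
        table = tabulate([_case("2014-01-15")], config)
        assert table.counts.loc[("65-79", "F", "FemurHip", 1)] == 1
        assert table.total == 1

    def test_months_pool_across_years(self, config):
        cases = [
            _case("2014-02-10", patient="p1"),
            _case("2015-02-20", patient="p2"),
            _case("2016-02-05", patient="p3"),
        ]
        table = tabulate(cases, config)
        assert table.margin("month").loc[2] == 3

    def test_empty_case_list_is_all_zero(self, config):
        assert tabulate([], config).total == 0

    def test_case_outside_window_is_fatal(self, config):
        with pytest.raises(ValueError, match="outside case_window"):
            tabulate([_case("2016-03-20")], config)

    def test_conservation_under_every_margin(self, config):
        rng = np.random.default_rng(0)
        days = pd.date_range(*config.case_window, freq="D")
        cases = [
            _case(
                str(rng.choice(days.strftime("%Y-%m-%d"))),
                site=SiteGroup(str(rng.choice([s.value for s in SiteGroup]))),
                age=str(rng.choice([a.value for a in AgeBand])),
                sex=str(rng.choice(["M", "F"])),
                patient=f"p{i}",
            )
            for i in range(500)
        ]
        table = tabulate(cases, config)
        assert table.total == 500
        for margin in ("age_group", "sex", "site", "month"):
            assert table.margin(margin).sum() == 500


class TestSuppression:
    @pytest.mark.parametrize("count,rendered", [(10, "<=10"), (11, "11"), (0, "<=10")])
    def test_threshold_boundary(self, config, count, rendered):
        cases = [
            _case("2014-01-15", patient=f"p{i}") for i in range(count)
        ]
        table = suppress_small_cells(tabulate(cases, config), 10)
        report = render_report(table)
        row = report[(report.age_group == "65-79") & (report.site == "Femur - hip")]
        assert row["Jan"].item() == rendered

    def test_true_counts_retained_internally(self, config):
        table = suppress_small_cells(tabulate([_case("2014-01-15")], config), 10)
        assert table.counts.loc[("65-79", "F", "FemurHip", 1)] == 1
        assert bool(table.suppressed.loc[("65-79", "F", "FemurHip", 1)])

    def test_serialized_report_never_exposes_small_counts(self, config):
        """Every numeric cell of the public rendering exceeds the threshold."""
        rng = np.random.default_rng(1)
        days = pd.date_range(*config.case_window, freq="D")
        cases = [
            _case(
                str(rng.choice(days.strftime("%Y-%m-%d"))),
                site=SiteGroup(str(rng.choice([s.value for s in SiteGroup]))),
                age=str(rng.choice([a.value for a in AgeBand])),
                patient=f"p{i}",
            )
            for i in range(800)
        ]
        table = suppress_small_cells(tabulate(cases, config), 10)
        report = render_report(table)
        month_cols = report.columns[2:]
        for value in report[report.site != "Number of days during the study period"][
            month_cols
        ].to_numpy().ravel():
            if value != "<=10":
                assert int(value) > 10


class TestCalendarAccounting:
    def test_study_window_days_row(self, config):
        days = days_in_month_within(config.case_window)
        assert [days[m] for m in range(1, 13)] == [
            93, 85, 77, 74, 93, 90, 93, 93, 90, 93, 90, 93
        ]

    def test_sum_equals_inclusive_window_length(self, config):
        lo, hi = config.case_window
        days = days_in_month_within(config.case_window)
        assert sum(days.values()) == (hi - lo).days + 1 == 1064

    def test_single_month_window(self):
        days = days_in_month_within((date(2014, 1, 1), date(2014, 1, 31)))
        assert days[1] == 31 and sum(days.values()) == 31

    def test_each_month_bounded_by_window_years(self, config):
        days = days_in_month_within(config.case_window)
        lo, hi = config.case_window
        years = ((hi - lo).days + 1) / 365.25
        for m, n in days.items():
            assert 28 * int(years) <= n <= 31 * int(np.ceil(years))


class TestConsistencyReport:
    def test_reproduces_published_marginals(self):
        report = consistency_report(_reference_counts())
        assert report["by_sex"]["M"] == 211275
        assert report["by_sex"]["F"] == 296776
        assert report["grand_total"] == 508051
        assert report["by_age_group"] == {
            "0-19": 113775,
            "20-39": 40314,
            "40-64": 91574,
            "65-79": 114983,
            "80+": 147405,
        }

    def test_empty_table_all_margins_zero(self):
        report = consistency_report(pd.DataFrame(columns=["age_group", "sex", "cases"]))
        assert report["grand_total"] == 0
        assert report["by_sex"] == {} and report["by_age_group"] == {}


class TestIncidenceRates:
    def test_definitional_rate(self, config):
        """1 case, 1000 persons, one-year window -> 100 per 100,000 PY."""
        from claimcase.aggregation import PopulationTable, StratifiedTable

        cfg = StudyConfig(
            claim_window=(date(2014, 1, 1), date(2014, 12, 31)),
            case_window=(date(2014, 1, 2), date(2014, 12, 31)),
        )
        table = tabulate([_case("2014-06-15")], cfg)
        table.window = (date(2014, 1, 1), date(2014, 12, 31))
        pop = PopulationTable(
            entries={(a, s): 1.0 for a in AgeBand for s in Sex}
        )
        rates = incidence_rates(table, pop)
        hit = rates[(rates.age_group == "65-79") & (rates.sex == "F") & (rates.site == "FemurHip")]
        years = 365 / 365.25
        assert hit.rate_per_100k_py.item() == pytest.approx(100.0 / years)
        zero = rates[(rates.age_group == "0-19") & (rates.sex == "M") & (rates.site == "Ankle")]
        assert zero.rate_per_100k_py.item() == 0.0

    def test_population_table_totals(self):
        pop = load_population()
        assert pop.total_thousands == 42787
        for band, (men, women) in KANTO_POP_THOUSANDS.items():
            assert pop.population(AgeBand(band), Sex.M) == men
            assert pop.population(AgeBand(band), Sex.F) == women

    def test_overall_kanto_rate(self, config):
        """Grand-total arithmetic: 508,051 cases over 42,787 thousand persons
        and a 1064-day window is about 408 cases per 100,000 person-years."""
        person_years = 42787 * 1000 * 1064 / 365.25
        rate = 508051 / person_years * 1e5
        assert rate == pytest.approx(407.6, abs=0.05)
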