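"""Candidate events, date-spread exclusion, first-visit resolution, deduplication."""

import random
from datetime import date, timedelta

import pytest

from claimcase import StudyConfig
from claimcase.case_builder import (
    BLookupIndex,
    candidate_events,
    dedupe_first_incidence,
    passes_date_spread,
    resolve_first_visit,
)
from claimcase.code_maps import SiteGroup
from claimcase.extraction import Dataset, build_dataset_a, build_dataset_b
from claimcase.linkage import assign_patient_keys
from claimcase.model import AgeBand, CandidateEvent, Sex


def _dataset(claims):
    keys = assign_patient_keys(claims).keys
    return Dataset(claims=claims, patient_keys=keys)


def _event(diag, proc=(), hosp=None, facility="F1", patient="P:1:a", site=SiteGroup.HandBone):
    return CandidateEvent(
        patient=patient,
        site=site,
        claim_id="c1",
        facility_id=facility,
        diagnosis_dates=frozenset(date.fromisoformat(d) for d in diag),
        procedure_dates=frozenset(date.fromisoformat(d) for d in proc),
        hospitalized_on=date.fromisoformat(hosp) if hosp else None,
        age_group=AgeBand.A40_64,
        sex=Sex.M,
    )


class TestCandidateEvents:
    def test_two_codes_one_site_group_is_one_event(self, make_claim, config):
        c = make_claim(
            dx=[("S62.0", "2014-05-02", "principal"), ("S62.3", "2014-05-02", "secondary")],
            px=[("K044", "2014-05-02")],
        )
        events = candidate_events(_dataset([c]))
        assert len(events) == 1
        assert events[0].site is SiteGroup.HandBone
        assert events[0].diagnosis_dates == frozenset({date(2014, 5, 2)})

    def test_two_site_groups_are_two_events(self, make_claim, config):
        c = make_claim(
            dx=[("S52.5", "2014-05-02", "principal"), ("S72.0", "2014-05-02", "secondary")],
            px=[("K044", "2014-05-02")],
        )
        sites = {e.site for e in candidate_events(_dataset([c]))}
        assert sites == {SiteGroup.RadiusUlnaDistal, SiteGroup.FemurHip}

    def test_claim_without_qualifying_diagnosis_yields_nothing(self, make_claim):
        c = make_claim(dx=[("S52.5", "2014-05-02", "suspected")], px=[("K044", "2014-05-02")])
        assert candidate_events(_dataset([c])) == []

    def test_unlisted_procedure_dates_do_not_enter_key_dates(self, make_claim):
        c = make_claim(
            dx=[("S62.0", "2014-05-02", "principal")],
            px=[("K044", "2014-05-03"), ("D007", "2014-07-01")],
        )
        (event,) = candidate_events(_dataset([c]))
        assert event.procedure_dates == frozenset({date(2014, 5, 3)})


class TestDateSpread:
    def test_three_dates_within_limit_pass(self, config):
        ev = _event(diag=["2014-05-01"], proc=["2014-05-10"], hosp="2014-05-03")
        assert passes_date_spread(ev, config)

    def test_nineteen_day_gap_excluded(self, config):
        ev = _event(diag=["2014-05-01"], proc=["2014-05-20"])
        assert not passes_date_spread(ev, config)

    def test_single_date_always_passes(self, config):
        assert passes_date_spread(_event(diag=["2014-05-01"]), config)

    @pytest.mark.parametrize("gap,expected", [(13, True), (14, True), (15, False)])
    def test_boundary_is_strict(self, config, gap, expected):
        ev = _event(diag=["2014-05-01"], proc=[(date(2014, 5, 1) + timedelta(days=gap)).isoformat()])
        assert passes_date_spread(ev, config) is expected

    def test_spread_uses_earliest_diagnosis_date_only(self, config):
        # two documentation dates 20 d apart for the same site: only the
        # earliest enters the rule, so the event survives
        ev = _event(diag=["2014-05-01", "2014-05-21"], proc=["2014-05-02"])
        assert passes_date_spread(ev, config)


def _b_dataset(make_claim, entries):
    """entries: (facility, iso-date, icd10) diagnosis-only claims of patient a/x."""
    claims = [
        make_claim(dx=[(code, d, "principal")], facility=fac)
        for fac, d, code in entries
    ]
    return _dataset(claims)


class TestResolveFirstVisit:
    def test_no_b_claims_returns_earliest_key_date(self, make_claim, config):
        ev = _event(diag=["2014-06-10"], proc=["2014-06-12"])
        b = BLookupIndex(_dataset([]))
        assert resolve_first_visit(ev, b, config).first_visit == date(2014, 6, 10)

    def test_single_lookback_step(self, make_claim, config):
        ev = _event(diag=["2014-06-10"], site=SiteGroup.HandBone)
        b = BLookupIndex(_b_dataset(make_claim, [("F2", "2014-06-01", "S62.0")]))
        assert resolve_first_visit(ev, b, config).first_visit == date(2014, 6, 1)

    def test_chain_following_resolves_multi_hop_referral(self, make_claim, config):
        ev = _event(diag=["2014-06-10"], site=SiteGroup.HandBone)
        b = BLookupIndex(
            _b_dataset(
                make_claim,
                [("F2", "2014-06-01", "S62.0"), ("F3", "2014-05-25", "S62.1")],
            )
        )
        assert resolve_first_visit(ev, b, config).first_visit == date(2014, 5, 25)

    def test_single_step_config_stops_after_one_hop(self, make_claim, config):
        ev = _event(diag=["2014-06-10"], site=SiteGroup.HandBone)
        b = BLookupIndex(
            _b_dataset(
                make_claim,
                [("F2", "2014-06-01", "S62.0"), ("F3", "2014-05-25", "S62.1")],
            )
        )
        cfg = config.with_overrides(chain_lookback=False)
        assert resolve_first_visit(ev, b, cfg).first_visit == date(2014, 6, 1)

    def test_b_claim_outside_lookback_does_not_shift(self, make_claim, config):
        ev = _event(diag=["2014-06-21"], site=SiteGroup.HandBone)
        b = BLookupIndex(_b_dataset(make_claim, [("F2", "2014-06-01", "S62.0")]))
        assert resolve_first_visit(ev, b, config).first_visit == date(2014, 6, 21)

    def test_same_facility_b_claim_does_not_shift(self, make_claim, config):
        ev = _event(diag=["2014-06-10"], facility="F2", site=SiteGroup.HandBone)
        b = BLookupIndex(_b_dataset(make_claim, [("F2", "2014-06-01", "S62.0")]))
        assert resolve_first_visit(ev, b, config).first_visit == date(2014, 6, 10)

    def test_other_site_b_claim_does_not_shift(self, make_claim, config):
        ev = _event(diag=["2014-06-10"], site=SiteGroup.HandBone)
        b = BLookupIndex(_b_dataset(make_claim, [("F2", "2014-06-01", "S72.0")]))
        assert resolve_first_visit(ev, b, config).first_visit == date(2014, 6, 10)

    def test_demographics_follow_the_claim_fixing_the_date(self, make_claim, config):
        ev = _event(diag=["2014-06-10"], site=SiteGroup.HandBone)
        b_claims = [
            make_claim(
                dx=[("S62.0", "2014-06-01", "principal")], facility="F2", age="20-39"
            )
        ]
        visit = resolve_first_visit(ev, BLookupIndex(_dataset(b_claims)), config)
        assert visit.first_visit == date(2014, 6, 1)
        assert visit.age_group is AgeBand.A20_39

    @pytest.mark.parametrize("seed", range(10))
    def test_random_chains_match_brute_force_oracle(self, make_claim, config, seed):
        """Resolved date equals the reachable minimum of the lookback relation,
        computed by brute-force fixpoint iteration over B dates."""
        rng = random.Random(seed)
        anchor = date(2014, 6, 20)
        entries = []
        for j in range(rng.randint(1, 6)):
            d = anchor - timedelta(days=rng.randint(1, 40))
            entries.append((f"B{j}", d.isoformat(), "S62.0"))
        ev = _event(diag=[anchor.isoformat()], site=SiteGroup.HandBone)
        got = resolve_first_visit(ev, BLookupIndex(_b_dataset(make_claim, entries)), config)

        # oracle: iterate "reachable within lookback from any reachable date"
        dates = sorted({date.fromisoformat(d) for _, d, _ in entries})
        reachable = {anchor}
        changed = True
        while changed:
            changed = False
            cur = min(reachable)
            for d in dates:
                if d not in reachable and 0 < (cur - d).days <= config.lookback_days:
                    reachable.add(d)
                    changed = True
        assert got.first_visit == min(reachable)

    def test_shrinking_lookback_never_gives_earlier_dates(self, make_claim, config):
        rng = random.Random(3)
        anchor = date(2014, 6, 20)
        entries = [
            (f"B{j}", (anchor - timedelta(days=rng.randint(1, 40))).isoformat(), "S62.0")
            for j in range(6)
        ]
        b = BLookupIndex(_b_dataset(make_claim, entries))
        ev = _event(diag=[anchor.isoformat()], site=SiteGroup.HandBone)
        prev = None
        for lb in range(20, 0, -1):
            d = resolve_first_visit(ev, b, config.with_overrides(lookback_days=lb)).first_visit
            if prev is not None:
                assert d >= prev
            prev = d


class TestDedupe:
    def _resolved(self, events_dates, config):
        from claimcase.case_builder import ResolvedVisit

        out = []
        for patient, site, d in events_dates:
            ev = _event(diag=[d], patient=patient, site=site)
            out.append((ev, ResolvedVisit(date.fromisoformat(d), ev.age_group, ev.sex)))
        return out

    def test_recurrent_same_site_keeps_earliest(self, config):
        cases = dedupe_first_incidence(
            self._resolved(
                [("p", SiteGroup.HandBone, "2014-07-01"), ("p", SiteGroup.HandBone, "2014-09-01")],
                config,
            ),
            config,
        )
        assert len(cases) == 1
        assert cases[0].first_visit == date(2014, 7, 1)

    def test_different_sites_same_day_are_two_cases(self, config):
        cases = dedupe_first_incidence(
            self._resolved(
                [("p", SiteGroup.RadiusUlnaDistal, "2014-07-01"), ("p", SiteGroup.FemurHip, "2014-07-01")],
                config,
            ),
            config,
        )
        assert len(cases) == 2

    def test_identical_dates_collapse_to_one_case(self, config):
        cases = dedupe_first_incidence(
            self._resolved(
                [("p", SiteGroup.HandBone, "2014-07-01"), ("p", SiteGroup.HandBone, "2014-07-01")],
                config,
            ),
            config,
        )
        assert len(cases) == 1

    @pytest.mark.parametrize(
        "day,expected_cases",
        [("2013-04-10", 0), ("2013-04-17", 1), ("2016-03-15", 1), ("2016-03-20", 0)],
    )
    def test_case_window_boundaries(self, config, day, expected_cases):
        cases = dedupe_first_incidence(
            self._resolved([("p", SiteGroup.HandBone, day)], config), config
        )
        assert len(cases) == expected_cases

    def test_first_incidence_before_window_suppresses_later_recurrence(self, config):
        """A patient whose true first incidence predates the case window must
        not re-enter via a recurrence inside the window."""
        cases = dedupe_first_incidence(
            self._resolved(
                [("p", SiteGroup.HandBone, "2013-04-10"), ("p", SiteGroup.HandBone, "2014-01-10")],
                config,
            ),
            config,
        )
        assert cases == []
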