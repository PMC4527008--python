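"""Coverage and compliance classification against brute-force checkers."""

import datetime as dt

import numpy as np
import pytest

from vaxrecon import (
    Compliance,
    Coverage,
    ValidationError,
    antigen_coverage_table,
    compliance_by_age_group,
    compliance_status,
    coverage_status,
    load_schedule,
)
from vaxrecon.status import DoseStatus, age_in_months
from conftest import make_child, make_event
from test_schedule import add_months_oracle

AS_OF = dt.date(2013, 4, 30)


def events_on_due_dates(policy, birth, skip=(), offsets=None, child_id="C1"):
    """One event per due dose, vaccinated on its due date unless offset."""
    offsets = offsets or {}
    evs = []
    for d in policy:
        due = add_months_oracle(birth, d.recommended_age_months)
        if due > AS_OF or d.label in skip:
            continue
        evs.append(
            make_event(
                child_id=child_id,
                antigen=d.antigen,
                dose_index=d.dose_index,
                vaccination_date=due + dt.timedelta(days=offsets.get(d.label, 0)),
            )
        )
    return evs


def brute_force_classify(policy, child, as_of):
    """Independent classifier: enumerate every due dose, its window, and every
    adjacent order pair among received due doses."""
    dated = {
        (e.antigen, e.dose_index): e.vaccination_date
        for e in child.events
        if e.vaccination_date is not None
    }
    due = [
        d
        for d in policy
        if add_months_oracle(child.birth_date, d.recommended_age_months) <= as_of
    ]
    missed = [d for d in due if (d.antigen, d.dose_index) not in dated]
    coverage = Coverage.INCOMPLETE if missed else Coverage.COMPLETE
    if missed:
        return coverage, Compliance.INCOMPLETE
    if not due:
        return coverage, Compliance.PENDING
    window_ok = all(
        0
        <= (dated[(d.antigen, d.dose_index)] - add_months_oracle(child.birth_date, d.recommended_age_months)).days
        <= policy.on_time_window_days
        for d in due
    )
    dates = [dated[(d.antigen, d.dose_index)] for d in due]
    order_ok = all(a <= b for a, b in zip(dates, dates[1:]))
    status = Compliance.ON_TIME if window_ok and order_ok else Compliance.OUT_OF_SCHEDULE
    return coverage, status


def random_children(policy, rng, n):
    """Children with random births, random subsets of due doses, random delays."""
    children = []
    for i in range(n):
        birth = dt.date(2007, 5, 1) + dt.timedelta(days=int(rng.integers(0, 2100)))
        evs = []
        for d in policy:
            due = add_months_oracle(birth, d.recommended_age_months)
            if due > AS_OF or rng.random() < 0.15:
                continue
            delay = int(rng.integers(-5, 60)) if rng.random() < 0.4 else 0
            vacc = max(birth, due + dt.timedelta(days=delay))
            evs.append(
                make_event(
                    child_id=f"R{i}",
                    antigen=d.antigen,
                    dose_index=d.dose_index,
                    vaccination_date=vacc,
                )
            )
        children.append(make_child(evs, child_id=f"R{i}", birth=birth))
    return children


class TestCoverage:
    def test_all_due_doses_received_is_complete(self, policy):
        birth = dt.date(2012, 6, 1)
        child = make_child(events_on_due_dates(policy, birth), birth=birth)
        cov = coverage_status(policy, child, AS_OF)
        assert cov.overall is Coverage.COMPLETE
        assert DoseStatus.MISSED not in cov.per_dose.values()

    def test_one_missed_due_dose_is_incomplete(self, policy):
        birth = dt.date(2012, 6, 1)  # all 11 doses due by AS_OF
        child = make_child(events_on_due_dates(policy, birth, skip=("OPV2",)), birth=birth)
        cov = coverage_status(policy, child, AS_OF)
        assert cov.overall is Coverage.INCOMPLETE
        assert sum(s is DoseStatus.MISSED for s in cov.per_dose.values()) == 1

    def test_pending_doses_never_penalize(self, policy):
        birth = AS_OF  # newborn: only 0-month doses due
        child = make_child(events_on_due_dates(policy, birth), birth=birth)
        cov = coverage_status(policy, child, AS_OF)
        assert cov.overall is Coverage.COMPLETE
        assert sum(s is DoseStatus.PENDING for s in cov.per_dose.values()) == 9

    def test_randomized_children_match_brute_force(self, policy):
        rng = np.random.default_rng(3)
        for child in random_children(policy, rng, 150):
            expected, _ = brute_force_classify(policy, child, AS_OF)
            assert coverage_status(policy, child, AS_OF).overall is expected


class TestCompliance:
    def test_vaccination_exactly_on_due_dates_is_on_time(self, policy):
        birth = dt.date(2012, 6, 1)
        child = make_child(events_on_due_dates(policy, birth), birth=birth)
        assert compliance_status(policy, child, AS_OF).status is Compliance.ON_TIME

    def test_sequence_break_is_out_of_schedule(self):
        # wide window so both doses are individually timely but out of order
        pol = load_schedule(
            {
                "on_time_window_days": 120,
                "doses": [
                    {"antigen": "DTP", "dose_index": 3, "recommended_age_months": 6, "label": "DTP3"},
                    {"antigen": "MMR", "dose_index": 1, "recommended_age_months": 9, "label": "M/MMR1"},
                ],
            }
        )
        birth = dt.date(2012, 1, 1)
        child = make_child(
            [
                make_event(antigen="DTP", dose_index=3,
                           vaccination_date=add_months_oracle(birth, 6) + dt.timedelta(days=110)),
                make_event(antigen="MMR", dose_index=1,
                           vaccination_date=add_months_oracle(birth, 9)),
            ],
            birth=birth,
        )
        st = compliance_status(pol, child, dt.date(2013, 4, 30))
        assert st.status is Compliance.OUT_OF_SCHEDULE
        assert st.first_violation.label == "M/MMR1"

    def test_early_dose_counts_as_window_violation(self, policy):
        birth = dt.date(2012, 6, 1)
        child = make_child(
            events_on_due_dates(policy, birth, offsets={"DTP2": -3}), birth=birth
        )
        st = compliance_status(policy, child, AS_OF)
        assert st.status is Compliance.OUT_OF_SCHEDULE
        assert st.first_violation.label == "DTP2"

    def test_missed_dose_is_incomplete_not_out_of_schedule(self, policy):
        birth = dt.date(2012, 6, 1)
        child = make_child(events_on_due_dates(policy, birth, skip=("HB3",)), birth=birth)
        assert compliance_status(policy, child, AS_OF).status is Compliance.INCOMPLETE

    def test_no_due_dose_is_pending(self, policy):
        pol_no_birth_doses = load_schedule(
            {"doses": [{"antigen": "MMR", "dose_index": 1, "recommended_age_months": 9}]}
        )
        child = make_child(
            [make_event(antigen="X", dose_index=1, vaccination_date=AS_OF)], birth=AS_OF
        )
        assert (
            compliance_status(pol_no_birth_doses, child, AS_OF).status
            is Compliance.PENDING
        )

    def test_on_time_implies_complete(self, policy):
        rng = np.random.default_rng(4)
        for child in random_children(policy, rng, 100):
            cov = coverage_status(policy, child, AS_OF).overall
            st = compliance_status(policy, child, AS_OF).status
            if st is Compliance.ON_TIME:
                assert cov is Coverage.COMPLETE

    def test_randomized_children_match_brute_force(self, policy):
        rng = np.random.default_rng(5)
        for child in random_children(policy, rng, 150):
            _, expected = brute_force_classify(policy, child, AS_OF)
            assert compliance_status(policy, child, AS_OF).status is expected


class TestCoverageTable:
    def test_fully_vaccinated_cohort_is_100_everywhere(self, policy):
        cohort = [
            make_child(
                events_on_due_dates(policy, b, child_id=f"C{i}"), child_id=f"C{i}", birth=b
            )
            for i, b in enumerate([dt.date(2011, 1, 1), dt.date(2011, 8, 1)])
        ]
        tab = antigen_coverage_table(cohort, policy, AS_OF)
        assert (tab["pct"] == "100.0").all()
        assert (tab["n_received"] <= tab["n_due"]).all()

    def test_newborn_cohort_has_denominators_only_at_birth_doses(self, policy):
        cohort = [make_child(events_on_due_dates(policy, AS_OF), birth=AS_OF)]
        tab = antigen_coverage_table(cohort, policy, AS_OF).set_index("label")
        assert tab.loc["BCG", "n_due"] == 1
        assert tab.loc["DTP1", "n_due"] == 0
        assert tab.loc["DTP1", "pct"] is None

    def test_mixed_cohort_matches_independent_tally(self, policy):
        rng = np.random.default_rng(6)
        cohort = random_children(policy, rng, 80)
        tab = antigen_coverage_table(cohort, policy, AS_OF).set_index("label")
        for d in policy:
            due = [
                c for c in cohort
                if add_months_oracle(c.birth_date, d.recommended_age_months) <= AS_OF
            ]
            got = [
                c for c in due
                if any(e.key == d.key and e.vaccination_date for e in c.events)
            ]
            assert tab.loc[d.label, "n_due"] == len(due)
            assert tab.loc[d.label, "n_received"] == len(got)


class TestComplianceByAge:
    def test_first_year_group_all_on_time(self, policy):
        birth = AS_OF - dt.timedelta(days=330)  # ~11 months old
        cohort = [
            make_child(
                events_on_due_dates(policy, birth, child_id=f"C{i}"),
                child_id=f"C{i}",
                birth=birth,
            )
            for i in range(4)
        ]
        tab = compliance_by_age_group(cohort, policy, AS_OF)
        first = tab[(tab.age_group == "0-11m") & (tab.status == "on time")].iloc[0]
        assert first["count"] == 4 and first["pct"] == "100.0"

    def test_empty_group_has_zero_row_without_division_error(self, policy):
        birth = AS_OF - dt.timedelta(days=30)
        cohort = [make_child(events_on_due_dates(policy, birth), birth=birth)]
        tab = compliance_by_age_group(cohort, policy, AS_OF)
        empty = tab[tab.age_group == "24-35m"]
        assert (empty["count"] == 0).all()
        assert empty["pct"].isna().all()

    def test_age_assignment_matches_independent_binning(self, policy):
        rng = np.random.default_rng(7)
        cohort = random_children(policy, rng, 60)
        edges = [12, 24, 36, 48, 60, 72]
        tab = compliance_by_age_group(cohort, policy, AS_OF, age_group_edges=edges)
        sizes = tab.groupby("age_group")["count"].sum()
        expected = {g: 0 for g in sizes.index}
        for c in cohort:
            m = age_in_months(c.birth_date, AS_OF)
            idx = np.searchsorted(edges, m, side="right")
            label = f">={edges[-1]}m" if idx == len(edges) else (
                f"{([0]+edges)[idx]}-{edges[idx]-1}m"
            )
            expected[label] += 1
        assert dict(sizes) == expected

    def test_older_child_lands_in_open_top_group(self, policy):
        birth = dt.date(2005, 1, 1)
        cohort = [make_child(events_on_due_dates(policy, birth), birth=birth)]
        tab = compliance_by_age_group(cohort, policy, AS_OF)
        assert tab[tab.age_group == ">=72m"]["count"].sum() == 1

    def test_merge_incomplete_folds_into_out_of_schedule(self, policy):
        birth = dt.date(2012, 6, 1)
        cohort = [make_child(events_on_due_dates(policy, birth, skip=("HB3",)), birth=birth)]
        tab = compliance_by_age_group(cohort, policy, AS_OF, merge_incomplete=True)
        assert "incomplete" not in set(tab.status)
        row = tab[(tab.age_group == "0-11m") & (tab.status == "out of schedule")].iloc[0]
        assert row["count"] == 1

    def test_event_before_birth_rejected(self, policy):
        child = make_child([make_event(vaccination_date=dt.date(2012, 1, 1))], birth=dt.date(2012, 1, 1))
        object.__setattr__(child.events[0], "vaccination_date", dt.date(2011, 1, 1))
        with pytest.raises(ValidationError):
            compliance_status(policy, child, AS_OF)
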