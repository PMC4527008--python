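import datetime as dt

import pytest

from vaxrecon import (
    DEPIC,
    HCIS,
    ChildPair,
    ChildRecord,
    ImmunizationEvent,
    default_schedule,
)


@pytest.fixture(scope="session")
def policy():
    return default_schedule()


def make_event(
    child_id="C1",
    antigen="BCG",
    dose_index=1,
    appointment_date=None,
    vaccination_date=dt.date(2012, 1, 15),
    source=DEPIC,
):
    return ImmunizationEvent(
        child_id=child_id,
        antigen=antigen,
        dose_index=dose_index,
        appointment_date=appointment_date,
        vaccination_date=vaccination_date,
        source=source,
    )


def make_child(events, child_id="C1", birth=dt.date(2012, 1, 1), source=DEPIC):
    return ChildRecord(
        child_id=child_id, birth_date=birth, events=tuple(events), source=source
    )


def make_pair(depic_keys, hcis_keys, birth=dt.date(2012, 1, 1), hcis_dates=None):
    """Build a ChildPair from (antigen, dose) keys; all vaccination dates equal
    the birth date unless overridden per-key via hcis_dates."""
    hcis_dates = hcis_dates or {}
    depic = [
        make_event("C1", a, d, vaccination_date=birth, source=DEPIC)
        for a, d in depic_keys
    ]
    hcis = [
        make_event("C1", a, d, vaccination_date=hcis_dates.get((a, d), birth), source=HCIS)
        for a, d in hcis_keys
    ]
    return ChildPair(
        child_id="C1", birth_date=birth, depic_events=tuple(depic), hcis_events=tuple(hcis)
    )
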