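"""Immunization coverage and schedule-compliance classification.

Coverage: a child is COMPLETE when every dose due by the analysis date has
a recorded vaccination, INCOMPLETE when at least one due dose is missed;
doses not yet due are PENDING and never count against the child.

Compliance: among children with no missed due dose, ON_TIME requires every
received due dose to fall inside its timeliness window (from the due date
to due date + the policy's on-time window) and the vaccination dates to be
non-decreasing in schedule order; any violation makes the child
OUT_OF_SCHEDULE.  A child with no dose yet due is PENDING.  Children that
miss a due dose form a fourth, exhaustive bucket, INCOMPLETE, which report
layouts may fold into OUT_OF_SCHEDULE to mimic a three-way display.
A dose given before its due date counts as a window violation.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

import pandas as pd
from dateutil.relativedelta import relativedelta

from .errors import DomainError, ValidationError
from .records import ChildRecord
from .report import format_pct
from .schedule import AntigenDose, SchedulePolicy, doses_due, due_date

__all__ = [
    "DoseStatus",
    "Coverage",
    "Compliance",
    "CoverageStatus",
    "ComplianceStatus",
    "coverage_status",
    "compliance_status",
    "antigen_coverage_table",
    "compliance_by_age_group",
    "age_in_months",
    "DEFAULT_AGE_GROUP_EDGES",
]

DEFAULT_AGE_GROUP_EDGES = (12, 24, 36, 48, 60, 72)


class DoseStatus(str, Enum):
    RECEIVED = "received"
    MISSED = "missed"
    PENDING = "pending"


class Coverage(str, Enum):
    COMPLETE = "complete"
    INCOMPLETE = "incomplete"


class Compliance(str, Enum):
    ON_TIME = "on time"
    OUT_OF_SCHEDULE = "out of schedule"
    PENDING = "pending schedule"
    INCOMPLETE = "incomplete"


@dataclass(frozen=True)
class CoverageStatus:
    child_id: str
    overall: Coverage
    per_dose: dict[AntigenDose, DoseStatus]


@dataclass(frozen=True)
class ComplianceStatus:
    child_id: str
    status: Compliance
    first_violation: Optional[AntigenDose] = None


def _received_dates(child: ChildRecord) -> dict[tuple[str, int], dt.date]:
    return {
        e.key: e.vaccination_date
        for e in child.events
        if e.vaccination_date is not None and e.dose_index is not None
    }


def coverage_status(
    policy: SchedulePolicy, child: ChildRecord, as_of: dt.date
) -> CoverageStatus:
    """Per-dose received/missed/pending plus the overall complete/incomplete
    call, evaluated at ``as_of``."""
    if child.birth_date > as_of:
        raise DomainError(f"{child.child_id}: born after analysis date")
    due = set(doses_due(policy, child.birth_date, as_of))
    dated = _received_dates(child)
    per_dose: dict[AntigenDose, DoseStatus] = {}
    for dose in policy:
        if dose not in due:
            per_dose[dose] = DoseStatus.PENDING
        elif dose.key in dated:
            per_dose[dose] = DoseStatus.RECEIVED
        else:
            per_dose[dose] = DoseStatus.MISSED
    overall = (
        Coverage.INCOMPLETE
        if any(s is DoseStatus.MISSED for s in per_dose.values())
        else Coverage.COMPLETE
    )
    return CoverageStatus(child_id=child.child_id, overall=overall, per_dose=per_dose)


def compliance_status(
    policy: SchedulePolicy, child: ChildRecord, as_of: dt.date
) -> ComplianceStatus:
    """Timeliness-and-sequence classification at ``as_of``.

    The first failing dose in schedule order (window miss, or vaccinated
    earlier than the preceding due dose) is reported as the violation.
    """
    for e in child.events:
        if e.vaccination_date is not None and e.vaccination_date < child.birth_date:
            raise ValidationError(f"{child.child_id}: event dated before birth")
    cov = coverage_status(policy, child, as_of)
    if cov.overall is Coverage.INCOMPLETE:
        first_missed = next(
            d for d in policy if cov.per_dose[d] is DoseStatus.MISSED
        )
        return ComplianceStatus(child.child_id, Compliance.INCOMPLETE, first_missed)
    due = [d for d in policy if cov.per_dose[d] is DoseStatus.RECEIVED]
    if not due:
        return ComplianceStatus(child.child_id, Compliance.PENDING)
    dated = _received_dates(child)
    window = policy.on_time_window_days
    prev_date: Optional[dt.date] = None
    for dose in due:
        v = dated[dose.key]
        target = due_date(policy, dose, child.birth_date)
        if not (target <= v <= target + dt.timedelta(days=window)):
            return ComplianceStatus(child.child_id, Compliance.OUT_OF_SCHEDULE, dose)
        if prev_date is not None and v < prev_date:
            return ComplianceStatus(child.child_id, Compliance.OUT_OF_SCHEDULE, dose)
        prev_date = v
    return ComplianceStatus(child.child_id, Compliance.ON_TIME)


def antigen_coverage_table(
    cohort: Sequence[ChildRecord], policy: SchedulePolicy, as_of: dt.date
) -> pd.DataFrame:
    """Per antigen-dose: children due, children received, percentage.

    The denominator for each dose is the number of children for whom it is
    due at ``as_of``; a dose due for nobody gets an absent percentage.
    """
    if not cohort:
        raise DomainError("empty cohort")
    n_due = {d: 0 for d in policy}
    n_received = {d: 0 for d in policy}
    for child in cohort:
        cov = coverage_status(policy, child, as_of)
        for dose, s in cov.per_dose.items():
            if s is not DoseStatus.PENDING:
                n_due[dose] += 1
                if s is DoseStatus.RECEIVED:
                    n_received[dose] += 1
    rows = []
    for dose in policy:
        rows.append(
            {
                "label": dose.label,
                "n_received": n_received[dose],
                "n_due": n_due[dose],
                "pct": format_pct(n_received[dose], n_due[dose]) if n_due[dose] else None,
            }
        )
    return pd.DataFrame(rows)


def age_in_months(birth_date: dt.date, as_of: dt.date) -> int:
    """Age in completed calendar months."""
    if as_of < birth_date:
        raise DomainError("as_of precedes birth date")
    delta = relativedelta(as_of, birth_date)
    return delta.years * 12 + delta.months


def _group_labels(edges: Sequence[int]) -> list[str]:
    labels = []
    lo = 0
    for hi in edges:
        labels.append(f"{lo}-{hi - 1}m")
        lo = hi
    labels.append(f">={lo}m")
    return labels


def compliance_by_age_group(
    cohort: Sequence[ChildRecord],
    policy: SchedulePolicy,
    as_of: dt.date,
    *,
    age_group_edges: Sequence[int] = DEFAULT_AGE_GROUP_EDGES,
    merge_incomplete: bool = False,
) -> pd.DataFrame:
    """Compliance-status frequencies per age group at ``as_of``.

    Children older than the last edge fall into an open-ended top group.
    ``merge_incomplete`` folds INCOMPLETE into OUT_OF_SCHEDULE for a
    three-way (on time / out of schedule / pending) display.
    """
    edges = list(age_group_edges)
    if edges != sorted(edges) or len(set(edges)) != len(edges):
        raise DomainError("age group edges must be strictly increasing")
    labels = _group_labels(edges)
    statuses = list(Compliance)
    if merge_incomplete:
        statuses = [s for s in statuses if s is not Compliance.INCOMPLETE]
    counts = {g: {s: 0 for s in statuses} for g in labels}
    totals = {g: 0 for g in labels}
    for child in cohort:
        months = age_in_months(child.birth_date, as_of)
        idx = sum(months >= e for e in edges)
        group = labels[idx]
        st = compliance_status(policy, child, as_of).status
        if merge_incomplete and st is Compliance.INCOMPLETE:
            st = Compliance.OUT_OF_SCHEDULE
        counts[group][st] += 1
        totals[group] += 1
    rows = []
    for g in labels:
        n = totals[g]
        for s in statuses:
            k = counts[g][s]
            rows.append(
                {
                    "age_group": g,
                    "status": s.value,
                    "count": k,
                    "n_group": n,
                    "pct": format_pct(k, n) if n else None,
                }
            )
    return pd.DataFrame(rows)
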