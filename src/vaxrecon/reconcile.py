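"""Per-child completeness-difference and date-consistency metrics.

For each child the logbook (DEPIC) event set is taken as the complete
reference.  Two percentages are computed over the logbook record count
``n_depic``:

* completeness difference — the share of logbook records absent from the
  registry copy (matched on antigen + dose index);
* date consistency — the share of logbook records whose actual vaccination
  date is reproduced in the registry (within a configurable day tolerance,
  default exact day).

Each percentage is then binned into the four reporting categories used for
cohort summaries.  Registry-only records affect neither metric; they are
reported separately.  Percentages carry full precision internally; rounding
happens only at report formatting.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Optional, Sequence

import pandas as pd

from .errors import DomainError
from .records import ChildPair, ImmunizationEvent
from .report import format_pct

__all__ = [
    "CompletenessCategory",
    "ConsistencyCategory",
    "MatchResult",
    "ReconciliationRow",
    "match_events",
    "completeness_diff_pct",
    "date_consistency_pct",
    "bin_completeness",
    "bin_consistency",
    "reconcile_cohort",
]


class CompletenessCategory(str, Enum):
    """Bins for the per-child completeness-difference percentage."""

    LE50_DIFF = "<=50% difference"
    P51_80_DIFF = "51%-80% difference"
    P81_99_DIFF = "81%-99% difference"
    P100_DIFF = "100% difference"


class ConsistencyCategory(str, Enum):
    """Bins for the per-child actual-vaccination-date consistency percentage."""

    UNMATCHED_100 = "100% unmatched"
    LE50_MATCH = "<=50% matched"
    P51_70_MATCH = "51%-70% matched"
    GT70_MATCH = ">70% matched"


@dataclass(frozen=True)
class MatchResult:
    """Outcome of matching one child's logbook events to the registry copy."""

    child_id: str
    matched_pairs: tuple[tuple[ImmunizationEvent, ImmunizationEvent], ...]
    depic_only: tuple[ImmunizationEvent, ...]
    hcis_only: tuple[ImmunizationEvent, ...]
    n_date_matched: int

    @property
    def n_depic(self) -> int:
        return len(self.matched_pairs) + len(self.depic_only)

    @property
    def n_matched(self) -> int:
        return len(self.matched_pairs)

    def __post_init__(self) -> None:
        if self.n_date_matched > len(self.matched_pairs):
            raise DomainError("date matches cannot exceed key matches")


@dataclass(frozen=True)
class ReconciliationRow:
    child_id: str
    n_depic: int
    n_matched: int
    n_date_matched: int
    completeness_diff_pct: float
    date_consistency_pct: float
    completeness_category: CompletenessCategory
    consistency_category: ConsistencyCategory


def _dates_agree(
    a: Optional[object], b: Optional[object], tolerance_days: int
) -> bool:
    if a is None or b is None:
        return False
    return abs((a - b).days) <= tolerance_days


def match_events(pair: ChildPair, *, tolerance_days: int = 0) -> MatchResult:
    """Classify each logbook event as matched (same antigen + dose present in
    the registry) or logbook-only; leftover registry events are reported
    separately.  A matched pair counts as date-matched when both actual
    vaccination dates are present and differ by at most ``tolerance_days``.
    """
    hcis_by_key = {e.key: e for e in pair.hcis_events}
    matched, depic_only = [], []
    for e in pair.depic_events:
        h = hcis_by_key.pop(e.key, None)
        if h is None:
            depic_only.append(e)
        else:
            matched.append((e, h))
    n_date = sum(
        _dates_agree(d.vaccination_date, h.vaccination_date, tolerance_days)
        for d, h in matched
    )
    return MatchResult(
        child_id=pair.child_id,
        matched_pairs=tuple(matched),
        depic_only=tuple(depic_only),
        hcis_only=tuple(hcis_by_key.values()),
        n_date_matched=n_date,
    )


def completeness_diff_pct(m: MatchResult) -> float:
    """100 x (logbook records absent from the registry) / (logbook records)."""
    if m.n_depic == 0:
        raise DomainError(f"{m.child_id}: no logbook records")
    return 100.0 * len(m.depic_only) / m.n_depic


def date_consistency_pct(m: MatchResult) -> float:
    """100 x (date-matched records) / (logbook records)."""
    if m.n_depic == 0:
        raise DomainError(f"{m.child_id}: no logbook records")
    return 100.0 * m.n_date_matched / m.n_depic


def _check_pct(pct: float) -> None:
    if not 0.0 <= pct <= 100.0:
        raise DomainError(f"percentage {pct} outside [0, 100]")


def bin_completeness(pct: float) -> CompletenessCategory:
    """Bin a completeness-difference percentage.

    The top bin is reserved for exactly 100% (no logbook record reproduced
    at all); 81-99% therefore covers the open interval (80, 100).
    """
    _check_pct(pct)
    if pct == 100.0:
        return CompletenessCategory.P100_DIFF
    if pct > 80.0:
        return CompletenessCategory.P81_99_DIFF
    if pct > 50.0:
        return CompletenessCategory.P51_80_DIFF
    return CompletenessCategory.LE50_DIFF


def bin_consistency(pct: float, n_date_matched: int) -> ConsistencyCategory:
    """Bin a date-consistency percentage.

    Zero date matches takes precedence over the "<=50% matched" bin so that
    the four categories stay disjoint (0 lies in both printed ranges).
    """
    _check_pct(pct)
    if n_date_matched == 0:
        return ConsistencyCategory.UNMATCHED_100
    if pct > 70.0:
        return ConsistencyCategory.GT70_MATCH
    if pct > 50.0:
        return ConsistencyCategory.P51_70_MATCH
    return ConsistencyCategory.LE50_MATCH


def reconcile_child(pair: ChildPair, *, tolerance_days: int = 0) -> ReconciliationRow:
    m = match_events(pair, tolerance_days=tolerance_days)
    comp = completeness_diff_pct(m)
    cons = date_consistency_pct(m)
    return ReconciliationRow(
        child_id=pair.child_id,
        n_depic=m.n_depic,
        n_matched=m.n_matched,
        n_date_matched=m.n_date_matched,
        completeness_diff_pct=comp,
        date_consistency_pct=cons,
        completeness_category=bin_completeness(comp),
        consistency_category=bin_consistency(cons, m.n_date_matched),
    )


def reconcile_cohort(
    pairs: Sequence[ChildPair], *, tolerance_days: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-child reconciliation rows plus the cohort category frequency table.

    Returns ``(per_child, summary)``: ``per_child`` has one row per child;
    ``summary`` lists count and percentage of children per category, in the
    standard report order (four completeness bins, then four consistency
    bins), with percentages formatted half-up at one decimal.
    """
    if not pairs:
        raise DomainError("empty cohort")
    rows = [reconcile_child(p, tolerance_days=tolerance_days) for p in pairs]
    per_child = pd.DataFrame(
        {
            "child_id": [r.child_id for r in rows],
            "n_depic": [r.n_depic for r in rows],
            "n_matched": [r.n_matched for r in rows],
            "n_date_matched": [r.n_date_matched for r in rows],
            "completeness_diff_pct": [r.completeness_diff_pct for r in rows],
            "date_consistency_pct": [r.date_consistency_pct for r in rows],
            "completeness_category": [r.completeness_category.value for r in rows],
            "consistency_category": [r.consistency_category.value for r in rows],
        }
    )
    n = len(rows)
    summary_rows = []
    for section, enum, column in (
        ("completeness", CompletenessCategory, "completeness_category"),
        ("consistency", ConsistencyCategory, "consistency_category"),
    ):
        counts = per_child[column].value_counts()
        for cat in enum:
            k = int(counts.get(cat.value, 0))
            summary_rows.append(
                {
                    "section": section,
                    "category": cat.value,
                    "count": k,
                    "pct": format_pct(k, n),
                }
            )
    summary = pd.DataFrame(summary_rows)
    return per_child, summary
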