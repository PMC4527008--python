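"""Immunization-event data model, CSV I/O and per-child linkage.

Two parallel event sources are handled: the gold "logbook" source (DEPIC,
records transcribed directly from the mother-and-child health booklet) and
the secondary registry source (HCIS, Thailand's national health care
information system).  Events carry both the appointment date set at the
previous visit and the actual vaccination date; dates are ISO 8601, with
an optional switch for Thai Buddhist-era years (BE = CE + 543) as found
on many Thai source documents.

The CSV contract: UTF-8, header row, columns ``child_id, birth_date,
antigen, dose_index, appointment_date, vaccination_date``; the empty
string means absent; one file per source.
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

from .errors import SchemaError, ValidationError

__all__ = [
    "DEPIC",
    "HCIS",
    "ImmunizationEvent",
    "ChildRecord",
    "ChildPair",
    "LinkReport",
    "read_events",
    "write_events",
    "link_children",
]

DEPIC = "DEPIC"
HCIS = "HCIS"
_SOURCES = (DEPIC, HCIS)

REQUIRED_COLUMNS = (
    "child_id",
    "birth_date",
    "antigen",
    "dose_index",
    "appointment_date",
    "vaccination_date",
)


@dataclass(frozen=True)
class ImmunizationEvent:
    """One vaccination record from one source."""

    child_id: str
    antigen: str
    dose_index: Optional[int]
    appointment_date: Optional[dt.date]
    vaccination_date: Optional[dt.date]
    source: str

    def __post_init__(self) -> None:
        if not self.child_id:
            raise ValidationError("event with empty child_id")
        if self.source not in _SOURCES:
            raise ValidationError(f"unknown source {self.source!r}")
        if self.appointment_date is None and self.vaccination_date is None:
            raise ValidationError(
                f"{self.child_id}/{self.antigen}: event has neither appointment "
                "nor vaccination date"
            )
        if self.dose_index is not None and self.dose_index < 1:
            raise ValidationError(f"{self.child_id}/{self.antigen}: dose_index must be >= 1")

    @property
    def key(self) -> tuple[str, Optional[int]]:
        return (self.antigen, self.dose_index)


@dataclass(frozen=True)
class ChildRecord:
    """All events for one child from a single source."""

    child_id: str
    birth_date: dt.date
    events: tuple[ImmunizationEvent, ...]
    source: str

    def __post_init__(self) -> None:
        keys = set()
        for e in self.events:
            if e.child_id != self.child_id:
                raise ValidationError(f"{self.child_id}: event belongs to {e.child_id}")
            if e.source != self.source:
                raise ValidationError(f"{self.child_id}: mixed sources in one record")
            if e.vaccination_date is not None and e.vaccination_date < self.birth_date:
                raise ValidationError(
                    f"{self.child_id}/{e.antigen}: vaccinated {e.vaccination_date} "
                    f"before birth {self.birth_date}"
                )
            if e.key in keys:
                raise ValidationError(
                    f"{self.child_id}: duplicate event {e.antigen} #{e.dose_index}"
                )
            keys.add(e.key)


@dataclass(frozen=True)
class ChildPair:
    """A child's linked logbook-source and registry-source event sets."""

    child_id: str
    birth_date: dt.date
    depic_events: tuple[ImmunizationEvent, ...]
    hcis_events: tuple[ImmunizationEvent, ...]

    def __post_init__(self) -> None:
        if not self.depic_events:
            raise ValidationError(f"{self.child_id}: pair without logbook events")


@dataclass
class LinkReport:
    """Children that could not be paired, plus cross-source conflicts."""

    hcis_only: list[str] = field(default_factory=list)
    birth_date_conflicts: list[str] = field(default_factory=list)
    depic_empty: list[str] = field(default_factory=list)

    @property
    def clean(self) -> bool:
        return not self.hcis_only and not self.birth_date_conflicts and not self.depic_empty


def _parse_date(token: str, *, buddhist_era: bool = False) -> Optional[dt.date]:
    """Strict ISO 8601 YYYY-MM-DD; optionally convert Thai BE years."""
    if token is None or token == "":
        return None
    d = dt.date.fromisoformat(token)
    if buddhist_era:
        d = d.replace(year=d.year - 543)
    return d


def _assign_dose_indices(events: list[ImmunizationEvent]) -> list[ImmunizationEvent]:
    """Fill in absent dose indices within each antigen.

    Unnumbered events are ranked by ascending vaccination date, ties broken
    by appointment date then input order (mirroring how doses are listed on
    history cards), and receive the smallest positive indices not already
    taken by explicitly numbered events.
    """
    out = list(events)
    by_antigen: dict[str, list[int]] = {}
    for i, e in enumerate(out):
        by_antigen.setdefault(e.antigen, []).append(i)
    far_future = dt.date.max
    for antigen, idxs in by_antigen.items():
        used = {out[i].dose_index for i in idxs if out[i].dose_index is not None}
        missing = [i for i in idxs if out[i].dose_index is None]
        missing.sort(
            key=lambda i: (
                out[i].vaccination_date or far_future,
                out[i].appointment_date or far_future,
                i,
            )
        )
        next_free = 1
        for i in missing:
            while next_free in used:
                next_free += 1
            used.add(next_free)
            out[i] = replace(out[i], dose_index=next_free)
            next_free += 1
    return out


def read_events(
    table: Union[str, Path],
    source: str,
    *,
    buddhist_era: bool = False,
) -> list[ChildRecord]:
    """Read one source's event CSV into validated per-child records.

    Rows whose mandatory fields (child_id, birth_date, antigen) cannot be
    parsed are dropped with a warning naming their row numbers.  Duplicate
    (child, antigen, dose) combinations raise :class:`ValidationError`.
    """
    if source not in _SOURCES:
        raise ValidationError(f"unknown source {source!r}")
    df = pd.read_csv(table, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    bad_rows: list[int] = []
    children: dict[str, dict] = {}
    for pos, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        try:
            child_id = row.child_id.strip()
            birth = _parse_date(row.birth_date, buddhist_era=buddhist_era)
            antigen = row.antigen.strip()
            if not child_id or birth is None or not antigen:
                raise ValueError("mandatory field absent")
            dose = int(row.dose_index) if row.dose_index != "" else None
            appt = _parse_date(row.appointment_date, buddhist_era=buddhist_era)
            vacc = _parse_date(row.vaccination_date, buddhist_era=buddhist_era)
            event = ImmunizationEvent(
                child_id=child_id,
                antigen=antigen,
                dose_index=dose,
                appointment_date=appt,
                vaccination_date=vacc,
                source=source,
            )
        except (ValueError, ValidationError):
            bad_rows.append(pos)
            continue
        entry = children.setdefault(child_id, {"birth": birth, "events": []})
        entry["events"].append(event)
    if bad_rows:
        warnings.warn(
            f"{table}: dropped {len(bad_rows)} unparseable row(s) at line(s) "
            f"{', '.join(map(str, bad_rows))}",
            stacklevel=2,
        )

    records = []
    for child_id, entry in children.items():
        events = _assign_dose_indices(entry["events"])
        dupes = _duplicate_keys(events)
        if dupes:
            raise ValidationError(
                f"{child_id}: duplicate (antigen, dose) entries: "
                + ", ".join(f"{a} #{d}" for a, d in dupes)
            )
        records.append(
            ChildRecord(
                child_id=child_id,
                birth_date=entry["birth"],
                events=tuple(events),
                source=source,
            )
        )
    return records


def _duplicate_keys(events: Sequence[ImmunizationEvent]) -> list[tuple[str, int]]:
    seen, dupes = set(), []
    for e in events:
        if e.key in seen:
            dupes.append(e.key)
        seen.add(e.key)
    return dupes


def write_events(records: Iterable[ChildRecord], path: Union[str, Path]) -> None:
    """Inverse of :func:`read_events`: one CSV row per event."""
    rows = []
    for rec in sorted(records, key=lambda r: r.child_id):
        for e in rec.events:
            rows.append(
                {
                    "child_id": rec.child_id,
                    "birth_date": rec.birth_date.isoformat(),
                    "antigen": e.antigen,
                    "dose_index": "" if e.dose_index is None else e.dose_index,
                    "appointment_date": (
                        "" if e.appointment_date is None else e.appointment_date.isoformat()
                    ),
                    "vaccination_date": (
                        "" if e.vaccination_date is None else e.vaccination_date.isoformat()
                    ),
                }
            )
    pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS)).to_csv(path, index=False)


def link_children(
    depic: Iterable[ChildRecord], hcis: Iterable[ChildRecord]
) -> tuple[list[ChildPair], LinkReport]:
    """Pair the two sources on exact child-id (hospital-number) equality.

    Children present only in the logbook source yield pairs with empty
    registry events (the "100% difference" situation); children present only
    in the registry are reported, not paired.  When the two sources disagree
    on a birth date the logbook value is retained and the conflict flagged.
    """
    depic_by_id = {r.child_id: r for r in depic}
    hcis_by_id = {r.child_id: r for r in hcis}
    report = LinkReport()
    pairs = []
    for child_id in sorted(depic_by_id):
        d = depic_by_id[child_id]
        h = hcis_by_id.get(child_id)
        if not d.events:
            # no logbook records: both metrics are undefined for this child
            report.depic_empty.append(child_id)
            continue
        if h is not None and h.birth_date != d.birth_date:
            report.birth_date_conflicts.append(child_id)
        pairs.append(
            ChildPair(
                child_id=child_id,
                birth_date=d.birth_date,
                depic_events=d.events,
                hcis_events=h.events if h is not None else (),
            )
        )
    report.hcis_only = sorted(set(hcis_by_id) - set(depic_by_id))
    return pairs, report
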