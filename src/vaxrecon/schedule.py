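"""Immunization schedule model and calendar-aware due-date queries.

The national EPI (Expanded Programme on Immunization) schedule is modelled
as an ordered list of antigen-doses, each carrying a recommended age in
completed calendar months.  A dose's due date is the child's birth date
advanced by that many calendar months, clamping to month-end when the
target day does not exist (e.g. 31 Jan + 1 month -> 28/29 Feb).  Ages and
due dates compare in whole days; there is no time-of-day component.

The shipped default configuration covers the first-year portion of the
Thai childhood schedule (BCG, HB1-3, DTP1-3, OPV1-3, M/MMR1); any
guideline revision can be loaded from a YAML/JSON document instead.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Union

import yaml
from dateutil.relativedelta import relativedelta

from .errors import DomainError, ScheduleError

__all__ = [
    "AntigenDose",
    "SchedulePolicy",
    "load_schedule",
    "default_schedule",
    "due_date",
    "doses_due",
]


@dataclass(frozen=True, order=True)
class AntigenDose:
    """One numbered dose of a vaccine antigen, e.g. DTP2.

    Ordering is (recommended_age_months, antigen, dose_index), the order in
    which doses appear in the schedule and in all reports.
    """

    recommended_age_months: int
    antigen: str
    dose_index: int
    label: str = field(compare=False)

    def __post_init__(self) -> None:
        if self.dose_index < 1:
            raise ScheduleError(f"{self.label!r}: dose_index must be >= 1")
        if self.recommended_age_months < 0:
            raise ScheduleError(f"{self.label!r}: recommended age must be >= 0 months")

    @property
    def key(self) -> tuple[str, int]:
        """Cross-source matching identity: (antigen, dose_index)."""
        return (self.antigen, self.dose_index)


@dataclass(frozen=True)
class SchedulePolicy:
    """An ordered, duplicate-free collection of antigen-doses plus the
    timeliness window applied after each due date."""

    name: str
    doses: tuple[AntigenDose, ...]
    on_time_window_days: int = 28

    def __post_init__(self) -> None:
        if not self.doses:
            raise ScheduleError("schedule must list at least one dose")
        if self.on_time_window_days < 0:
            raise ScheduleError("on_time_window_days must be >= 0")
        object.__setattr__(self, "doses", tuple(sorted(self.doses)))
        seen: dict[tuple[str, int], AntigenDose] = {}
        for d in self.doses:
            if d.key in seen:
                raise ScheduleError(
                    f"duplicate dose {d.antigen} #{d.dose_index} ({d.label!r})"
                )
            seen[d.key] = d
        # within one antigen, later doses must be recommended later
        by_antigen: dict[str, list[AntigenDose]] = {}
        for d in self.doses:
            by_antigen.setdefault(d.antigen, []).append(d)
        for antigen, ds in by_antigen.items():
            ds.sort(key=lambda d: d.dose_index)
            ages = [d.recommended_age_months for d in ds]
            if any(b <= a for a, b in zip(ages, ages[1:])):
                raise ScheduleError(
                    f"{antigen}: recommended ages must strictly increase with dose index"
                )

    def __iter__(self):
        return iter(self.doses)

    def __len__(self) -> int:
        return len(self.doses)

    def find(self, antigen: str, dose_index: int) -> AntigenDose:
        for d in self.doses:
            if d.key == (antigen, dose_index):
                return d
        raise KeyError(f"{antigen} #{dose_index} not in schedule {self.name!r}")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(d.label for d in self.doses)


def _parse_document(text: str) -> dict:
    # YAML is a superset of JSON, but try JSON first for crisper errors on .json
    stripped = text.lstrip()
    if stripped.startswith("{"):
        return json.loads(text)
    return yaml.safe_load(text)


def load_schedule(source: Union[str, Path, dict]) -> SchedulePolicy:
    """Build a :class:`SchedulePolicy` from a YAML/JSON document.

    ``source`` may be a path to a document, the document text itself, or an
    already-parsed mapping with keys ``name``, ``on_time_window_days`` and
    ``doses`` (each dose: antigen, dose_index, label, recommended_age_months).
    """
    if isinstance(source, dict):
        doc = source
    else:
        path = Path(source)
        if isinstance(source, Path) or path.suffix.lower() in {".yaml", ".yml", ".json"}:
            text = path.read_text(encoding="utf-8")
        else:
            text = str(source)
        try:
            doc = _parse_document(text)
        except (yaml.YAMLError, json.JSONDecodeError) as exc:
            raise ScheduleError(f"cannot parse schedule document: {exc}") from exc
    if not isinstance(doc, dict) or "doses" not in doc:
        raise ScheduleError("schedule document must be a mapping with a 'doses' list")
    entries = doc["doses"]
    if not entries:
        raise ScheduleError("schedule document lists no doses")
    doses = []
    for i, entry in enumerate(entries):
        try:
            doses.append(
                AntigenDose(
                    antigen=str(entry["antigen"]),
                    dose_index=int(entry["dose_index"]),
                    recommended_age_months=int(entry["recommended_age_months"]),
                    label=str(entry.get("label") or f"{entry['antigen']}{entry['dose_index']}"),
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ScheduleError(f"malformed dose entry #{i + 1}: {entry!r}") from exc
    return SchedulePolicy(
        name=str(doc.get("name", "unnamed")),
        doses=tuple(doses),
        on_time_window_days=int(doc.get("on_time_window_days", 28)),
    )


def default_schedule() -> SchedulePolicy:
    """The shipped first-year Thai EPI schedule."""
    text = resources.files("vaxrecon.data").joinpath("schedule_default.yaml").read_text("utf-8")
    return load_schedule(yaml.safe_load(text))


def due_date(policy: SchedulePolicy, dose: AntigenDose, birth_date: dt.date) -> dt.date:
    """Birth date advanced by the dose's recommended age in calendar months."""
    if dose.key not in {d.key for d in policy.doses}:
        raise KeyError(f"{dose.label!r} does not belong to schedule {policy.name!r}")
    return birth_date + relativedelta(months=dose.recommended_age_months)


def doses_due(
    policy: SchedulePolicy, birth_date: dt.date, as_of: dt.date
) -> tuple[AntigenDose, ...]:
    """Doses whose due date has arrived by ``as_of``, in policy order.

    The complement of the returned set is the child's "pending" set: doses
    not yet required at the analysis time.
    """
    if as_of < birth_date:
        raise DomainError(f"as_of {as_of} precedes birth date {birth_date}")
    return tuple(d for d in policy if due_date(policy, d, birth_date) <= as_of)
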