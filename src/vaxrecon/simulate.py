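"""Synthetic paired-cohort generation with controlled error injection.

The generator emulates the study design the analysis assumes: a cohort of
children whose mother-and-child-health logbook (gold source) records are
near-complete, and a registry copy degraded by three error processes seen
in routine registry data entry — record omission (optionally heavier for
some antigens), date-transcription errors (a copied vaccination date
shifted by a nonzero number of days), and vaccination delays relative to
the scheduled appointment.

Two independent random streams are used: the cohort seed drives births,
attendance and delays; the error-model seed drives omission and
transcription, so one gold cohort can be degraded under several error
models for controlled experiments.  Identical parameters and seeds yield
byte-identical cohorts.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .errors import ValidationError
from .records import DEPIC, HCIS, ChildPair, ChildRecord, ImmunizationEvent
from .reconcile import match_events
from .schedule import SchedulePolicy, due_date, doses_due

__all__ = [
    "DelayModel",
    "CohortParams",
    "ErrorModel",
    "RateEstimate",
    "generate_gold_cohort",
    "degrade_to_registry",
    "recover_error_rates",
]


@dataclass(frozen=True)
class DelayModel:
    """Days-late distribution for actual vaccination vs the appointment.

    With probability ``1 - p_delayed`` the child is vaccinated on the due
    date; otherwise the delay is a discretized right-skewed draw,
    ``ceil(Gamma(shape, scale))`` days (defaults give mean ~10 days).
    """

    p_delayed: float = 0.2
    gamma_shape: float = 2.0
    gamma_scale: float = 5.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_delayed <= 1.0:
            raise ValidationError("p_delayed must lie in [0, 1]")
        if self.gamma_shape <= 0 or self.gamma_scale <= 0:
            raise ValidationError("gamma parameters must be positive")

    def draw_days(self, rng: np.random.Generator) -> int:
        if rng.random() >= self.p_delayed:
            return 0
        return int(math.ceil(rng.gamma(self.gamma_shape, self.gamma_scale)))


@dataclass(frozen=True)
class CohortParams:
    """Study-cohort parameters for the gold (logbook) source."""

    n_children: int = 363
    birth_window: tuple[dt.date, dt.date] = (dt.date(2007, 5, 1), dt.date(2013, 4, 30))
    analysis_date: dt.date = dt.date(2013, 4, 30)
    attendance_prob: float = 0.95
    attendance_by_antigen: Mapping[str, float] = field(default_factory=dict)
    delay_model: DelayModel = field(default_factory=DelayModel)
    seed: int = 0

    def __post_init__(self) -> None:
        probs = [self.attendance_prob, *self.attendance_by_antigen.values()]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValidationError("attendance probabilities must lie in [0, 1]")
        start, end = self.birth_window
        if not start <= end <= self.analysis_date:
            raise ValidationError("require birth_window.start <= end <= analysis_date")
        if self.n_children < 1:
            raise ValidationError("n_children must be >= 1")

    def attendance(self, antigen: str) -> float:
        return self.attendance_by_antigen.get(antigen, self.attendance_prob)


@dataclass(frozen=True)
class ErrorModel:
    """Degradation applied when copying the gold cohort into the registry."""

    omission_prob: float = 0.3
    omission_multipliers: Mapping[str, float] = field(default_factory=dict)
    date_error_prob: float = 0.2
    date_error_max_days: int = 14
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.omission_prob <= 1.0:
            raise ValidationError("omission_prob must lie in [0, 1]")
        if not 0.0 <= self.date_error_prob <= 1.0:
            raise ValidationError("date_error_prob must lie in [0, 1]")
        if self.date_error_max_days < 1:
            raise ValidationError("date_error_max_days must be >= 1")
        if any(m < 0 for m in self.omission_multipliers.values()):
            raise ValidationError("omission multipliers must be >= 0")

    def omission(self, antigen: str) -> float:
        return min(1.0, self.omission_prob * self.omission_multipliers.get(antigen, 1.0))

    def draw_offset(self, rng: np.random.Generator) -> int:
        """Signed nonzero day offset, uniform over +-1..max."""
        magnitude = int(rng.integers(1, self.date_error_max_days + 1))
        sign = 1 if rng.random() < 0.5 else -1
        return sign * magnitude


def generate_gold_cohort(
    params: CohortParams, policy: SchedulePolicy
) -> list[ChildRecord]:
    """Simulate the logbook source.

    Each child gets a birth date uniform over the birth window; every dose
    due by the analysis date is attended with the antigen's attendance
    probability, yielding an event with the due date as appointment and a
    possibly delayed actual vaccination date (capped at the analysis date,
    since later vaccinations are not yet in any record).
    """
    rng = np.random.default_rng(params.seed)
    start, end = params.birth_window
    span = (end - start).days
    width = len(str(params.n_children))
    records = []
    for i in range(params.n_children):
        child_id = f"C{i + 1:0{width}d}"
        birth = start + dt.timedelta(days=int(rng.integers(0, span + 1)))
        events = []
        for dose in doses_due(policy, birth, params.analysis_date):
            if rng.random() >= params.attendance(dose.antigen):
                continue
            appt = due_date(policy, dose, birth)
            vacc = appt + dt.timedelta(days=params.delay_model.draw_days(rng))
            vacc = min(vacc, params.analysis_date)
            events.append(
                ImmunizationEvent(
                    child_id=child_id,
                    antigen=dose.antigen,
                    dose_index=dose.dose_index,
                    appointment_date=appt,
                    vaccination_date=vacc,
                    source=DEPIC,
                )
            )
        records.append(
            ChildRecord(child_id=child_id, birth_date=birth, events=tuple(events), source=DEPIC)
        )
    return records


def degrade_to_registry(
    gold: Sequence[ChildRecord], em: ErrorModel
) -> list[ChildRecord]:
    """Copy the gold cohort into a degraded registry source.

    Each gold event survives independently with probability
    ``1 - omission(antigen)``; each surviving vaccination date is perturbed
    with probability ``date_error_prob`` by a nonzero day offset (kept on or
    after the birth date, and never equal to the true date).
    """
    rng = np.random.default_rng(em.seed)
    out = []
    for rec in gold:
        events = []
        for e in rec.events:
            if rng.random() < em.omission(e.antigen):
                continue
            vacc = e.vaccination_date
            if vacc is not None and rng.random() < em.date_error_prob:
                shifted = vacc + dt.timedelta(days=em.draw_offset(rng))
                if shifted < rec.birth_date:
                    shifted = vacc + dt.timedelta(days=abs((shifted - vacc).days))
                vacc = shifted
            events.append(
                ImmunizationEvent(
                    child_id=e.child_id,
                    antigen=e.antigen,
                    dose_index=e.dose_index,
                    appointment_date=e.appointment_date,
                    vaccination_date=vacc,
                    source=HCIS,
                )
            )
        out.append(
            ChildRecord(
                child_id=rec.child_id,
                birth_date=rec.birth_date,
                events=tuple(events),
                source=HCIS,
            )
        )
    return out


@dataclass(frozen=True)
class RateEstimate:
    """A pooled binomial proportion with its standard error."""

    rate: float
    se: float
    n: int


def _binomial_estimate(k: int, n: int) -> Optional[RateEstimate]:
    if n == 0:
        return None
    p = k / n
    return RateEstimate(rate=p, se=math.sqrt(p * (1.0 - p) / n), n=n)


def recover_error_rates(
    pairs: Sequence[ChildPair], *, tolerance_days: int = 0
) -> tuple[Optional[RateEstimate], Optional[RateEstimate]]:
    """Estimate the injected error rates back from a reconciled cohort.

    Returns ``(omission_rate, date_error_rate)``: the pooled share of
    logbook records absent from the registry, and the pooled share of
    key-matched record pairs whose vaccination dates disagree.  Either
    estimate is absent when its denominator is zero.
    """
    if not pairs:
        raise ValidationError("empty cohort")
    n_depic = n_omitted = n_matched = n_date_mismatch = 0
    for pair in pairs:
        m = match_events(pair, tolerance_days=tolerance_days)
        n_depic += m.n_depic
        n_omitted += len(m.depic_only)
        n_matched += m.n_matched
        n_date_mismatch += m.n_matched - m.n_date_matched
    return (
        _binomial_estimate(n_omitted, n_depic),
        _binomial_estimate(n_date_mismatch, n_matched),
    )
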