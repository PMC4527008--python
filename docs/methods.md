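# Methods

## Record model and linkage

An immunization event is one vaccination record from one source: child id
(hospital number), antigen code, dose index, the appointment date set at
the previous visit, and the actual vaccination date. Sources are linked
per child by exact hospital-number equality; no probabilistic or
name-based matching is attempted. The logbook source is treated as the
complete reference throughout: children present only in the logbook form
pairs with an empty registry side, children present only in the registry
are reported but never paired, and on a cross-source birth-date conflict
the logbook value is retained and the conflict flagged. A logbook record
with no events at all is excluded at linkage (both metrics are undefined
for it) and listed in the link report.

Within a source, a child may not carry two events with the same
(antigen, dose index); registry rows lacking a dose index are assigned one
by ascending vaccination date (ties: appointment date, then input order),
taking the smallest indices not already claimed by explicitly numbered
rows. This mirrors how doses are listed on history cards and makes the
assignment deterministic. Dates parse strictly as ISO 8601; a switch
converts Thai Buddhist-era years (BE = CE + 543), which are common on Thai
source documents.

## Reconciliation metrics

Cross-source record identity is the key (antigen, dose index) — dates
cannot serve as identity because date disagreement is itself one of the
measured outcomes. For a child with n logbook records of which m are
key-matched in the registry and d of those agree on the actual vaccination
date:

- completeness difference = 100 (n − m) / n
- date consistency = 100 d / n

Both use the logbook count n as denominator, so registry-only records
affect neither metric (they are surfaced separately in the match result).
A date "agrees" when both actual vaccination dates are present and differ
by at most a tolerance, default 0 days (exact day); the tolerance is
configurable because audit practice varies. Appointment dates are never
compared. It follows directly that date consistency ≤ 100 − completeness
difference for every child.

Category bins partition [0, 100]:

- completeness: [0, 50], (50, 80], (80, 100), {100} — the top bin is
  reserved for children with no record reproduced at all;
- consistency: zero date matches (regardless of percentage), then
  (0, 50], (50, 70], (70, 100]. Zero matches takes precedence over the
  "≤50% matched" bin so the four bins stay disjoint.

Percentages carry full float precision through binning; rounding happens
only when a report cell is formatted. Cell formatting is decimal half-up
(not banker's) at one decimal for cohort tables, two decimals where finer
figures are conventional. One caveat worth recording: for a cohort of 363,
a count of 63 formats as 17.4%, while at least one published table of this
shape prints 17.3% for the same fraction; the package keeps consistent
half-up rounding rather than matching any one table's rounding.

## Schedule model and classification

The schedule is data, not code: an ordered list of (antigen, dose index,
recommended age in months) plus a single on-time window. Due dates use
calendar-month arithmetic with month-end clamping (31 Jan + 1 month →
28/29 Feb), matching how clinic appointments are actually set; fixed
30-day months were rejected as neither calendar-faithful nor simpler. The
shipped default covers the standard first-year antigens; the exact
recommended ages in the national guideline are configurable and the
defaults are a documented stand-in, not a claim about any guideline
edition.

Coverage at an analysis date: a dose is received if due and an event with
a vaccination date exists, missed if due without one, pending if not yet
due. A child is complete iff nothing is missed; pending doses never
penalize. Compliance refines coverage for children with nothing missed:
every received due dose must fall in [due date, due date + window]
(default window 28 days — one scheduling month; a dose given *early* also
violates its window) and vaccination dates must be non-decreasing in
schedule order. Any violation makes the child out of schedule, with the
first failing dose in schedule order reported. A child with no dose due
yet is pending. Children missing a due dose form a fourth, exhaustive
bucket, "incomplete", because the classical three-way taxonomy
(on time / out of schedule / pending) does not cover them; report layouts
can fold it into "out of schedule" via a switch when a three-way display
is wanted. Age groups for the compliance summary default to year-of-age
edges (12, 24, …, 72 months) with an open-ended top group.

## Synthetic cohort generator

The generator emulates the study design the analysis assumes — a cohort of
children with near-complete logbooks and a degraded registry copy — under
two independent random streams, so one gold cohort can be degraded under
several error models.

Gold source: births uniform over a configurable window (default spanning
the six years before a fixed analysis date, matching an under-six field
cohort); for every dose due by the analysis date the child attends with
probability 0.95 (default; per-antigen overrides supported), the
appointment is the due date, and the vaccination is delayed with
probability 0.2 by ⌈Gamma(2, 5)⌉ days (mean ≈ 10) — enough delay mass to
produce both on-time and out-of-schedule children. A delayed vaccination
is capped at the analysis date, since later vaccinations would not yet be
in any record.

Registry copy: each gold event is dropped with the omission probability
(default 0.30, with optional per-antigen multipliers to mimic the wide
antigen-to-antigen variation registries show), and each surviving
vaccination date is shifted with the date-error probability (default
0.20) by a uniform nonzero offset of ±1…14 days, kept on or after the
birth date and never equal to the true date. These defaults are documented
stand-ins: no quantitative error-process parameters for the real setting
were available to calibrate against.

What this does and does not show: the generator reproduces the
*statistical* structure (omission, transcription error, delay) but none of
the operational features of real data — no duplicate registrations, no
misrecorded antigens, no children present only in the registry, no OCR or
image-capture noise. Passing tests therefore validate the metric and
classification machinery, not any claim about a particular field setting.

`recover_error_rates` closes the loop: pooled over a reconciled cohort,
(logbook-only records / logbook records) estimates the omission rate and
(date-mismatched / key-matched pairs) the date-error rate, each with a
binomial standard error. Tests check recovery within three standard
errors at cohorts of 200 and 2000 children; 2000 is used as the standard
demonstration size because binomial noise there (< 1 percentage point SE)
is small against the injected rates while a run stays near-instant.

## Numerical and design notes

- Determinism: all randomness flows through seeded numpy generators;
  report files contain no timestamps or locale-dependent content, so equal
  configs and seeds give byte-identical outputs.
- Duplicate registry entries for one (child, antigen, dose) raise a
  validation error listing the offenders rather than being silently
  merged; silent merging would hide exactly the data-quality signal the
  pipeline measures.
- Degenerate inputs: an empty cohort, a zero denominator, or an analysis
  date before birth raise domain errors; a dose due for no child reports
  an absent (not zero) percentage.
- Known limitations: no catch-up scheduling, minimum-interval or
  combination-vaccine rules; no statistical comparison tests between
  sources; cause attribution (omission vs transcription) is only valid on
  synthetic data where the truth is known.
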