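"""Percentage formatting and report-bundle assembly.

All table percentages are rendered with half-up rounding (not banker's):
one decimal for cohort tables, two where a finer figure is conventional.
Rounding happens only here — every metric carries full precision until it
is formatted for a report cell.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

from .errors import DomainError

__all__ = ["format_pct"]


def format_pct(numerator: int, denominator: int, decimals: int = 1) -> str:
    """``100 * numerator / denominator`` rounded half-up to ``decimals``.

    >>> format_pct(88, 363)
    '24.2'
    >>> format_pct(64, 726, decimals=2)
    '8.82'
    """
    if denominator <= 0:
        raise DomainError("denominator must be positive")
    if not 0 <= numerator <= denominator:
        raise DomainError(f"numerator {numerator} outside [0, {denominator}]")
    exact = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    quantum = Decimal(1).scaleb(-decimals)
    return str(exact.quantize(quantum, rounding=ROUND_HALF_UP))
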