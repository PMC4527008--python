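"""Exception hierarchy shared across the package."""


class VaxreconError(Exception):
    """Base class for all package-specific errors."""


class ScheduleError(VaxreconError):
    """Malformed or inconsistent schedule configuration."""


class SchemaError(VaxreconError):
    """Input table is missing required columns."""


class ValidationError(VaxreconError):
    """Input rows violate data-model invariants."""


class DomainError(VaxreconError):
    """Arguments outside an operation's domain (e.g. zero denominator)."""
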