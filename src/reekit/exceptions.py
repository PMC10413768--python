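"""Exception hierarchy for reekit.

All library errors derive from :class:`ReekitError` so callers (and the CLI)
can catch one base class.  Errors are specific enough to name the offending
field or equation in their message.
"""

from __future__ import annotations


class ReekitError(Exception):
    """Base class for all reekit errors."""


class ConfigurationError(ReekitError):
    """Invalid configuration value (unknown unit, bad alpha, malformed spec)."""


class DomainError(ReekitError):
    """Input outside the mathematical domain of an operation."""


class DispatchError(ReekitError):
    """No equation variant matches a subject's sex/age."""


class InapplicableError(ReekitError):
    """An equation cannot be evaluated because a required field is absent."""

    def __init__(self, field: str, equation_id: str | None = None):
        self.field = field
        self.equation_id = equation_id
        where = f" for equation '{equation_id}'" if equation_id else ""
        super().__init__(f"missing required field '{field}'{where}")


class CoverageError(ReekitError):
    """Age outside the coverage of a growth-reference table."""


class CalibrationError(ReekitError):
    """Generator calibration is infeasible (e.g. implied noise variance < 0)."""


class DegenerateDataError(ReekitError):
    """Data unusable for a fit (zero variance, too few rows, rank problems)."""
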