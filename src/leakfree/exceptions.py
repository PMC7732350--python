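"""Exception hierarchy for leakfree.

All errors raised by the library derive from :class:`LeakfreeError` so that
callers (and the CLI) can distinguish configuration problems from numerical
failures.
"""


class LeakfreeError(Exception):
    """Base class for all leakfree errors."""


class InvalidGeometryError(LeakfreeError, ValueError):
    """Degenerate or physically impossible source/electrode geometry."""


class RankDeficiencyError(LeakfreeError, ValueError):
    """Unregularized inversion requested for a rank-deficient operator."""


class PSDViolationError(LeakfreeError, ValueError):
    """A spectral matrix is not positive semi-definite."""


class SizeCapError(LeakfreeError, ValueError):
    """Dense materialization refused because the problem exceeds the size cap."""


class ConfigurationError(LeakfreeError, ValueError):
    """Inconsistent or invalid configuration (e.g. mismatched lambda scales)."""


class InsufficientSamplesError(LeakfreeError, ValueError):
    """Too few samples to form the requested estimate."""


class UnstableRegionError(LeakfreeError, ValueError):
    """Too few Monte-Carlo replicates for a stable confidence region."""


class UndefinedQuotientError(LeakfreeError, ZeroDivisionError):
    """Rayleigh quotient requested with a vanishing denominator."""
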