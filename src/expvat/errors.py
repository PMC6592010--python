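"""Exception hierarchy for CPX data handling and estimation."""


class ExpvatError(Exception):
    """Base class for all package errors."""


class FormatError(ExpvatError):
    """A breath table is structurally malformed (missing columns, bad header)."""


class DataError(ExpvatError):
    """A breath table parsed but violates a data invariant (time order, signs)."""


class InsufficientDataError(ExpvatError):
    """Too few usable samples for the requested operation."""


class DomainError(ExpvatError):
    """An input value lies outside the mathematical domain of an operation."""


class FitError(ExpvatError):
    """A regression could not be computed (degenerate regressor)."""


class ValidationError(ExpvatError):
    """Simulation parameters violate their constraints.

    The message lists every violated constraint, not just the first.
    """
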