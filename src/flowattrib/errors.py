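"""Exception hierarchy.

All package-specific failures derive from :class:`FlowAttribError` so callers
can catch one base class; subclasses distinguish malformed inputs (tables,
configs) from domain violations (nonpositive fluxes, out-of-range fractions)
and degenerate statistical designs.
"""


class FlowAttribError(Exception):
    """Base class for all errors raised by flowattrib."""


class ValidationError(FlowAttribError):
    """An in-memory object violates one of its invariants."""


class TableFormatError(FlowAttribError):
    """A delimited table is missing columns or cannot be parsed."""


class DataError(FlowAttribError):
    """Required data are absent or incomplete for the requested operation."""


class DomainError(FlowAttribError):
    """A numeric argument lies outside the mathematical domain of a formula."""


class SingularDesignError(FlowAttribError):
    """A regression design matrix is rank-deficient (e.g. constant regressor)."""
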