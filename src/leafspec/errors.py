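"""Exception hierarchy shared across the package.

Every error raised on purpose derives from :class:`LeafspecError`, so callers
can catch one base class; the subclasses distinguish bad arguments, malformed
tabular input, and data that is formally valid but makes the requested
statistic undefined (zero variance, singular design, ...).
"""


class LeafspecError(Exception):
    """Base class for all errors raised by leafspec."""


class InvalidParameterError(LeafspecError, ValueError):
    """An argument violates a documented precondition."""


class SchemaError(LeafspecError, ValueError):
    """Tabular input does not match the expected layout (columns, bands, ids)."""


class DegenerateDataError(LeafspecError, ValueError):
    """Input is structurally valid but the requested quantity is undefined on it.

    Examples: a zero-variance spectrum handed to SNV, a constant response
    handed to R², a zero family variance handed to a genetic correlation.
    """
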