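"""Exception hierarchy shared across the package.

All user-input problems raise :class:`ValidationError` (or a subclass), which
the CLI maps to exit code 2; anything else is treated as an internal error.
"""


class ActirhythmError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(ActirhythmError):
    """Input values violate a documented precondition."""


class FormatError(ValidationError):
    """A file does not conform to the expected dialect (e.g. missing columns)."""


class EmptySeriesError(ValidationError):
    """All days of a subject were removed; the subject must be excluded."""
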