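"""Exception hierarchy.

The CLI maps these onto exit codes: usage errors -> 1, validation and
format errors -> 2, degeneracy errors -> 3.
"""


class CalveHMMError(Exception):
    """Base class for all package-specific errors."""


class FormatError(CalveHMMError):
    """A file is structurally malformed (missing columns, bad JSON, ...)."""


class ValidationError(CalveHMMError):
    """Content violates a domain invariant (negative count, hour gap, ...)."""


class InsufficientDataError(ValidationError):
    """Too few observations for the requested statistic."""


class AlignmentError(ValidationError):
    """Series length is incompatible with the requested window."""


class DegeneracyError(CalveHMMError):
    """A Markov chain has no unique stationary distribution."""
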