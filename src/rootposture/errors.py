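"""Exception hierarchy for rootposture.

Everything raised on bad user input derives from :class:`RootPostureError`
so callers can catch one type at a batch boundary.
"""


class RootPostureError(Exception):
    """Base class for all rootposture errors."""


class TraceParseError(RootPostureError):
    """A coordinate file could not be parsed; the message names the line."""


class SchemaError(RootPostureError):
    """A tabular input is missing required columns or is malformed."""


class DegenerateTraceError(RootPostureError):
    """A trace has too few distinct points to describe a centerline."""


class TooShortError(RootPostureError):
    """A root is too short for the requested operation (trim, tip window)."""


class ParameterError(RootPostureError):
    """An analysis parameter violates its precondition."""
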