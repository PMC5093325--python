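"""Exception hierarchy.

Everything derives from :class:`PeptubeError` (itself a ``ValueError``) so
callers can catch package errors with a single except clause while plain
``except ValueError`` keeps working.
"""


class PeptubeError(ValueError):
    """Base class for all errors raised by peptube."""


class ConfigError(PeptubeError):
    """Invalid simulation, measurement or experiment configuration."""


class UnitMismatchError(PeptubeError):
    """Concentrations with different unit tags were combined."""


class UnreachableTargetError(PeptubeError):
    """A target mixed concentration lies outside the inlet concentrations."""


class DegenerateDesignError(PeptubeError):
    """A regression was requested on a design with no spread in x."""


class UndefinedCriticalConcentrationError(PeptubeError):
    """Critical concentration k_off/k_on requested with k_on = 0."""


class ModeError(PeptubeError):
    """Operation valid only for the other bath mode (open vs closed)."""


class SchemaError(PeptubeError):
    """A trace table is structurally malformed (missing columns, empty file)."""


class TraceValidationError(PeptubeError):
    """A trace table is structurally fine but semantically invalid."""
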