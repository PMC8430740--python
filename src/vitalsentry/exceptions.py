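"""Exception hierarchy.

All input-validation failures derive from :class:`VitalSentryError` and the
matching builtin (``ValueError`` / ``RuntimeError``) so callers may catch
either.
"""


class VitalSentryError(Exception):
    """Base class for all errors raised by vitalsentry."""


class ConfigurationError(VitalSentryError, ValueError):
    """A configuration object violates one of its invariants."""


class RangeError(VitalSentryError, ValueError):
    """A window or episode falls outside the bounds of its series."""


class ShapeError(VitalSentryError, ValueError):
    """Array dimensions do not agree."""


class DegenerateChannelError(VitalSentryError, ValueError):
    """A channel is constant on the training data and cannot be scaled."""


class FormatError(VitalSentryError, ValueError):
    """A file does not conform to the expected column/row layout."""


class TrainingError(VitalSentryError, RuntimeError):
    """Optimization diverged (non-finite loss)."""
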