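"""Exception hierarchy for slopesync.

All errors derive from :class:`SlopeSyncError` and from ``ValueError`` so that
callers may catch either the package-specific or the generic class.
"""


class SlopeSyncError(ValueError):
    """Base class for all slopesync errors."""


class InvalidInputError(SlopeSyncError):
    """An argument violates a precondition (bad interval, trace too short...)."""


class InsufficientDataError(SlopeSyncError):
    """Not enough observations to compute the requested statistic."""


class DegenerateInputError(SlopeSyncError):
    """Input is formally valid but carries no usable signal (e.g. all-zero slopes)."""


class TraceParseError(SlopeSyncError):
    """A trace/trigger file could not be parsed; message names the offending line."""


class ConfigError(SlopeSyncError):
    """A configuration file contains unknown or malformed keys."""
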