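"""Exception hierarchy.

All failures raised by this package derive from :class:`TrophomitoError` so
pipeline callers can distinguish bad inputs (exit code 1) from internal
faults (exit code 2).
"""


class TrophomitoError(Exception):
    """Base class for every error raised by trophomito."""


class ConfigurationError(TrophomitoError):
    """A column mapping, config file or parameter set is unusable."""


class ParseError(TrophomitoError):
    """A cell of an input table could not be interpreted; carries row context."""


class ValidationError(TrophomitoError):
    """Structurally parseable input that violates a domain invariant."""
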