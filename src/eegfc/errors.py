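"""Exception hierarchy.

``ConfigurationError`` maps to CLI exit code 2, ``DataError`` (and its
subclass ``DegenerateInputError``) to exit code 3.
"""


class EegfcError(Exception):
    """Base class for all package errors."""


class ConfigurationError(EegfcError):
    """Invalid configuration: unknown mode/dialect, bad parameter values."""


class DataError(EegfcError):
    """Input data violates a contract (missing labels, too short, ...)."""


class DegenerateInputError(DataError):
    """Numerically degenerate input: constant envelope, near-zero regressor,
    colinear signal pair.  Raised rather than silently returning zero."""
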