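"""Exception hierarchy.

``ParameterError`` — a caller-supplied parameter is outside its valid range.
``DataError`` — the input data violate an invariant (non-finite values, missing
labels, ragged channels, ...).
``ConfigurationError`` — mutually inconsistent components (e.g. a law bank fitted
at a different embedding order than requested).
``NumericalError`` — a numerical routine failed (eigen-solver non-convergence).
"""


class LinlawError(Exception):
    """Base class for all package errors."""


class ParameterError(LinlawError, ValueError):
    pass


class DataError(LinlawError, ValueError):
    pass


class ConfigurationError(LinlawError, ValueError):
    pass


class NumericalError(LinlawError, RuntimeError):
    pass
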