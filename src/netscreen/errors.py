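"""Exception hierarchy.

Errors are grouped so the CLI can map them onto distinct exit codes:
data problems (missing/malformed input) vs compute problems (invalid
parameters, degenerate sampling, numerical failure).
"""


class NetscreenError(Exception):
    """Base class for all package errors."""


class DataError(NetscreenError):
    """Problems with input files or input content."""


class ParseError(DataError):
    """A file could not be parsed; message names the offending line."""


class ValidationError(DataError):
    """Input violated a structural invariant (empty set, bad weight, ...)."""


class FormatError(DataError):
    """A cache file is corrupt, truncated, or has the wrong magic/version."""


class ComputeError(NetscreenError):
    """Problems arising during computation."""


class ParameterError(ComputeError):
    """A numeric parameter is outside its admissible range."""


class SamplingError(ComputeError):
    """A null-model candidate pool was exhausted; message names the pool."""
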